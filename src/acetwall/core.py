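"""Annotated structure/trajectory containers and periodic geometry.

The containers are deliberately plain: numpy arrays indexed by a 0-based
atom index, with per-atom component labels (cellulose / hemicellulose /
lignin / water / ion) and functional-group labels (hydroxyl / carboxyl /
acetyl / none).  Boxes are orthorhombic; lengths are Å and times ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

COMPONENTS = ("cellulose", "hemicellulose", "lignin", "water", "ion")
GROUPS = ("hydroxyl", "carboxyl", "acetyl", "none")
#: functional groups may only decorate these components
GROUP_BEARING = ("hemicellulose", "lignin")


class AnnotationError(ValueError):
    """Raised when structure annotations violate the data model."""


def _as_box(box) -> np.ndarray:
    arr = np.asarray(box, dtype=float).reshape(3)
    if not np.all(arr > 0):
        raise ValueError(f"box lengths must be positive, got {arr}")
    return arr


@dataclass
class FrameBox:
    """Orthorhombic box lengths (Lx, Ly, Lz) in Å."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = _as_box(self.lengths)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass
class StructureModel:
    """Atom records for an annotated molecular structure.

    Attributes
    ----------
    elements : array of str
        Element symbols per atom.
    masses : array of float
        Atomic masses in g/mol; strictly positive.
    components : array of str
        One of :data:`COMPONENTS` per atom.
    groups : array of str
        Functional-group label; ``"none"`` for unlabelled atoms.
        Functional groups occur only on hemicellulose and lignin
        (cellulose is not acetylated in this model).
    resids : array of int
        Residue (molecule) identifiers.
    charges : array of float
        Formal charges in elementary-charge units.
    site_ids : array of int
        Functional-group instance identifier per atom (-1 when the atom
        belongs to no group).  Atoms sharing a site id form one hydroxyl /
        carboxyl / acetyl instance; abundance counts instances, not atoms.
    """

    elements: np.ndarray
    masses: np.ndarray
    components: np.ndarray
    groups: np.ndarray
    resids: np.ndarray
    charges: np.ndarray | None = None
    site_ids: np.ndarray | None = None
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        n = self.elements.size
        self.masses = np.asarray(self.masses, dtype=float)
        self.components = np.asarray(self.components, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.site_ids is None:
            self.site_ids = np.full(n, -1, dtype=int)
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        if self.names is None:
            self.names = self.elements.copy()
        self.names = np.asarray(self.names, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = self.n_atoms
        for arr, label in [
            (self.masses, "masses"),
            (self.components, "components"),
            (self.groups, "groups"),
            (self.resids, "resids"),
            (self.charges, "charges"),
            (self.site_ids, "site_ids"),
            (self.names, "names"),
        ]:
            if arr.shape != (n,):
                raise AnnotationError(f"{label} has shape {arr.shape}, expected ({n},)")
        if np.any(self.masses <= 0):
            raise AnnotationError("all atomic masses must be positive")
        bad = set(self.components) - set(COMPONENTS)
        if bad:
            raise AnnotationError(f"unknown component labels: {sorted(bad)}")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise AnnotationError(f"unknown group labels: {sorted(bad)}")
        grouped = self.groups != "none"
        offending = grouped & ~np.isin(self.components, GROUP_BEARING)
        if np.any(offending):
            raise AnnotationError(
                "functional-group labels are only valid on hemicellulose/lignin atoms"
            )

    @property
    def n_atoms(self) -> int:
        return self.elements.size

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def indices(self, component: str | None = None, group: str | None = None,
                element: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if component is not None:
            mask &= self.components == component
        if group is not None:
            mask &= self.groups == group
        if element is not None:
            mask &= self.elements == element
        return np.flatnonzero(mask)

    def select(self, name: str, component: str | None = None,
               group: str | None = None, element: str | None = None) -> "SelectionGroup":
        idx = self.indices(component=component, group=group, element=element)
        abundance = None
        if group is not None and group != "none":
            abundance = self.group_abundance(group)
        return SelectionGroup(name=name, indices=idx, abundance=abundance)

    def group_abundance(self, group: str) -> int:
        """Number of functional-group *instances* (not atoms).

        Uses explicit site ids when present; otherwise falls back to
        dividing the heavy-atom count by the atoms-per-instance of the
        group (hydroxyl 1, carboxyl 3, acetyl 4).
        """
        from .constants import HEAVY_ATOMS_PER_GROUP

        mask = self.groups == group
        if not mask.any():
            return 0
        sids = self.site_ids[mask]
        if np.all(sids >= 0):
            return int(np.unique(sids).size)
        heavy = mask & (self.elements != "H")
        per = HEAVY_ATOMS_PER_GROUP[group]
        count, rem = divmod(int(heavy.sum()), per)
        if rem:
            raise AnnotationError(
                f"heavy-atom count for group {group!r} not divisible by {per}; "
                "cannot infer abundance without site ids"
            )
        return count

    def functional_group_map(self) -> dict[str, "SelectionGroup"]:
        """Per-group selections with instance abundances."""
        out = {}
        for g in ("hydroxyl", "carboxyl", "acetyl"):
            idx = self.indices(group=g)
            if idx.size:
                out[g] = SelectionGroup(name=g, indices=idx,
                                        abundance=self.group_abundance(g))
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(
            elements=self.elements.copy(), masses=self.masses.copy(),
            components=self.components.copy(), groups=self.groups.copy(),
            resids=self.resids.copy(), charges=self.charges.copy(),
            site_ids=self.site_ids.copy(), names=self.names.copy(),
        )


@dataclass
class SelectionGroup:
    """A named set of atom indices, optionally with an instance abundance."""

    name: str
    indices: np.ndarray
    abundance: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.abundance is not None and self.abundance < 1:
            raise ValueError("abundance must be >= 1 when provided")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class Trajectory:
    """Frames of periodic-box coordinates bound to a :class:`StructureModel`.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``boxes`` is
    (n_frames, 3) and may vary frame to frame (semi-isotropic pressure
    coupling in the source data).  ``frame_interval`` is ns per frame and
    ``equilibration`` the leading stretch (ns) excluded from dynamical
    statistics (default 50 ns).
    """

    structure: StructureModel
    coords: np.ndarray
    boxes: np.ndarray
    frame_interval: float
    equilibration: float = 50.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise ValueError("coords second axis must match the structure atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        boxes = np.asarray(self.boxes, dtype=float)
        if boxes.ndim == 1:
            boxes = np.tile(boxes, (self.n_frames, 1))
        if boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if not np.all(boxes > 0):
            raise ValueError("box lengths must be positive")
        self.boxes = boxes
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time stamps in ns (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def production_mask(self) -> np.ndarray:
        """Boolean mask of post-equilibration frames (t > equilibration)."""
        return self.times >= self.equilibration

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return replace(self, coords=coords)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image_displacement(point_a, point_b, box) -> np.ndarray:
    """Minimum-image displacement vector from ``point_a`` to ``point_b``.

    Each component of the result lies in [-L/2, L/2); the returned vector
    is the shortest of all periodic images of ``b - a`` in an orthorhombic
    box.  Broadcasts over leading axes.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = np.asarray(point_b, dtype=float) - np.asarray(point_a, dtype=float)
    return (d + box / 2.0) % box - box / 2.0


def minimum_image_distance(point_a, point_b, box) -> np.ndarray:
    d = minimum_image_displacement(point_a, point_b, box)
    return np.linalg.norm(d, axis=-1)


def wrap_coords(coords, box) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    box = np.asarray(box, dtype=float)
    return np.mod(coords, box)


def periodic_neighbor_pairs(group_a: SelectionGroup, group_b: SelectionGroup,
                            coords: np.ndarray, box, cutoff: float,
                            dedupe: bool | None = None):
    """All atom pairs (a in A, b in B) with minimum-image distance <= cutoff.

    Uses a periodic KD-tree when ``cutoff <= min(L)/2``; otherwise warns
    and falls back to a brute-force minimum-image scan.  Self-pairs
    (identical atom index) are excluded when the groups overlap.  When the
    two groups contain the same index set, each unordered pair is emitted
    once.

    Returns a list of ``(index_a, index_b, distance)`` tuples.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia = group_a.indices
    ib = group_b.indices
    if ia.size == 0 or ib.size == 0:
        return []
    if dedupe is None:
        dedupe = ia.size == ib.size and np.array_equal(np.sort(ia), np.sort(ib))

    if cutoff <= box.min() / 2.0:
        wa = wrap_coords(coords[ia], box)
        wb = wrap_coords(coords[ib], box)
        # cKDTree requires strictly inside [0, L)
        wa = np.where(wa >= box, 0.0, wa)
        wb = np.where(wb >= box, 0.0, wb)
        tree_b = cKDTree(wb, boxsize=box)
        neighbours = cKDTree(wa, boxsize=box).query_ball_tree(tree_b, r=cutoff)
        pairs = []
        for ka, hits in enumerate(neighbours):
            a_idx = ia[ka]
            for kb in hits:
                b_idx = ib[kb]
                if a_idx == b_idx:
                    continue
                if dedupe and a_idx > b_idx:
                    continue
                dist = float(minimum_image_distance(coords[a_idx], coords[b_idx], box))
                if dist <= cutoff:
                    pairs.append((int(a_idx), int(b_idx), dist))
        return pairs

    warnings.warn(
        f"cutoff {cutoff} Å exceeds half the smallest box length "
        f"({box.min() / 2:.2f} Å); using brute-force minimum-image search",
        stacklevel=2,
    )
    disp = minimum_image_displacement(coords[ia][:, None, :], coords[ib][None, :, :], box)
    dist = np.linalg.norm(disp, axis=-1)
    pairs = []
    for ka, kb in zip(*np.nonzero(dist <= cutoff)):
        a_idx, b_idx = int(ia[ka]), int(ib[kb])
        if a_idx == b_idx:
            continue
        if dedupe and a_idx > b_idx:
            continue
        pairs.append((a_idx, b_idx, float(dist[ka, kb])))
    return pairs
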