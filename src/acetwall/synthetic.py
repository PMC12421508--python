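"""Synthetic trajectory generators with known ground truth.

Each generator emulates one statistical structure the analysis stages
assume — free diffusion, two-state binding kinetics, Boltzmann-weighted
site occupancy, and a toy cell-wall configuration — and returns a
machine-readable ground-truth record alongside the trajectory.  These
are statistical stand-ins, not physical simulations: no force field, no
excluded volume, no electrostatics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ATOMIC_MASSES, DEFAULT_CONSTANTS, Constants, MW_H2O
from .core import StructureModel, Trajectory, minimum_image_distance


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_sidecar(record, path: str | Path) -> None:
    """Write a ground-truth record as a JSON sidecar file."""
    payload = dataclasses.asdict(record)
    payload["__type__"] = type(record).__name__
    Path(path).write_text(json.dumps(payload, default=_json_default, indent=1))


# ---------------------------------------------------------------------------
# Brownian tracers


@dataclass
class BrownianSpec:
    """Free Gaussian random walks in a periodic box.

    Per-step per-dimension displacement variance is ``2 * d_true * dt``,
    so the 3D mean-squared displacement grows as ``6 * d_true * t``.
    """

    d_true: float              # Å²/ns
    n_particles: int = 500
    n_frames: int = 1000
    frame_interval: float = 0.1   # ns
    box: tuple[float, float, float] = (60.0, 60.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_true) or self.d_true < 0:
            raise ValueError("d_true must be finite and non-negative")
        if self.n_particles < 1 or self.n_frames < 1:
            raise ValueError("particle and frame counts must be positive")
        if self.frame_interval <= 0 or not np.isfinite(self.frame_interval):
            raise ValueError("frame interval must be positive and finite")


@dataclass
class BrownianTruth:
    d_true: float
    n_particles: int
    n_frames: int
    frame_interval: float
    seed: int


def _tracer_structure(n: int) -> StructureModel:
    return StructureModel(
        elements=np.full(n, "O", dtype=object),
        masses=np.full(n, MW_H2O),
        components=np.full(n, "water", dtype=object),
        groups=np.full(n, "none", dtype=object),
        resids=np.arange(1, n + 1),
        names=np.full(n, "OW", dtype=object),
    )


def gen_brownian(spec: BrownianSpec, equilibration: float = 0.0):
    """Generate wrapped Brownian tracer trajectories.

    Returns ``(trajectory, truth)`` where the trajectory holds wrapped
    coordinates (as saved MD frames would) and ``truth`` records the
    planted diffusion coefficient.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    start = rng.uniform(0.0, box, size=(spec.n_particles, 3))
    sigma = np.sqrt(2.0 * spec.d_true * spec.frame_interval)
    steps = rng.normal(0.0, sigma, size=(spec.n_frames - 1, spec.n_particles, 3)) \
        if spec.n_frames > 1 else np.zeros((0, spec.n_particles, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    coords = np.mod(unwrapped, box)
    traj = Trajectory(structure=_tracer_structure(spec.n_particles),
                      coords=coords, boxes=box, frame_interval=spec.frame_interval,
                      equilibration=equilibration)
    truth = BrownianTruth(spec.d_true, spec.n_particles, spec.n_frames,
                          spec.frame_interval, spec.seed)
    return traj, truth


# ---------------------------------------------------------------------------
# two-state binding kinetics


@dataclass
class BindingSpec:
    """Ion <-> site binding as a two-state Markov chain.

    Run lengths in each state are geometric in frames; mean dwell times
    are specified in ns and converted through the frame interval.
    """

    n_sites: int = 10
    n_ions: int = 50
    mean_bound_dwell: float = 10.0     # ns
    mean_unbound_dwell: float = 2.0    # ns
    contact_radius: float = 3.0        # Å
    n_frames: int = 2000
    frame_interval: float = 0.2        # ns
    box: tuple[float, float, float] = (80.0, 80.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_bound_dwell <= 0 or self.mean_unbound_dwell < 0:
            raise ValueError("dwell means must be positive (unbound may be ~0)")
        if self.contact_radius >= min(self.box) / 2:
            raise ValueError("contact radius must be below half the box")


@dataclass
class BindingTruth:
    mean_bound_dwell: float
    mean_unbound_dwell: float
    frame_interval: float
    #: per bound run: (ion index, start frame, length in frames, censored)
    bound_runs: np.ndarray = field(default_factory=lambda: np.empty((0, 4), dtype=int))

    @property
    def uncensored_durations(self) -> np.ndarray:
        runs = self.bound_runs
        keep = runs[:, 3] == 0
        return runs[keep, 2] * self.frame_interval


def _binding_structure(n_sites: int, n_ions: int) -> StructureModel:
    n = n_sites + n_ions
    elements = np.array(["O"] * n_sites + ["NA"] * n_ions, dtype=object)
    masses = np.array([ATOMIC_MASSES["O"]] * n_sites
                      + [ATOMIC_MASSES["NA"]] * n_ions)
    components = np.array(["hemicellulose"] * n_sites + ["ion"] * n_ions, dtype=object)
    groups = np.array(["carboxyl"] * n_sites + ["none"] * n_ions, dtype=object)
    site_ids = np.array(list(range(n_sites)) + [-1] * n_ions)
    charges = np.array([0.0] * n_sites + [1.0] * n_ions)
    names = np.array(["OC1"] * n_sites + ["NA"] * n_ions, dtype=object)
    return StructureModel(elements=elements, masses=masses, components=components,
                          groups=groups, resids=np.arange(1, n + 1),
                          charges=charges, site_ids=site_ids, names=names)


def _grid_positions(n: int, spacing: float, origin: np.ndarray) -> np.ndarray:
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append(origin + spacing * np.array([i, j, k], dtype=float))
                if len(pts) == n:
                    return np.array(pts)
    return np.array(pts)


def gen_binding(spec: BindingSpec):
    """Generate teleporting ions with geometric bound/unbound run lengths."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    # sites clustered in a low-z slab; the "far" state lives in a high-z slab.
    # 12 Å spacing keeps a bound ion (<= 3 Å from its site) more than 6 Å
    # from every other site, so contact runs map 1:1 onto the Markov state
    sites = _grid_positions(spec.n_sites, 12.0, np.array([6.0, 6.0, 6.0]))
    if sites[:, 2].max() + spec.contact_radius + 10.0 > box[2] - 10.0:
        raise ValueError("box too small to place an unbound region away from sites")
    far_zlo = sites[:, 2].max() + spec.contact_radius + 10.0
    far_zhi = box[2] - 5.0

    m_b = spec.mean_bound_dwell / spec.frame_interval     # mean frames bound
    m_u = spec.mean_unbound_dwell / spec.frame_interval
    p_leave_b = min(1.0, 1.0 / m_b)
    p_leave_u = 1.0 if m_u <= 1.0 else 1.0 / m_u

    n_i, n_f = spec.n_ions, spec.n_frames
    p_bound0 = m_b / (m_b + max(m_u, 1e-12))
    bound = rng.random(n_i) < p_bound0
    which_site = rng.integers(0, spec.n_sites, size=n_i)

    coords = np.empty((n_f, spec.n_sites + n_i, 3))
    states = np.empty((n_f, n_i), dtype=bool)

    def ion_positions(bound_mask, site_idx):
        pos = np.empty((n_i, 3))
        nb = int(bound_mask.sum())
        if nb:
            r = rng.uniform(0.3, spec.contact_radius, size=nb)
            v = rng.normal(size=(nb, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pos[bound_mask] = sites[site_idx[bound_mask]] + r[:, None] * v
        nf = n_i - nb
        if nf:
            pos[~bound_mask, 0] = rng.uniform(5, box[0] - 5, size=nf)
            pos[~bound_mask, 1] = rng.uniform(5, box[1] - 5, size=nf)
            pos[~bound_mask, 2] = rng.uniform(far_zlo, far_zhi, size=nf)
        return pos

    for f in range(n_f):
        states[f] = bound
        coords[f, :spec.n_sites] = sites
        coords[f, spec.n_sites:] = ion_positions(bound, which_site)
        u = rng.random(n_i)
        leave = np.where(bound, u < p_leave_b, u < p_leave_u)
        if m_u == 0:
            # unbound residence below frame resolution: rebind immediately
            # at a fresh site, so every frame is observed bound
            rebind = leave & bound
            which_site[rebind] = rng.integers(0, spec.n_sites,
                                              size=int(rebind.sum()))
            bound[:] = True
            continue
        newly_bound = leave & ~bound
        which_site[newly_bound] = rng.integers(0, spec.n_sites,
                                               size=int(newly_bound.sum()))
        bound = np.where(leave, ~bound, bound)

    runs = []
    for i in range(n_i):
        s = states[:, i].astype(int)
        edges = np.flatnonzero(np.diff(s) != 0) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [n_f]])
        for a, b in zip(starts, ends):
            if s[a]:
                censored = int(a == 0 or b == n_f)
                runs.append((i, a, b - a, censored))
    truth = BindingTruth(spec.mean_bound_dwell, spec.mean_unbound_dwell,
                         spec.frame_interval,
                         np.array(runs, dtype=int).reshape(-1, 4))
    traj = Trajectory(structure=_binding_structure(spec.n_sites, spec.n_ions),
                      coords=coords, boxes=box,
                      frame_interval=spec.frame_interval, equilibration=0.0)
    return traj, truth


# ---------------------------------------------------------------------------
# Boltzmann-weighted site occupancy


@dataclass
class BoltzmannSiteSpec:
    """Ions partitioned among functional-group sites by Boltzmann weights.

    Each frame, each ion independently occupies a site of type ``s`` with
    probability proportional to ``count_s * exp(-E_s / RT)``; occupancy
    is resampled every frame (no kinetics), which makes this the ground
    truth for thermodynamic estimators rather than dwell times.
    """

    site_counts: dict[str, int] = field(default_factory=lambda: {
        "carboxyl": 150, "acetyl": 600, "hydroxyl": 600})
    site_energies: dict[str, float] = field(default_factory=lambda: {
        "carboxyl": 0.0, "acetyl": 1.18, "hydroxyl": 2.26})
    n_ions: int = 150
    n_frames: int = 400
    frame_interval: float = 0.5   # ns
    spacing: float = 14.0         # Å between site grid points
    constants: Constants = DEFAULT_CONSTANTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.site_counts or sum(self.site_counts.values()) == 0:
            raise ValueError("at least one site is required")
        if any(c < 1 for c in self.site_counts.values()):
            raise ValueError("site counts must be >= 1")
        if not all(np.isfinite(list(self.site_energies.values()))):
            raise ValueError("site energies must be finite")
        if set(self.site_counts) != set(self.site_energies):
            raise ValueError("site_counts and site_energies must share keys")


@dataclass
class BoltzmannTruth:
    #: planted relative free energy per site type (kcal/mol vs carboxyl)
    delta_g: dict[str, float]
    temperature: float
    n_ions: int
    n_frames: int


def gen_boltzmann_sites(spec: BoltzmannSiteSpec):
    """Generate per-frame categorical ion placements over typed sites."""
    rng = np.random.default_rng(spec.seed)
    types = sorted(spec.site_counts)
    counts = np.array([spec.site_counts[t] for t in types])
    energies = np.array([spec.site_energies[t] for t in types])
    n_sites = int(counts.sum())

    positions = _grid_positions(n_sites, spec.spacing, np.full(3, spec.spacing / 2))
    box = np.full(3, positions.max() + spec.spacing / 2 + 6.0)
    type_of_site = np.repeat(np.arange(len(types)), counts)
    rng.shuffle(type_of_site)
    site_index_by_type = [np.flatnonzero(type_of_site == k) for k in range(len(types))]

    weights = counts * np.exp(-energies / spec.constants.kT)
    p_type = weights / weights.sum()

    n = n_sites + spec.n_ions
    elements = np.array(["O"] * n_sites + ["NA"] * spec.n_ions, dtype=object)
    masses = np.array([ATOMIC_MASSES["O"]] * n_sites
                      + [ATOMIC_MASSES["NA"]] * spec.n_ions)
    components = np.array(["hemicellulose"] * n_sites + ["ion"] * spec.n_ions,
                          dtype=object)
    groups = np.array([types[k] for k in type_of_site] + ["none"] * spec.n_ions,
                      dtype=object)
    site_ids = np.array(list(range(n_sites)) + [-1] * spec.n_ions)
    structure = StructureModel(elements=elements, masses=masses,
                               components=components, groups=groups,
                               resids=np.arange(1, n + 1), site_ids=site_ids,
                               names=np.array(["OS"] * n_sites + ["NA"] * spec.n_ions,
                                              dtype=object))

    coords = np.empty((spec.n_frames, n, 3))
    coords[:, :n_sites] = positions
    for f in range(spec.n_frames):
        ks = rng.choice(len(types), size=spec.n_ions, p=p_type)
        for i, k in enumerate(ks):
            site = rng.choice(site_index_by_type[k])
            # bell-shaped coordination distance: a clear RDF peak near 2 Å
            # with an exact-zero gap out to the next site, so the first
            # minimum is unambiguous for every site type
            r = float(np.clip(rng.normal(2.0, 0.35), 1.0, 2.9))
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            coords[f, n_sites + i] = positions[site] + r * v

    truth = BoltzmannTruth(
        delta_g={t: spec.site_energies[t] - spec.site_energies.get("carboxyl", 0.0)
                 for t in types},
        temperature=spec.constants.temperature,
        n_ions=spec.n_ions, n_frames=spec.n_frames)
    traj = Trajectory(structure=structure, coords=coords, boxes=box,
                      frame_interval=spec.frame_interval, equilibration=0.0)
    return traj, truth


# ---------------------------------------------------------------------------
# toy cell wall


@dataclass
class ToyCellWallSpec:
    """A single-frame toy wall with exactly known exposure distances.

    Hydroxyl sites sit on the slab surface; the i-th site's nearest water
    oxygen is placed at exactly ``hydroxyl_water_distances[i]`` Å.  Bulk
    waters live far (> 5 Å) from every polymer atom, bound-shell waters
    close to the slab, so the bulk fraction is known by construction.
    """

    hydroxyl_water_distances: tuple[float, ...] = (2.5, 4.0, 7.0, 10.0)
    n_carboxyl: int = 2
    n_bulk_water: int = 10
    n_bound_water: int = 10
    n_ions: int = 4
    box: tuple[float, float, float] = (80.0, 120.0, 80.0)
    seed: int = 0


@dataclass
class ToyCellWallTruth:
    #: exact minimum-image distance from each hydroxyl O to its nearest water O
    exposure_distances: np.ndarray
    #: per water molecule: True if >= 5 Å from every polymer atom
    water_is_bulk: np.ndarray
    bulk_fraction_percent: float


def gen_toy_cellwall(spec: ToyCellWallSpec):
    """Build the toy wall and audit its ground truth by brute force."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    dists = np.asarray(spec.hydroxyl_water_distances, dtype=float)
    n_oh = dists.size
    z_surf = 16.0
    lateral = 2 * (dists.max() if n_oh else 5.0) + 4.0

    rows = []  # (element, name, component, group, site_id, resid, charge, pos)
    resid = 0
    site_id = 0

    # cellulose slab beads, x in [5, 25]
    for ix in range(5):
        for iz in range(3):
            resid += 1
            rows.append(("C", "CB", "cellulose", "none", -1, resid, 0.0,
                         np.array([5.0 + 4 * ix, 10.0, 8.0 + 3 * iz])))

    # hemicellulose hydroxyl sites along y at x = 40, on the surface
    oh_positions = []
    for i in range(n_oh):
        resid += 1
        pos = np.array([40.0, 6.0 + i * lateral, z_surf])
        if pos[1] > box[1] - 6:
            raise ValueError("box too small for the requested hydroxyl spacing")
        oh_positions.append(pos)
        rows.append(("O", "OH", "hemicellulose", "hydroxyl", site_id, resid, 0.0, pos))
        rows.append(("H", "HO", "hemicellulose", "hydroxyl", site_id, resid, 0.0,
                     pos + np.array([0.0, 0.0, -0.95])))
        site_id += 1

    # lignin carboxyl sites at x = 60
    for i in range(spec.n_carboxyl):
        resid += 1
        pos = np.array([60.0, 8.0 + 6.0 * i, z_surf])
        rows.append(("C", "CC", "lignin", "carboxyl", site_id, resid, 0.0, pos))
        rows.append(("O", "OC1", "lignin", "carboxyl", site_id, resid, -0.5,
                     pos + np.array([0.8, 0.8, 0.0])))
        rows.append(("O", "OC2", "lignin", "carboxyl", site_id, resid, -0.5,
                     pos + np.array([-0.8, 0.8, 0.0])))
        site_id += 1

    n_polymer_atoms = len(rows)
    polymer_pos = np.array([r[7] for r in rows])

    def add_water(opos):
        nonlocal resid
        resid += 1
        rows.append(("O", "OW", "water", "none", -1, resid, 0.0, opos))
        rows.append(("H", "HW1", "water", "none", -1, resid, 0.0,
                     opos + np.array([0.76, 0.59, 0.0])))
        rows.append(("H", "HW2", "water", "none", -1, resid, 0.0,
                     opos + np.array([-0.76, 0.59, 0.0])))

    # designated nearest water for each hydroxyl, straight up from the surface
    for pos, d in zip(oh_positions, dists):
        add_water(pos + np.array([0.0, 0.0, d]))
    # extra bound-shell waters hugging the cellulose slab
    for _ in range(spec.n_bound_water):
        base = polymer_pos[rng.integers(0, 15)]
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        add_water(base + v * rng.uniform(2.0, 3.5))
    # bulk waters high above everything
    z_bulk_lo = z_surf + max(dists.max() if n_oh else 0.0, 5.0) + 6.0
    for _ in range(spec.n_bulk_water):
        add_water(np.array([rng.uniform(5, box[0] - 5), rng.uniform(5, box[1] - 5),
                            rng.uniform(z_bulk_lo, min(z_bulk_lo + 15, box[2] - 10))]))
    for _ in range(spec.n_ions):
        resid += 1
        rows.append(("NA", "NA", "ion", "none", -1, resid, 1.0,
                     np.array([rng.uniform(5, box[0] - 5), rng.uniform(5, box[1] - 5),
                               rng.uniform(z_bulk_lo, min(z_bulk_lo + 15, box[2] - 10))])))

    structure = StructureModel(
        elements=np.array([r[0] for r in rows], dtype=object),
        masses=np.array([ATOMIC_MASSES[r[0]] for r in rows]),
        components=np.array([r[2] for r in rows], dtype=object),
        groups=np.array([r[3] for r in rows], dtype=object),
        resids=np.array([r[5] for r in rows]),
        charges=np.array([r[6] for r in rows]),
        site_ids=np.array([r[4] for r in rows]),
        names=np.array([r[1] for r in rows], dtype=object),
    )
    coords = np.array([r[7] for r in rows])[None, :, :]
    traj = Trajectory(structure=structure, coords=coords, boxes=box,
                      frame_interval=1.0, equilibration=0.0)

    # ground-truth audit, brute force
    water_o = structure.indices(component="water", element="O")
    water_pos = coords[0][water_o]
    exposure = np.array([
        minimum_image_distance(p, water_pos, box).min() for p in oh_positions
    ]) if n_oh else np.empty(0)
    if n_oh and not np.allclose(exposure, dists, atol=1e-9):
        raise RuntimeError("toy wall construction violated prescribed exposure distances")
    poly_mask = np.isin(structure.components[:coords.shape[1]],
                        ("cellulose", "hemicellulose", "lignin"))
    poly_pos = coords[0][poly_mask]
    is_bulk = np.array([
        minimum_image_distance(p, poly_pos, box).min() >= 5.0 for p in water_pos
    ])
    truth = ToyCellWallTruth(exposure_distances=exposure, water_is_bulk=is_bulk,
                             bulk_fraction_percent=100.0 * is_bulk.mean())
    return traj, truth
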