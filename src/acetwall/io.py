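"""File I/O: standard topology/trajectory formats via MDAnalysis.

Structures travel as PDB or GRO topologies and DCD or XTC coordinate
trajectories.  Annotation is rule-driven: residue-name patterns map to
components and atom-name patterns to functional groups, so archive files
and synthetic fixtures load through the same path.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .constants import ATOMIC_MASSES
from .core import AnnotationError, StructureModel, Trajectory


@dataclass
class AnnotationRules:
    """Residue/atom-name pattern rules mapping file contents to labels.

    ``component_rules`` maps residue-name glob patterns to component
    labels; ``group_rules`` maps atom-name glob patterns to functional
    groups (checked only on hemicellulose/lignin atoms); ``charge_rules``
    maps atom-name patterns to formal charges.  First match wins.
    """

    component_rules: list[tuple[str, str]] = field(default_factory=lambda: [
        ("CEL*", "cellulose"),
        ("HEM*", "hemicellulose"),
        ("XYL*", "hemicellulose"),
        ("LIG*", "lignin"),
        ("TIP*", "water"),
        ("HOH", "water"),
        ("SOL", "water"),
        ("WAT", "water"),
        ("SOD", "ion"),
        ("NA*", "ion"),
        ("FE*", "ion"),
        ("ION", "ion"),
    ])
    group_rules: list[tuple[str, str]] = field(default_factory=lambda: [
        ("OH*", "hydroxyl"),
        ("HO*", "hydroxyl"),
        ("CC*", "carboxyl"),
        ("OC*", "carboxyl"),
        ("CA*", "acetyl"),   # carbonyl carbon
        ("OA*", "acetyl"),   # carbonyl oxygen
        ("OE*", "acetyl"),   # ester oxygen (former hydroxyl O)
        ("CM*", "acetyl"),   # methyl carbon
        ("HM*", "acetyl"),
    ])
    charge_rules: list[tuple[str, float]] = field(default_factory=lambda: [
        ("NA*", 1.0),
        ("FE*", 3.0),
        ("OC1", -0.5),
        ("OC2", -0.5),
    ])
    default_component: str | None = None

    def component_for(self, resname: str) -> str | None:
        for pat, comp in self.component_rules:
            if fnmatch.fnmatch(resname.upper(), pat):
                return comp
        return self.default_component

    def group_for(self, atomname: str) -> str:
        for pat, grp in self.group_rules:
            if fnmatch.fnmatch(atomname.upper(), pat):
                return grp
        return "none"

    def charge_for(self, atomname: str) -> float:
        for pat, q in self.charge_rules:
            if fnmatch.fnmatch(atomname.upper(), pat):
                return q
        return 0.0


DEFAULT_RULES = AnnotationRules()


def _element_from_name(name: str) -> str:
    name = name.strip()
    if name[:2].upper() in ("NA", "FE") and len(name) <= 3:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise AnnotationError(f"cannot infer element from atom name {name!r}")


def load_structure(topology: str | Path, rules: AnnotationRules | None = None,
                   required_groups: tuple[str, ...] = ()) -> StructureModel:
    """Read a topology file (PDB/GRO/PSF) into an annotated StructureModel.

    Atoms whose residue matches no component rule raise unless the rules
    define a default component; functional-group labels are attached only
    on hemicellulose/lignin atoms.  ``required_groups`` may list component
    or group labels that must match at least one atom.
    """
    rules = rules or DEFAULT_RULES
    u = mda.Universe(str(topology))
    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)

    components = np.empty(n, dtype=object)
    groups = np.empty(n, dtype=object)
    elements = np.empty(n, dtype=object)
    charges = np.empty(n, dtype=float)
    for i in range(n):
        comp = rules.component_for(resnames[i])
        if comp is None:
            raise AnnotationError(
                f"residue {resnames[i]!r} matches no component rule"
            )
        components[i] = comp
        elements[i] = _element_from_name(names[i])
        groups[i] = rules.group_for(names[i]) if comp in ("hemicellulose", "lignin") else "none"
        charges[i] = rules.charge_for(names[i]) if comp == "ion" else 0.0

    try:
        masses = np.array([ATOMIC_MASSES[e] for e in elements], dtype=float)
    except KeyError as exc:  # pragma: no cover - depends on input file
        raise AnnotationError(f"no mass tabulated for element {exc}") from exc

    structure = StructureModel(
        elements=elements, masses=masses, components=components,
        groups=groups, resids=resids, charges=charges, names=names,
    )
    for label in required_groups:
        if label in ("hydroxyl", "carboxyl", "acetyl"):
            hit = np.any(structure.groups == label)
        else:
            hit = np.any(structure.components == label)
        if not hit:
            raise AnnotationError(f"required selection {label!r} matched zero atoms")
    return structure


def load_trajectory(topology: str | Path, trajectory: str | Path,
                    rules: AnnotationRules | None = None,
                    frame_interval: float | None = None,
                    equilibration: float = 50.0) -> Trajectory:
    """Read topology + coordinate trajectory into a :class:`Trajectory`.

    ``frame_interval`` is in ns; when omitted it is taken from the file's
    time step metadata (converted from ps) and must be present there.
    """
    structure = load_structure(topology, rules=rules)
    u = mda.Universe(str(topology), str(trajectory))
    coords, boxes = [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise ValueError("trajectory frame has no valid box dimensions")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise ValueError("only orthorhombic boxes are supported")
        boxes.append(np.asarray(dims[:3], dtype=float))
    if frame_interval is None:
        dt_ps = getattr(u.trajectory, "dt", None)
        if not dt_ps:
            raise ValueError("frame interval not present in file; pass frame_interval")
        frame_interval = float(dt_ps) / 1000.0
    return Trajectory(structure=structure, coords=np.array(coords),
                      boxes=np.array(boxes), frame_interval=frame_interval,
                      equilibration=equilibration)


def _universe_from(structure: StructureModel, trajectory: Trajectory | None = None):
    n = structure.n_atoms
    resids = structure.resids
    _, res_index = np.unique(resids, return_inverse=True)
    n_res = int(res_index.max()) + 1 if n else 0
    u = mda.Universe.empty(n_atoms=n, n_residues=n_res,
                           atom_resindex=res_index,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in structure.names])
    u.add_TopologyAttr("elements", [str(x) for x in structure.elements])
    u.add_TopologyAttr("masses", structure.masses)
    resname_by_res = np.empty(n_res, dtype=object)
    comp_to_resname = {"cellulose": "CEL", "hemicellulose": "HEM",
                       "lignin": "LIG", "water": "TIP3", "ion": "ION"}
    for i in range(n):
        comp = structure.components[i]
        rn = comp_to_resname[comp]
        if comp == "ion":
            rn = "SOD" if structure.elements[i] == "NA" else "FE"
        resname_by_res[res_index[i]] = rn
    u.add_TopologyAttr("resnames", [str(x) for x in resname_by_res])
    u.add_TopologyAttr("resids", np.unique(resids))
    return u


def write_fixture(trajectory: Trajectory, topology_path: str | Path,
                  trajectory_path: str | Path | None = None) -> None:
    """Write a trajectory as a standard-format fixture.

    The topology (with frame-0 coordinates) goes to ``topology_path``
    (PDB or GRO by extension); frames go to ``trajectory_path`` (DCD or
    XTC) when given.
    """
    u = _universe_from(trajectory.structure)
    u.atoms.positions = trajectory.coords[0]
    u.dimensions = [*trajectory.boxes[0], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n_atoms=trajectory.n_atoms) as w:
                for f in range(trajectory.n_frames):
                    u.atoms.positions = trajectory.coords[f]
                    u.dimensions = [*trajectory.boxes[f], 90.0, 90.0, 90.0]
                    w.write(u.atoms)
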