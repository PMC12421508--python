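"""Acetylation model construction: exposure-based hydroxyl selection,
weight-percent-gain and moisture bookkeeping, and constant-volume water
removal.

Acetylation replaces a hydroxyl group's hydrogen with an acetyl group
(-C(=O)CH3): six atoms are added and one removed (net +5), and the dry
mass grows by 43.045 - 1.008 = 42.037 g/mol per site.  Only hydroxyls on
hemicellulose and lignin are eligible; cellulose is not acetylated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    A3_TO_CM3,
    ACETYLATION_ATOM_DELTA,
    ACETYLATION_MASS_DELTA,
    ATOMIC_MASSES,
    ATOMS_PER_WATER,
    DEFAULT_CONSTANTS,
    Constants,
)
from .core import (
    SelectionGroup,
    StructureModel,
    Trajectory,
    minimum_image_distance,
)


def compute_wpg(m_pre: float, m_post: float) -> float:
    """Percent dry weight gain, ``100 * (m_post - m_pre) / m_pre``."""
    if m_pre <= 0:
        raise ValueError("pre-acetylation dry mass must be positive")
    return 100.0 * (m_post - m_pre) / m_pre


def waters_to_remove(delta_volume: float,
                     constants: Constants = DEFAULT_CONSTANTS) -> int:
    """Water molecules displaced by a volume change of ``delta_volume`` Å³.

    ``round(rho * N_A * dV / MW_H2O)`` with dV converted to cm³; the count
    is the number of waters occupying the volume the acetyl groups added.
    """
    if delta_volume < 0:
        raise ValueError("volume change must be non-negative")
    n = (constants.rho_water * constants.avogadro * delta_volume * A3_TO_CM3
         / constants.mw_water)
    return int(round(n))


def sites_from_atom_counts(pre_atoms: int, post_atoms: int,
                           waters_removed: int) -> int:
    """Invert the atom bookkeeping to the number of acetylated sites.

    Each site contributes +5 atoms and each removed water -3, so
    ``post = pre + 5*sites - 3*waters`` and
    ``sites = (post - pre + 3*waters) / 5``; a non-integer result signals
    inconsistent inputs.
    """
    if min(pre_atoms, post_atoms, waters_removed) < 0:
        raise ValueError("inputs must be non-negative integers")
    num = post_atoms - pre_atoms + ATOMS_PER_WATER * waters_removed
    sites, rem = divmod(num, ACETYLATION_ATOM_DELTA)
    if rem:
        raise ValueError(
            f"atom counts inconsistent with +5/-3 bookkeeping (remainder {rem})"
        )
    return sites


def counterions_needed(total_charge: float, valence: int) -> int:
    """Cations of the given valence required to neutralise ``total_charge``.

    A -150 e polymer charge needs 150 monovalent or 50 trivalent cations.
    """
    if valence < 1:
        raise ValueError("valence must be a positive integer")
    return math.ceil(abs(total_charge) / valence - 1e-9)


def moisture_content(structure: StructureModel, include_ions: bool = False) -> float:
    """Water mass as a percent of total system mass.

    ``include_ions`` controls whether ion mass counts in the denominator
    (excluded by default).
    """
    water = structure.masses[structure.components == "water"].sum()
    total = structure.total_mass
    if not include_ions:
        total -= structure.masses[structure.components == "ion"].sum()
    if total <= 0:
        raise ValueError("total mass is zero")
    return 100.0 * water / total


def dry_mass(structure: StructureModel) -> float:
    """Mass of the biopolymers only (no water, no ions), g/mol."""
    mask = np.isin(structure.components, ("cellulose", "hemicellulose", "lignin"))
    return float(structure.masses[mask].sum())


def find_exposed_hydroxyls(structure: StructureModel, frame: np.ndarray,
                           box, cutoff: float) -> np.ndarray:
    """Hydroxyl sites whose oxygen lies within ``cutoff`` Å of water.

    Exposure is the minimum-image distance from the hydroxyl oxygen to
    the nearest water oxygen.  ``cutoff = inf`` selects every hydroxyl
    site on hemicellulose and lignin.  Returns sorted site ids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    oh_mask = (structure.groups == "hydroxyl") & (structure.elements == "O")
    site_ids = structure.site_ids[oh_mask]
    if np.any(site_ids < 0):
        raise ValueError("hydroxyl atoms must carry site ids for selection")
    if np.isinf(cutoff):
        return np.sort(np.unique(site_ids))
    water_o = structure.indices(component="water", element="O")
    if water_o.size == 0:
        raise ValueError("no water present for a finite exposure cutoff")
    oh_pos = frame[oh_mask]
    water_pos = frame[water_o]
    selected = [
        sid for sid, pos in zip(site_ids, oh_pos)
        if minimum_image_distance(pos, water_pos, box).min() <= cutoff
    ]
    return np.sort(np.unique(selected))


@dataclass
class AcetylationPlan:
    """A resolved set of hydroxyl sites to acetylate plus its bookkeeping."""

    sites: np.ndarray
    cutoff: float
    mode: str = "expanded"            # or "constant"
    n_water_removed: int = 0
    water_policy: str = "displace"    # or "random"
    seed: int = 0
    m_pre: float = float("nan")
    m_post: float = float("nan")

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)
        if self.mode not in ("expanded", "constant"):
            raise ValueError("mode must be 'expanded' or 'constant'")
        if self.water_policy not in ("displace", "random"):
            raise ValueError("water policy must be 'displace' or 'random'")
        if self.n_water_removed < 0:
            raise ValueError("water removal count must be non-negative")
        if self.mode == "expanded" and self.n_water_removed:
            raise ValueError("expanded mode removes no water")

    @property
    def wpg(self) -> float:
        return compute_wpg(self.m_pre, self.m_post)


def plan_acetylation(structure: StructureModel, frame: np.ndarray, box,
                     cutoff: float, mode: str = "expanded",
                     delta_volume: float | None = None,
                     n_water_removed: int | None = None,
                     water_policy: str = "displace", seed: int = 0,
                     constants: Constants = DEFAULT_CONSTANTS) -> AcetylationPlan:
    """Select exposed hydroxyls and resolve the full bookkeeping plan.

    In constant (fixed-volume) mode the number of waters to displace is
    either given directly or derived from the expanded-system volume
    change ``delta_volume`` (Å³).
    """
    sites = find_exposed_hydroxyls(structure, frame, box, cutoff)
    m_pre = dry_mass(structure)
    m_post = m_pre + ACETYLATION_MASS_DELTA * sites.size
    n_rm = 0
    if mode == "constant":
        if n_water_removed is not None:
            n_rm = int(n_water_removed)
        elif delta_volume is not None:
            n_rm = waters_to_remove(delta_volume, constants)
        else:
            raise ValueError("constant mode needs delta_volume or n_water_removed")
    return AcetylationPlan(sites=sites, cutoff=cutoff, mode=mode,
                           n_water_removed=n_rm, water_policy=water_policy,
                           seed=seed, m_pre=m_pre, m_post=m_post)


@dataclass
class AcetylationReport:
    n_sites: int
    atoms_pre: int
    atoms_post: int
    wpg: float
    moisture_pre: float
    moisture_post: float
    n_water_removed: int


def apply_plan(trajectory: Trajectory, plan: AcetylationPlan,
               frame_index: int = 0):
    """Apply an acetylation plan to a structure (bookkeeping level).

    Per selected hydroxyl site: the hydroxyl hydrogen is deleted, the
    hydroxyl oxygen is relabelled as the acetyl ester oxygen, and five
    further atoms (carbonyl C and O, methyl C and 3 H) are added near the
    site.  Constant mode then removes ``plan.n_water_removed`` whole water
    molecules, either those nearest the new acetyl atoms ("displace") or
    seeded-random bulk waters ("random").

    Returns ``(new_trajectory, report)``; placements are pseudo-coordinates
    adequate for label/count/mass analyses, not minimised geometry.
    """
    structure = trajectory.structure
    coords = trajectory.coords[frame_index]
    box = trajectory.boxes[frame_index]
    atoms_pre = structure.n_atoms
    moisture_pre = moisture_content(structure)

    site_set = set(int(s) for s in plan.sites)
    for sid in site_set:
        mask = structure.site_ids == sid
        if not mask.any() or not np.all(structure.groups[mask] == "hydroxyl"):
            raise ValueError(f"site {sid} is not a hydroxyl site")

    keep = np.ones(atoms_pre, dtype=bool)
    new_rows = []
    acetyl_anchor = []
    offsets = [("C", "CA", np.array([0.0, 0.0, 1.3])),
               ("O", "OA", np.array([1.1, 0.0, 1.9])),
               ("C", "CM", np.array([-1.2, 0.0, 2.1])),
               ("H", "HM1", np.array([-1.2, 0.9, 2.7])),
               ("H", "HM2", np.array([-1.2, -0.9, 2.7])),
               ("H", "HM3", np.array([-2.1, 0.0, 1.5]))]
    for sid in sorted(site_set):
        mask = structure.site_ids == sid
        h_idx = np.flatnonzero(mask & (structure.elements == "H"))
        o_idx = np.flatnonzero(mask & (structure.elements == "O"))
        if h_idx.size != 1 or o_idx.size != 1:
            raise ValueError(f"hydroxyl site {sid} must have exactly one O and one H")
        keep[h_idx[0]] = False
        opos = coords[o_idx[0]]
        comp = structure.components[o_idx[0]]
        resid = structure.resids[o_idx[0]]
        acetyl_anchor.append(opos)
        for elem, name, off in offsets:
            new_rows.append((elem, name, comp, "acetyl", sid, resid, opos + off))

    elements = list(structure.elements[keep])
    masses = list(structure.masses[keep])
    components = list(structure.components[keep])
    groups = list(structure.groups[keep])
    resids = list(structure.resids[keep])
    charges = list(structure.charges[keep])
    site_ids = list(structure.site_ids[keep])
    names = list(structure.names[keep])
    pos = list(coords[keep])
    # relabel surviving hydroxyl O atoms of acetylated sites as ester oxygens
    for i in range(len(elements)):
        if site_ids[i] in site_set and groups[i] == "hydroxyl":
            groups[i] = "acetyl"
            names[i] = "OE"
    for elem, name, comp, grp, sid, resid, p in new_rows:
        elements.append(elem)
        masses.append(ATOMIC_MASSES[elem])
        components.append(comp)
        groups.append(grp)
        resids.append(resid)
        charges.append(0.0)
        site_ids.append(sid)
        names.append(name)
        pos.append(p)

    new_structure = StructureModel(
        elements=np.array(elements, dtype=object),
        masses=np.array(masses), components=np.array(components, dtype=object),
        groups=np.array(groups, dtype=object), resids=np.array(resids),
        charges=np.array(charges), site_ids=np.array(site_ids),
        names=np.array(names, dtype=object))
    pos = np.array(pos)

    # constant-volume mode: remove whole water molecules
    n_rm = plan.n_water_removed if plan.mode == "constant" else 0
    if n_rm:
        water_o = np.flatnonzero((new_structure.components == "water")
                                 & (new_structure.elements == "O"))
        if n_rm > water_o.size:
            raise ValueError("not enough water molecules to remove")
        if plan.water_policy == "displace" and acetyl_anchor:
            anchors = np.array(acetyl_anchor)
            d = np.array([minimum_image_distance(pos[i], anchors, box).min()
                          for i in water_o])
            doomed_o = water_o[np.argsort(d, kind="stable")[:n_rm]]
        else:
            rng = np.random.default_rng(plan.seed)
            doomed_o = rng.choice(water_o, size=n_rm, replace=False)
        doomed_res = set(new_structure.resids[doomed_o].tolist())
        keep2 = np.array([not (c == "water" and r in doomed_res)
                          for c, r in zip(new_structure.components,
                                          new_structure.resids)])
        new_structure = StructureModel(
            elements=new_structure.elements[keep2], masses=new_structure.masses[keep2],
            components=new_structure.components[keep2],
            groups=new_structure.groups[keep2], resids=new_structure.resids[keep2],
            charges=new_structure.charges[keep2],
            site_ids=new_structure.site_ids[keep2], names=new_structure.names[keep2])
        pos = pos[keep2]

    report = AcetylationReport(
        n_sites=len(site_set), atoms_pre=atoms_pre,
        atoms_post=new_structure.n_atoms,
        wpg=compute_wpg(plan.m_pre, plan.m_post) if np.isfinite(plan.m_pre)
        else compute_wpg(dry_mass(structure),
                         dry_mass(structure) + ACETYLATION_MASS_DELTA * len(site_set)),
        moisture_pre=moisture_pre,
        moisture_post=moisture_content(new_structure),
        n_water_removed=n_rm)
    new_traj = Trajectory(structure=new_structure, coords=pos[None, :, :],
                          boxes=box, frame_interval=trajectory.frame_interval,
                          equilibration=trajectory.equilibration)
    return new_traj, report
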