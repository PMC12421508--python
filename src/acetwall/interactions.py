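"""Contact statistics, RDFs, relative binding free energies and dwell times.

Contacts use a logistic switching weight ``1 / (1 + exp(k (d - d0)))``
with midpoint ``d0 = 5 Å`` and steepness ``k = 5 Å⁻¹`` summed over heavy
atom pairs.  Interaction probabilities per functional group, normalised
by group abundance, convert into relative binding free energies against
the carboxyl reference, ``ΔG = -RT ln(P_s / P_c)``, with uncertainty
propagated from block standard errors.  An independent route integrates
the ion-group radial distribution function to its first minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree

from .constants import DEFAULT_CONSTANTS, Constants
from .core import (
    SelectionGroup,
    Trajectory,
    minimum_image_distance,
    periodic_neighbor_pairs,
    wrap_coords,
)

SWITCH_MIDPOINT = 5.0    # Å
SWITCH_STEEPNESS = 5.0   # Å^-1
#: beyond this the switching weight is < 1e-15 and is treated as zero,
#: making scores independent of the neighbour-search radius
CONTACT_TRUNCATION = 12.0


def switching_weight(distance) -> np.ndarray:
    """Logistic contact weight; 0.5 at the 5 Å midpoint, in (0, 1)."""
    x = SWITCH_STEEPNESS * (np.asarray(distance, dtype=float) - SWITCH_MIDPOINT)
    return 1.0 / (1.0 + np.exp(np.clip(x, -700, 700)))


def _heavy(group: SelectionGroup, trajectory: Trajectory) -> SelectionGroup:
    elems = trajectory.structure.elements[group.indices]
    return SelectionGroup(name=group.name, indices=group.indices[elems != "H"],
                          abundance=group.abundance)


def contact_score(group_a: SelectionGroup, group_b: SelectionGroup,
                  frame: np.ndarray, box,
                  truncation: float = CONTACT_TRUNCATION) -> float:
    """Switching-weighted contact score between two groups in one frame.

    Sums the logistic weight over pairs with minimum-image distance below
    the truncation radius; atoms shared by both groups never pair with
    themselves.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("contact groups must be nonempty")
    box = np.asarray(box, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = periodic_neighbor_pairs(group_a, group_b, frame, box,
                                        cutoff=truncation)
    if not pairs:
        return 0.0
    d = np.array([p[2] for p in pairs])
    return float(switching_weight(d).sum())


@dataclass
class ContactSeries:
    """Per-frame weighted contact scores between two named groups."""

    name_a: str
    name_b: str
    times: np.ndarray
    scores: np.ndarray
    midpoint: float = SWITCH_MIDPOINT
    steepness: float = SWITCH_STEEPNESS

    @property
    def mean(self) -> float:
        return float(self.scores.mean())


def group_contact_timeseries(trajectory: Trajectory,
                             pairs: list[tuple[SelectionGroup, SelectionGroup]],
                             heavy_only: bool = True,
                             use_equilibration_cutoff: bool = True
                             ) -> list[ContactSeries]:
    """Evaluate the contact score per frame for each requested group pair.

    Restricted to heavy atoms by default and to post-equilibration frames
    (t >= 50 ns by default on loaded data).
    """
    mask = trajectory.production_mask() if use_equilibration_cutoff \
        else np.ones(trajectory.n_frames, dtype=bool)
    frames = np.flatnonzero(mask)
    if frames.size == 0:
        raise ValueError("no frames remain after the equilibration cutoff")
    out = []
    for ga, gb in pairs:
        if heavy_only:
            ga, gb = _heavy(ga, trajectory), _heavy(gb, trajectory)
        scores = np.array([
            contact_score(ga, gb, trajectory.coords[f], trajectory.boxes[f])
            for f in frames
        ])
        out.append(ContactSeries(name_a=ga.name, name_b=gb.name,
                                 times=trajectory.times[frames], scores=scores))
    return out


def interaction_probability(mean_scores: dict[str, float],
                            abundances: dict[str, int]) -> dict[str, float]:
    """Abundance-normalised interaction probabilities per functional group.

    ``P_s`` is proportional to the per-site mean contact score
    (score / abundance), normalised over the groups present so the values
    are comparable probabilities.
    """
    per_site = {}
    for name, score in mean_scores.items():
        ab = abundances[name]
        if ab < 1:
            raise ValueError(f"abundance for {name!r} must be >= 1")
        per_site[name] = score / ab
    total = sum(per_site.values())
    if total <= 0:
        raise ValueError("all mean scores are zero; probabilities undefined")
    return {k: v / total for k, v in per_site.items()}


def delta_g(p_s: float, p_c: float, constants: Constants = DEFAULT_CONSTANTS,
            is_reference: bool = False) -> float:
    """Relative binding free energy ``-RT ln(P_s / P_c)`` in kcal/mol."""
    if is_reference:
        return 0.0
    if p_s <= 0 or p_c <= 0:
        raise ValueError("free energy not estimable from zero probability")
    return -constants.kT * np.log(p_s / p_c)


def delta_g_error(p_s: float, sigma_s: float, p_c: float, sigma_c: float,
                  constants: Constants = DEFAULT_CONSTANTS) -> float:
    """``σ_ΔG = RT sqrt((σ_s/P_s)² + (σ_c/P_c)²)`` in kcal/mol."""
    if p_s <= 0 or p_c <= 0:
        raise ValueError("probabilities must be positive")
    return constants.kT * float(np.hypot(sigma_s / p_s, sigma_c / p_c))


@dataclass
class FreeEnergyTable:
    """Per-group relative ΔG (kcal/mol) versus the carboxyl reference."""

    probabilities: dict[str, float]
    delta_g: dict[str, float]
    sigma: dict[str, float]
    route: str                      # "atom_pair" or "rdf"
    reference: str = "carboxyl"
    n_blocks: int = 20


def _blocked(values: np.ndarray, n_blocks: int) -> np.ndarray:
    usable = values[: values.size - values.size % n_blocks]
    return usable.reshape(n_blocks, -1).mean(axis=1)


def contact_free_energy(trajectory: Trajectory, ions: SelectionGroup,
                        groups: dict[str, SelectionGroup],
                        reference: str = "carboxyl", n_blocks: int = 20,
                        constants: Constants = DEFAULT_CONSTANTS,
                        use_equilibration_cutoff: bool = True) -> FreeEnergyTable:
    """Atom-pair route: ΔG from abundance-normalised mean contact scores.

    Block standard errors come from dividing the production frames into
    ``n_blocks`` equal contiguous parts.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    series = group_contact_timeseries(
        trajectory, [(ions, g) for g in groups.values()],
        use_equilibration_cutoff=use_equilibration_cutoff)
    names = list(groups)
    mean_scores = {n: s.mean for n, s in zip(names, series)}
    abundances = {n: groups[n].abundance for n in names}
    probs = interaction_probability(mean_scores, abundances)

    rel_err = {}
    for n, s in zip(names, series):
        blocks = _blocked(s.scores, n_blocks)
        se = np.std(blocks, ddof=1) / np.sqrt(n_blocks)
        rel_err[n] = se / s.scores.mean() if s.scores.mean() > 0 else np.nan

    dg, sg = {}, {}
    for n in names:
        if n == reference:
            dg[n], sg[n] = 0.0, 0.0
            continue
        dg[n] = delta_g(probs[n], probs[reference], constants)
        sg[n] = constants.kT * float(np.hypot(rel_err[n], rel_err[reference]))
    return FreeEnergyTable(probabilities=probs, delta_g=dg, sigma=sg,
                           route="atom_pair", reference=reference,
                           n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# radial distribution function


@dataclass
class RDFProfile:
    """A number-density-normalised g(r) with raw per-centre pair counts."""

    bin_centers: np.ndarray
    g: np.ndarray
    raw_counts: np.ndarray          # mean pairs per centre per bin
    center_name: str
    target_name: str
    r_max: float
    first_minimum: float | None = None


def rdf(trajectory: Trajectory, centers: SelectionGroup, targets: SelectionGroup,
        r_max: float = 10.0, bin_width: float = 0.1,
        use_equilibration_cutoff: bool = True,
        frames: np.ndarray | None = None) -> RDFProfile:
    """Standard g(r) of targets around centers under periodic boundaries.

    Per-bin pair counts are normalised by shell volume, mean target
    number density, centre count and frame count; raw mean pair counts
    per centre are retained so the profile can be integrated into a
    coordination number.
    """
    if len(centers) == 0 or len(targets) == 0:
        raise ValueError("centre and target groups must be nonempty")
    if r_max > trajectory.boxes.min() / 2:
        raise ValueError("r_max must not exceed half the smallest box length")
    if frames is None:
        mask = trajectory.production_mask() if use_equilibration_cutoff \
            else np.ones(trajectory.n_frames, dtype=bool)
        frames = np.flatnonzero(mask)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist = np.zeros(edges.size - 1)
    inv_density = 0.0
    same = np.array_equal(np.sort(centers.indices), np.sort(targets.indices))
    for f in frames:
        box = trajectory.boxes[f]
        ca = wrap_coords(trajectory.coords[f][centers.indices], box)
        ta = wrap_coords(trajectory.coords[f][targets.indices], box)
        ca = np.where(ca >= box, 0.0, ca)
        ta = np.where(ta >= box, 0.0, ta)
        tree = cKDTree(ta, boxsize=box)
        dists = cKDTree(ca, boxsize=box).sparse_distance_matrix(
            tree, max_distance=r_max, output_type="coo_matrix")
        d = dists.data
        if same:
            d = d[dists.row != dists.col]
        d = d[d > 1e-12] if same else d
        hist += np.histogram(d, bins=edges)[0]
        inv_density += np.prod(box) / len(targets)
    n_frames = len(frames)
    raw = hist / (n_frames * len(centers))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    mean_inv_density = inv_density / n_frames
    g = raw * mean_inv_density / shell
    centers_r = 0.5 * (edges[1:] + edges[:-1])
    profile = RDFProfile(bin_centers=centers_r, g=g, raw_counts=raw,
                         center_name=centers.name, target_name=targets.name,
                         r_max=r_max)
    profile.first_minimum = find_first_minimum(profile)
    return profile


def find_first_minimum(profile: RDFProfile) -> float | None:
    """First strict local minimum of the smoothed g(r) after the main peak.

    The profile is cubic-spline smoothed on its bin centres; returns None
    for monotone profiles with no interior minimum (the caller may then
    supply a fixed integration radius).
    """
    g = profile.g
    r = profile.bin_centers
    if g.size < 5 or not np.any(g > 0):
        return None
    win = min(9, g.size - (1 - g.size % 2))
    smooth = savgol_filter(g, window_length=win, polyorder=2) if win >= 5 else g
    spline = CubicSpline(r, smooth)
    rf = np.linspace(r[0], r[-1], 10 * r.size)
    gf = spline(rf)
    peak = int(np.argmax(gf))
    # a coordination-shell boundary must sit well below the peak; without
    # the guard, bin noise on the peak's flank fakes shallow minima
    guard = 0.5 * gf[peak]
    fallback = None
    for i in range(peak + 1, gf.size - 1):
        if gf[i] < gf[i - 1] and gf[i] <= gf[i + 1]:
            if gf[i] <= guard:
                return float(rf[i])
            if fallback is None:
                fallback = float(rf[i])
    return fallback


def integrate_rdf_to_first_minimum(profile: RDFProfile,
                                   radius: float | None = None):
    """Coordination number: mean pairs per centre out to the first minimum.

    Returns ``(coordination_number, radius)``.  Sums the raw per-centre
    pair counts over bins at or below the first-minimum radius (or an
    explicitly supplied radius).
    """
    r_min = radius if radius is not None else profile.first_minimum
    if r_min is None:
        raise ValueError("profile has no detected first minimum; supply a radius")
    mask = profile.bin_centers <= r_min
    return float(profile.raw_counts[mask].sum()), float(r_min)


def rdf_free_energy(trajectory: Trajectory, ions: SelectionGroup,
                    groups: dict[str, SelectionGroup],
                    reference: str = "carboxyl", r_max: float = 10.0,
                    bin_width: float = 0.1, n_blocks: int = 20,
                    constants: Constants = DEFAULT_CONSTANTS,
                    use_equilibration_cutoff: bool = True) -> FreeEnergyTable:
    """RDF route: ΔG from integrated g(r) up to its first minimum.

    The coordination number of each group's heavy atoms around the ions,
    normalised by group abundance, plays the role of the interaction
    probability; uncertainties come from recomputing the integral on 20
    equal trajectory chunks using the full-trajectory minimum radius.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    mask = trajectory.production_mask() if use_equilibration_cutoff \
        else np.ones(trajectory.n_frames, dtype=bool)
    frames = np.flatnonzero(mask)
    per_site, rel_err = {}, {}
    for name, grp in groups.items():
        heavy = _heavy(grp, trajectory)
        profile = rdf(trajectory, ions, heavy, r_max=r_max, bin_width=bin_width,
                      frames=frames)
        coord, r_min = integrate_rdf_to_first_minimum(profile)
        per_site[name] = coord / grp.abundance
        blocks = np.array_split(frames, n_blocks)
        vals = []
        for chunk in blocks:
            p = rdf(trajectory, ions, heavy, r_max=r_max, bin_width=bin_width,
                    frames=chunk)
            vals.append(integrate_rdf_to_first_minimum(p, radius=r_min)[0])
        vals = np.asarray(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        rel_err[name] = se / coord if coord > 0 else np.nan
    total = sum(per_site.values())
    probs = {k: v / total for k, v in per_site.items()}
    dg, sg = {}, {}
    for n in groups:
        if n == reference:
            dg[n], sg[n] = 0.0, 0.0
            continue
        dg[n] = delta_g(probs[n], probs[reference], constants)
        sg[n] = constants.kT * float(np.hypot(rel_err[n], rel_err[reference]))
    return FreeEnergyTable(probabilities=probs, delta_g=dg, sigma=sg,
                           route="rdf", reference=reference, n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# dwell times


@dataclass
class DwellDistribution:
    """Sorted ion-site dwell durations with censoring flags."""

    durations: np.ndarray        # ns, sorted
    censored: np.ndarray         # True if the run touches a trajectory end
    frame_interval: float

    @property
    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())


def _runs(mask: np.ndarray):
    """Maximal runs of True: list of (start, length, touches_either_end)."""
    n = mask.size
    padded = np.concatenate([[0], mask.astype(int), [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(a), int(b - a), bool(a == 0 or b == n))
            for a, b in zip(starts, ends)]


def dwell_times(trajectory: Trajectory, ions: SelectionGroup,
                sites: SelectionGroup, cutoff: float = 6.0,
                use_equilibration_cutoff: bool = False) -> DwellDistribution:
    """Per ion-site contact dwell durations.

    A dwell is a maximal run of consecutive frames in which the
    minimum-image ion-site distance stays within ``cutoff`` (default
    6 Å); its duration is the run length times the frame interval.  Runs
    touching either trajectory end are flagged censored, since their true
    length is unknown (some span the whole simulation).
    """
    if cutoff >= trajectory.boxes.min() / 2:
        raise ValueError("dwell cutoff must be below half the box")
    mask = trajectory.production_mask() if use_equilibration_cutoff \
        else np.ones(trajectory.n_frames, dtype=bool)
    frames = np.flatnonzero(mask)
    n_f = frames.size
    contact = np.empty((n_f, len(ions), len(sites)), dtype=bool)
    for k, f in enumerate(frames):
        box = trajectory.boxes[f]
        d = minimum_image_distance(
            trajectory.coords[f][ions.indices][:, None, :],
            trajectory.coords[f][sites.indices][None, :, :], box)
        contact[k] = d <= cutoff
    durations, censored = [], []
    for i in range(len(ions)):
        for s in range(len(sites)):
            for _, length, cens in _runs(contact[:, i, s]):
                durations.append(length * trajectory.frame_interval)
                censored.append(cens)
    durations = np.asarray(durations, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    order = np.argsort(durations, kind="stable")
    return DwellDistribution(durations=durations[order], censored=censored[order],
                             frame_interval=trajectory.frame_interval)


def time_weighted_cdf(durations: np.ndarray):
    """Time-weighted cumulative distribution of dwell durations.

    Each event is weighted by its duration over the total bound time, so
    the CDF at x is the fraction of total bound time spent in events of
    duration <= x.  Returns ``(sorted_durations, cdf_values)``.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("no dwell events")
    order = np.argsort(durations, kind="stable")
    d = durations[order]
    cdf = np.cumsum(d) / d.sum()
    return d, cdf


def eval_time_weighted_cdf(durations: np.ndarray, at: float) -> float:
    """CDF value at a given duration (fraction of bound time in events <= at)."""
    d, cdf = time_weighted_cdf(durations)
    idx = np.searchsorted(d, at, side="right") - 1
    return float(cdf[idx]) if idx >= 0 else 0.0
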