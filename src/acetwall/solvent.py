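"""Bulk-water-pocket quantification.

A water molecule is "bulk" when its oxygen sits at least 5 Å (by
default) from every cell-wall biopolymer atom, and is therefore not
hydrogen-bonded to the polymer mesh.  The per-frame bulk fraction tracks
how acetylation squeezes out interstitial water pockets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import SelectionGroup, Trajectory, wrap_coords

POLYMER_COMPONENTS = ("cellulose", "hemicellulose", "lignin")


def polymer_selection(trajectory: Trajectory, heavy_only: bool = False) -> SelectionGroup:
    """All cell-wall biopolymer atoms (hydrogens included by default)."""
    s = trajectory.structure
    mask = np.isin(s.components, POLYMER_COMPONENTS)
    if heavy_only:
        mask &= s.elements != "H"
    return SelectionGroup(name="polymer", indices=np.flatnonzero(mask))


def water_oxygen_selection(trajectory: Trajectory) -> SelectionGroup:
    s = trajectory.structure
    return SelectionGroup(name="water_oxygen",
                          indices=s.indices(component="water", element="O"))


def classify_bulk_water(frame: np.ndarray, box, waters: SelectionGroup,
                        polymers: SelectionGroup, threshold: float = 5.0
                        ) -> np.ndarray:
    """Boolean bulk flag per water (oxygen) position.

    A water is bulk iff its minimum-image distance to every polymer atom
    exceeds the threshold.
    """
    if len(waters) == 0:
        raise ValueError("water group is empty")
    if len(polymers) == 0:
        raise ValueError("polymer group is empty")
    box = np.asarray(box, dtype=float)
    wp = wrap_coords(frame[waters.indices], box)
    pp = wrap_coords(frame[polymers.indices], box)
    wp = np.where(wp >= box, 0.0, wp)
    pp = np.where(pp >= box, 0.0, pp)
    tree = cKDTree(pp, boxsize=box)
    d, _ = tree.query(wp, k=1)
    return d > threshold


def bulk_water_fraction(frame: np.ndarray, box, waters: SelectionGroup,
                        polymers: SelectionGroup, threshold: float = 5.0) -> float:
    """Percent of water molecules that are bulk in this frame."""
    flags = classify_bulk_water(frame, box, waters, polymers, threshold)
    return 100.0 * float(flags.mean())


def count_water_pockets(frame: np.ndarray, box, waters: SelectionGroup,
                        polymers: SelectionGroup, threshold: float = 5.0,
                        linkage: float = 3.5) -> int:
    """Number of discrete bulk-water pockets in one frame.

    Bulk waters are single-linkage clustered at ``linkage`` Å (periodic
    distances); each connected component is one pocket.  This is an
    optional descriptive extra — the validated observable is the bulk
    fraction, not the pocket count.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    flags = classify_bulk_water(frame, box, waters, polymers, threshold)
    bulk = waters.indices[flags]
    if bulk.size == 0:
        return 0
    box = np.asarray(box, dtype=float)
    pos = wrap_coords(frame[bulk], box)
    pos = np.where(pos >= box, 0.0, pos)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(r=linkage, output_type="ndarray")
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(bulk.size, bulk.size))
    n, _ = connected_components(adj, directed=False)
    return int(n)


@dataclass
class BulkWaterSeries:
    """Per-frame bulk-water fraction (percent) over a trajectory."""

    times: np.ndarray
    fractions: np.ndarray
    threshold: float
    equilibration_mask: np.ndarray   # True where the frame is equilibration

    @property
    def production_mean(self) -> float:
        vals = self.fractions[~self.equilibration_mask]
        return float(vals.mean()) if vals.size else float("nan")


def bulk_fraction_series(trajectory: Trajectory, threshold: float = 5.0,
                         heavy_only: bool = False) -> BulkWaterSeries:
    """Bulk-water fraction per frame; equilibration frames are flagged."""
    waters = water_oxygen_selection(trajectory)
    polymers = polymer_selection(trajectory, heavy_only=heavy_only)
    fractions = np.array([
        bulk_water_fraction(trajectory.coords[f], trajectory.boxes[f],
                            waters, polymers, threshold)
        for f in range(trajectory.n_frames)
    ])
    return BulkWaterSeries(times=trajectory.times, fractions=fractions,
                           threshold=threshold,
                           equilibration_mask=~trajectory.production_mask())
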