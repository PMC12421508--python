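"""Bulk-water-pocket quantification on a constructed toy wall.

A water molecule counts as bulk when its oxygen is at least 5 Å from
every biopolymer atom.  The toy wall places 10 waters in a distant
pocket and 10 hugging the polymer slab, so the bulk fraction is 50% by
construction; inserting acetyl pseudo-atoms into the pocket then lowers
it, the direction expected when acetylation fills void space.
"""

import numpy as np

from acetwall import (
    StructureModel,
    ToyCellWallSpec,
    Trajectory,
    bulk_fraction_series,
    gen_toy_cellwall,
)

traj, truth = gen_toy_cellwall(ToyCellWallSpec(
    hydroxyl_water_distances=(), n_bulk_water=10, n_bound_water=10, seed=1))
series = bulk_fraction_series(traj, threshold=5.0)
print(f"bulk water fraction: {series.fractions[0]:.1f} % "
      f"(constructed ground truth: {truth.bulk_fraction_percent:.1f} %)")

# drop acetyl pseudo-atoms next to half the pocket waters
s = traj.structure
bulk_o = np.flatnonzero((s.components == "water")
                        & (s.elements == "O"))[truth.water_is_bulk]
targets = traj.coords[0][bulk_o[: bulk_o.size // 2]]
n_new = targets.shape[0]
filled = StructureModel(
    elements=np.concatenate([s.elements, ["C"] * n_new]),
    masses=np.concatenate([s.masses, [12.011] * n_new]),
    components=np.concatenate([s.components, ["hemicellulose"] * n_new]),
    groups=np.concatenate([s.groups, ["acetyl"] * n_new]),
    resids=np.concatenate([s.resids, np.arange(n_new) + s.resids.max() + 1]),
    site_ids=np.concatenate([s.site_ids,
                             np.arange(n_new) + s.site_ids.max() + 1]),
    names=np.concatenate([s.names, ["CA"] * n_new]))
coords = np.concatenate([traj.coords[0], targets + np.array([3.0, 0, 0])])[None]
after = bulk_fraction_series(
    Trajectory(structure=filled, coords=coords, boxes=traj.boxes,
               frame_interval=1.0, equilibration=0.0), threshold=5.0)
print(f"after inserting {n_new} acetyl pseudo-atoms into the pocket: "
      f"{after.fractions[0]:.1f} %")
print("acetylation that fills voids converts bulk water into bound water")
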