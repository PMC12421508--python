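"""Relative ion-binding free energies from contacts and from the RDF.

Generates per-frame ion placements over carboxyl and acetyl sites with
a planted 1.18 kcal/mol penalty for acetyl (Boltzmann-weighted
occupancy at 300 K), then recovers that offset two independent ways:
from abundance-normalised switching-function contact scores, and from
the integral of the ion-group RDF up to its first minimum.
"""

from acetwall import (
    BoltzmannSiteSpec,
    contact_free_energy,
    gen_boltzmann_sites,
    rdf_free_energy,
)

spec = BoltzmannSiteSpec(
    site_counts={"carboxyl": 150, "acetyl": 600},
    site_energies={"carboxyl": 0.0, "acetyl": 1.18},
    n_ions=150, n_frames=200, seed=1)
traj, truth = gen_boltzmann_sites(spec)
ions = traj.structure.select("ions", component="ion")
groups = traj.structure.functional_group_map()

contact = contact_free_energy(traj, ions, groups, use_equilibration_cutoff=False)
via_rdf = rdf_free_energy(traj, ions, groups, use_equilibration_cutoff=False)

print(f"planted acetyl offset: {truth.delta_g['acetyl']:.2f} kcal/mol "
      "(relative to carboxyl, the reference at 0)")
for table in (contact, via_rdf):
    dg, sg = table.delta_g["acetyl"], table.sigma["acetyl"]
    print(f"{table.route:>9} route: ΔG = {dg:.3f} ± {sg:.3f} kcal/mol "
          f"({table.n_blocks}-block standard error)")
print("agreement of the two routes cross-validates the abundance "
      "normalisation behind the probability ratio")
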