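# acetwall

Structure and transport analysis for acetylated plant secondary cell
wall models.

Wood acetylation — replacing hydroxyl groups on hemicellulose and
lignin with acetyl groups (–C(=O)CH₃) — protects timber against fungal
decay, plausibly by slowing the diffusion of the ions that drive
chelator-mediated Fenton chemistry. Molecular dynamics models of a
hydrated cellulose/hemicellulose/lignin mesh let the two candidate
mechanisms be separated: direct acetyl–ion interactions versus water
displacement (dehydration of the polymer network). `acetwall`
implements the full analysis layer of such a study as a reusable,
tested library:

- **Acetylation bookkeeping** — exposure-based hydroxyl selection
  (distance of the hydroxyl oxygen to the nearest water oxygen),
  weight-percent gain `WPG = 100·(m_post − m_pre)/m_pre`, constant-volume
  water removal `N = ρ·N_A·ΔV / MW_H₂O`, atom-count inversion
  (+5 atoms per acetylated site, −3 per removed water), moisture
  content, counterion counts.
- **Diffusion** — displacement-based unwrapping, translation-only drift
  removal against a reference group, fixed-origin mean squared
  displacement, and the Einstein relation `MSD = 6Dt` via two
  estimators: a (generalised) least-squares fit to the MSD curve and a
  fixed-lag sliding-window average with block standard errors.
- **Interactions** — switching-function contacts
  `C = Σ [1 + e^{5(d−5Å)}]⁻¹` over heavy-atom pairs with periodic
  KD-tree neighbour search; abundance-normalised interaction
  probabilities; relative binding free energies
  `ΔG = −RT ln(P_s/P_c)` against the carboxyl reference with
  20-block error propagation `σ_ΔG = RT·√((σ_s/P_s)² + (σ_c/P_c)²)`;
  an independent ΔG route from radial distribution functions
  integrated to their first minimum; ion–site dwell times (maximal
  runs of frames within 6 Å, end-censoring flagged) summarised as a
  time-weighted cumulative distribution.
- **Solvent structure** — bulk-water pockets: the fraction of waters at
  least 5 Å from every biopolymer atom, per frame.
- **Synthetic ground truth** — generators for free Brownian tracers,
  two-state Markov binding kinetics, Boltzmann-weighted site occupancy
  and toy cell-wall configurations, so every estimator is validated
  against planted parameters without any trajectory download.

Trajectories load from standard formats (PDB/GRO/PSF topology, DCD/XTC
coordinates) through MDAnalysis with rule-driven component and
functional-group annotation. Boxes are orthorhombic; lengths in Å,
times in ns, energies in kcal/mol.

## Worked example

Recovering a planted binding free energy from synthetic occupancy data
(`examples/binding_free_energy.py`):

```
planted acetyl offset: 1.18 kcal/mol (relative to carboxyl, the reference at 0)
atom_pair route: ΔG = 1.174 ± 0.006 kcal/mol (20-block standard error)
      rdf route: ΔG = 1.174 ± 0.006 kcal/mol (20-block standard error)
```

Ions were distributed each frame over 150 carboxyl and 600 acetyl sites
with Boltzmann weights at 300 K, penalising acetyl by 1.18 kcal/mol —
the size of the acetyl–ion penalty in a lightly acetylated wall. Both
estimation routes (contact scores and integrated RDFs, each normalised
by site abundance) recover the planted offset within their reported
uncertainty, and the carboxyl reference is exactly 0 by construction.

The other examples follow the same pattern, one capability each:
`acetylation_bookkeeping.py` (exposure selection, WPG, moisture, and
the inversion of the published system sizes to 4098 acetyl groups),
`diffusion_recovery.py` (6.1 Å²/ns planted, 6.16/6.17 recovered by the
two estimators), `dwell_times.py` (10 ns planted mean dwell, 10.12 ns
recovered from ~5,900 events), `water_pockets.py` (a constructed 50%
bulk-water fraction, reduced to 25% after acetyl pseudo-atoms fill the
pocket).

A thin CLI wraps the same pipeline for shell use:

```sh
acetwall pockets --generator toy_cellwall --equilibration 0 --out results
acetwall run config.yaml
```

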