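# Methods

This note documents the models, conventions and numerical choices
behind `acetwall`, and what its synthetic validations do and do not
demonstrate about real trajectory data.

## Data model and units

Structures are flat atom tables: element, mass (g/mol), component
(cellulose, hemicellulose, lignin, water, ion), functional group
(hydroxyl, carboxyl, acetyl, none), residue id, formal charge, and a
site id grouping the atoms of one functional-group instance. Functional
groups may only decorate hemicellulose and lignin: cellulose is not
acetylated in this model family. Group *abundance* counts instances,
not atoms (hydroxyl = 1 heavy atom, carboxyl = 3, acetyl = 4 including
the ester oxygen inherited from the hydroxyl); loaders that cannot
recover site ids fall back to dividing heavy-atom counts by these
ratios.

Boxes are orthorhombic (triclinic input is rejected) and may fluctuate
frame to frame, as under semi-isotropic pressure coupling. Lengths are
Å, times ns, energies kcal/mol; diffusion converts exactly as
1 Å²/ns = 10⁻⁷ cm²/s. Atom indexing is 0-based throughout. The default
equilibration cutoff discards the first 50 ns of a trajectory from all
dynamical statistics. Frame intervals are read from trajectory
metadata when present and must otherwise be supplied: archived
metadata of this kind is frequently wrong or missing, so the interval
is always overridable in configuration.

## Acetylation bookkeeping

Acetylation replaces the hydroxyl hydrogen with –C(=O)CH₃: +6 atoms
added, 1 removed (net +5), dry-mass change +43.045 − 1.008 =
+42.037 g/mol per site. Exposure is the minimum-image distance from
the hydroxyl *oxygen* to the nearest water *oxygen* — a convention
chosen because it is insensitive to hydrogen placement; the cutoff
(3, 6, 12 Å or ∞) tunes the acetylation degree. Two modes are
supported: *expanded* (all water retained, the box grows) and
*constant* (fixed volume; `round(ρ_H₂O·N_A·ΔV/MW_H₂O)` whole water
molecules are removed, with ρ_H₂O defaulting to 0.997 g/cm³ at 300 K —
configurable, since the bookkeeping convention leaves it open). The
default removal policy deletes the waters nearest the newly added
acetyl atoms, matching the picture of acetyl groups directly
displacing water; a seeded random-bulk policy is available for
comparison, and the dry-mass-based WPG is invariant to the choice.
Atom placement for added acetyl atoms is bookkeeping-level (labels,
masses, pseudo-coordinates near the site), not a minimised geometry:
downstream analyses consume labels and counts. Moisture content is
water mass over total mass excluding ions by default (a flag includes
them).

The inverse bookkeeping `sites = (atoms_post − atoms_pre + 3·waters)/5`
must divide exactly; a remainder signals inconsistent inputs. Applied
to the published system sizes of this model family it recovers 4098
acetyl sites at full acetylation and 1193 at the 3 Å cutoff (29% of
4098); the 6 Å column of the published table is known to be internally
inconsistent with its system sizes and is not used as a check.

## Diffusion

Coordinates are unwrapped by accumulating per-frame minimum-image
displacements (`u(t) = u(t−1) + Δ_min(w(t−1), w(t))`, using the current
frame's box), which is valid while no particle moves half a box length
per frame — a warning fires otherwise. Drift is removed by subtracting
the centre-of-mass displacement of a reference group (the central
cellulose fibril in the real system); this is translation-only, since a
rotational superposition would corrupt the MSDs of everything outside
the reference.

Two estimators implement the Einstein relation `MSD = 6Dt`:

- **Fixed-origin linear fit** (for large independent populations such
  as water): `MSD(t) = ⟨|r(t) − r(t_ref)|²⟩` with `t_ref` the first
  post-equilibration frame, fitted over 10–90% of the lag span by
  default. The default fit is a generalised least squares through the
  origin: a fixed-origin MSD of independent random walks has covariance
  ∝ min(s,t)², so `r(t) = MSD(t)/t` is an AR(1)-like sequence whose
  innovations can be whitened exactly. On Brownian test data this
  halves the sampling error of the recovered D relative to ordinary
  least squares (≈2.5% vs ≈5% relative sd at 500 particles × 1000
  frames); for exactly linear input both methods return the exact
  slope, and plain OLS remains available (`method="ols"`). The GLS
  weighting assumes a through-origin linear MSD and should not be used
  on strongly subdiffusive curves.
- **Sliding window** (for collectively moving biopolymers and ions):
  `D = ⟨|r(t₀+Δt) − r(t₀)|²⟩ / 6Δt` averaged over all window starts
  (stride one frame, maximally overlapping), with Δt = 50 ns by
  default. The standard error is computed on *non-overlapping* windows
  only, to avoid understating uncertainty from overlap; with a 1000 ns
  trajectory and 50 ns windows this gives the 19-block convention.
  When the window spans the whole trajectory the estimate reduces
  exactly to the single-interval value `MSD(T)/6T`.

## Contacts and free energies

Contacts are logistic switching weights `w(d) = [1 + e^{5(d−5Å)}]⁻¹`
summed over heavy-atom pairs, found with a periodic KD-tree
(`cutoff ≤ min(L)/2`; otherwise a warned brute-force minimum-image
scan). Pairs beyond 12 Å are skipped: the weight there is < 10⁻¹⁵, so
scores are bit-stable regardless of search radius. Self-pairs are
excluded when groups overlap.

Interaction probabilities are per-site mean contact scores
(score / group abundance) normalised across the groups present; the
normalisation constant cancels in every ratio. Relative binding free
energy against the carboxyl reference is `ΔG = −RT ln(P_s/P_c)`
(R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, T = 300 K default); the reference
is exactly 0 with σ exactly 0. Uncertainties divide the production
frames into 20 equal blocks and propagate relative standard errors as
`σ_ΔG = RT·√((σ_s/P_s)² + (σ_c/P_c)²)`. Zero probabilities are
signalled as not estimable rather than returned as infinities. The
exact normalisation converting group scores into probabilities is a
genuinely open convention (per-site vs per-atom, per-frame vs pooled);
the per-site pooled convention is implemented because it makes the
two-route cross-check below exact on occupancy models.

The independent RDF route computes a number-density-normalised g(r)
(bins to 10 Å by default, raw per-centre pair counts retained),
integrates it to the first minimum to get a coordination number per
ion, normalises by group abundance and applies the same ΔG formula.
First-minimum detection smooths the profile (Savitzky–Golay, window 9,
order 2, then a cubic spline on a 10× refined grid) and takes the
first strict local minimum after the global peak *below half the peak
height*; the guard exists because bin noise on a peak flank otherwise
fakes shallow minima and silently truncates the shell. Profiles
without a qualifying minimum fall back to the first strict minimum, or
signal the caller to supply a radius explicitly (real acetyl RDFs are
multi-peaked from the group's internal structure, so the manual
override matters there). Block errors reuse the full-profile minimum
radius across the 20 chunks so the blocks measure counting noise, not
detection jitter.

## Dwell times

A dwell is a maximal run of consecutive frames with an ion–site
minimum-image distance ≤ 6 Å, per ion–site pair; duration = run length
× frame interval. Runs touching either trajectory end are flagged
censored and excluded from mean statistics — in the real system some
trivalent-ion dwells outlast the entire simulation, so censoring must
be explicit rather than silently averaged in. Distributions are
summarised time-weighted: each event weighted by its duration over
total bound time, which answers "how long will an interaction observed
at a random bound moment last" rather than over-representing the many
short events.

## Water pockets

A water molecule is bulk when its oxygen is more than 5 Å from every
biopolymer atom (hydrogens included on the polymer side, reading the
definition literally; a flag restricts to heavy atoms). The water-side
reference is the oxygen, consistent with the exposure convention.
Classification uses a periodic KD-tree nearest-neighbour query and is
invariant under rigid translation and re-wrapping. Ions do not count
as biopolymer for the exclusion. An optional single-linkage clustering
(3.5 Å) can count discrete pockets, but the validated observable is
the fraction.

## Synthetic generators

Each generator is deterministic under a fixed seed and returns a
machine-readable ground-truth record alongside the trajectory (sidecar
JSON available), so tests never re-derive truth from the code under
test. They are statistical stand-ins, not physics: no force field, no
excluded volume, no electrostatics.

- **Brownian tracers**: independent Gaussian walks, per-step
  per-dimension variance `2·D·Δt`, wrapped into the box. Defaults (500
  particles, 1000 frames, 0.1 ns) are the validation conditions for
  the diffusion estimators; planted coefficients 0.05, 0.62 and
  6.1 Å²/ns span the iron-to-sodium range of the real system.
- **Two-state binding**: ions teleport between "within 3 Å of a site"
  and "far from every site" with geometric run lengths (the estimator
  sees frames, not continuous time); mean dwells are specified in ns
  and converted by the frame interval. Sites sit on a 12 Å grid so a
  bound ion can never graze a neighbouring site's 6 Å dwell shell,
  making estimator runs map one-to-one onto the planted state
  sequence. A zero mean unbound dwell means rebinding within a frame:
  ions are observed always bound.
- **Boltzmann occupancy**: each frame, each ion independently occupies
  a site of type s with probability ∝ count_s·e^{−E_s/RT}, at a
  bell-shaped coordination distance (normal, mean 2.0 Å, sd 0.35,
  clipped to [1.0, 2.9] Å) from its site; sites sit on a 14 Å grid so
  each RDF has an interior peak followed by an exact-zero gap. Because
  occupancy is resampled per frame there are no kinetics: this fixture
  validates the thermodynamic estimators, while the binding fixture
  validates the kinetic ones. Default counts (150 carboxyl versus
  several hundred competing sites, 150 ions) mirror the real model's
  carboxyl and ion counts.
- **Toy cell wall**: a single-frame slab with hydroxyl sites whose
  nearest-water distances are prescribed exactly (audited internally
  by brute force), carboxyl sites, bound-shell and pocket waters, and
  ions. Ground truth records the exposure distances and the per-water
  bulk flag under the 5 Å rule.

What passing these validations shows: the estimators are unbiased and
correctly calibrated on data that satisfies their statistical
assumptions, and all geometric machinery agrees exactly with
brute-force enumeration. What they do not show: correctness of any
physical force field, behaviour under correlated or subdiffusive
motion, or the adequacy of 50 ns equilibration for a real wall — those
are properties of the data, not of this code.

## Problem sizes and determinism

Validation suites run at deliberately modest scale — 500 tracers ×
1000 frames for diffusion, 150 ions × 200 frames for occupancy, ~6,000
dwell events, 2000 ideal-gas particles × 50 frames for the flat-g(r)
identity — chosen so the whole suite completes in about a minute while
leaving each recovery tolerance several standard errors wide. All
randomness flows from explicit integer seeds through numpy
`default_rng`; pipeline runs with the same seed produce byte-identical
reports.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- The acetylation step is bookkeeping, not chemistry: no reaction
  energetics, no differential lignin-versus-hemicellulose reactivity,
  no cellulose acetylation.
- Fixed-origin MSD follows the stated definition (no multi-origin
  averaging); the GLS default assumes linear-through-origin MSDs.
- The contact-to-probability normalisation is one defensible
  convention among several; alternatives are config-switchable but not
  cross-validated against each other on real data.
- No absolute binding constants; only relative ΔG against carboxyl,
  with no unbound reference state.
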