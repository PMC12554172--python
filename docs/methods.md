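# Methods

This note documents the models, estimators and numerical conventions
implemented in `degronmap`, the assumptions behind them, and what the
synthetic-data generators do and do not emulate.

## Substitution-array analysis

**Model.** A positional substitution scan prints one peptide per
(position, residue) cell plus a parent-residue reference cell at every
position and a C-terminal truncation series. Replicated fluorescence is
treated as parent-proportional with multiplicative cell effects: the
quantity of interest at cell (p, a) is the ratio of its expected signal to
the parent cell's at the same position, reported as percent.

**Normalization.** Every replicate value is divided by the *pooled mean*
of the parent cell at its position (not by a per-replicate parent value);
the per-cell mean and SD across all replicates are reported in percentage
points. Consequences: the parent cell's mean is exactly 100 with an SD
equal to its own replicate scatter, and the matrix is invariant to any
global rescaling of a replicate.

**Significance.** Replicate values (parent-normalized by default; raw
fluorescence by option — the assay axis is "% immunoreactivity", so
normalized is the default) enter a two-way ANOVA with position,
substituted residue and their interaction. Per-position inference is the
"simple effect within columns" reading: Tukey HSD contrasts of every
substitution against the parent residue among the k = 20 residue groups of
that position, using the pooled within-position mean square. The
studentized-range survival function is evaluated on a cached q-grid
(step 0.05 up to q = 10) and log-interpolated; the grid is exact to ~1e−4
in p, far below any decision boundary, and costs one scipy evaluation pass
per (k, df) instead of one per contrast. Cells with zero pooled
within-scatter are handled deterministically (p = 1 for zero difference,
p = 0 otherwise). With a single replicate per cell inference is refused
and a descriptive table returned with a warning.

**Classification.** Defaults: `essential_floor` = 20% of parent,
`essential_fraction` = 0.8, with Arg and Lys exempted from the essential
count because a positive charge can rescue binding through the acidic
receptor interface rather than through the parent residue's chemistry. A
position is *essential* when ≥ 80% of the remaining 17 substitutions fall
below 20% of parent *and* are flagged significant decreases;
*charge-enhanced* when Arg and/or Lys are flagged increases; *mixed* for
any other flagged effect; *tolerant* otherwise.

**Truncation boundary.** Truncation-peptide means are expressed as percent
of the longest (full-length) truncation peptide and scanned from full
length toward the N terminus; the boundary is the last-retained position
just above the first truncation below `loss_threshold` (default 20%),
i.e. the most C-terminal residue whose removal abolishes binding. If no
truncation crosses the threshold the function returns `None`.

## Trajectory post-processing

**Superposition and RMSD.** Kabsch superposition via SVD of the
cross-covariance of the centered point sets, with the determinant
correction that enforces a proper rotation; collinear point sets are
rejected (the rotation is underdetermined). RMSD series use frame 0 of the
same trial as the reference and superpose on the *selection's own* Cα
atoms — the common MD-toolchain default; rigid-body motion of the
selection is therefore invisible by construction, and peptide "drift" means
internal deformation or motion relative to the receptor when the complex
selection is used. Fit-on-receptor / compute-on-peptide is not the
default because the source protocol for the whole-complex RMSD is
unspecified; the choice is documented rather than asserted. Mass-weighting
is not applied (Cα-only coarse graining makes all weights equal anyway).

**Aggregation.** Pointwise mean and *population* variance (ddof = 0)
across trials; series of unequal length are truncated to the shortest with
a warning; a single trial yields zero variance with a warning.

**Contacts.** Two residues are in contact when their Cα–Cα distance is
*strictly* below the cutoff (0.8 nm default); d = cutoff exactly is no
contact. The boundary convention is arbitrary but fixed and tested. The
indicator is averaged over retained frames within each trial, then over
trials; with equal frame counts this equals pooled-frame averaging (an
asserted test invariant). Burn-in is a fixed discard of the first 500
frames by default (configurable); with the 10 ps frame spacing used
throughout this corresponds to the first 5 ns of a production run. Only
cross-chain (receptor × peptide) pairs are stored.

**Pose ranking.** Composite score per pose: the pair (time-mean peptide
RMSD, time-mean trial variance), ranked ascending lexicographically —
drift dominates, variance breaks near-ties only when drifts are exactly
equal (floating-point equality; documented, not fuzzy). Remaining ties
fall back to the maximum contact-map entry (descending) and pose label.

**Static contacts.** Atoms on different chains contact when
`r_i + r_j − d_ij ≥ −0.40 Å`. Van der Waals radii are the standard Bondi
(1964) values with Mantina et al. (2009) metals, bundled as a plain dict;
a missing element raises an error naming it. Pairs overlapping by ≥ 0.6 Å
additionally raise a steric-clash warning. A k-d tree restricts the pair
search to the maximal possible contact distance. Trajectory math is in nm,
static-structure math in Å (native to each file family).

## Equilibrium binding

**Model.** One-site Langmuir saturation of equilibrium responses,
`R(C) = B_max·C/(K_D + C)`; association/dissociation kinetics are out of
scope (contact-time metadata is consumed, not modeled). Reference
subtraction is per-concentration (`Fc2 − Fc1`); negative specific
responses are retained and flagged, never clipped, since they indicate
over-subtraction rather than impossible data.

**Fitting.** Unweighted trust-region least squares (`scipy.curve_fit`,
positivity bounds), initialized at B_max = max response, K_D = median
concentration; optional 1/variance weights. The instrument noise model is
unknown, hence unweighted by default. CIs from the parameter covariance
with a t quantile on n − 2 df. Preconditions: ≥ 4 concentrations spanning
≥ 1 decade. A K_D estimate outside [min C/10, max C·10] triggers a
"poorly constrained" warning. Noiseless generator output is recovered to
well beyond 4 significant figures; the estimator is equivariant under
response and concentration rescaling (tested).

**Dose–response.** Spearman rank correlation between spotted amount and
intensity with a one-sided (increasing) p-value, computed *exactly* by
enumerating all n! permutations (vectorized; n ≤ 8) and asymptotically
beyond. The verdict is based on the statistic (ρ ≥ 0.8 dose-dependent,
ρ ≤ 0.2 or constant input flat, else ambiguous) because with 3–5 dose
levels the exact p is necessarily coarse; the p-value is reported
alongside for inference.

## Turnover

**Half-life.** Single-exponential decay `N(t) = 100·2^(−t/t_half)` — one
half-life per condition, no plateau, matching how chase experiments are
conventionally summarized; a raw-scale nonlinear fit is available as an
option. The default estimator regresses ln N on t with a *free* intercept:
chase densitometry normalizes every replicate to its own t = 0 band, which
injects the t = 0 noise into all points of that replicate, and a free
intercept keeps the slope (hence t_half = ln 2 / k) unbiased under that
correlation. Non-positive abundances are dropped with a warning before the
log; a non-positive fitted rate raises a "no decay detected" error. CI by
inverting the t-interval on k.

**Normalization and co-IP.** Band / loading-control per lane, scaled so
the designated reference (t = 0 or untreated wild type) means 100%; co-IP
association is IP/input scaled so the wild-type mean is 100%, with
negative-control (IgG) lanes excluded from scaling but reported on the
same scale. All normalizations are invariant to per-replicate global
intensity scaling.

**Stabilization comparisons.** Full factorial genotype × treatment tables
get a two-way ANOVA (type II) plus post hoc pairwise comparisons across
the design cells — Tukey HSD by default, Bonferroni-adjusted Welch t tests
by option, since both conventions appear in this literature; a degenerate
single-factor two-group table falls back to an unpaired Student's t test.
Empty cells are rejected by name.

## Synthetic-data generators

The generators define the study conditions the tests run under:

- **Arrays** — 12 positions × 20 residues plus truncations, 9 replicates
  (emulating 3 experiments × 3 technical replicates, flattened),
  multiplicative lognormal noise with log-sd 0.1 (≈10% CV, a typical
  well-behaved fluorescence assay). `rgs2_degron_profile()` encodes the
  degron's qualitative ground truth: inert hydrophobic 5–10, essential
  Cys13 (all substitutions ≈ 2% of parent except Arg/Lys, with bulky
  aromatics partially retained), across-the-board enhancement at Asp12,
  Arg/Lys enhancement in the 11–16 half, Pro15→Ala/Gly loss, and a
  truncation series that retains ≥ 90% signal down to last-retained 13 and
  ≈ 2% below.
- **Trajectories** — kinematic constructions, not physics. Receptor sites
  sit on a wide helix ≥ 10 nm apart, so unlisted cross-chain pairs can
  never approach the cutoff; a paired peptide residue sits 0.5 nm (contact)
  or 1.5 nm (apart) from its site, realizing `round(f·n)` contact frames
  per trial exactly — first-frames-first when noise is off (making the
  noiseless occupancy post-condition exact), randomly permuted otherwise
  (preserving the count, hence the realized fraction, while decoupling
  occupancy from burn-in). The stability ensemble plants pose drift as an
  isotropic expansion of the peptide about its centroid ramping linearly
  to `drift · g_trial` (g lognormal per trial), which the peptide-selection
  RMSD reproduces exactly since superposition cannot absorb a scaling;
  defaults (drift 0.10/0.40/0.50/0.60/0.12 nm, trial spread
  0.10/0.35/0.35/0.35/0.10 for poses 1–5) emulate a five-pose ensemble
  whose first and fifth poses are the stable binders.
- **Isotherms** — 9-point two-fold series 0.29–75 μM, specific Langmuir
  term plus a linear nonspecific term present in both channels (slope
  1 RU/μM default), lognormal 2% noise for the recovery studies.
- **Chase courses** — timepoints {0, 10, 20, 30, 45, 60} min (a stand-in
  grid, configurable), 3 replicates, 5% lognormal noise applied to raw
  intensities *before* per-replicate renormalization to t = 0 — exactly the
  processing order of real chase densitometry, so t = 0 is 100 by
  construction even under noise.

One global seed fans out to fixed per-generator substreams
(`default_rng([stream, seed])`), so generators are independent yet jointly
reproducible; identical (inputs, seed) give byte-identical outputs.

**What the generators do not emulate:** spot-finding artifacts, spatial
gradients or saturated pixels on arrays; force-field physics, solvent, or
correlated residue motion in trajectories; SPR drift, bulk shifts or
kinetic transients; blot background or nonlinear film response. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise models, not robustness to every instrument pathology.

## Problem sizes and determinism

Recovery studies use 100 seeds per condition; the null false-positive
study uses 200 arrays; trajectory checks use 4 trials × 200 frames
(stability ensembles 100 frames), sizes at which the Monte-Carlo medians
are stable to well under the tolerances tested. Property tests
(hypothesis) run with fixed example counts and derandomized seeds. The
acceptance script derives every stream from its `--seed` argument and
writes identical output for identical seeds.

## Known limitations

- Tukey p-values below ~1e−300 clip at the grid floor (irrelevant in
  practice); the familywise adjustment treats the 20 residue groups of a
  position as the comparison family, not the whole array.
- The truncation boundary assumes a monotone-loss series; non-monotone
  signals return the first crossing from full length.
- `fit_saturation` covariance CIs are symmetric-in-parameter approximations;
  profile-likelihood intervals are not implemented.
- The peptide-spelling check recognizes only the two published variants of
  the RGS2 degron; other sequences pass through unchecked.
- GRO-format trajectory frames are not parsed; multi-model PDB and the
  plain coordinate table are the supported interchange formats.
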