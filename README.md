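# degronmap

Analysis toolkit for mapping a protein **degron** — the minimal sequence
element an E3 ubiquitin-ligase component recognizes to target a substrate
for proteasomal degradation. The motivating system is the N-terminal degron
of RGS2 (residues 5–16, `MFLAVQHDCRPM`) bound by the F-box–associated (FBA)
domain of FBXO44, but every operation is generic over parent sequence,
chain labels and experimental design.

The package covers the four quantitative legs such a study stands on, plus
a ground-truth synthetic-data generator so the whole chain is testable
without instrument output:

1. **Substitution/truncation peptide arrays** (`degronmap.arrays`) —
   replicated fluorescence per (position, substituted residue) peptide is
   normalized to the parent residue at each position
   (`mean% = 100 · x̄_cell / x̄_parent`), substitution effects are called by
   two-way ANOVA with Tukey HSD contrasts against the parent within each
   position, positions are classified (*essential* / *charge-enhanced* /
   *mixed* / *tolerant*), and a C-terminal truncation boundary is located.
2. **MD-trajectory post-processing** (`degronmap.trajectory`) — per-frame
   RMSD of a selection versus the production-start conformation after
   Kabsch least-squares superposition; mean/variance aggregation over
   independent trials; Cα contact-frequency maps (contact ⇔ d < 0.8 nm,
   averaged over post-burn-in frames within each trial, then over trials,
   so scores run 0–1); composite pose-stability ranking. Static structures
   get interface contacts via the van der Waals overlap criterion
   `r_i + r_j − d_ij ≥ −0.40 Å` (`degronmap.structure`).
3. **Equilibrium binding** (`degronmap.binding`) — two-channel SPR
   reference subtraction (specific = Fc2 − Fc1) and a one-site saturation
   fit `R(C) = B_max·C / (K_D + C)` for the dissociation constant, plus an
   exact rank-based dose–response check for dot-blot dilution series.
4. **Protein turnover** (`degronmap.turnover`) — loading-control
   densitometry normalization, co-IP association as % of wild type,
   single-exponential chase half-life fits `N(t) = 100 · 2^(−t/t_half)`,
   and factorial genotype × treatment stabilization comparisons.

`degronmap.synthetic` generates all of the above with known ground truth
(deterministic per seed; exact closed-form expectations with noise off),
and `degronmap.io` round-trips everything through plain-text TSV /
multi-model PDB.

## Worked example

`examples/` holds one short narrative script per capability. For instance,
fitting a noisy synthetic SPR isotherm (`python examples/03_binding_fit.py`):

```
Concentration series (μM): [0.29, 0.59, 1.17, 2.34, 4.69, 9.38, 18.75, 37.5, 75.0]
Fitted K_D  = 2.19 μM  (95% CI 2.08-2.30)
Fitted Bmax = 100.5 RU (95% CI 99.3-101.6)
```

The fitted K_D is the analyte concentration at half-maximal specific
response; with 2% multiplicative noise it lands within a few percent of the
2.1 μM ground truth the isotherm was generated from. Likewise,
`examples/04_turnover.py` fits chase courses generated at 19.5 min
(wild-type) and 33.5 min (degron-mutant) half-lives:

```
WT: fitted t_1/2 = 19.9 min (95% CI 19.1-20.7, R^2 = 0.994)
C13S: fitted t_1/2 = 34.6 min (95% CI 32.3-37.2, R^2 = 0.983)
```

— the near-doubling of half-life is the signature of a degron mutant that
escapes its E3 ligase. `examples/01_substitution_array.py` recovers the
array classification (position 13 essential, truncation boundary 13) and
`examples/02_trajectory_contacts.py` the planted pose-stability ordering.

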