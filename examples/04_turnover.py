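"""Protein turnover: chase half-life fits and stabilization comparison.

Generates cycloheximide-chase decay courses at the wild-type (19.5 min) and
degron-mutant (33.5 min) half-lives with 5% multiplicative noise, fits the
single-exponential model N(t) = 100 * 2^(-t/t_half), and runs a factorial
genotype x treatment stabilization comparison emulating a proteasome-
inhibitor experiment in which only the wild type responds.
"""

import numpy as np
import pandas as pd

from degronmap import GeneratorConfig, compare_stabilization, fit_decay, gen_chase

for label, t_half in (("WT", 19.5), ("C13S", 33.5)):
    cfg = GeneratorConfig(seed=21, noise_model="lognormal", noise_scale=0.05, n_replicates=3)
    course = gen_chase(t_half, config=cfg, condition=label)
    fit = fit_decay(course)
    print(
        f"{label}: fitted t_1/2 = {fit.t_half_min:.1f} min "
        f"(95% CI {fit.t_half_ci[0]:.1f}-{fit.t_half_ci[1]:.1f}, R^2 = {fit.r_squared:.3f})"
    )
print()
print(
    "The mutant half-life comes out close to double the wild type's, the signature\n"
    "of a degron mutation that escapes its E3 ligase."
)

# proteasome-inhibitor response: WT doubles, mutant unchanged
rng = np.random.default_rng(2)
rows = []
for geno, effect in (("WT", 2.0), ("C13S", 1.0)):
    for treat, mult in (("vehicle", 1.0), ("MG132", effect)):
        for _ in range(3):
            rows.append(
                {
                    "genotype": geno,
                    "treatment": treat,
                    "value": 100.0 * mult * (1 + 0.05 * rng.standard_normal()),
                }
            )
res = compare_stabilization(pd.DataFrame(rows))
print()
print("Two-way ANOVA (genotype x treatment):")
print(res.anova.round(4).to_string())
print()
sig = res.pairwise[res.pairwise["significant"]]
print("Significant Tukey pairwise comparisons:")
print(sig.to_string(index=False))
print()
print(
    "A significant interaction plus a WT vehicle-vs-MG132 pairwise difference, with\n"
    "no corresponding mutant difference, is the stabilization fingerprint."
)
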