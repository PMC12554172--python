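"""SPR equilibrium analysis: reference subtraction and one-site K_D fit.

Generates a two-channel isotherm over the 9-point two-fold series from 0.29
to 75 μM with a 2.1 μM ground-truth dissociation constant and linear
nonspecific binding, subtracts the reference channel, and fits the one-site
saturation model R(C) = Bmax C / (K_D + C).  Also runs the monotonic
dose-response check used for dot-blot dilution series.
"""

from degronmap import (
    GeneratorConfig,
    dose_response_check,
    fit_saturation,
    gen_isotherm,
    reference_subtract,
)

config = GeneratorConfig(seed=5, noise_model="lognormal", noise_scale=0.02)
isotherm = gen_isotherm(kd=2.1, bmax=100.0, nonspecific_slope=1.0, config=config)
specific = reference_subtract(isotherm)
fit = fit_saturation(specific)

print("Concentration series (μM):", [round(float(c), 2) for c in isotherm.concentrations])
print(f"Fitted K_D  = {fit.kd_uM:.2f} μM  (95% CI {fit.kd_ci[0]:.2f}-{fit.kd_ci[1]:.2f})")
print(f"Fitted Bmax = {fit.bmax_RU:.1f} RU (95% CI {fit.bmax_ci[0]:.1f}-{fit.bmax_ci[1]:.1f})")
print()
print(
    "K_D is the analyte concentration giving half-maximal specific response; with\n"
    "2% noise the fit lands within a few percent of the 2.1 μM ground truth."
)

# dot-blot style dilution series: signal should rise monotonically with amount
amounts = [0.5, 1.0, 2.0, 4.0, 8.0]
signal = [3.0, 8.0, 15.0, 33.0, 70.0]
res = dose_response_check(amounts, signal)
print()
print(
    f"Dose-response check: Spearman rho = {res.statistic:.2f}, one-sided exact "
    f"p = {res.p_value:.3f} -> verdict: {res.verdict}"
)
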