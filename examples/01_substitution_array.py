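"""Substitution-array scan: from replicated fluorescence to an essential-residue call.

Generates a replicated 12-position x 20-amino-acid substitution array for
the RGS2 degron peptide (residues 5-16) with the known ground-truth effect
pattern, normalizes every cell to the parent residue at its position, calls
significant effects (Tukey contrasts against the parent within each
position), classifies positions, and locates the C-terminal truncation
boundary.
"""

from degronmap import (
    GeneratorConfig,
    classify_positions,
    gen_array_signals,
    normalize_to_parent,
    rgs2_degron_profile,
    test_substitution_effects,
    truncation_boundary,
)

profile = rgs2_degron_profile()
config = GeneratorConfig(seed=11, noise_model="lognormal", noise_scale=0.1, n_replicates=9)
dataset = gen_array_signals(profile, parent_signal=1000.0, config=config)

matrix = normalize_to_parent(dataset)
table = test_substitution_effects(dataset)
categories = classify_positions(matrix, table)
boundary = truncation_boundary(dataset)

print("Mean % of parent signal at position 13 (Cys):")
print(matrix.mean_pct.loc[13].round(1).to_string())
print()
print("Per-position classification:")
print(categories.to_string())
print()
print(f"Truncation boundary (last essential position): {boundary}")
print()
print(
    "Position 13 should be the only 'essential' call — nearly every substitution\n"
    "collapses the signal below 20% of parent — and removing it (truncation past\n"
    "position 13) abolishes binding, so the boundary lands on 13."
)
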