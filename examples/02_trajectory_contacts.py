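"""MD post-processing: RMSD stability, contact maps and pose ranking.

Builds a five-pose, four-trial synthetic trajectory ensemble in which poses
1 and 5 are planted as the stable binders (small drift from the starting
conformation, low trial variance), computes peptide RMSD series versus the
production start, aggregates them over trials, and ranks the poses; then
demonstrates the 0-1 normalized Cα contact-frequency map on an ensemble
with prescribed occupancies.
"""

from degronmap import (
    ContactParams,
    GeneratorConfig,
    aggregate_rmsd,
    contact_frequency,
    gen_stability_ensemble,
    gen_trajectories,
    rank_pose_stability,
    rmsd_series,
)

ensemble = gen_stability_ensemble(config=GeneratorConfig(seed=3), n_frames=200)
aggregates = {
    pose: aggregate_rmsd([rmsd_series(ensemble, pose, t) for t in ensemble.trials(pose)])
    for pose in ensemble.poses
}
ranking = rank_pose_stability(aggregates)
print("Pose stability ranking (drift = time-mean peptide RMSD vs frame 0):")
print(ranking.round(4).to_string(index=False))
print()
print(
    "Poses 1 and 5 occupy the top two ranks: their peptide drifts stay near\n"
    "0.05-0.06 nm with tiny trial variance, while the unstable poses drift 3-5x further."
)

# a touch of coordinate noise randomizes the contact schedule so occupancy
# targets survive the burn-in discard
contacts = gen_trajectories(
    {(234, 15): 1.0, (235, 13): 0.75, (168, 12): 0.4, (167, 11): 0.0},
    n_trials=4,
    n_frames=200,
    config=GeneratorConfig(seed=3, noise_model="gaussian", noise_scale=0.02),
)
cmap = contact_frequency(contacts, 1, ContactParams(burn_in=50))
print()
print("Contact-frequency map (receptor residues x peptide residues, 0-1):")
print(cmap.freq.to_string())
print()
print(
    "A score of 1 means the Cα pair sat within 0.8 nm in every retained frame of\n"
    "all four trials; 0 means it never did; fractions are the retained-frame average."
)
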