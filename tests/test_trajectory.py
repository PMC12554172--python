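"""Trajectory post-processing: Kabsch, RMSD series, contact maps, pose ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from degronmap import (
    ContactParams,
    DegenerateGeometryError,
    GeneratorConfig,
    TrajectoryEnsemble,
    aggregate_rmsd,
    contact_frequency,
    gen_stability_ensemble,
    gen_trajectories,
    kabsch_superpose,
    rank_pose_stability,
    rmsd_series,
)
from degronmap.trajectory import BurnInError, RMSDAggregate


def brute_force_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: minimize RMSD over rotation (rotvec) + translation numerically."""

    def cost(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = mobile @ rot.T + params[3:]
        return np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))

    best = np.inf
    for x0_rot in ([0, 0, 0], [1, 1, 1], [-2, 0.5, 1.5], [0.1, -3, 0.2]):
        x0 = np.concatenate([x0_rot, reference.mean(axis=0) - mobile.mean(axis=0)])
        res = minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.standard_normal((8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)

    def test_recovers_known_transform(self, rng):
        ref = rng.standard_normal((10, 3))
        true_rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ true_rot.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot @ true_rot, np.eye(3), atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_numeric_minimization_on_jittered_clouds(self, rng):
        for _ in range(3):
            ref = rng.standard_normal((10, 3))
            mobile = ref + 0.3 * rng.standard_normal((10, 3))
            _, _, rmsd = kabsch_superpose(mobile, ref)
            assert rmsd == pytest.approx(brute_force_rmsd(mobile, ref), abs=1e-6)

    def test_rejects_mismatched_counts(self, rng):
        with pytest.raises(ValueError, match="differ"):
            kabsch_superpose(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))

    def test_rejects_collinear_points(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


def toy_ensemble(frames_by_trial: dict, chains, resids) -> TrajectoryEnsemble:
    return TrajectoryEnsemble(
        coords={(1, t): np.asarray(f, dtype=float) for t, f in frames_by_trial.items()},
        chains=np.asarray(chains),
        resids=np.asarray(resids),
    )


class TestRMSDSeries:
    def _static(self, rng, n_frames=5):
        frame = rng.standard_normal((6, 3))
        return toy_ensemble(
            {0: np.repeat(frame[None], n_frames, axis=0)},
            chains=["A"] * 3 + ["B"] * 3,
            resids=[1, 2, 3, 1, 2, 3],
        )

    def test_static_trajectory_is_zero(self, rng):
        ens = self._static(rng)
        assert np.allclose(rmsd_series(ens, 1, 0, "peptide").values, 0.0, atol=1e-12)
        assert np.allclose(rmsd_series(ens, 1, 0, "complex").values, 0.0, atol=1e-12)

    def test_rigid_body_motion_is_invisible(self, rng):
        frame = rng.standard_normal((6, 3))
        frames = [frame]
        for angle in (10.0, 130.0, 250.0):
            rot = Rotation.from_euler("xyz", [angle, angle / 2, 7.0], degrees=True).as_matrix()
            frames.append(frame @ rot.T + angle / 30.0)
        ens = toy_ensemble({0: np.stack(frames)}, ["A"] * 3 + ["B"] * 3, [1, 2, 3, 1, 2, 3])
        series = rmsd_series(ens, 1, 0, "complex")
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_rigid_peptide_shift_matches_brute_force_on_complex(self, rng):
        frame0 = rng.standard_normal((12, 3))
        frame1 = frame0.copy()
        frame1[8:] += np.array([0.3, 0.0, 0.0])  # peptide shifted, receptor fixed
        ens = toy_ensemble({0: np.stack([frame0, frame1])}, ["A"] * 8 + ["B"] * 4, list(range(1, 9)) + list(range(1, 5)))
        series = rmsd_series(ens, 1, 0, "complex")
        assert series.values[1] == pytest.approx(brute_force_rmsd(frame1, frame0), abs=1e-6)

    def test_unknown_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="selection"):
            rmsd_series(self._static(rng), 1, 0, "ligand")

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_rigid_transform_invariance_property(self, seed):
        """Applying any proper rigid transform to all frames leaves the series unchanged."""
        rng = np.random.default_rng(seed)
        frames = rng.standard_normal((4, 6, 3))
        ens = toy_ensemble({0: frames}, ["A"] * 3 + ["B"] * 3, [1, 2, 3, 1, 2, 3])
        base = rmsd_series(ens, 1, 0, "complex").values
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.standard_normal(3)
        moved = frames @ rot.T + shift
        ens2 = toy_ensemble({0: moved}, ["A"] * 3 + ["B"] * 3, [1, 2, 3, 1, 2, 3])
        assert np.allclose(rmsd_series(ens2, 1, 0, "complex").values, base, atol=1e-9)


class TestAggregate:
    def test_identical_series_zero_variance(self, rng):
        ens = gen_trajectories({(1, 1): 1.0, (2, 2): 1.0, (3, 3): 0.5}, n_trials=4, n_frames=10)
        series = [rmsd_series(ens, 1, t) for t in range(4)]
        agg = aggregate_rmsd(series)
        assert np.allclose(agg.variance, 0.0)

    def test_mean_and_variance_arithmetic(self):
        from degronmap.trajectory import RMSDSeries

        s1 = RMSDSeries(np.full(5, 0.1), "peptide", 1, 0)
        s2 = RMSDSeries(np.full(5, 0.3), "peptide", 1, 1)
        agg = aggregate_rmsd([s1, s2])
        assert np.allclose(agg.mean, 0.2)
        assert np.allclose(agg.variance, 0.01)

    def test_single_trial_warns(self):
        from degronmap.trajectory import RMSDSeries

        with pytest.warns(UserWarning, match="single trial"):
            agg = aggregate_rmsd([RMSDSeries(np.arange(3.0), "peptide", 1, 0)])
        assert np.allclose(agg.variance, 0.0)

    def test_unequal_lengths_truncate_with_warning(self):
        from degronmap.trajectory import RMSDSeries

        s1 = RMSDSeries(np.zeros(5), "peptide", 1, 0)
        s2 = RMSDSeries(np.zeros(3), "peptide", 1, 1)
        with pytest.warns(UserWarning, match="truncating"):
            agg = aggregate_rmsd([s1, s2])
        assert len(agg.mean) == 3

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rmsd([])


def brute_force_contact_map(ens: TrajectoryEnsemble, pose: int, params: ContactParams):
    """Independent oracle: double loop over residue pairs and frames."""
    rec_idx = np.where(ens.chains == "A")[0]
    pep_idx = np.where(ens.chains == "B")[0]
    trials = ens.trials(pose)
    out = np.zeros((len(rec_idx), len(pep_idx)))
    for trial in trials:
        traj = ens.coords[(pose, trial)][params.burn_in :: params.stride]
        for a, i in enumerate(rec_idx):
            for b, j in enumerate(pep_idx):
                hits = 0
                for frame in traj:
                    if np.linalg.norm(frame[i] - frame[j]) < params.cutoff_nm:
                        hits += 1
                out[a, b] += hits / len(traj)
    return out / len(trials)


class TestContactFrequency:
    def test_hand_counted_fraction(self):
        # one pair at distances 0.5, 0.9, 0.7 nm over 3 frames -> 2/3
        frames = np.zeros((3, 2, 3))
        for f, d in enumerate((0.5, 0.9, 0.7)):
            frames[f, 1, 0] = d
        ens = toy_ensemble({0: frames}, ["A", "B"], [1, 1])
        cmap = contact_frequency(ens, 1, ContactParams(burn_in=0))
        assert cmap.freq.loc[1, 1] == pytest.approx(2.0 / 3.0)

    def test_strict_cutoff_convention(self):
        # exactly at the cutoff is NOT a contact; just inside is
        for d, expected in ((0.8, 0.0), (0.8 - 1e-9, 1.0)):
            frames = np.zeros((1, 2, 3))
            frames[0, 1, 0] = d
            ens = toy_ensemble({0: frames}, ["A", "B"], [1, 1])
            cmap = contact_frequency(ens, 1, ContactParams(burn_in=0))
            assert cmap.freq.loc[1, 1] == expected

    def test_burn_in_removal(self):
        frames = np.zeros((10, 2, 3))
        frames[:5, 1, 0] = 0.5  # contact only during the first half
        frames[5:, 1, 0] = 1.5
        ens = toy_ensemble({0: frames}, ["A", "B"], [1, 1])
        assert contact_frequency(ens, 1, ContactParams(burn_in=5)).freq.loc[1, 1] == 0.0
        assert contact_frequency(ens, 1, ContactParams(burn_in=0)).freq.loc[1, 1] == 0.5

    def test_burn_in_exceeding_trial_length_raises(self):
        ens = toy_ensemble({0: np.zeros((4, 2, 3))}, ["A", "B"], [1, 1])
        with pytest.raises(BurnInError, match="burn-in"):
            contact_frequency(ens, 1, ContactParams(burn_in=4))

    def test_matches_brute_force_loop(self, rng):
        cfg = GeneratorConfig(seed=17, noise_model="gaussian", noise_scale=0.05)
        occ = {(i, j): float(rng.uniform()) for i, j in [(101, 1), (102, 2), (103, 3)]}
        ens = gen_trajectories(occ, n_trials=3, n_frames=50, config=cfg)
        params = ContactParams(burn_in=10)
        cmap = contact_frequency(ens, 1, params)
        assert np.allclose(cmap.freq.to_numpy(), brute_force_contact_map(ens, 1, params))

    def test_trial_then_pool_equals_pooled_with_equal_frames(self):
        cfg = GeneratorConfig(seed=23, noise_model="gaussian", noise_scale=0.03)
        ens = gen_trajectories({(1, 1): 0.6, (2, 2): 0.3}, n_trials=4, n_frames=40, config=cfg)
        params = ContactParams(burn_in=0)
        cmap = contact_frequency(ens, 1, params)
        # pooled-frame averaging across all trials at once
        rec = ens.selection_mask("receptor")
        pep = ens.selection_mask("peptide")
        pooled = np.concatenate([ens.coords[(1, t)] for t in range(4)])
        d = np.linalg.norm(pooled[:, rec, None, :] - pooled[:, None, pep, :], axis=-1)
        assert np.allclose(cmap.freq.to_numpy(), (d < params.cutoff_nm).mean(axis=0))

    def test_entries_within_unit_interval(self, rng):
        cfg = GeneratorConfig(seed=3, noise_model="gaussian", noise_scale=0.1)
        occ = {(i, i): float(rng.uniform()) for i in range(1, 6)}
        ens = gen_trajectories(occ, n_trials=2, n_frames=30, config=cfg)
        freq = contact_frequency(ens, 1, ContactParams(burn_in=0)).freq.to_numpy()
        assert (freq >= 0.0).all() and (freq <= 1.0).all()


class TestPoseRanking:
    def _agg(self, pose, drift, var):
        return RMSDAggregate(
            mean=np.full(5, drift), variance=np.full(5, var), n_trials=4, selection="peptide", pose=pose
        )

    def test_lower_drift_wins(self):
        ranked = rank_pose_stability({1: self._agg(1, 0.2, 0.01), 2: self._agg(2, 0.6, 0.01)})
        assert list(ranked["pose"]) == [1, 2]

    def test_equal_drift_lower_variance_wins(self):
        ranked = rank_pose_stability({1: self._agg(1, 0.3, 0.09), 2: self._agg(2, 0.3, 0.01)})
        assert list(ranked["pose"]) == [2, 1]

    def test_planted_stable_poses_take_top_ranks(self):
        ens = gen_stability_ensemble(config=GeneratorConfig(seed=31), n_frames=100)
        aggs = {
            p: aggregate_rmsd([rmsd_series(ens, p, t) for t in ens.trials(p)]) for p in ens.poses
        }
        ranked = rank_pose_stability(aggs)
        assert set(ranked["pose"].iloc[:2]) == {1, 5}

    def test_planted_ordering_recovery_rate(self):
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            ens = gen_stability_ensemble(config=GeneratorConfig(seed=seed), n_frames=60)
            aggs = {
                p: aggregate_rmsd([rmsd_series(ens, p, t) for t in ens.trials(p)])
                for p in ens.poses
            }
            hits += set(rank_pose_stability(aggs)["pose"].iloc[:2]) == {1, 5}
        assert hits / n_runs >= 0.95
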