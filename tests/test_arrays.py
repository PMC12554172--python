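"""Array-scan analysis: enumeration, normalization, significance, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degronmap import (
    ArrayDesign,
    EffectProfile,
    GeneratorConfig,
    SubstitutionArrayDataset,
    classify_positions,
    enumerate_peptides,
    gen_array_signals,
    normalize_to_parent,
    truncation_boundary,
)
from degronmap import test_substitution_effects as substitution_effects
from degronmap.arrays import ParentSignalError, UnknownResidueError


def make_dataset(cell_values: dict, design: ArrayDesign) -> SubstitutionArrayDataset:
    """Build a dataset from {(position, residue): [replicate values]} plus defaults of 1000."""
    rows = []
    for pos in design.positions:
        parent_aa = design.parent_residue(pos)
        for aa in design.alphabet:
            values = cell_values.get((pos, aa), [1000.0])
            kind = "parent" if aa == parent_aa else "substitution"
            for rep, v in enumerate(values):
                rows.append(
                    {
                        "peptide_id": f"p{pos}{parent_aa}{aa}",
                        "kind": kind,
                        "position": pos,
                        "residue": aa,
                        "trunc_last": pd.NA,
                        "replicate": rep,
                        "signal": v,
                    }
                )
    return SubstitutionArrayDataset(design=design, signals=pd.DataFrame(rows))


class TestDesignAndEnumeration:
    def test_substitution_count_for_full_degron_design(self):
        design = ArrayDesign("MFLAVQHDCRPM", position_offset=5)
        peptides = enumerate_peptides(design)
        assert (peptides["kind"] == "substitution").sum() == 12 * 19
        assert (peptides["kind"] == "parent").sum() == 12

    def test_no_truncations_means_substitutions_only(self):
        peptides = enumerate_peptides(ArrayDesign("MFLAVQHDCRPM", 5))
        assert (peptides["kind"] == "truncation").sum() == 0

    def test_full_truncation_series(self):
        design = ArrayDesign("MFLAVQHDCRPM", 5, truncations=tuple(range(16, 4, -1)))
        trunc = enumerate_peptides(design).query("kind == 'truncation'")
        assert len(trunc) == 12
        assert trunc["sequence"].str.len().min() == 1
        assert trunc.loc[trunc["trunc_last"] == 5, "sequence"].iloc[0] == "M"

    def test_rejects_nonincreasing_truncations(self):
        with pytest.raises(ValueError, match="decreasing"):
            ArrayDesign("MFLAVQHDCRPM", 5, truncations=(14, 16))

    def test_rejects_nonstandard_alphabet(self):
        with pytest.raises(UnknownResidueError):
            ArrayDesign("MFLAVQHDCRPM", 5, alphabet="ACDEFGHIKLMNPQRSTVWX")


class TestNormalization:
    def test_simple_ratio(self):
        design = ArrayDesign("MC", 5)
        ds = make_dataset({(5, "A"): [500.0], (5, "M"): [2000.0]}, design)
        mat = normalize_to_parent(ds)
        assert mat.mean_pct.loc[5, "A"] == pytest.approx(25.0)

    def test_parent_cell_is_100_with_replicate_scatter(self):
        design = ArrayDesign("MC", 5)
        ds = make_dataset({(5, "M"): [900.0, 1000.0, 1100.0]}, design)
        mat = normalize_to_parent(ds)
        assert mat.mean_pct.loc[5, "M"] == 100.0
        expected_sd = 100.0 * np.std([900, 1000, 1100], ddof=1) / 1000.0
        assert mat.sd_pct.loc[5, "M"] == pytest.approx(expected_sd)

    def test_noiseless_generator_round_trip_recovers_profile(self, degron_profile):
        ds = gen_array_signals(degron_profile, 1000.0, GeneratorConfig(n_replicates=2))
        mat = normalize_to_parent(ds)
        for (pos, aa), factor in degron_profile.effect.items():
            assert mat.mean_pct.loc[pos, aa] == pytest.approx(100.0 * factor)

    def test_zero_parent_signal_raises_named_error(self):
        design = ArrayDesign("MC", 5)
        ds = make_dataset({(6, "C"): [0.0]}, design)
        with pytest.raises(ParentSignalError, match="position 6"):
            normalize_to_parent(ds)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        """Multiplying all signals of a replicate by a constant leaves the matrix unchanged."""
        design = ArrayDesign("MC", 5)
        ds = make_dataset({(5, "A"): [400.0, 600.0], (5, "M"): [1000.0, 1200.0]}, design)
        scaled = ds.signals.copy()
        scaled["signal"] *= scale
        mat = normalize_to_parent(ds)
        mat2 = normalize_to_parent(SubstitutionArrayDataset(design, scaled))
        pd.testing.assert_frame_equal(mat.mean_pct, mat2.mean_pct)
        pd.testing.assert_frame_equal(mat.sd_pct, mat2.sd_pct)


class TestSignificance:
    def test_null_zero_variance_never_flags(self):
        design = ArrayDesign("MCW", 5)
        ds = make_dataset({}, design)  # all cells identical
        ds = SubstitutionArrayDataset(
            design, pd.concat([ds.signals.assign(replicate=i) for i in range(3)], ignore_index=True)
        )
        table = substitution_effects(ds)
        assert not table.table["significant"].any()

    def test_planted_fivefold_increase_is_flagged(self):
        cfg = GeneratorConfig(seed=3, noise_model="lognormal", noise_scale=0.01, n_replicates=9)
        profile = EffectProfile("MFLAVQHDCRPM", {(12, "W"): 5.0}, {16: 1.0})
        ds = gen_array_signals(profile, 1000.0, cfg)
        row = substitution_effects(ds).lookup(12, "W")
        assert row["significant"] and row["direction"] == "increase"

    def test_single_replicate_refuses_inference(self):
        design = ArrayDesign("MC", 5)
        ds = make_dataset({(5, "A"): [100.0]}, design)
        with pytest.warns(UserWarning, match="single replicate"):
            table = substitution_effects(ds)
        assert table.descriptive_only
        assert table.table["p_adj"].isna().all()
        assert not table.table["significant"].any()

    def test_matches_statsmodels_tukey_contrasts(self, rng):
        """Parent-vs-substitution q/p computed in-package agree with statsmodels' Tukey HSD."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        design = ArrayDesign("MCW", 5, alphabet="ACMW")
        cells = {}
        for pos in design.positions:
            for aa in design.alphabet:
                base = 1000.0 * (2.0 if (pos, aa) == (5, "C") else 1.0)
                cells[(pos, aa)] = list(base + 30.0 * rng.standard_normal(4))
        ds = make_dataset(cells, design)
        table = substitution_effects(ds, on="raw")
        for pos in design.positions:
            sub = ds.signals[ds.signals["position"] == pos]
            tuk = pairwise_tukeyhsd(sub["signal"].to_numpy(), sub["residue"].to_numpy(), alpha=0.05)
            parent_aa = design.parent_residue(pos)
            groups = list(tuk.groupsunique)
            import itertools

            for (g1, g2), p in zip(itertools.combinations(groups, 2), tuk.pvalues):
                if parent_aa not in (g1, g2):
                    continue
                aa = g2 if g1 == parent_aa else g1
                ours = table.lookup(pos, aa)["p_adj"]
                assert ours == pytest.approx(p, abs=2e-3)


class TestClassification:
    def test_recovers_degron_pattern(self, noisy_degron_dataset):
        mat = normalize_to_parent(noisy_degron_dataset)
        table = substitution_effects(noisy_degron_dataset)
        cats = classify_positions(mat, table)
        essential = [p for p, c in cats.items() if c == "essential"]
        assert essential == [13]
        assert all(cats[p] == "tolerant" for p in range(5, 11))

    def test_flat_profile_all_tolerant(self):
        cfg = GeneratorConfig(seed=9, noise_model="lognormal", noise_scale=0.1, n_replicates=9)
        ds = gen_array_signals(EffectProfile.flat(), 1000.0, cfg)
        cats = classify_positions(normalize_to_parent(ds), substitution_effects(ds))
        assert (cats == "tolerant").all()

    def test_uniform_enhancement_is_charge_enhanced(self):
        effects = {(12, aa): 1.8 for aa in "ACEFGHIKLMNPQRSTVWY" if aa != "D"}
        profile = EffectProfile("MFLAVQHDCRPM", effects, {16: 1.0})
        cfg = GeneratorConfig(seed=5, noise_model="lognormal", noise_scale=0.05, n_replicates=9)
        ds = gen_array_signals(profile, 1000.0, cfg)
        cats = classify_positions(normalize_to_parent(ds), substitution_effects(ds))
        assert cats[12] == "charge-enhanced"


class TestTruncationBoundary:
    def _trunc_dataset(self, factors: dict) -> SubstitutionArrayDataset:
        profile = EffectProfile("MFLAVQHDCRPM", {}, factors)
        return gen_array_signals(profile, 1000.0, GeneratorConfig(n_replicates=2))

    def test_degron_pattern_boundary_at_cys13(self, degron_profile):
        ds = gen_array_signals(degron_profile, 1000.0, GeneratorConfig(n_replicates=2))
        assert truncation_boundary(ds) == 13

    def test_no_loss_returns_sentinel(self):
        ds = self._trunc_dataset({last: 1.0 for last in range(5, 17)})
        assert truncation_boundary(ds) is None

    def test_hand_computed_threshold_crossing(self):
        ds = self._trunc_dataset({16: 1.0, 15: 0.6, 14: 0.4})
        assert truncation_boundary(ds, loss_threshold=50.0) == 15

    def test_missing_truncations_rejected(self):
        ds = gen_array_signals(
            EffectProfile("MFLAVQHDCRPM", {}, {}), 1000.0, GeneratorConfig(n_replicates=2)
        )
        with pytest.raises(ValueError, match="truncation"):
            truncation_boundary(ds)
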