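"""Prioritization cascade: normalization, filters, conjunction order."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakeomp import synthetic
from lakeomp.screening import (
    Feature,
    FeatureTable,
    ReferenceProfile,
    ScreeningConfig,
    build_reference_profile,
    correlation_filter,
    normalize_profile,
    pearson_r,
    prioritize_features,
    spike_filter,
    static_filters,
)

DEPTHS = np.array([6.0, 7.0, 8.0, 9.0, 10.0])


def make_feature(intensities, blank=None, fid="F1"):
    return Feature(
        feature_id=fid, mz=300.0, retention_time=5.0,
        intensities=np.asarray(intensities, dtype=float), blank_intensity=blank,
    )


class TestNormalizeProfile:
    def test_max_mode(self):
        np.testing.assert_allclose(
            normalize_profile([2, 4, 8], "max"), [0.25, 0.5, 1.0]
        )

    def test_constant_profile(self):
        np.testing.assert_allclose(normalize_profile([5, 5, 5], "max"), 1.0)

    def test_mean_mode(self):
        out = normalize_profile([2, 4, 6], "mean")
        assert out.mean() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile([0, 0, 0])

    @given(
        st.lists(st.floats(0.1, 1e6), min_size=2, max_size=10),
        st.sampled_from(["max", "mean"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values, mode):
        once = normalize_profile(values, mode)
        twice = normalize_profile(once, mode)
        np.testing.assert_allclose(once, twice, rtol=1e-12)


class TestReferenceProfile:
    def test_single_profile_unchanged(self):
        p = np.array([0.2, 1.0, 0.4])
        ref = build_reference_profile([p], [6, 7, 8])
        np.testing.assert_allclose(ref.values, p)

    def test_symmetric_pair(self):
        ref = build_reference_profile(
            [np.array([1.0, 0.0]), np.array([0.0, 1.0])], [6, 7]
        )
        np.testing.assert_allclose(ref.values, [1.0, 1.0])

    def test_identical_profiles_zero_band(self):
        p = np.array([0.1, 1.0, 0.5])
        ref = build_reference_profile([p] * 10, [6, 7, 8])
        np.testing.assert_allclose(ref.values, p)
        np.testing.assert_allclose(ref.std, 0.0, atol=1e-12)

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_reference_profile([np.array([1.0, 0.5])], [6, 7, 8])


class TestPearsonR:
    def test_identity_and_reversal(self):
        assert pearson_r([1, 5, 9], [1, 5, 9]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # sum-of-products by hand: r = 3 / sqrt(2 * 14/3) = 0.98198
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_two_pass_covariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        xm, ym = x - x.mean(), y - y.mean()
        oracle = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert pearson_r(x, y) == pytest.approx(oracle, abs=1e-10)


class TestSpikeFilter:
    cfg = ScreeningConfig(spike_depth=7.0, adjacent_depths=(6.0, 8.0))

    @pytest.mark.parametrize(
        "i6,i7,i8,expected",
        [
            (100, 130, 100, True),
            (100, 110, 100, False),
            (100, 120, 100, True),  # inclusive at exactly 1.2-fold
            (100, 130, 120, False),  # must hold against both neighbours
        ],
    )
    def test_fold_change(self, i6, i7, i8, expected):
        feat = make_feature([i6, i7, i8, 50, 40])
        res = spike_filter(feat, DEPTHS, self.cfg)
        assert res.passed is expected

    def test_zero_adjacent_passes_flagged(self):
        res = spike_filter(make_feature([0, 130, 100, 50, 40]), DEPTHS, self.cfg)
        assert res.passed and res.detail["zero_adjacent"]
        assert res.detail["ratios"][6.0] == np.inf


class TestStaticFilters:
    cfg = ScreeningConfig()

    def test_passes(self):
        res = static_filters(make_feature([2e5, 3e5, 2e5, 1e5, 1e5]), self.cfg)
        assert res.passed

    def test_missing_depth_fails_presence(self):
        res = static_filters(make_feature([2e5, 3e5, 0.0, 1e5, 1e5]), self.cfg)
        assert not res.passed and not res.detail["present_all"]

    def test_floor_is_strict(self):
        res = static_filters(make_feature([1e4, 1e5, 1e4, 1e4, 1e4]), self.cfg)
        assert not res.passed and not res.detail["above_floor"]

    def test_blank_ratio(self):
        res = static_filters(
            make_feature([2e5, 3e5, 2e5, 1e5, 1e5], blank=2e5), self.cfg
        )
        assert not res.passed and not res.detail["blank_ok"]


class TestCorrelationFilter:
    ref = ReferenceProfile(depths=DEPTHS, values=np.array([0.5, 1.0, 0.4, 0.3, 0.2]))

    def test_proportional_passes(self):
        feat = make_feature(1e6 * self.ref.values)
        res = correlation_filter(feat, self.ref, ScreeningConfig())
        assert res.passed and res.detail["r"] == pytest.approx(1.0)

    def test_reversed_fails(self):
        feat = make_feature(1e6 * self.ref.values[::-1])
        res = correlation_filter(feat, self.ref, ScreeningConfig())
        assert not res.passed and res.detail["r"] < 0

    def test_threshold_is_strict(self):
        feat = make_feature([3e5, 9e5, 5e5, 2e5, 4e5])
        r = pearson_r(
            normalize_profile(feat.intensities), self.ref.values
        )
        res = correlation_filter(
            feat, self.ref, ScreeningConfig(r_threshold=r)
        )
        assert not res.passed  # r == threshold must fail

    def test_constant_profile_flagged_not_raised(self):
        res = correlation_filter(
            make_feature([1e5] * 5), self.ref, ScreeningConfig()
        )
        assert not res.passed and res.detail["undefined"]


class TestPrioritizeFeatures:
    def test_zero_noise_recall_and_rejection(self, scenario):
        table = synthetic.generate_feature_table(
            scenario, n_planted=5, n_decoys=50, seed=1, noise_cv=0.0,
            decoy_families=("flat",),
        )
        ref = synthetic.reference_profile_for(scenario)
        selected, audit = prioritize_features(table, ref)
        truth = table.frame.set_index("feature_id")["truth"]
        assert set(selected["feature_id"]) == set(truth.index[truth == "planted"])
        assert len(audit) == len(table)

    def test_empty_table(self, scenario):
        table = synthetic.generate_feature_table(
            scenario, n_planted=0, n_decoys=0, seed=1
        )
        ref = synthetic.reference_profile_for(scenario)
        selected, audit = prioritize_features(table, ref)
        assert selected.empty and audit.empty

    def test_missing_depth_rejected_with_presence_reason(self, scenario):
        table = synthetic.generate_feature_table(
            scenario, n_planted=1, n_decoys=0, seed=1, noise_cv=0.0
        )
        col = table.intensity_columns[3]
        table.frame.loc[0, col] = 0.0
        ref = synthetic.reference_profile_for(scenario)
        selected, audit = prioritize_features(table, ref)
        assert selected.empty
        assert audit.loc[0, "reject_reason"] == "presence"

    def test_retained_set_invariant_to_row_order(self, scenario):
        table = synthetic.generate_feature_table(
            scenario, n_planted=5, n_decoys=30, seed=2, noise_cv=0.05
        )
        ref = synthetic.reference_profile_for(scenario)
        sel_a, _ = prioritize_features(table, ref)
        shuffled = FeatureTable(
            depths=table.depths,
            frame=table.frame.sample(frac=1.0, random_state=0).reset_index(
                drop=True
            ),
        )
        sel_b, _ = prioritize_features(shuffled, ref)
        assert list(sel_a["feature_id"]) == list(sel_b["feature_id"])

    def test_decoy_pass_rate_monotone_in_threshold(self, scenario):
        table = synthetic.generate_feature_table(
            scenario, n_planted=0, n_decoys=60, seed=3, noise_cv=0.05,
            decoy_families=("random",),
        )
        ref = synthetic.reference_profile_for(scenario)
        counts = []
        for thr in (0.0, 0.4, 0.8):
            cfg = ScreeningConfig(r_threshold=thr)
            n = sum(
                correlation_filter(table.feature(row), ref, cfg).passed
                for _, row in table.frame.iterrows()
            )
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]
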