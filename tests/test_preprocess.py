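import numpy as np
import pandas as pd
import pytest

from phosrewire.core_io import ValidationError
from phosrewire.preprocess import (
    FilterSpec,
    ImputationParams,
    default_imputation_params,
    filter_features,
    impute_condition_pair,
    impute_self,
    log2_median_normalize,
)

from conftest import make_table


class TestFilterFeatures:
    def test_min_total_removes_underquantified(self):
        vals = np.full((2, 24), 20.0)
        vals[0, 7:] = np.nan  # quantified in 7/24 samples
        t = make_table(vals, {"CTRL": (6, 6), "HFD": (6, 6)})
        out = filter_features(t, FilterSpec(min_total_replicates=8))
        assert list(out.feature_ids) == ["f1"]

    def test_zero_threshold_is_identity(self):
        vals = np.full((3, 8), 20.0)
        vals[1, :5] = np.nan
        t = make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)})
        out = filter_features(t, FilterSpec(min_total_replicates=0))
        assert list(out.feature_ids) == list(t.feature_ids)

    def test_required_group_absence_removes(self):
        vals = np.full((1, 20), 20.0)
        t = make_table(vals, {"CTRL": (6, 4), "CI": (6, 4)})
        ctrl_cols = [c for c in t.sample_ids if c.startswith("CTRL")]
        t.values.loc["f0", ctrl_cols] = np.nan  # quantified 10x, never in CTRL
        out = filter_features(t, FilterSpec(min_total_replicates=0,
                                            require_group="CTRL"))
        assert len(out.feature_ids) == 0


class TestNormalize:
    def test_log2_and_columns_share_median(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1e5, 1e7, size=(41, 8))
        t = make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)},
                       scale_state="raw")
        out = log2_median_normalize(t)
        med = out.values.median(axis=0)
        assert np.allclose(med, med.iloc[0], atol=1e-9)
        assert out.scale_state == "log2_norm"

    def test_scaling_one_column_is_absorbed(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1e5, 1e7, size=(31, 8))
        t1 = make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)}, scale_state="raw")
        vals2 = vals.copy()
        vals2[:, 3] *= 2.0  # doubling a raw column is a +1 log2 shift
        t2 = make_table(vals2, {"CTRL": (2, 2), "DEX": (2, 2)}, scale_state="raw")
        a = log2_median_normalize(t1).values.to_numpy()
        b = log2_median_normalize(t2).values.to_numpy()
        # identical up to the common grand-median shift
        diff = b - a
        assert np.allclose(diff, diff.ravel()[0], atol=1e-9)

    def test_nonpositive_raw_rejected(self):
        vals = np.full((2, 8), 100.0)
        vals[0, 0] = 0.0
        t = make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)}, scale_state="raw")
        with pytest.raises(ValidationError, match="non-positive"):
            log2_median_normalize(t)


def _pair_table(bas_vals, ins_vals, n_bas=4, n_ins=4, extra_group=None):
    """Single-group table with explicit BAS/INS values (NaN = missing)."""
    groups = {"CTRL": (n_bas, n_ins)}
    row = list(bas_vals) + list(ins_vals)
    if extra_group:
        groups[extra_group[0]] = (len(extra_group[1]) // 2,) * 2
        row += list(extra_group[1])
    return make_table(np.array([row]), groups)


class TestConditionPairImputation:
    def test_downshifted_distribution_mean(self):
        # 2,500 identical features -> 10,000 draws from N(val_min - 1, sigma^2)
        n_feat = 2500
        row = [np.nan] * 4 + [20.0, 21.0, 20.0, 21.0]
        t = make_table(np.tile(row, (n_feat, 1)), {"CTRL": (4, 4)})
        params = ImputationParams(poor_max=0, well_min=4, downshift=1.0,
                                  rng_seed=11)
        out = impute_condition_pair(t, params, "CTRL")
        bas_cols = out.samples_of("CTRL", "BAS")
        draws = out.values[bas_cols].to_numpy().ravel()
        assert len(draws) == 10_000
        assert abs(draws.mean() - 19.0) <= 0.02
        sigma = np.std([20.0, 21.0, 20.0, 21.0], ddof=1)
        assert abs(draws.std(ddof=1) - sigma) < 0.03

    def test_imputed_mean_sits_below_val_min(self):
        # left-censoring semantics: draws are centred one unit under val_min
        row = [np.nan] * 4 + [22.0, 23.0, 22.5, 23.5]
        t = make_table(np.tile(row, (500, 1)), {"CTRL": (4, 4)})
        out = impute_condition_pair(
            t, ImputationParams(poor_max=0, well_min=4, rng_seed=3), "CTRL")
        draws = out.values[out.samples_of("CTRL", "BAS")].to_numpy().ravel()
        assert draws.mean() < 22.0

    def test_partial_quantification_untouched(self):
        row = [10.0, 11.0, 12.0, np.nan] + [20.0, 21.0, 20.5, 21.5]
        t = _pair_table(row[:4], row[4:])
        out = impute_condition_pair(
            t, ImputationParams(poor_max=0, well_min=4, rng_seed=0), "CTRL")
        assert np.isnan(out.values.iloc[0, 3])
        assert not out.imputed.to_numpy().any()

    def test_lone_high_value_blocks_imputation(self):
        # inhibitor-study rule: 1 basal value above the treated mean -> skip
        row = [25.0, np.nan, np.nan, np.nan] + [20.0, 20.5, 19.5, 20.0]
        t = _pair_table(row[:4], row[4:], n_bas=4, n_ins=4)
        params = ImputationParams(poor_max=1, well_min=3,
                                  skip_single_above_mean=True, rng_seed=0)
        out = impute_condition_pair(t, params, "CTRL")
        assert out.values.iloc[0, 1:4].isna().all()
        # mirrored: lone low value below the treated mean IS imputed
        row2 = [18.0, np.nan, np.nan, np.nan] + [20.0, 20.5, 19.5, 20.0]
        t2 = _pair_table(row2[:4], row2[4:])
        out2 = impute_condition_pair(t2, params, "CTRL")
        assert not out2.values.iloc[0].isna().any()

    def test_val_min_spans_all_conditions(self):
        # another group holds the study-wide minimum (15): draws centre on 14
        row = [np.nan] * 4 + [20.0, 21.0, 20.0, 21.0]
        t = _pair_table(row[:4], row[4:],
                        extra_group=("DEX", [15.0, 16.0, 15.5, 16.5]))
        outs = []
        for seed in range(60):
            p = ImputationParams(poor_max=0, well_min=4, rng_seed=seed)
            out = impute_condition_pair(t, p, "CTRL")
            outs.append(out.values[out.samples_of("CTRL", "BAS")].to_numpy())
        assert abs(np.mean(outs) - 14.0) < 0.2

    def test_observed_values_never_overwritten(self):
        rng = np.random.default_rng(5)
        vals = 20 + rng.normal(0, 1, size=(40, 8))
        vals[rng.random(vals.shape) < 0.4] = np.nan
        t = make_table(vals, {"CTRL": (4, 4)})
        p = ImputationParams(poor_max=0, well_min=4, rng_seed=1)
        out = impute_condition_pair(t, p, "CTRL")
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert not out.imputed.to_numpy()[obs].any()

    def test_determinism_and_row_order_independence(self):
        rng = np.random.default_rng(9)
        vals = 20 + rng.normal(0, 1, size=(30, 8))
        vals[:, :4][rng.random((30, 4)) < 0.9] = np.nan
        t = make_table(vals, {"CTRL": (4, 4)})
        p = ImputationParams(poor_max=0, well_min=4, rng_seed=42)
        a = impute_condition_pair(t, p, "CTRL").values
        b = impute_condition_pair(t, p, "CTRL").values
        pd.testing.assert_frame_equal(a, b)
        # reversing row order must not change any feature's draws
        rev = t.subset(list(t.feature_ids)[::-1])
        c = impute_condition_pair(rev, p, "CTRL").values
        pd.testing.assert_frame_equal(a.sort_index(), c.sort_index())


class TestSelfImputation:
    def test_degenerate_sd_fills_constant(self):
        row = [10.0] * 5 + [np.nan] * 7 + [20.0] * 12
        t = make_table(np.array([row]), {"CHOW": (12, 12)})
        p = ImputationParams(poor_max=0, well_min=7, step2_min=5, rng_seed=0)
        out = impute_self(t, p)
        assert np.allclose(out.values.iloc[0, :12], 10.0)

    def test_below_step2_untouched(self):
        row = [10.0] * 4 + [np.nan] * 8 + [20.0] * 12
        t = make_table(np.array([row]), {"CHOW": (12, 12)})
        p = ImputationParams(poor_max=0, well_min=7, step2_min=5, rng_seed=0)
        out = impute_self(t, p)
        assert out.values.iloc[0, 4:12].isna().all()

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(2)
        vals = 20 + rng.normal(0, 1, size=(20, 24))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        t = make_table(vals, {"CHOW": (12, 12)})
        p = ImputationParams(poor_max=0, well_min=7, step2_min=5, rng_seed=7)
        a = impute_self(t, p).values
        b = impute_self(t, p).values
        pd.testing.assert_frame_equal(a, b)


def test_study_default_criteria_wired():
    p = default_imputation_params("cell_ir")
    assert p.poor_max == 0 and p.well_min_for("CTRL") == 5
    assert p.well_min_for("DEX") == 4 and p.step2_min is None
    p = default_imputation_params("mouse")
    assert (p.poor_max, p.well_min, p.step2_min) == (0, 7, 5)
    p = default_imputation_params("gsk3i")
    assert (p.poor_max, p.well_min, p.step2_min) == (1, 3, 3)
    assert p.skip_single_above_mean
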