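import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosrewire import preprocess, regulation, rewiring
from phosrewire.rewiring import (
    anova_insulin_response,
    attribute_defect,
    classify_defective_contrast,
    classify_emergent_contrast,
    classify_mouse_mode,
    compare_models,
    defect_bias_tests,
    insulin_response_vectors,
)
from phosrewire.synthetic_data import generate_study, recovery_benchmark_config

from conftest import make_table


class TestAnova:
    def test_worked_example(self):
        f, df1, df2, p = anova_insulin_response(
            {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])})
        assert f == pytest.approx(13.5, abs=1e-10)
        assert (df1, df2) == (1, 4)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_identical_groups(self):
        f, _, _, p = anova_insulin_response(
            {"a": np.array([2.0, 2, 2]), "b": np.array([2.0, 2, 2])})
        assert f == 0.0 and p == 1.0

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 1, rng.integers(2, 8))
            f, _, _, p_f = anova_insulin_response({"a": a, "b": b})
            t, p_t = stats.ttest_ind(a, b, equal_var=True)
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p_f == pytest.approx(p_t, rel=1e-10)


class TestResponseVectors:
    def test_subtracts_bas_median(self):
        vals = np.array([[1.0, 2.0, 3.0, 10.0, 11.0]])
        t = make_table(vals, {"CTRL": (3, 2)})
        resp = insulin_response_vectors(t, "CTRL")
        assert np.allclose(resp.iloc[0].to_numpy(), [8.0, 9.0])

    def test_undersized_arm_yields_nan(self):
        vals = np.array([[1.0, np.nan, np.nan, 10.0, 11.0]])
        t = make_table(vals, {"CTRL": (3, 2)})
        resp = insulin_response_vectors(t, "CTRL")
        assert resp.iloc[0].isna().all()


class TestClassificationRules:
    @pytest.mark.parametrize(
        "ctrl,mfc,p,expect",
        [("up", 0.20, 0.01, True),
         ("up", 0.70, 0.01, False),    # model response still large enough
         ("down", -0.70, 0.20, False),  # not significant
         ("down", -0.20, 0.01, True),
         ("unregulated", 0.20, 0.01, False)],
    )
    def test_defective_contrast(self, ctrl, mfc, p, expect):
        assert classify_defective_contrast(ctrl, mfc, p) is expect

    @pytest.mark.parametrize(
        "cp,cfc,mfc,dp,expect",
        [(0.8, 0.1, 1.2, 0.001, True),
         (0.01, 1.0, 1.2, 0.001, False),   # control itself responds
         (0.8, 0.1, 0.4, 0.001, False),    # magnitude too small
         (0.8, 0.7, 1.2, 0.001, False),    # control fc above threshold
         (np.nan, np.nan, 1.2, 0.001, False)],
    )
    def test_emergent_contrast(self, cp, cfc, mfc, dp, expect):
        assert classify_emergent_contrast(cp, cfc, mfc, dp) is expect

    def test_mouse_rules(self):
        chow_up = pd.Series({"label": "up", "log2fc": 1.0, "p_adj": 0.01})
        assert classify_mouse_mode(chow_up,
                                   pd.Series({"label": "unregulated",
                                              "log2fc": 0.3, "p_adj": 0.5})) \
            == (True, False)
        assert classify_mouse_mode(chow_up,
                                   pd.Series({"label": "up", "log2fc": 0.9,
                                              "p_adj": 0.01})) == (False, False)
        chow_null = pd.Series({"label": "unregulated", "log2fc": 0.2,
                               "p_adj": 0.5})
        hfd_down = pd.Series({"label": "down", "log2fc": -0.8, "p_adj": 0.01})
        assert classify_mouse_mode(chow_null, hfd_down) == (False, True)


class TestFisherBias:
    def test_small_table_enumeration(self):
        # [[2,0],[0,2]] one-sided "greater": only 1 of C(4,2)=6 splits is as
        # extreme -> p = 1/6
        _, p = stats.fisher_exact([[2, 0], [0, 2]], alternative="greater")
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_fisher_equals_hypergeom_tail(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            tail = stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c)
            assert p == pytest.approx(float(tail), abs=1e-12)

    def test_equal_proportions_give_unit_ratio(self):
        calls = pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(8)],
            "model": ["M1"] * 8,
            "defective": [True, True, False, False] * 2,
        })
        ctrl = pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(8)],
            "label": ["down", "up"] * 4,
        }).set_index("feature_id", drop=False)
        bias = defect_bias_tests(calls, ctrl, max_k=1)
        assert bias.loc[0, "relative_ratio"] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def benchmark_run():
    bundle = generate_study(recovery_benchmark_config(seed=3, n_features=600))
    table = preprocess.preprocess_study(bundle.table, "cell_ir", seed=3)
    res = regulation.adjust_within_family(
        regulation.insulin_response_test(table, "CTRL"), "CTRL")
    ctrl = regulation.call_regulated(res).set_index("feature_id", drop=False)
    calls = compare_models(table, ctrl)
    return bundle, table, ctrl, calls


class TestEndToEndCalls:
    def test_mutual_exclusivity_and_prerequisites(self, benchmark_run):
        _, _, ctrl, calls = benchmark_run
        assert not (calls["defective"] & calls["emergent"]).any()
        lab = calls["feature_id"].map(ctrl["label"])
        assert lab[calls["defective"]].isin(["up", "down"]).all()
        assert (lab[calls["emergent"]] == "unregulated").all()

    def test_recovers_most_planted_defects(self, benchmark_run):
        bundle, _, _, calls = benchmark_run
        hit = calls[calls["defective"]]
        pred = set(zip(hit["feature_id"], hit["model"]))
        truth = bundle.truth.defective_pairs()
        assert len(pred & truth) / len(truth) > 0.6
        assert len(pred - truth) / max(len(pred), 1) < 0.15

    def test_defect_attribution_finds_insulin_mode(self, benchmark_run):
        bundle, table, ctrl, calls = benchmark_run
        modes = attribute_defect(table, calls, ctrl)
        counts = modes["defect_mode"].value_counts()
        # benchmark plants pure insulin-mode defects
        assert counts.get("insulin_defect", 0) > 5 * counts.get("basal_defect", 0)


def test_basal_defect_detected_on_constructed_feature():
    """A control-up feature whose model basal level is raised to the
    stimulated level is attributed to the basal state."""
    rng = np.random.default_rng(8)
    n = 40
    vals = 20 + rng.normal(0, 0.2, size=(n, 20))
    # CTRL (6,6) + DEX (4,4): feature 0 responds in CTRL, basal-raised in DEX
    vals[0, 6:12] += 1.5          # CTRL INS
    vals[0, 12:16] += 1.5         # DEX BAS raised
    vals[0, 16:20] += 1.5         # DEX INS (no further response)
    t = make_table(vals, {"CTRL": (6, 6), "DEX": (4, 4)})
    res = regulation.adjust_within_family(
        regulation.insulin_response_test(t, "CTRL"), "CTRL")
    ctrl = regulation.call_regulated(res).set_index("feature_id", drop=False)
    assert ctrl.loc["f0", "label"] == "up"
    calls = compare_models(t, ctrl)
    row = calls[(calls.feature_id == "f0") & (calls.model == "DEX")].iloc[0]
    assert row["defective"]
    modes = attribute_defect(t, calls, ctrl)
    mode = modes[(modes.feature_id == "f0")]["defect_mode"].iloc[0]
    assert "basal_defect" in mode and "insulin_defect" not in mode
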