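import itertools

import numpy as np
import pandas as pd
import pytest

from phosrewire.core_io import KinaseAnnotationSet
from phosrewire.ksea import (
    Signature,
    _es_from_hits,
    batch_ksea,
    build_signature,
    ksea_permutation_p,
    ksea_score,
    map_substrates,
)
from phosrewire.synthetic_data import default_config, generate_study
from phosrewire import preprocess

from conftest import make_table


def _sig(scores: dict[str, float]) -> Signature:
    return Signature(scores=pd.Series(scores), semantics="test")


def exhaustive_tail(scores: dict[str, float], substrates: set[str]) -> float:
    """Exact sign-matched tail over all same-size subsets (oracle)."""
    sig = _sig(scores)
    obs = ksea_score(sig, substrates)
    m = len(substrates)
    hits_count = 0
    total = 0
    for combo in itertools.combinations(scores, m):
        es = ksea_score(sig, set(combo))
        total += 1
        if np.sign(es) == np.sign(obs) and abs(es) >= abs(obs):
            hits_count += 1
    return hits_count / total


class TestRunningSum:
    def test_top_ranked_substrates_maximal(self):
        scores = {f"f{i}": 5 - i for i in range(5)}
        assert ksea_score(_sig(scores), {"f0", "f1"}) == pytest.approx(1.0)

    def test_bottom_ranked_substrates_minimal(self):
        scores = {f"f{i}": 5 - i for i in range(5)}
        assert ksea_score(_sig(scores), {"f3", "f4"}) == pytest.approx(-1.0)

    def test_hand_enumerated_interior_case(self):
        # universe ranked f0..f4, hits at ranks 1 and 4:
        # steps +1/2, -1/3, -1/3, +1/2, -1/3 -> running max |.| = 1/2
        scores = {f"f{i}": 5 - i for i in range(5)}
        es = ksea_score(_sig(scores), {"f0", "f3"})
        assert es == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ksea_score(_sig({"a": 1.0}), set())

    def test_set_equals_universe(self):
        scores = {f"f{i}": float(i) for i in range(4)}
        res = ksea_permutation_p(_sig(scores), set(scores), n_perm=50, seed=0)
        assert res.p_emp == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = {f"f{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        sub = {f"f{i}" for i in rng.choice(30, 8, replace=False)}
        es1 = ksea_score(_sig(scores), sub)
        es2 = ksea_score(_sig({k: np.exp(3 * v) for k, v in scores.items()}), sub)
        assert es1 == pytest.approx(es2)


class TestPermutationP:
    def test_matches_exhaustive_oracle_small_universes(self):
        rng = np.random.default_rng(1)
        for n, m in [(5, 2), (6, 3), (8, 4), (7, 2)]:
            scores = {f"f{i}": float(v)
                      for i, v in enumerate(rng.normal(size=n))}
            sub = set(rng.choice(sorted(scores), m, replace=False))
            exact = exhaustive_tail(scores, sub)
            res = ksea_permutation_p(_sig(scores), sub, n_perm=4000, seed=2)
            # (1+x)/(n+1) estimator vs exact tail: binomial tolerance
            se = np.sqrt(exact * (1 - exact) / 4000) + 1e-4
            assert res.p_emp == pytest.approx(exact + 1 / 4001, abs=4 * se + 5e-4)

    def test_maximal_es_gets_smallest_p(self):
        scores = {f"f{i}": 50 - i for i in range(50)}
        res = ksea_permutation_p(_sig(scores), {f"f{i}" for i in range(4)},
                                 n_perm=200, seed=0)
        assert res.p_emp == pytest.approx(1 / 201)

    def test_null_calibration(self):
        """Under exchangeable null scores the |ES| tail p is uniform; the
        directional p is sub-uniform (its direction is data-chosen)."""
        rng = np.random.default_rng(3)
        p_dir, p_two = [], []
        for _ in range(120):
            scores = {f"f{i}": float(v)
                      for i, v in enumerate(rng.normal(size=60))}
            sub = set(rng.choice(sorted(scores), 10, replace=False))
            res = ksea_permutation_p(_sig(scores), sub, n_perm=199,
                                     seed=int(rng.integers(2**31)))
            p_dir.append(res.p_emp)
            p_two.append(res.p_two_sided)
        assert 0.4 < np.mean(p_two) < 0.6
        assert 0.15 < np.mean(p_dir) < 0.4
        assert np.all(np.asarray(p_two) >= np.asarray(p_dir))

    def test_planted_block_detected(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=300)
        sub_idx = rng.choice(300, 25, replace=False)
        scores[sub_idx] += 1.0
        sig = _sig({f"f{i}": float(v) for i, v in enumerate(scores)})
        res = ksea_permutation_p(sig, {f"f{i}" for i in sub_idx},
                                 n_perm=500, seed=5)
        assert res.es > 0 and res.p_emp < 0.05


class TestSignatures:
    def test_ins_bas_is_mean_difference(self, two_group_table):
        sig = build_signature(two_group_table, "ins_bas", "CTRL")
        vals = two_group_table.values
        bas = vals[two_group_table.samples_of("CTRL", "BAS")].mean(axis=1)
        ins = vals[two_group_table.samples_of("CTRL", "INS")].mean(axis=1)
        assert np.allclose(sig.scores, ins - bas)

    def test_ctrl_normalized_control_is_zero(self, two_group_table):
        sig = build_signature(two_group_table, "ctrl_norm", "CTRL")
        assert np.allclose(sig.scores, 0.0)

    def test_semantics_tag_required(self):
        with pytest.raises(ValueError):
            Signature(scores=pd.Series({"a": 1.0}), semantics="")


class TestBatch:
    def _fixture(self):
        rng = np.random.default_rng(6)
        n = 40
        vals = 20 + rng.normal(0, 0.3, size=(n, 8))
        sites = [f"S{100 + i}" for i in range(n)]
        t = make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)}, sites=sites)
        recs = pd.DataFrame(
            [("KIN_A", f"P{i}", f"S{100 + i}") for i in range(12)]
            + [("KIN_B", f"P{i}", f"S{100 + i}") for i in range(12, 21)],
            columns=["kinase", "substrate_accession", "site"])
        return t, KinaseAnnotationSet(records=recs)

    def test_min_substrate_exclusion(self):
        t, kset = self._fixture()
        sigs = [build_signature(t, "ins_bas", "CTRL")]
        res = batch_ksea(sigs, t, kset, min_substrates=10, n_perm=50, seed=0)
        assert set(res["kinase"]) == {"KIN_A"}  # KIN_B has only 9 mapped
        res2 = batch_ksea(sigs, t, kset, min_substrates=1, n_perm=50, seed=0)
        assert set(res2["kinase"]) == {"KIN_A", "KIN_B"}

    def test_merged_isoform_counts_are_union(self):
        t, _ = self._fixture()
        recs = pd.DataFrame(
            [("Gsk3a", f"P{i}", f"S{100 + i}") for i in range(8)]
            + [("Gsk3b", f"P{i}", f"S{100 + i}") for i in range(4, 12)],
            columns=["kinase", "substrate_accession", "site"])
        recs["kinase"] = "GSK3"  # as produced by isoform merging
        kset = KinaseAnnotationSet(records=recs.drop_duplicates())
        mapped = map_substrates(t, kset)
        assert len(mapped["GSK3"]) == 12  # union of the two site lists

    def test_multisite_peptidoform_matches_any_site(self):
        rng = np.random.default_rng(7)
        vals = 20 + rng.normal(0, 0.3, size=(2, 8))
        t = make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)},
                       sites=["S100;S104", "S200"])
        recs = pd.DataFrame([("KIN", "P0", "S104")],
                            columns=["kinase", "substrate_accession", "site"])
        mapped = map_substrates(t, KinaseAnnotationSet(records=recs))
        assert mapped["KIN"] == {"f0"}


def test_planted_kinase_recovered_through_pipeline():
    cfg = default_config("cell_ir", seed=11, n_features=600)
    bundle = generate_study(cfg)
    table = preprocess.preprocess_study(bundle.table, "cell_ir", seed=11)
    sig = build_signature(table, "ins_bas", "CTRL")
    sub = map_substrates(table, bundle.annotations)["AKT1"]
    res = ksea_permutation_p(sig, sub, n_perm=500, seed=1, kinase="AKT1")
    assert res.es > 0 and res.p_emp < 0.05
    null = map_substrates(table, bundle.annotations)["CSNK2A1"]
    res_null = ksea_permutation_p(sig, null, n_perm=500, seed=1)
    assert res_null.p_two_sided > 0.05
    assert abs(res_null.es) < res.es
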