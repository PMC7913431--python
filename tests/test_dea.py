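"""Differential expression: CPM normalization, both tests, BH, union merge."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonet.containers import ExpressionMatrix
from exonet.dea import (bh_adjust, cpm, de_test_parametric, de_test_rank,
                        merge_de, normalize_cpm, run_dea, _assemble)
from exonet.errors import InputError

from conftest import make_labeled_matrix


class TestCpm:
    def test_single_sample_proportions(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1, 1, 2]}, index=list("abc")))
        out = cpm(m)
        assert out["s1"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_cpm_columns_sum_to_one_million(self, rng):
        counts = rng.poisson(30.0, size=(40, 6))
        m = ExpressionMatrix(pd.DataFrame(counts))
        sums = cpm(m).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=0, atol=1e-6)

    def test_all_zero_sample_named_in_error(self, rng):
        counts = pd.DataFrame(rng.poisson(10.0, size=(5, 3)),
                              columns=["s1", "dead", "s3"])
        counts["dead"] = 0
        with pytest.raises(InputError, match="dead"):
            cpm(ExpressionMatrix(counts))

    def test_all_zero_feature_dropped_by_filter(self, rng):
        counts = pd.DataFrame(rng.poisson(50.0, size=(10, 4)))
        counts.iloc[3] = 0
        out = normalize_cpm(ExpressionMatrix(counts), low_expr_min_cpm=1.0,
                            low_expr_min_samples=1)
        assert 3 not in out.features

    def test_log2_scale_output(self, rng):
        counts = pd.DataFrame(rng.poisson(50.0, size=(10, 4)))
        out = normalize_cpm(ExpressionMatrix(counts))
        expected = np.log2(cpm(ExpressionMatrix(counts)) + 1.0)
        pd.testing.assert_frame_equal(out.data, expected.loc[out.features])


class TestParametric:
    def test_constant_feature_not_called(self, rng):
        matrix, meta = make_labeled_matrix(rng)
        matrix.data.iloc[0] = 5.0
        res = de_test_parametric(matrix, meta).set_index("feature_id")
        assert res.loc["f0", "log2fc"] == 0.0
        assert res.loc["f0", "p_value"] == 1.0
        assert not res.loc["f0", "called"]

    def test_log2fc_is_group_mean_difference(self, rng):
        matrix, meta = make_labeled_matrix(rng, n_features=3)
        matrix.data.iloc[1] = np.where(meta["group"] == "tumor", 8.0, 2.0)
        res = de_test_parametric(matrix, meta).set_index("feature_id")
        assert res.loc["f1", "log2fc"] == pytest.approx(6.0)

    def test_welch_pvalues_match_independent_computation(self, rng):
        # Independent Welch oracle coded from the textbook formulas.
        matrix, meta = make_labeled_matrix(rng, n_features=50)
        res = de_test_parametric(matrix, meta).set_index("feature_id")
        tumor = matrix.data.loc[:, (meta["group"] == "tumor").to_numpy()]
        normal = matrix.data.loc[:, (meta["group"] == "normal").to_numpy()]
        for fid in matrix.features:
            x, y = tumor.loc[fid].to_numpy(), normal.loc[fid].to_numpy()
            vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
            t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
            df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
            p = 2 * stats.t.sf(abs(t), df)
            assert res.loc[fid, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_too_small_group_rejected(self, rng):
        matrix, meta = make_labeled_matrix(rng, n_control=1)
        with pytest.raises(InputError):
            de_test_parametric(matrix, meta)


class TestRank:
    def test_perfect_separation_3v3_exact_p(self):
        ids = [f"s{i}" for i in range(6)]
        data = pd.DataFrame([[10.0, 11.0, 12.0, 1.0, 2.0, 3.0]],
                            index=["f0"], columns=ids)
        meta = pd.DataFrame({"group": ["tumor"] * 3 + ["normal"] * 3}, index=ids)
        res = de_test_rank(ExpressionMatrix(data, "log2"), meta)
        assert res.loc[0, "p_value"] == pytest.approx(0.1)  # 2/20 by enumeration

    def test_constant_feature_p_one(self, rng):
        matrix, meta = make_labeled_matrix(rng)
        matrix.data.iloc[0] = 7.0
        res = de_test_rank(matrix, meta).set_index("feature_id")
        assert res.loc["f0", "p_value"] == 1.0
        assert not res.loc["f0", "called"]

    def test_null_rejection_rate_near_alpha(self, rng):
        matrix, meta = make_labeled_matrix(rng, n_features=400, n_tumor=25,
                                           n_control=25)
        res = de_test_rank(matrix, meta)
        rate = (res["p_value"] < 0.05).mean()
        assert 0.02 < rate < 0.09


class TestBh:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    @pytest.mark.parametrize("p_in, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.02, 0.01], [0.02, 0.02]),
    ])
    def test_hand_computed_step_up(self, p_in, expected):
        assert bh_adjust(p_in).tolist() == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 200)))
            mine = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(mine - ref)) < 1e-12

    def test_fdr_never_below_p(self, rng):
        p = rng.random(500)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCallingRule:
    @pytest.mark.parametrize("log2fc, p, called", [
        (1.0, 0.001, False),     # |lfc| = 1 exactly: strict, not called
        (-1.0, 0.001, False),
        (1.001, 0.05, False),    # FDR = 0.05 exactly (m=1): not called
        (1.001, 0.049, True),
        (-2.0, 0.01, True),
    ])
    def test_strict_inequalities_at_boundary(self, log2fc, p, called):
        res = _assemble(["x"], np.array([log2fc]), np.array([p]),
                        "rank", 1.0, 0.05)
        assert bool(res.loc[0, "called"]) is called


class TestMerge:
    def _result(self, ids, called):
        return pd.DataFrame({"feature_id": ids, "log2fc": 2.0, "p_value": 0.0,
                             "fdr": 0.0, "called": called, "method": "rank"})

    def test_union_of_called_sets(self):
        a = self._result(["g1", "g2", "g3"], [True, True, False])
        b = self._result(["g1", "g2", "g3"], [False, True, True])
        assert merge_de(a, b) == {"g1", "g2", "g3"}

    def test_empty_set_is_identity(self):
        a = self._result(["g1"], [True])
        b = self._result(["g1"], [False])
        assert merge_de(a, b) == {"g1"}
        assert merge_de(b, b) == set()

    def test_union_bounds(self, rng):
        ids = [f"g{i}" for i in range(30)]
        a = self._result(ids, rng.random(30) < 0.4)
        b = self._result(ids, rng.random(30) < 0.4)
        na = a["called"].sum()
        nb = b["called"].sum()
        merged = merge_de(a, b)
        assert max(na, nb) <= len(merged) <= na + nb

    def test_adding_a_called_feature_never_shrinks_union(self):
        a = self._result(["g1"], [True])
        b = self._result(["g2"], [True])
        before = merge_de(a, b)
        b2 = self._result(["g2", "g3"], [True, True])
        assert before <= merge_de(a, b2)


class TestRunDea:
    def test_sensitivity_on_planted_counts(self):
        from exonet.simulate import SimulationConfig, simulate_tissue_counts
        cfg = SimulationConfig(n_features_mrna=300, n_tumor=30, n_control=30,
                               n_planted_de=30, n_planted_key=0,
                               planted_log2fc=2.0, baseline_mean=50.0, seed=21)
        matrix, truth, meta = simulate_tissue_counts(cfg)
        out = run_dea(matrix, meta)
        planted = truth.planted_de["mrna"]
        recovered = len(planted & out["merged"]) / len(planted)
        assert recovered >= 0.9
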