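"""Validation statistics: AUC, Kaplan-Meier/log-rank, stage and MSI tests."""

import numpy as np
import pandas as pd
import pytest

from exonet.errors import InputError
from exonet.validate import (km_logrank_median_split, msi_association,
                             roc_auc, stage_association)


def brute_force_auc(scores, labels):
    """Pairwise concordance with ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50)
        assert res.auc == 1.0

    def test_half_concordant_pairs(self):
        res = roc_auc([3, 1, 2, 4], [0, 1, 0, 1], n_boot=50)
        assert res.auc == 0.5  # 2 concordant of 4 pos-neg pairs

    def test_all_ties_give_half(self):
        res = roc_auc([5, 5, 5, 5], [0, 1, 0, 1], n_boot=50)
        assert res.auc == 0.5

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = roc_auc(scores, labels, n_boot=10)
            assert abs(res.auc - brute_force_auc(scores, labels)) < 1e-12

    def test_label_swap_antisymmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels, n_boot=10).auc
        b = roc_auc(scores, 1 - labels, n_boot=10).auc
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_ci_brackets_point_estimate(self, rng):
        scores = rng.normal(size=40) + 0.8 * rng.integers(0, 2, size=40)
        labels = (scores > np.median(scores)).astype(int)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels, n_boot=200, seed=5)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([1.0, 2.0], [1, 1])


def survival_meta(times, events, expr, prefix="T"):
    ids = [f"{prefix}{i}" for i in range(len(times))]
    meta = pd.DataFrame({"group": "tumor", "survival_time": times,
                         "event": events}, index=ids)
    return pd.Series(expr, index=ids), meta


def hand_logrank(times_a, times_b):
    """Independent observed-minus-expected log-rank oracle (no censoring)."""
    events = sorted(set(times_a) | set(times_b))
    o_minus_e, var = 0.0, 0.0
    for t in events:
        na = sum(x >= t for x in times_a)
        nb = sum(x >= t for x in times_b)
        n = na + nb
        d = list(times_a).count(t) + list(times_b).count(t)
        da = list(times_a).count(t)
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKmLogrank:
    def test_identical_groups_give_zero_statistic(self):
        expr, meta = survival_meta([1, 2, 3, 1, 2, 3], [1] * 6,
                                   [1, 1, 1, 9, 9, 9])
        res = km_logrank_median_split(expr, meta)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_oracle_on_six_samples(self):
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        expr, meta = survival_meta(times, [1] * 6, [1, 1, 1, 9, 9, 9])
        res = km_logrank_median_split(expr, meta)
        expected = hand_logrank([1.0, 3.0, 5.0], [2.0, 4.0, 6.0])
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_statistic_symmetric_under_group_swap(self):
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        expr, meta = survival_meta(times, [1] * 6, [1, 1, 1, 9, 9, 9])
        flipped, _ = survival_meta(times, [1] * 6, [9, 9, 9, 1, 1, 1])
        a = km_logrank_median_split(expr, meta)
        b = km_logrank_median_split(flipped, meta)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_km_curves_reach_empirical_survival_without_censoring(self):
        times = [1.0, 2.0, 4.0, 3.0, 5.0, 6.0]
        expr, meta = survival_meta(times, [1] * 6, [1, 1, 1, 9, 9, 9])
        res = km_logrank_median_split(expr, meta)
        low = res.curves["low"]
        # step function starts at 1, is non-increasing, ends at 0
        assert low["survival"].iloc[0] == 1.0
        assert (np.diff(low["survival"]) <= 1e-12).all()
        assert low["survival"].iloc[-1] == pytest.approx(0.0)
        # at each event time survival equals the empirical fraction alive
        for t, s in zip(low["time"], low["survival"]):
            if t > 0:
                frac = np.mean(np.array([1.0, 2.0, 4.0]) > t)
                assert s == pytest.approx(frac)

    def test_degenerate_split_names_feature(self):
        expr, meta = survival_meta([1, 2, 3, 4], [1] * 4, [5, 5, 5, 5])
        with pytest.raises(InputError, match="flatline"):
            km_logrank_median_split(expr, meta, feature_id="flatline")


class TestStageAssociation:
    def test_constant_expression_gives_zero(self):
        stat, p = stage_association([3.0] * 12, ["I", "II", "III"] * 4)
        assert stat == 0.0 and p == 1.0

    def test_two_stages_equal_rank_sum_chi_square(self, rng):
        # with two groups, Kruskal-Wallis equals the squared standardized
        # rank-sum statistic (no continuity correction)
        x = rng.normal(size=20)
        stage = np.array(["I"] * 10 + ["II"] * 10)
        stat, _ = stage_association(x, stage)
        from scipy.stats import rankdata
        ranks = rankdata(x)
        ra = ranks[:10].sum()
        n, na, nb = 20, 10, 10
        mu = na * (n + 1) / 2
        var = na * nb * (n + 1) / 12
        assert stat == pytest.approx((ra - mu) ** 2 / var, abs=1e-10)

    def test_small_stage_dropped_with_warning(self, rng):
        x = rng.normal(size=11)
        stage = ["I"] * 5 + ["II"] * 5 + ["IV"]
        with pytest.warns(UserWarning, match="IV"):
            stat, p = stage_association(x, stage)
        assert np.isfinite(stat)

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        for _ in range(200):
            x = rng.normal(size=40)
            stage = np.repeat(["I", "II", "III", "IV"], 10)
            _, p = stage_association(x, stage)
            rejections += p < 0.05
        assert 0.01 < rejections / 200 < 0.10

    def test_fewer_than_two_stages_rejected(self, rng):
        with pytest.raises(InputError):
            stage_association(rng.normal(size=5), ["I"] * 5)


class TestMsiAssociation:
    def test_complete_separation_4v4_exact_p(self):
        expr = [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]
        msi = ["MSS"] * 4 + ["MSI-H"] * 4
        _, p = msi_association(expr, msi)
        assert p == pytest.approx(2 / 70)  # exact enumeration

    def test_constant_expression_p_one(self):
        _, p = msi_association([2.0] * 8, ["MSS"] * 4 + ["MSI-H"] * 4)
        assert p == 1.0

    def test_single_phenotype_rejected(self):
        with pytest.raises(InputError):
            msi_association([1.0, 2.0], ["MSS", "MSS"])

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        for _ in range(200):
            expr = rng.normal(size=30)
            msi = np.array(["MSS"] * 20 + ["MSI-H"] * 10)
            _, p = msi_association(expr, msi)
            rejections += p < 0.05
        assert 0.01 < rejections / 200 < 0.10
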