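"""Error metrics, KS machinery, ROC/AUC and the DeLong test."""

import numpy as np
import pytest
from scipy import stats

from tumorhab import evaluation as ev


class TestPctDeltaTTC:
    @pytest.mark.parametrize("factor,expected", [(2.0, 100.0), (1.0, 0.0),
                                                 (0.75, -25.0)])
    def test_scaling(self, factor, expected):
        a = np.full((3, 3, 1), 100.0)
        assert ev.pct_delta_ttc(a, factor * a) == pytest.approx(expected)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            ev.pct_delta_ttc(np.zeros(3), np.ones(3))


class TestPctDeltaTTV:
    theta = 1000.0

    def test_identical_zero(self):
        a = np.full(10, 500.0)
        assert ev.pct_delta_ttv(a, a, self.theta) == 0.0

    def test_half_volume(self):
        a = np.full(8, 500.0)
        b = np.r_[np.full(4, 500.0), np.full(4, 10.0)]
        assert ev.pct_delta_ttv(a, b, self.theta) == pytest.approx(-50.0)

    def test_threshold_counting(self):
        field = np.array([0.2, 0.3]) * self.theta
        assert ev.tumor_volume(field, self.theta, 1.0, 0.25) == 1.0

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            ev.tumor_volume(np.ones(3), self.theta, 1.0, 1.5)


class TestMsePctDeltaTC:
    def brute_force(self, ma, mb, da, db, roi, eps=1.0):
        total, n = 0.0, 0
        for idx in np.argwhere(roi):
            i = tuple(idx)
            mc = (mb[i] - ma[i]) / max(ma[i], eps)
            dc = (db[i] - da[i]) / max(da[i], eps)
            total += (mc - dc) ** 2
            n += 1
        return total / n

    def test_zero_when_model_equals_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((4, 4, 2)) + 1, rng.random((4, 4, 2)) + 1
        roi = np.ones((4, 4, 2), bool)
        assert ev.mse_pct_delta_tc(a, b, a, b, roi) == 0.0

    def test_constant_offset(self):
        a = np.full((3, 3, 1), 10.0)
        data_b = np.full((3, 3, 1), 12.0)
        model_b = data_b + 0.1 * a      # model change exceeds data by 0.1
        roi = np.ones((3, 3, 1), bool)
        assert ev.mse_pct_delta_tc(a, model_b, a, data_b, roi) == \
            pytest.approx(0.01)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        shape = (5, 4, 2)
        ma, mb = rng.random(shape) * 20, rng.random(shape) * 20
        da, db = ma.copy(), rng.random(shape) * 20
        roi = rng.random(shape) < 0.7
        assert ev.mse_pct_delta_tc(ma, mb, da, db, roi) == pytest.approx(
            self.brute_force(ma, mb, da, db, roi))

    def test_empty_roi(self):
        z = np.zeros((2, 2, 1))
        with pytest.raises(ValueError):
            ev.mse_pct_delta_tc(z, z, z, z, np.zeros((2, 2, 1), bool))


class TestKS:
    def test_identical_samples(self):
        x = np.arange(10.0)
        stat, p = ev.ks_two_sample(x, x)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ev.ks_two_sample(np.arange(5.0), np.arange(10.0, 15.0))
        assert stat == 1.0

    def test_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(7), rng.random(9)
        grid = np.unique(np.r_[x, y])
        sup = max(abs((x <= g).mean() - (y <= g).mean()) for g in grid)
        stat, _ = ev.ks_two_sample(x, y)
        assert stat == pytest.approx(sup)


class TestSelectOptimalH:
    def tables(self, per_h):
        return {h: {m: np.asarray(v) for m, v in t.items()}
                for h, t in per_h.items()}

    def test_identical_distributions_return_smallest(self):
        base = {"ttc": np.arange(8.0), "ttv": np.arange(8.0),
                "mse": np.arange(8.0)}
        tabs = self.tables({h: base for h in (2, 3, 4, 5)})
        res = ev.select_optimal_H(tabs)
        assert res.H == 2 and res.qualified

    def test_improvement_up_to_three(self):
        # H=2 errors clearly larger; H>=3 flat -> choose 3
        hi = {"ttc": np.linspace(10, 12, 8), "ttv": np.linspace(10, 12, 8),
              "mse": np.linspace(10, 12, 8)}
        lo = {"ttc": np.linspace(1, 2, 8), "ttv": np.linspace(1, 2, 8),
              "mse": np.linspace(1, 2, 8)}
        tabs = self.tables({2: hi, 3: lo, 4: lo, 5: lo})
        res = ev.select_optimal_H(tabs)
        assert res.H == 3 and res.qualified

    def test_monotone_safe_under_duplicate(self):
        hi = {"m": np.linspace(10, 12, 8)}
        lo = {"m": np.linspace(1, 2, 8)}
        r1 = ev.select_optimal_H(self.tables({2: hi, 3: lo, 4: lo}))
        r2 = ev.select_optimal_H(self.tables({2: hi, 3: lo, 4: lo, 5: lo}))
        assert r1.H == r2.H == 3

    def test_no_h_qualifies(self):
        tabs = self.tables({
            2: {"m": np.linspace(10, 12, 8)},
            3: {"m": np.linspace(5, 6, 8)},
            4: {"m": np.linspace(1, 2, 8)}})
        res = ev.select_optimal_H(tabs)
        assert res.H == 4 and not res.qualified

    def test_single_patient_errors(self):
        with pytest.raises(ValueError):
            ev.select_optimal_H(self.tables({2: {"m": [1.0]},
                                             3: {"m": [1.0]}}))


def auc_pair_counting(scores, labels):
    """Brute-force Mann-Whitney AUC: concordant pairs + half ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total, conc = 0, 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


class TestRocAuc:
    def test_perfect_separation(self):
        r = ev.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_hand_counted_values(self):
        assert ev.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        # swapping the middle pair discords one of four comparisons
        assert ev.roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(6, 15)
            scores = rng.integers(0, 6, n).astype(float)   # with ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = ev.roc_auc(scores, labels)
            assert r.auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_orientation_flip(self):
        scores = [10.0, 9.0, 2.0, 1.0]
        labels = [1, 1, 0, 0]
        assert ev.roc_auc(scores, labels, "greater").auc == 1.0
        assert ev.roc_auc(scores, labels, "less").auc == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert ev.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self):
        s = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0])
        y = np.array([1, 0, 1, 0, 1, 0])
        assert ev.delong_test(s, s, y) == 1.0

    def test_variance_matches_placement_covariance(self):
        rng = np.random.default_rng(5)
        s1, s2 = rng.random(12), rng.random(12)
        y = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        # brute-force placement values
        def placements(s):
            pos, neg = s[y], s[~y]
            psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None]
                                                         == neg[None, :])
            return psi.mean(axis=1), psi.mean(axis=0)
        v10 = np.column_stack([placements(s)[0] for s in (s1, s2)])
        v01 = np.column_stack([placements(s)[1] for s in (s1, s2)])
        s10, s01 = np.cov(v10, rowvar=False), np.cov(v01, rowvar=False)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 6 \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / 6
        d_auc = v10[:, 0].mean() - v10[:, 1].mean()
        expected_p = 2 * stats.norm.sf(abs(d_auc / np.sqrt(var)))
        assert ev.delong_test(s1, s2, y) == pytest.approx(expected_p)

    def test_null_p_uniformity(self):
        """Permuted-within-class scores: p should not pile up below 0.05."""
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        hits = 0
        reps = 200
        for _ in range(reps):
            s1 = rng.random(30)
            s2 = s1.copy()
            s2[y] = rng.permutation(s2[y])
            s2[~y] = rng.permutation(s2[~y])
            try:
                hits += ev.delong_test(s1, s2, y) < 0.05
            except ValueError:
                pass
        assert hits / reps < 0.12


class TestWilcoxon:
    def test_identical_near_one(self):
        x = np.arange(10.0)
        assert ev.wilcoxon_rank_sum(x, x) > 0.9

    def test_separated_samples(self):
        assert ev.wilcoxon_rank_sum(np.arange(10.0),
                                    np.arange(100.0, 110.0)) < 1e-3

    def test_u_statistic_matches_pair_counting(self):
        rng = np.random.default_rng(7)
        x, y = rng.integers(0, 8, 9).astype(float), \
            rng.integers(0, 8, 11).astype(float)
        u = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                for a in x for b in y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert res.statistic == pytest.approx(u)
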