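import numpy as np
import pytest

from conftest import random_harmonized
from neuromr.estimators import (DegenerateInstrumentError, MREstimate,
                                _weighted_median, consistent_direction, egger,
                                ivw, run_uvmr, wald_ratio, weighted_median)
from neuromr.harmonize import HarmonizedInstruments
from neuromr.instruments import InsufficientInstrumentsError


def make_h(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    j = len(bx)
    sx = np.full(j, 0.005) if sx is None else np.asarray(sx, float)
    ids = np.array([f"rs{i}" for i in range(j)], dtype=object)
    return HarmonizedInstruments(["x"], "y", ids, bx, sx,
                                 np.asarray(by, float), np.asarray(sy, float))


class TestWaldRatio:
    @pytest.mark.parametrize("bx,sx,by,sy,ratio,se", [
        (0.1, 0.01, 0.05, 0.01, 0.5, 0.1),
        (-0.1, 0.01, 0.05, 0.01, -0.5, 0.1),
    ])
    def test_examples(self, bx, sx, by, sy, ratio, se):
        r, s = wald_ratio(bx, sx, by, sy)
        assert r == pytest.approx(ratio) and s == pytest.approx(se)

    def test_second_order_reduces_to_first_at_zero_sx(self):
        r1, s1 = wald_ratio(0.1, 0.0, 0.05, 0.01)
        r2, s2 = wald_ratio(0.1, 0.0, 0.05, 0.01, second_order=True)
        assert (r1, s1) == (r2, s2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_closed_form_two_snp_example(self):
        h = make_h([0.1, 0.2], [0.05, 0.10], [0.01, 0.01])
        est = ivw(h)
        assert est.beta == pytest.approx(0.5, abs=1e-15)
        assert est.scale_factor == 1.0  # Q = 0 exactly
        assert est.method == "ivw_mre"

    def test_consensus_across_weights(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.2, 10)
        h = make_h(bx, 0.7 * bx, rng.uniform(0.005, 0.05, 10))
        assert ivw(h).beta == pytest.approx(0.7, abs=1e-12)

    def test_scale_equivariance_in_se_y(self):
        h1 = random_harmonized(3)
        h2 = HarmonizedInstruments(["x"], "y", h1.snp_ids, h1.beta_x, h1.se_x,
                                   h1.beta_y, 2 * h1.se_y)
        e1, e2 = ivw(h1, random_effects=False), ivw(h2, random_effects=False)
        assert e2.beta == pytest.approx(e1.beta)
        assert e2.se == pytest.approx(2 * e1.se)

    def test_single_snp_degrades_to_wald(self):
        h = make_h([0.1], [0.05], [0.01])
        est = ivw(h)
        assert est.method == "wald" and est.beta == pytest.approx(0.5)

    def test_mre_se_never_below_fe_se(self):
        for seed in range(30):
            h = random_harmonized(seed)
            assert ivw(h, True).se >= ivw(h, False).se - 1e-15
            assert ivw(h, True).scale_factor >= 1.0

    def test_ivw_equals_weighted_mean_of_ratios(self):
        """Algebraic identity with ratio weights (se_y/bx)^-2, to 1e-10."""
        for seed in range(20):
            h = random_harmonized(seed)
            ratios = h.beta_y / h.beta_x
            w = (h.se_y / h.beta_x) ** -2
            assert ivw(h).beta == pytest.approx(np.sum(w * ratios) / np.sum(w),
                                                abs=1e-10)

    def test_empty_set_rejected(self):
        h = make_h(np.empty(0), np.empty(0), np.empty(0))
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_h(bx, 0.02 + 0.5 * bx, [0.01] * 3)
        est = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.02, abs=1e-12)
        assert est.scale_factor == 1.0  # zero residuals truncate at 1

    def test_orientation_invariance(self):
        h1 = random_harmonized(8)
        flip = np.ones(h1.n_snp)
        flip[::3] = -1.0
        h2 = HarmonizedInstruments(["x"], "y", h1.snp_ids, h1.beta_x * flip,
                                   h1.se_x, h1.beta_y * flip, h1.se_y)
        e1, e2 = egger(h1), egger(h2)
        assert e2.beta == pytest.approx(e1.beta, abs=1e-12)
        assert e2.intercept == pytest.approx(e1.intercept, abs=1e-12)
        assert e2.se == pytest.approx(e1.se)

    def test_snp_order_invariance(self):
        h1 = random_harmonized(9)
        perm = np.random.default_rng(0).permutation(h1.n_snp)
        h2 = HarmonizedInstruments(["x"], "y", h1.snp_ids[perm],
                                   h1.beta_x[perm], h1.se_x[perm],
                                   h1.beta_y[perm], h1.se_y[perm])
        assert egger(h2).beta == pytest.approx(egger(h1).beta, abs=1e-12)

    def test_null_intercept_p_large_sample(self):
        rng = np.random.default_rng(12)
        j = 2000
        bx = rng.uniform(0.05, 0.2, j)
        sy = np.full(j, 0.01)
        h = make_h(bx, rng.normal(0.4 * bx, sy), sy)
        est = egger(h)
        assert est.intercept == pytest.approx(0.0, abs=1e-3)
        assert est.intercept_p > 0.05

    def test_arity(self):
        h = make_h([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_ratios_equal_weights(self):
        h = make_h([0.1, 0.1, 0.1], [0.04, 0.05, 0.06], [0.01] * 3)
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.5)

    def test_dominant_weight_wins(self):
        """One SNP carrying nearly all weight drives the estimate."""
        ratios = np.array([0.2, 0.9, 0.5])
        w = np.array([1e-6, 1e-6, 1e6])
        assert _weighted_median(ratios, w) == pytest.approx(0.5, abs=1e-3)

    def test_interpolation_against_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            r = rng.normal(0.5, 0.2, 7)
            w = rng.uniform(0.1, 2, 7)
            order = np.argsort(r)
            b, ww = r[order], w[order]
            s = (np.cumsum(ww) - ww / 2) / ww.sum()
            expect = np.interp(0.5, s, b)
            assert _weighted_median(r, w) == pytest.approx(expect, abs=1e-12)

    def test_majority_valid_robustness(self):
        """40% pleiotropic instruments barely move the weighted median."""
        rng = np.random.default_rng(14)
        j = 50
        bx = rng.uniform(0.05, 0.2, j)
        sy = np.full(j, 0.004)
        by = rng.normal(0.5 * bx, sy)
        by[:20] += 0.1  # shifted ratios for 40% of SNPs
        h = make_h(bx, by, sy)
        wm = weighted_median(h, n_boot=100, seed=1).beta
        naive = np.mean(by / bx)
        assert abs(wm - 0.5) < 0.1
        assert abs(naive - 0.5) > 3 * abs(wm - 0.5)

    def test_seed_reproducibility(self):
        h = random_harmonized(15)
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se and a.seed == 7

    def test_order_invariance(self):
        h1 = random_harmonized(16)
        perm = np.random.default_rng(2).permutation(h1.n_snp)
        h2 = HarmonizedInstruments(["x"], "y", h1.snp_ids[perm],
                                   h1.beta_x[perm], h1.se_x[perm],
                                   h1.beta_y[perm], h1.se_y[perm])
        assert weighted_median(h2, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(h1, n_boot=10, seed=0).beta, abs=1e-12)


class TestRunUvmr:
    def test_perfect_proportionality_consensus(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        h = make_h(bx, 0.5 * bx, [0.01] * 4)
        ests = run_uvmr(h, seed=0, n_boot=50)
        assert {e.method for e in ests} == {"ivw_mre", "egger", "weighted_median"}
        for e in ests:
            assert e.beta == pytest.approx(0.5, abs=1e-10)
        assert consistent_direction(ests)

    def test_two_snps_reports_ivw_only(self):
        h = make_h([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        ests = run_uvmr(h, seed=0)
        assert [e.method for e in ests] == ["ivw_mre"]

    def test_ci_orientation(self):
        for seed in range(5):
            for est in run_uvmr(random_harmonized(seed), seed=0, n_boot=50):
                assert est.ci_low < est.beta < est.ci_high
                assert est.or_ == pytest.approx(np.exp(est.beta))
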