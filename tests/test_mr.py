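"""Univariable MR estimators against independent oracles and exact identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_harmonized
from mrmediate.mr import (
    MRModel,
    cochran_q,
    egger,
    ivw,
    mean_f_statistic,
    per_snp_ratios,
    wald_ratio,
    weighted_median,
    _weighted_median_point,
)


def wls_oracle(X, y, w):
    """Independent weighted least squares via normal equations."""
    X = np.atleast_2d(X.T).T if X.ndim == 1 else X
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    beta = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    return beta, np.sqrt(np.diag(cov))


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        theta, se = wald_ratio(0.5, 0.05, 0.25, 0.1, order="first")
        assert theta == pytest.approx(0.5) and se == pytest.approx(0.2)

    def test_zero_outcome_beta(self):
        theta, _ = wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert theta == 0.0

    def test_second_order_se_formula(self):
        bx, bx_se, by, by_se = 0.5, 0.05, 0.25, 0.1
        _, se = wald_ratio(bx, bx_se, by, by_se, order="second")
        expected = np.sqrt(by_se**2 / bx**2 + by**2 * bx_se**2 / bx**4)
        assert se == pytest.approx(expected, rel=1e-14)

    def test_zero_bx_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


class TestIvw:
    def test_single_snp_reduces_to_wald_ratio(self):
        h = make_harmonized([0.4], [0.02], [0.12], [0.03])
        res, _ = ivw(h)
        theta, se = wald_ratio(0.4, 0.02, 0.12, 0.03)
        assert res.theta == pytest.approx(theta) and res.se == pytest.approx(se)
        assert res.method == "wald_ratio"

    def test_homogeneous_ratios_give_zero_q_and_equal_ses(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3)
        fe, _ = ivw(h, "fixed")
        mre, _ = ivw(h, "multiplicative_random")
        assert fe.theta == pytest.approx(0.4, abs=1e-12)
        assert fe.q == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(fe.se)

    def test_matches_wls_oracle(self, random_harmonized):
        h = random_harmonized
        res, _ = ivw(h, "fixed")
        w = 1.0 / h.by_se**2
        beta, se = wls_oracle(h.bx.reshape(-1, 1), h.by, w)
        assert res.theta == pytest.approx(beta[0], abs=1e-10)
        assert res.se == pytest.approx(se[0], abs=1e-10)

    def test_weight_scaling_invariance(self, random_harmonized):
        h = random_harmonized
        res, _ = ivw(h, "fixed")
        h2 = make_harmonized(h.bx, h.bx_se, h.by, h.by_se * 3.0)
        res2, _ = ivw(h2, "fixed")
        assert res2.theta == pytest.approx(res.theta, abs=1e-12)

    def test_mre_se_at_least_fixed(self, rng):
        for s in range(10):
            g = np.random.default_rng(s)
            bx = g.uniform(0.05, 0.2, 8)
            by = 0.2 * bx + g.normal(0, 0.05, 8)
            h = make_harmonized(bx, [0.01] * 8, by, [0.02] * 8)
            fe, _ = ivw(h, "fixed")
            mre, _ = ivw(h, "multiplicative_random")
            assert mre.se >= fe.se - 1e-15

    def test_binary_outcome_populates_odds_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3, outcome_is_binary=True)
        res, _ = ivw(h)
        assert res.odds_ratio == pytest.approx(np.exp(res.theta))


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        by = 0.1 + 0.3 * bx
        h = make_harmonized(bx, [0.01] * 4, by, [0.02] * 4)
        res = egger(h)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert res.theta == pytest.approx(0.3, abs=1e-12)

    def test_sign_flip_invariance(self, random_harmonized):
        h = random_harmonized
        res = egger(h)
        bx, by = h.bx.copy(), h.by.copy()
        bx[0], by[0] = -bx[0], -by[0]
        res2 = egger(make_harmonized(bx, h.bx_se, by, h.by_se))
        assert res2.theta == pytest.approx(res.theta, abs=1e-12)
        assert res2.egger_intercept == pytest.approx(res.egger_intercept, abs=1e-12)

    def test_matches_wls_oracle_after_orientation(self, random_harmonized):
        h = random_harmonized
        res = egger(h)
        sign = np.where(h.bx < 0, -1.0, 1.0)
        bx, by = h.bx * sign, h.by * sign
        w = 1.0 / h.by_se**2
        X = np.column_stack([np.ones_like(bx), bx])
        beta, se_unscaled = wls_oracle(X, by, w)
        q = np.sum(w * (by - X @ beta) ** 2)
        scale = max(1.0, np.sqrt(q / (len(bx) - 2)))
        assert res.theta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se_unscaled[1] * scale, abs=1e-10)
        assert res.egger_intercept_se == pytest.approx(se_unscaled[0] * scale, abs=1e-10)

    def test_slope_equals_ivw_when_intercept_zero(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        by = 0.3 * bx  # exact line through the origin
        h = make_harmonized(bx, [0.01] * 4, by, [0.02] * 4)
        res_e = egger(h)
        res_i, _ = ivw(h, "fixed")
        assert res_e.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert res_e.theta == pytest.approx(res_i.theta, abs=1e-12)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.01] * 3, by, [0.05] * 3)
        res = weighted_median(h, n_boot=50, seed=1)
        assert res.theta == pytest.approx(0.2)

    def test_concentrated_weight_limit(self):
        # SNP 0 carries ~99.97% of the inverse-variance weight.
        bx = np.ones(3)
        by = np.array([0.7, 0.1, 0.2])
        by_se = np.array([0.001, 0.1, 0.1])
        h = make_harmonized(bx, [0.01] * 3, by, by_se)
        res = weighted_median(h, n_boot=50, seed=1)
        assert res.theta == pytest.approx(0.7, abs=0.01)

    def test_point_estimate_matches_interpolation_formula(self, rng):
        j = 7
        ratio = rng.normal(0.2, 0.3, j)
        weight = rng.uniform(0.5, 4.0, j)
        order = np.argsort(ratio)
        r, w = ratio[order], weight[order]
        s = np.cumsum(w)
        p = (s - w / 2) / s[-1]
        expected = np.interp(0.5, p, r)
        assert _weighted_median_point(ratio, weight) == pytest.approx(expected, abs=1e-14)

    def test_bootstrap_se_deterministic_under_seed(self, random_harmonized):
        r1 = weighted_median(random_harmonized, n_boot=200, seed=9)
        r2 = weighted_median(random_harmonized, n_boot=200, seed=9)
        assert r1.se == r2.se


class TestDiagnostics:
    def test_cochran_q_identical_ratios(self):
        bx = np.array([0.1, 0.2])
        h = make_harmonized(bx, [0.01] * 2, 0.4 * bx, [0.02] * 2)
        q, p, df = cochran_q(per_snp_ratios(h), 0.4)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0) and df == 1

    def test_cochran_q_two_snp_arithmetic(self):
        from mrmediate.mr import PerSnpRatios
        ratios = PerSnpRatios(
            snp_ids=np.array(["a", "b"], dtype=object),
            ratio=np.array([0.0, 1.0]),
            ratio_se=np.array([1.0, 1.0]),
            weight=np.array([1.0, 1.0]),
        )
        q, _, _ = cochran_q(ratios, 0.5)
        assert q == pytest.approx(0.5)

    def test_cochran_q_matches_summation_oracle(self, rng):
        from mrmediate.mr import PerSnpRatios
        j = 15
        ratio = rng.normal(0, 1, j)
        w = rng.uniform(0.5, 5, j)
        ratios = PerSnpRatios(
            snp_ids=np.array([f"s{i}" for i in range(j)], dtype=object),
            ratio=ratio, ratio_se=1 / np.sqrt(w), weight=w,
        )
        theta = 0.123
        q, _, _ = cochran_q(ratios, theta)
        assert q == pytest.approx(float(np.sum(w * (ratio - theta) ** 2)), abs=1e-12)

    def test_mean_f_values(self):
        h = make_harmonized([0.05, 0.10], [0.01, 0.02], [0.01, 0.02], [0.02, 0.02])
        assert mean_f_statistic(h) == pytest.approx(25.0)
        h1 = make_harmonized([0.031623], [0.01], [0.01], [0.02])
        assert mean_f_statistic(h1) == pytest.approx(10.0, rel=1e-3)


class TestCoverage:
    def test_all_estimators_cover_truth_without_pleiotropy(self):
        """Strong instruments, no pleiotropy: 95% CIs cover theta in >=90% of runs."""
        from mrmediate.simulate import SimulationConfig, simulate
        from mrmediate.summary_io import harmonize
        theta_true = 0.33
        methods = {"ivw": 0, "egger": 0, "weighted_median": 0}
        n_rep = 60
        for s in range(n_rep):
            study = simulate(SimulationConfig(
                seed=3000 + s, n_snps_exposure=30, n_snps_mediator=0,
                alpha=0.0, theta_m=0.0, theta_dir=theta_true,
            ))
            h = harmonize(study.exposure, study.outcome, outcome_is_binary=True)
            model = MRModel(h)
            for m in methods:
                res = model.fit(m, seed=s, n_boot=200)
                methods[m] += res.ci_low <= theta_true <= res.ci_high
        for m, hits in methods.items():
            assert hits / n_rep >= 0.90, (m, hits / n_rep)
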