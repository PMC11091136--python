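"""Multivariable Mendelian randomization (MVMR) with strength/heterogeneity diagnostics.

MVMR regresses outcome associations on a (J x K) matrix of exposure
associations (no intercept, weights 1/by_se²), estimating each exposure's
*direct* effect conditional on the others. Diagnostics:

* Q_A — a heterogeneity statistic generalising Cochran's Q, with per-SNP
  variances sigma_j² = by_se_j² + Σ_k θ_k²·bx_se_jk² (second-order form,
  cross-terms ignored — the standard published form).
* Conditional F — instrument strength for one exposure given the others:
  the weighted residual sum of squares of exposure k's betas regressed on
  the remaining exposures, divided by J - (K - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedSet

__all__ = [
    "MvmrResults",
    "MVMRModel",
    "CollinearityError",
    "mvmr_ivw",
    "q_a_statistic",
    "conditional_f",
]

_Z95 = stats.norm.ppf(0.975)


class CollinearityError(ValueError):
    """Exposure beta matrix is rank-deficient (perfect collinearity)."""


@dataclass
class MvmrResults:
    """Direct-effect estimates for K exposures with diagnostics."""

    exposure_names: list[str]
    thetas: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvals: np.ndarray
    conditional_f: np.ndarray
    q_a: float
    q_a_pval: float
    n_snps: int

    def __post_init__(self) -> None:
        k = len(self.thetas)
        if k < 2:
            raise ValueError("MVMR needs at least 2 exposures")
        for arr in (self.ses, self.ci_low, self.ci_high, self.pvals, self.conditional_f):
            if len(arr) != k:
                raise ValueError("per-exposure vectors must share length")
        if self.q_a < 0:
            raise ValueError("Q_A must be non-negative")

    def to_dict(self) -> dict:
        return {
            "exposure_names": list(self.exposure_names),
            "thetas": self.thetas.tolist(),
            "ses": self.ses.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "pvals": self.pvals.tolist(),
            "conditional_f": self.conditional_f.tolist(),
            "q_a": self.q_a,
            "q_a_pval": self.q_a_pval,
            "n_snps": self.n_snps,
        }

    def summary(self) -> str:
        header = f"{'exposure':<16}{'theta':>10}{'se':>10}{'95% CI':>22}{'p':>10}{'cond. F':>9}"
        rows = [
            f"{name:<16}{t:>10.4f}{s:>10.4f}"
            f"{'[' + format(lo, '.4f') + ', ' + format(hi, '.4f') + ']':>22}"
            f"{p:>10.3g}{f:>9.1f}"
            for name, t, s, lo, hi, p, f in zip(
                self.exposure_names, self.thetas, self.ses, self.ci_low, self.ci_high,
                self.pvals, self.conditional_f,
            )
        ]
        width = len(header)
        rule = "=" * width
        tail = f"J = {self.n_snps}   Q_A = {self.q_a:.2f} (p = {self.q_a_pval:.3g})"
        return "\n".join([rule, "Multivariable MR (IVW) results", rule, header, *rows, rule, tail])


def _check_design(h: HarmonizedSet) -> None:
    j, k = h.exposure_betas.shape
    if k < 2:
        raise ValueError("MVMR needs at least 2 exposures")
    if j <= k:
        raise ValueError(f"need more instruments than exposures (J={j}, K={k})")
    if np.linalg.matrix_rank(h.exposure_betas) < k:
        raise CollinearityError("exposure beta matrix is rank-deficient (no perfect collinearity allowed)")


def q_a_statistic(h: HarmonizedSet, thetas: np.ndarray) -> tuple[float, float]:
    """Heterogeneity Q_A at the supplied direct effects.

    Q_A = Σ_j sigma_j^{-2} (by_j - Σ_k θ_k bx_jk)² with
    sigma_j² = by_se_j² + Σ_k θ_k² bx_se_jk²; df = J - K; χ² p-value.
    """
    thetas = np.asarray(thetas, dtype=float)
    j, k = h.exposure_betas.shape
    resid = h.outcome_betas - h.exposure_betas @ thetas
    sigma2 = h.outcome_ses**2 + (h.exposure_ses**2) @ (thetas**2)
    q_a = float(np.sum(resid**2 / sigma2))
    df = j - k
    return q_a, float(stats.chi2.sf(q_a, df)) if df > 0 else float("nan")


def conditional_f(h: HarmonizedSet, k: int) -> float:
    """Conditional instrument-strength F for exposure ``k`` given the others.

    Exposure k's betas are regressed on the other exposures' betas (WLS with
    weights 1/bx_se_jk², no intercept); the weighted residual sum of squares
    Q_x is divided by J - (K - 1). Values above 10 indicate adequate
    conditional strength.
    """
    j, n_exp = h.exposure_betas.shape
    if n_exp < 2:
        raise ValueError("conditional F needs at least 2 exposures")
    _check_design(h)
    y = h.exposure_betas[:, k]
    others = np.delete(h.exposure_betas, k, axis=1)
    w = 1.0 / h.exposure_ses[:, k] ** 2
    fit = sm.WLS(y, others, weights=w).fit()
    resid = y - fit.fittedvalues
    q_x = float(np.sum(w * resid**2))
    return q_x / (j - (n_exp - 1))


def mvmr_ivw(h: HarmonizedSet) -> MvmrResults:
    """Multivariable IVW: WLS of by on the exposure beta matrix, no intercept.

    Standard errors are the unit-dispersion WLS errors inflated by
    max(1, sqrt(Q_A/(J-K))) to absorb heterogeneity.
    """
    _check_design(h)
    j, k = h.exposure_betas.shape
    w = 1.0 / h.outcome_ses**2
    fit = sm.WLS(h.outcome_betas, h.exposure_betas, weights=w).fit()
    thetas = np.asarray(fit.params, dtype=float)
    sigma2_hat = float(fit.scale)  # weighted RSS / (J-K)
    unscaled = np.asarray(fit.bse) / np.sqrt(sigma2_hat)
    q_a, q_a_pval = q_a_statistic(h, thetas)
    scale = max(1.0, np.sqrt(q_a / (j - k)))
    ses = unscaled * scale
    cond_f = np.array([conditional_f(h, i) for i in range(k)])
    ci_low, ci_high = thetas - _Z95 * ses, thetas + _Z95 * ses
    pvals = 2.0 * stats.norm.sf(np.abs(thetas / ses))
    return MvmrResults(
        exposure_names=list(h.exposure_names),
        thetas=thetas,
        ses=ses,
        ci_low=ci_low,
        ci_high=ci_high,
        pvals=pvals,
        conditional_f=cond_f,
        q_a=q_a,
        q_a_pval=q_a_pval,
        n_snps=j,
    )


class MVMRModel:
    """Multivariable MR model over a harmonized multi-exposure set."""

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_exposures < 2:
            raise ValueError("MVMRModel needs at least 2 exposures")
        self.harmonized = harmonized

    def fit(self) -> MvmrResults:
        return mvmr_ivw(self.harmonized)

    def conditional_f(self, k: int) -> float:
        return conditional_f(self.harmonized, k)
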