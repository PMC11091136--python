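"""Univariable two-sample Mendelian randomization estimators and diagnostics.

The model: for each instrument j, the exposure association bx_j and outcome
association by_j (from non-overlapping samples) satisfy by_j ≈ θ·bx_j under
the instrumental-variable assumptions, where θ is the causal effect of the
exposure on the outcome. Estimators:

* Wald ratio — θ_j = by_j / bx_j per SNP.
* IVW — inverse-variance-weighted regression of by on bx through the origin
  with weights 1/by_se², under fixed or multiplicative random effects.
* MR-Egger — same regression with an intercept; the intercept indexes
  directional horizontal pleiotropy.
* Weighted median — consistent when at least half the total weight comes
  from valid instruments.

Diagnostics: Cochran's Q heterogeneity statistic and the mean F-statistic
for instrument strength (F > 10 is the conventional adequacy bar).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedSet

__all__ = [
    "MRResults",
    "PerSnpRatios",
    "MRModel",
    "wald_ratio",
    "per_snp_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
    "mean_f_statistic",
]

_Z95 = stats.norm.ppf(0.975)


class DegenerateInstrumentsError(ValueError):
    """All exposure betas are zero; no causal slope is identified."""


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


@dataclass
class MRResults:
    """A causal-effect estimate with its uncertainty and diagnostics.

    ``theta`` is on the outcome scale per unit exposure (log-odds per
    exposure SD for binary outcomes); ``odds_ratio`` fields are populated
    only for binary outcomes.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def summary(self) -> str:
        lines = [
            f"{'Method':<22}{self.method}",
            f"{'No. instruments':<22}{self.n_snps}",
            f"{'Effect (theta)':<22}{self.theta:.4f}",
            f"{'Std. error':<22}{self.se:.4f}",
            f"{'95% CI':<22}[{self.ci_low:.4f}, {self.ci_high:.4f}]",
            f"{'P-value':<22}{self.pval:.3g}",
        ]
        if self.odds_ratio is not None:
            lines.append(
                f"{'Odds ratio':<22}{self.odds_ratio:.3f} [{self.or_ci_low:.3f}, {self.or_ci_high:.3f}]"
            )
        if self.q is not None:
            lines.append(f"{'Cochran Q (p)':<22}{self.q:.2f} ({self.q_pval:.3g})")
        if self.egger_intercept is not None:
            lines.append(
                f"{'Egger intercept (p)':<22}{self.egger_intercept:.4f} ({self.egger_intercept_pval:.3g})"
            )
        width = max(len(s) for s in lines)
        rule = "=" * width
        return "\n".join([rule, "Two-sample MR results", rule, *lines, rule])


@dataclass
class PerSnpRatios:
    """Per-SNP Wald ratios with inverse-variance weights (forest-plot data)."""

    snp_ids: np.ndarray
    ratio: np.ndarray
    ratio_se: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.snp_ids) == len(self.ratio) == len(self.ratio_se) == len(self.weight)):
            raise ValueError("per-SNP vectors must share length")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")


def _finalize(
    method: str,
    theta: float,
    se: float,
    n_snps: int,
    outcome_is_binary: bool,
    **extra,
) -> MRResults:
    ci_low, ci_high = theta - _Z95 * se, theta + _Z95 * se
    pval = 2.0 * stats.norm.sf(abs(theta / se))
    res = MRResults(
        method=method,
        theta=theta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        pval=pval,
        n_snps=n_snps,
        **extra,
    )
    if outcome_is_binary:
        res.odds_ratio = float(np.exp(theta))
        res.or_ci_low = float(np.exp(ci_low))
        res.or_ci_high = float(np.exp(ci_high))
    return res


def wald_ratio(
    bx: float,
    bx_se: float,
    by: float,
    by_se: float,
    order: Literal["first", "second"] = "first",
) -> tuple[float, float]:
    """Single-SNP causal estimate by/bx with first- or second-order SE.

    First order: se = by_se/|bx|. Second order additionally propagates the
    exposure-side uncertainty: se = sqrt(by_se²/bx² + by²·bx_se²/bx⁴).
    """
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx == 0")
    theta = by / bx
    if order == "first":
        se = by_se / abs(bx)
    elif order == "second":
        se = float(np.sqrt(by_se**2 / bx**2 + by**2 * bx_se**2 / bx**4))
    else:
        raise ValueError(f"unknown order {order!r}")
    return theta, se


def per_snp_ratios(h: HarmonizedSet, order: Literal["first", "second"] = "first") -> PerSnpRatios:
    """Wald ratios and inverse-variance weights for every instrument."""
    bx, bx_se, by, by_se = h.bx, h.bx_se, h.by, h.by_se
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for bx == 0")
    ratio = by / bx
    if order == "first":
        ratio_se = by_se / np.abs(bx)
    else:
        ratio_se = np.sqrt(by_se**2 / bx**2 + by**2 * bx_se**2 / bx**4)
    return PerSnpRatios(
        snp_ids=np.asarray(h.snp_ids),
        ratio=ratio,
        ratio_se=ratio_se,
        weight=1.0 / ratio_se**2,
    )


def ivw(
    h: HarmonizedSet,
    effects_model: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
    weights: Literal["first", "second"] = "first",
) -> tuple[MRResults, PerSnpRatios]:
    """Inverse-variance-weighted estimate.

    Equivalent to weighted least squares of by on bx through the origin with
    weights 1/by_se² (first-order). Under the multiplicative-random-effects
    (MRE) model the fixed-effects SE is inflated by max(1, sqrt(Q/(J-1)))
    to absorb heterogeneity; it is never allowed below the fixed SE.
    """
    bx, by = h.bx, h.by
    if np.all(bx == 0):
        raise DegenerateInstrumentsError("all exposure betas are zero")
    j = h.n_snps
    ratios = per_snp_ratios(h, order=weights)
    if j == 1:
        theta, se = wald_ratio(float(bx[0]), float(h.bx_se[0]), float(by[0]), float(h.by_se[0]), order=weights)
        res = _finalize("wald_ratio", theta, se, 1, h.outcome_is_binary)
        return res, ratios
    if weights == "first":
        w = 1.0 / h.by_se**2
    else:
        w = ratios.weight / bx**2  # 1/(by_se² + θ_j²·bx_se²) style per-SNP variance, on the by scale
    sw_xx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by) / sw_xx)
    se_fixed = float(1.0 / np.sqrt(sw_xx))
    q = float(np.sum(w * (by - theta * bx) ** 2))
    q_pval = float(stats.chi2.sf(q, j - 1))
    if effects_model == "fixed":
        se, method = se_fixed, "ivw_fe"
    elif effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, float(np.sqrt(q / (j - 1))))
        method = "ivw_mre"
    else:
        raise ValueError(f"unknown effects model {effects_model!r}")
    res = _finalize(method, theta, se, j, h.outcome_is_binary, q=q, q_pval=q_pval)
    return res, ratios


def egger(h: HarmonizedSet) -> MRResults:
    """MR-Egger regression: WLS of by on bx with an intercept.

    Instruments are oriented so bx >= 0 (both betas negated when bx < 0),
    which makes the fit invariant to each SNP's arbitrary allele coding. The
    intercept estimates the average directional pleiotropic effect; slope
    and intercept SEs are inflated by max(1, sqrt(Q_egger/(J-2))), and
    p-values and CIs use the t(J-2) reference (the dispersion is estimated
    from J-2 residual degrees of freedom).
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx, by = h.bx * sign, h.by * sign
    w = 1.0 / h.by_se**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    resid = by - fit.fittedvalues
    q = float(np.sum(w * resid**2))
    sigma2 = q / (j - 2)
    # statsmodels scales the covariance by sigma-hat²; rescale to the
    # unit-dispersion parameterisation, then apply the max(1, ·) floor.
    unscaled = np.asarray(fit.bse) / np.sqrt(sigma2)
    scale = max(1.0, np.sqrt(sigma2))
    int_se, slope_se = float(unscaled[0] * scale), float(unscaled[1] * scale)
    df = j - 2
    int_pval = float(2.0 * stats.t.sf(abs(intercept / int_se), df))
    tcrit = float(stats.t.ppf(0.975, df))
    res = MRResults(
        method="egger",
        theta=slope,
        se=slope_se,
        ci_low=slope - tcrit * slope_se,
        ci_high=slope + tcrit * slope_se,
        pval=float(2.0 * stats.t.sf(abs(slope / slope_se), df)),
        n_snps=j,
        q=q,
        q_pval=float(stats.chi2.sf(q, df)),
        egger_intercept=intercept,
        egger_intercept_se=int_se,
        egger_intercept_pval=int_pval,
    )
    if h.outcome_is_binary:
        res.odds_ratio = float(np.exp(slope))
        res.or_ci_low = float(np.exp(res.ci_low))
        res.or_ci_high = float(np.exp(res.ci_high))
    return res


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Linear interpolation of order-sorted ratios at cumulative weight 0.5."""
    order = np.argsort(ratio)
    r, w = ratio[order], weight[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, p, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResults:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Weights are first-order inverse-variance weights of the per-SNP ratios.
    Each bootstrap draw perturbs every bx_j and by_j by its own SE and
    re-evaluates the weighted median.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    ratios = per_snp_ratios(h, order="first")
    theta = _weighted_median_point(ratios.ratio, ratios.weight)
    rng = np.random.default_rng(seed)
    bx_b = h.bx + rng.standard_normal((n_boot, j)) * h.bx_se
    by_b = h.by + rng.standard_normal((n_boot, j)) * h.by_se
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    ratio_b = by_b / bx_b
    w_b = (np.abs(bx_b) / h.by_se) ** 2
    est = np.empty(n_boot)
    for i in range(n_boot):
        est[i] = _weighted_median_point(ratio_b[i], w_b[i])
    se = float(np.std(est, ddof=1))
    return _finalize("weighted_median", theta, se, j, h.outcome_is_binary)


def cochran_q(ratios: PerSnpRatios, theta: float) -> tuple[float, float, int]:
    """Cochran's Q = Σ W_j (θ_j - θ)² with a χ²(J-1) p-value."""
    j = len(ratios.ratio)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    q = float(np.sum(ratios.weight * (ratios.ratio - theta) ** 2))
    return q, float(stats.chi2.sf(q, j - 1)), j - 1


def mean_f_statistic(h: HarmonizedSet) -> float:
    """Mean instrument-strength F: mean over SNPs of (bx_j/bx_se_j)²."""
    if h.n_exposures != 1:
        raise ValueError("mean_f_statistic expects a single exposure")
    return float(np.mean((h.bx / h.bx_se) ** 2))


class MRModel:
    """Univariable two-sample MR model over a harmonized instrument set.

    Parameters
    ----------
    harmonized : HarmonizedSet with a single exposure.

    Examples
    --------
    >>> model = MRModel(harmonized)          # doctest: +SKIP
    >>> res = model.fit(method="ivw")        # doctest: +SKIP
    >>> print(res.summary())                 # doctest: +SKIP
    """

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_exposures != 1:
            raise ValueError("MRModel expects a single exposure; use MVMRModel otherwise")
        self.harmonized = harmonized

    def fit(
        self,
        method: Literal["ivw", "egger", "weighted_median"] = "ivw",
        effects_model: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> MRResults:
        if method == "ivw":
            res, _ = ivw(self.harmonized, effects_model=effects_model)
            return res
        if method == "egger":
            return egger(self.harmonized)
        if method == "weighted_median":
            return weighted_median(self.harmonized, n_boot=n_boot, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int = 0, n_boot: int = 1000) -> list[MRResults]:
        """IVW (fixed + MRE), Egger and weighted median in one call."""
        out = [
            self.fit("ivw", effects_model="fixed"),
            self.fit("ivw", effects_model="multiplicative_random"),
        ]
        if self.harmonized.n_snps >= 3:
            out.append(self.fit("egger"))
            out.append(self.fit("weighted_median", seed=seed, n_boot=n_boot))
        return out

    def ratios(self, order: Literal["first", "second"] = "first") -> PerSnpRatios:
        return per_snp_ratios(self.harmonized, order=order)

    def mean_f(self) -> float:
        return mean_f_statistic(self.harmonized)
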