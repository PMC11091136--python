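"""Heterogeneity-driven outlier detection and outlier-corrected re-estimation.

Two complementary procedures:

* ``presso`` — a simulation-based global / per-SNP outlier / distortion test
  in the MR-PRESSO style: the observed residual sum of squares around
  leave-one-out IVW fits is compared with its parametric-bootstrap null,
  per-SNP squared residuals give Bonferroni-adjusted empirical outlier
  p-values, and a distortion test asks whether removing the flagged SNPs
  moves the estimate more than removing random SNPs would.
* ``radial_ivw`` — radial (Galbraith) MR: per-SNP contributions Q_j to
  Cochran's Q under first-order or iterated modified second-order weights;
  SNPs whose Q_j exceeds the chi-square(1) upper-alpha quantile (alpha
  Bonferroni-corrected by default) are flagged.

Empirical p-values use the add-one convention (r+1)/(nsim+1) so they are
never exactly zero and live on a fixed grid for a given nsim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .mr import (
    InsufficientInstrumentsError,
    MRResults,
    _finalize,
    ivw,
    per_snp_ratios,
    wald_ratio,
)
from .summary_io import HarmonizedSet

__all__ = ["OutlierReport", "presso", "radial_ivw", "RadialConvergenceError"]


class RadialConvergenceError(RuntimeError):
    """Modified second-order weight iteration failed to converge."""

    def __init__(self, trace: list[float]):
        super().__init__(
            f"radial estimate did not converge in {len(trace)} iterations; trace tail: "
            + ", ".join(f"{t:.6g}" for t in trace[-5:])
        )
        self.trace = trace


@dataclass
class OutlierReport:
    """Result of an outlier analysis over one instrument set."""

    method: str
    global_stat: float
    global_pval: float
    per_snp: np.ndarray  # empirical p-values (presso) or Q_j contributions (radial)
    snp_ids: np.ndarray
    outlier_ids: list[str]
    corrected: MRResults
    alpha: float
    distortion_pval: float | None = None
    nsim: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not set(self.outlier_ids) <= set(self.snp_ids):
            raise ValueError("outlier ids must be a subset of instrument ids")
        if self.corrected.n_snps != len(self.snp_ids) - len(self.outlier_ids):
            raise ValueError("corrected estimate must use exactly the non-outlier SNPs")


def _loo_ivw_theta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for each SNP, via sum subtraction.

    Supports batched inputs: arrays of shape (..., J) give (..., J) slopes.
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def _rss_and_residuals(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta_loo = _loo_ivw_theta(bx, by, w)
    resid2 = (by - theta_loo * bx) ** 2
    return np.sum(resid2, axis=-1), resid2


def presso(
    h: HarmonizedSet,
    nsim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> OutlierReport:
    """Simulation-based global heterogeneity, outlier and distortion tests.

    The global statistic is the observed RSS around leave-one-out IVW fits;
    its null distribution comes from ``nsim`` parametric simulations with
    by*_j ~ N(theta_loo_j * bx_j, by_se_j) and bx*_j ~ N(bx_j, bx_se_j).
    Per-SNP outlier p-values compare each observed squared residual with its
    simulated distribution (Bonferroni-adjusted across J). The distortion
    test compares the estimate shift caused by removing the flagged SNPs
    with shifts from removing equally many random SNPs.
    """
    j = h.n_snps
    if j < 4:
        raise InsufficientInstrumentsError("presso needs at least 4 instruments")
    bx, bx_se, by, by_se = h.bx, h.bx_se, h.by, h.by_se
    w = 1.0 / by_se**2

    rss_obs, resid2_obs = _rss_and_residuals(bx, by, w)
    theta_loo = _loo_ivw_theta(bx, by, w)

    rng = np.random.default_rng(seed)
    by_sim = theta_loo * bx + rng.standard_normal((nsim, j)) * by_se
    bx_sim = bx + rng.standard_normal((nsim, j)) * bx_se
    rss_sim, resid2_sim = _rss_and_residuals(bx_sim, by_sim, w)

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (nsim + 1))
    per_snp_p = (np.sum(resid2_sim >= resid2_obs, axis=0) + 1) / (nsim + 1)
    adj = np.minimum(1.0, per_snp_p * j)
    outlier_mask = adj < outlier_alpha
    outlier_ids = [str(s) for s in h.snp_ids[outlier_mask]]

    if outlier_mask.any():
        corrected, _ = ivw(h.subset(~outlier_mask))
    else:
        corrected, _ = ivw(h)

    distortion_pval: float | None = None
    if outlier_mask.any() and outlier_mask.sum() < j:
        all_theta, _ = ivw(h)
        d_obs = corrected.theta - all_theta.theta
        n_out = int(outlier_mask.sum())
        rng2 = np.random.default_rng(seed + 1)
        n_draws = 1000
        d_null = np.empty(n_draws)
        s_xy, s_xx = float(np.sum(w * bx * by)), float(np.sum(w * bx * bx))
        for b in range(n_draws):
            drop = rng2.choice(j, size=n_out, replace=False)
            sub_xy = s_xy - float(np.sum(w[drop] * bx[drop] * by[drop]))
            sub_xx = s_xx - float(np.sum(w[drop] * bx[drop] * bx[drop]))
            d_null[b] = sub_xy / sub_xx - all_theta.theta
        distortion_pval = float((np.sum(np.abs(d_null) >= abs(d_obs)) + 1) / (n_draws + 1))

    return OutlierReport(
        method="presso",
        global_stat=float(rss_obs),
        global_pval=global_pval,
        per_snp=adj,
        snp_ids=np.asarray(h.snp_ids),
        outlier_ids=outlier_ids,
        corrected=corrected,
        alpha=outlier_alpha,
        distortion_pval=distortion_pval,
        nsim=nsim,
        seed=seed,
    )


def _radial_fit(
    ratio: np.ndarray,
    by_se: np.ndarray,
    bx: np.ndarray,
    bx_se: np.ndarray,
    weights: Literal["first", "modified_second"],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[float, np.ndarray]:
    """Radial IVW slope and final per-SNP weights."""
    w_first = bx**2 / by_se**2
    theta = float(np.sum(w_first * ratio) / np.sum(w_first))
    if weights == "first":
        return theta, w_first
    trace = [theta]
    for _ in range(max_iter):
        w = 1.0 / (by_se**2 / bx**2 + theta**2 * bx_se**2 / bx**2)
        theta_new = float(np.sum(w * ratio) / np.sum(w))
        trace.append(theta_new)
        if abs(theta_new - theta) < tol:
            return theta_new, w
        theta = theta_new
    raise RadialConvergenceError(trace)


def radial_ivw(
    h: HarmonizedSet,
    weights: Literal["first", "modified_second"] = "modified_second",
    alpha: float | None = None,
) -> OutlierReport:
    """Radial-MR outlier detection via per-SNP Q contributions.

    ``alpha`` defaults to the Bonferroni-corrected 0.05/J. With first-order
    weights the radial slope equals the fixed-effects IVW slope and the
    summed Q_j equal Cochran's Q at that slope.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientInstrumentsError("radial MR needs at least 3 instruments")
    if alpha is None:
        alpha = 0.05 / j
    ratios = per_snp_ratios(h, order="first")
    theta, w = _radial_fit(ratios.ratio, h.by_se, h.bx, h.bx_se, weights)
    q_j = w * (ratios.ratio - theta) ** 2
    q_total = float(np.sum(q_j))
    crit = stats.chi2.isf(alpha, df=1)
    outlier_mask = q_j > crit
    outlier_ids = [str(s) for s in h.snp_ids[outlier_mask]]

    keep = ~outlier_mask if outlier_mask.any() else np.ones(j, dtype=bool)
    h_keep = h.subset(keep)
    if h_keep.n_snps == 1:
        theta_c, se_c = wald_ratio(
            float(h_keep.bx[0]), float(h_keep.bx_se[0]), float(h_keep.by[0]), float(h_keep.by_se[0])
        )
        corrected = _finalize("wald_ratio", theta_c, se_c, 1, h.outcome_is_binary)
    else:
        r_keep = per_snp_ratios(h_keep, order="first")
        theta_c, w_c = _radial_fit(r_keep.ratio, h_keep.by_se, h_keep.bx, h_keep.bx_se, weights)
        q_c = float(np.sum(w_c * (r_keep.ratio - theta_c) ** 2))
        jc = h_keep.n_snps
        se_c = float(1.0 / np.sqrt(np.sum(w_c))) * max(1.0, float(np.sqrt(q_c / (jc - 1))))
        corrected = _finalize(
            "radial_ivw",
            theta_c,
            se_c,
            jc,
            h.outcome_is_binary,
            q=q_c,
            q_pval=float(stats.chi2.sf(q_c, jc - 1)),
        )

    return OutlierReport(
        method="radial",
        global_stat=q_total,
        global_pval=float(stats.chi2.sf(q_total, j - 1)),
        per_snp=q_j,
        snp_ids=np.asarray(h.snp_ids),
        outlier_ids=outlier_ids,
        corrected=corrected,
        alpha=alpha,
    )
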