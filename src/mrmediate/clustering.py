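"""Mixture-model clustering of per-SNP Wald-ratio estimates.

Heterogeneous instruments may act through distinct causal mechanisms, each
with its own ratio estimate. The model assigns each per-SNP ratio theta_j
(with known standard error se_j) to one of:

* K substantive clusters: theta_j ~ Normal(mu_k, se_j²),
* a null cluster: theta_j ~ Normal(0, se_j²),
* a junk cluster with a flat heavy density over
  [min theta - 3·max se, max theta + 3·max se]

fitted by expectation-maximization with seeded random restarts over
K = 0..k_max; K is chosen by minimum BIC. A SNP is labelled only when its
maximum posterior probability reaches ``prob_threshold`` (0.9 by default,
keeping assignments conservative); otherwise it is "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mr import (
    InsufficientInstrumentsError,
    MRResults,
    MRModel,
    PerSnpRatios,
    _finalize,
    wald_ratio,
)
from .summary_io import HarmonizedSet

__all__ = ["ClusterSolution", "cluster_ratios", "per_cluster_ivw", "EmConvergenceError"]


class EmConvergenceError(RuntimeError):
    """No EM restart converged for any number of clusters."""


@dataclass
class ClusterSolution:
    """A fitted clustering of per-SNP ratio estimates."""

    k_best: int
    cluster_means: np.ndarray
    cluster_assignments: list[str]  # "1".."K", "null", "junk", "unassigned"
    inclusion_probs: np.ndarray
    posterior: np.ndarray  # (J, k_best + 2): substantive clusters, null, junk
    bic_trace: dict[int, float]
    prob_threshold: float
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.inclusion_probs < 0) | (self.inclusion_probs > 1)):
            raise ValueError("inclusion probabilities must lie in [0, 1]")


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _component_logpdf(theta: np.ndarray, se: np.ndarray, means: np.ndarray, junk_logpdf: float) -> np.ndarray:
    """Log density of each ratio under each component (K substantive, null, junk)."""
    j = len(theta)
    k = len(means)
    log_se = np.log(se) + _LOG_SQRT_2PI
    out = np.empty((j, k + 2))
    if k:
        out[:, :k] = -0.5 * ((theta[:, None] - means[None, :]) / se[:, None]) ** 2 - log_se[:, None]
    out[:, k] = -0.5 * (theta / se) ** 2 - log_se
    out[:, k + 1] = junk_logpdf
    return out

def _em_fit_batch(
    theta: np.ndarray,
    se: np.ndarray,
    means0: np.ndarray,  # (R, K)
    pi0: np.ndarray,  # (R, K+2)
    junk_logpdf: float,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray] | None:
    """EM over R parallel restarts; returns the best converged run.

    Returns (loglik, means, pi, responsibilities) or None if no restart
    converged (absolute log-likelihood change < tol within max_iter).
    """
    r, k = means0.shape
    j = len(theta)
    means = means0.copy()
    pi = pi0.copy()
    inv_var = 1.0 / se**2
    log_se = np.log(se) + _LOG_SQRT_2PI
    null_logpdf = -0.5 * (theta / se) ** 2 - log_se  # (J,)
    loglik_prev = np.full(r, -np.inf)
    converged = np.zeros(r, dtype=bool)
    final_loglik = np.full(r, -np.inf)
    resp = np.empty((r, j, k + 2))
    for _ in range(max_iter):
        logp = np.empty((r, j, k + 2))
        if k:
            logp[:, :, :k] = (
                -0.5 * ((theta[None, :, None] - means[:, None, :]) / se[None, :, None]) ** 2
                - log_se[None, :, None]
            )
        logp[:, :, k] = null_logpdf[None, :]
        logp[:, :, k + 1] = junk_logpdf
        logp += np.log(pi)[:, None, :]
        m = logp.max(axis=2, keepdims=True)
        p = np.exp(logp - m)
        norm = p.sum(axis=2, keepdims=True)
        resp = p / norm
        loglik = np.sum(m[:, :, 0] + np.log(norm[:, :, 0]), axis=1)
        newly = ~converged & (np.abs(loglik - loglik_prev) < tol)
        converged |= newly
        final_loglik = np.where(converged, np.maximum(final_loglik, loglik), loglik)
        if converged.all():
            break
        loglik_prev = loglik
        # M-step: precision-weighted means for substantive components.
        if k:
            num = np.einsum("rjk,j->rk", resp[:, :, :k], theta * inv_var)
            den = np.einsum("rjk,j->rk", resp[:, :, :k], inv_var)
            means = np.where(den > 0, num / np.maximum(den, 1e-300), means)
        pi = resp.mean(axis=1)
        pi = np.maximum(pi, 1e-12)
        pi /= pi.sum(axis=1, keepdims=True)
    if not converged.any():
        return None
    final_loglik = np.where(converged, final_loglik, -np.inf)
    best = int(np.argmax(final_loglik))
    return float(final_loglik[best]), means[best], pi[best], resp[best]


def cluster_ratios(
    ratios: PerSnpRatios,
    k_max: int = 10,
    prob_threshold: float = 0.9,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterSolution:
    """Fit the substantive/null/junk mixture and assign SNPs by posterior.

    For each K in 0..k_max the EM is run from ``n_restarts`` seeded starts
    (means initialised at quantiles of the ratios, mixing proportions drawn
    Dirichlet-uniform) and the best log-likelihood is kept; the returned K
    minimises BIC. Clusters that end up with no assigned SNP are dropped.
    """
    theta = np.asarray(ratios.ratio, dtype=float)
    se = np.asarray(ratios.ratio_se, dtype=float)
    j = len(theta)
    if j < 3:
        raise InsufficientInstrumentsError("clustering needs at least 3 ratios")
    if np.any(se <= 0):
        raise ValueError("ratio standard errors must be positive")

    lo = float(theta.min() - 3.0 * se.max())
    hi = float(theta.max() + 3.0 * se.max())
    junk_logpdf = -np.log(hi - lo) if hi > lo else 0.0

    rng = np.random.default_rng(seed)
    best_by_k: dict[int, tuple[float, np.ndarray, np.ndarray, np.ndarray]] = {}
    bic_trace: dict[int, float] = {}
    k_cap = min(k_max, j)
    for k in range(0, k_cap + 1):
        r_n = n_restarts if k else 1
        means0 = np.empty((r_n, k))
        for r in range(r_n):
            if k:
                # First restart at even quantiles, the rest at random ones.
                qs = (np.arange(k) + 0.5) / k if r == 0 else np.sort(rng.uniform(0.0, 1.0, size=k))
                means0[r] = np.quantile(theta, qs)
        pi0 = rng.dirichlet(np.ones(k + 2), size=r_n)
        best = _em_fit_batch(theta, se, means0, pi0, junk_logpdf)
        if best is None:
            continue
        best_by_k[k] = best
        n_params = 2 * k + 1  # k means + (k+2)-1 free mixing proportions
        bic_trace[k] = -2.0 * best[0] + n_params * np.log(j)
    if not best_by_k:
        raise EmConvergenceError("EM failed to converge for every K and restart")

    k_best = min(bic_trace, key=lambda k: (bic_trace[k], k))
    _, means, pi, resp = best_by_k[k_best]

    # Drop substantive clusters that no SNP is assigned to (by argmax).
    if k_best:
        arg = resp.argmax(axis=1)
        used = sorted({a for a in arg if a < k_best})
        if len(used) < k_best:
            keep_cols = used + [k_best, k_best + 1]
            means = means[used]
            resp = resp[:, keep_cols]
            resp = resp / resp.sum(axis=1, keepdims=True)
            k_best = len(used)

    # Order clusters by mean for stable labelling.
    if k_best:
        order = np.argsort(means)
        means = means[order]
        resp = np.concatenate([resp[:, order], resp[:, k_best:]], axis=1)

    arg = resp.argmax(axis=1)
    maxp = resp.max(axis=1)
    labels: list[str] = []
    for a, p in zip(arg, maxp):
        if p < prob_threshold:
            labels.append("unassigned")
        elif a < k_best:
            labels.append(str(a + 1))
        elif a == k_best:
            labels.append("null")
        else:
            labels.append("junk")

    return ClusterSolution(
        k_best=k_best,
        cluster_means=means,
        cluster_assignments=labels,
        inclusion_probs=maxp,
        posterior=resp,
        bic_trace=bic_trace,
        prob_threshold=prob_threshold,
        snp_ids=np.asarray(ratios.snp_ids),
    )


def per_cluster_ivw(h: HarmonizedSet, solution: ClusterSolution) -> dict[str, MRResults]:
    """IVW (MRE) estimate within each substantive cluster.

    Singleton clusters fall back to the Wald ratio, labelled as such. A
    solution with only null/junk/unassigned SNPs yields an empty mapping.
    """
    by_label: dict[str, list[str]] = {}
    id_to_label = dict(zip(solution.snp_ids, solution.cluster_assignments))
    for sid in h.snp_ids:
        lab = id_to_label.get(sid)
        if lab is not None and lab not in ("null", "junk", "unassigned"):
            by_label.setdefault(lab, []).append(sid)
    out: dict[str, MRResults] = {}
    for lab in sorted(by_label, key=lambda s: int(s)):
        sub = h.subset(by_label[lab])
        if sub.n_snps == 1:
            t, s = wald_ratio(float(sub.bx[0]), float(sub.bx_se[0]), float(sub.by[0]), float(sub.by_se[0]))
            out[lab] = _finalize("wald_ratio_singleton", t, s, 1, h.outcome_is_binary)
        else:
            out[lab] = MRModel(sub).fit("ivw")
    return out
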