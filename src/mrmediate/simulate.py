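"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the exposure → mediator → outcome diagram the
pipeline analyses (childhood body size → mammographic dense area → breast
cancer, structurally): independent SNP instruments, an exposure with
normally distributed per-SNP effects, a mediator receiving alpha times the
exposure effect plus optional pleiotropy, and a binary-outcome log-odds
scale receiving theta_dir directly from the exposure and theta_m from the
mediator. Summary statistics are generated directly at the beta/SE level
(no individual-level genotypes): the observed beta is the true effect plus
independent Normal(0, SE) noise per trait, giving exact two-sample
(non-overlapping) sampling. SEs follow 1/sqrt(2·MAF·(1-MAF)·N) for
continuous traits and the logistic-information analogue
1/sqrt(2·MAF·(1-MAF)·N·v·(1-v)) for a binary outcome with case fraction v.

The ground truth is returned as a :class:`TruthLedger` whose implied total
(TE = theta_dir + alpha·theta_m), indirect (IE = alpha·theta_m) and
proportion-mediated (PM = IE/TE) quantities hold exactly by construction.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .summary_io import SnpAssociation, write_summary_stats

__all__ = ["SimulationConfig", "TruthLedger", "SimulatedStudy", "simulate", "plant_outlier", "write_study"]

# Ordered non-palindromic allele pairs (A/T and C/G excluded so that default
# output harmonizes without strand ambiguity).
_ALLELE_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("C", "T"), ("T", "C"), ("G", "T"), ("T", "G"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the analysis regime the pipeline is built for: a strong
    protective exposure→mediator effect (alpha = -0.63 mediator SD per
    exposure unit), a risk-increasing mediator→outcome direct effect
    (theta_m = 0.33 log-odds per mediator SD), a direct protective
    exposure→outcome path (theta_dir = -0.18 log-odds), 100 instruments per
    trait with per-SNP effect SD 0.05 and 200,000 individuals per
    (non-overlapping) sample.
    """

    seed: int
    n_snps_exposure: int = 100
    n_snps_mediator: int = 100
    n_snps_reverse: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05
    alpha: float = -0.63
    theta_m: float = 0.33
    theta_dir: float = -0.18
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_gamma_corr: float = 0.0
    reverse_effect: float = 0.0
    n_exposure: int = 200_000
    n_mediator: int = 200_000
    n_outcome: int = 200_000
    case_fraction: float = 0.5
    outcome_is_binary: bool = True
    planted_outliers: tuple[tuple[int, float], ...] = ()
    planted_clusters: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for sd in (self.gamma_sd, self.pleiotropy_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if sum(s for s, _ in self.planted_clusters) > self.n_snps_exposure:
            raise ValueError("planted clusters exceed the number of exposure SNPs")


@dataclass
class TruthLedger:
    """Ground truth of a simulated study; identities hold exactly."""

    snp_ids: list[str]
    beta_exposure: np.ndarray
    beta_mediator: np.ndarray
    beta_outcome: np.ndarray
    alpha: float
    theta_m: float
    theta_dir: float
    outlier_ids: list[str] = field(default_factory=list)
    cluster_labels: list[str] = field(default_factory=list)
    reverse_ids: list[str] = field(default_factory=list)

    @property
    def total_effect(self) -> float:
        return self.theta_dir + self.alpha * self.theta_m

    @property
    def indirect_effect(self) -> float:
        return self.alpha * self.theta_m

    @property
    def proportion_mediated(self) -> float:
        return self.indirect_effect / self.total_effect

    def to_dict(self) -> dict:
        return {
            "snp_ids": self.snp_ids,
            "beta_exposure": self.beta_exposure.tolist(),
            "beta_mediator": self.beta_mediator.tolist(),
            "beta_outcome": self.beta_outcome.tolist(),
            "alpha": self.alpha,
            "theta_m": self.theta_m,
            "theta_dir": self.theta_dir,
            "total_effect": self.total_effect,
            "indirect_effect": self.indirect_effect,
            "proportion_mediated": self.proportion_mediated,
            "outlier_ids": self.outlier_ids,
            "cluster_labels": self.cluster_labels,
            "reverse_ids": self.reverse_ids,
        }


@dataclass
class SimulatedStudy:
    """Three per-trait summary-statistics collections plus their ground truth."""

    exposure: list[SnpAssociation]
    mediator: list[SnpAssociation]
    outcome: list[SnpAssociation]
    truth: TruthLedger
    config: SimulationConfig


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, 1e-300)


def _records(
    ids: list[str],
    ea: list[str],
    oa: list[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[SnpAssociation]:
    pv = _pvals(beta, se)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # p/beta consistency holds by construction
        return [
            SnpAssociation(ids[i], ea[i], oa[i], float(eaf[i]), float(beta[i]), float(se[i]), float(pv[i]), n)
            for i in range(len(ids))
        ]


def simulate(config: SimulationConfig, noise: bool = True) -> SimulatedStudy:
    """Generate one synthetic study; deterministic under ``config.seed``.

    ``noise=False`` emits the true effects as observed betas (keeping the
    analytic SEs), which is useful for exact-identity checks.
    """
    if (
        config.gamma_sd == 0
        and config.alpha == 0
        and config.theta_m == 0
        and config.theta_dir == 0
        and config.pleiotropy_sd == 0
    ):
        warnings.warn("degenerate configuration: no effects and no variation", UserWarning, stacklevel=2)

    rng = np.random.default_rng(config.seed)
    jx, jm, jr = config.n_snps_exposure, config.n_snps_mediator, config.n_snps_reverse
    j = jx + jm + jr
    ids = [f"rs{i + 1:06d}" for i in range(j)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=j)
    eaf = np.where(rng.random(j) < 0.5, maf, 1.0 - maf)

    gamma = np.zeros(j)
    gamma[:jx] = rng.normal(0.0, config.gamma_sd, size=jx)
    m_own = np.zeros(j)
    m_own[jx : jx + jm] = rng.normal(0.0, config.gamma_sd, size=jm)
    omega = np.zeros(j)
    omega[jx + jm :] = rng.normal(0.0, config.gamma_sd, size=jr)

    delta = np.zeros(j)
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        z = rng.normal(0.0, 1.0, size=jx)
        if config.pleiotropy_gamma_corr != 0 and config.gamma_sd > 0:
            rho = config.pleiotropy_gamma_corr
            gstd = gamma[:jx] / config.gamma_sd
            z = rho * gstd + np.sqrt(1.0 - rho**2) * z
        # Directional pleiotropy is only meaningful relative to the
        # exposure-increasing allele (allele coding is arbitrary), so the
        # mean is applied in that orientation: a SNP whose coded allele
        # lowers the exposure carries the mirrored pleiotropic shift.
        orient = np.sign(gamma[:jx])
        delta[:jx] = orient * (config.pleiotropy_mean + config.pleiotropy_sd * z)

    beta_x = gamma.copy()
    beta_x[jx + jm :] = config.reverse_effect * omega[jx + jm :]
    beta_m = config.alpha * beta_x + m_own + delta
    beta_y = config.theta_dir * beta_x + config.theta_m * beta_m
    # Reverse-causal SNPs act on the outcome directly; their exposure and
    # mediator associations are induced downstream and carry no extra theta
    # paths back into the outcome.
    beta_y[jx + jm :] = omega[jx + jm :]

    cluster_labels = ["none"] * j
    start = 0
    for ci, (size, slope) in enumerate(config.planted_clusters, start=1):
        for i in range(start, start + size):
            beta_y[i] = slope * beta_x[i]
            cluster_labels[i] = f"cluster_{ci}"
        start += size

    var_factor = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_factor * config.n_exposure)
    se_m = 1.0 / np.sqrt(var_factor * config.n_mediator)
    if config.outcome_is_binary:
        cf = config.case_fraction
        se_y = 1.0 / np.sqrt(var_factor * config.n_outcome * cf * (1.0 - cf))
    else:
        se_y = 1.0 / np.sqrt(var_factor * config.n_outcome)

    if noise:
        obs_x = beta_x + rng.normal(0.0, 1.0, size=j) * se_x
        obs_m = beta_m + rng.normal(0.0, 1.0, size=j) * se_m
        obs_y = beta_y + rng.normal(0.0, 1.0, size=j) * se_y
    else:
        obs_x, obs_m, obs_y = beta_x.copy(), beta_m.copy(), beta_y.copy()

    truth = TruthLedger(
        snp_ids=ids,
        beta_exposure=beta_x,
        beta_mediator=beta_m,
        beta_outcome=beta_y,
        alpha=config.alpha,
        theta_m=config.theta_m,
        theta_dir=config.theta_dir,
        cluster_labels=cluster_labels,
        reverse_ids=ids[jx + jm :],
    )
    study = SimulatedStudy(
        exposure=_records(ids, ea, oa, eaf, obs_x, se_x, config.n_exposure),
        mediator=_records(ids, ea, oa, eaf, obs_m, se_m, config.n_mediator),
        outcome=_records(ids, ea, oa, eaf, obs_y, se_y, config.n_outcome),
        truth=truth,
        config=config,
    )
    for index, displacement in config.planted_outliers:
        study = plant_outlier(study, index, displacement)
    return study


def plant_outlier(study: SimulatedStudy, index: int, displacement: float) -> SimulatedStudy:
    """Shift one SNP's observed outcome beta by ``displacement`` outcome-SEs.

    Returns a new study with the ledger's outlier membership updated; a zero
    displacement leaves the records unchanged (but still marks nothing).
    """
    if not (0 <= index < len(study.outcome)):
        raise IndexError(f"SNP index {index} out of range for {len(study.outcome)} SNPs")
    if displacement == 0:
        return study
    rec = study.outcome[index]
    new_beta = rec.beta + displacement * rec.se
    new_p = float(max(2.0 * stats.norm.sf(abs(new_beta / rec.se)), 1e-300))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        shifted = dataclasses.replace(rec, beta=new_beta, pval=new_p)
    outcome = list(study.outcome)
    outcome[index] = shifted
    truth = dataclasses.replace(
        study.truth, outlier_ids=sorted(set(study.truth.outlier_ids) | {rec.snp_id})
    )
    return SimulatedStudy(
        exposure=study.exposure,
        mediator=study.mediator,
        outcome=outcome,
        truth=truth,
        config=study.config,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write exposure/mediator/outcome TSVs and ``truth.json``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "mediator": outdir / "mediator.tsv",
        "outcome": outdir / "outcome.tsv",
        "truth": outdir / "truth.json",
    }
    write_summary_stats(study.exposure, paths["exposure"])
    write_summary_stats(study.mediator, paths["mediator"])
    write_summary_stats(study.outcome, paths["outcome"])
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
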