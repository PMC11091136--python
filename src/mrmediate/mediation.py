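"""Mediation analysis: decomposing a total causal effect into direct and indirect parts.

Within the two-step MR framework, the exposure's total effect on the outcome
(univariable MR) splits into a direct effect (from MVMR of exposure and
mediator on the outcome) and an indirect, mediator-borne effect, estimated
two ways:

* Difference method — indirect = total - direct, with the
  propagation-of-errors SE sqrt(se_total² + se_direct²).
* Product method — indirect = (exposure→mediator) x (mediator→outcome
  direct), with the delta-method (Sobel) SE.

The proportion mediated is the product-method indirect effect divided by the
total effect, with a ratio delta-method CI. Covariances between the
constituent estimates (which share instruments/samples) are ignored, as in
the propagation-of-errors convention; this is a documented limitation.
For binary outcomes everything is combined on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .instruments import select_instruments
from .mr import MRModel, MRResults
from .mvmr import MVMRModel, MvmrResults
from .summary_io import SnpAssociation, harmonize

__all__ = [
    "Estimate",
    "MediationResult",
    "MediationMR",
    "indirect_difference",
    "indirect_product",
    "proportion_mediated",
    "mediate",
]

_Z95 = stats.norm.ppf(0.975)


class Estimate(NamedTuple):
    """A point estimate with its standard error."""

    est: float
    se: float


class IntervalEstimate(NamedTuple):
    est: float
    se: float
    ci_low: float
    ci_high: float


def indirect_difference(total: Estimate, direct: Estimate) -> IntervalEstimate:
    """Difference-method indirect effect: total - direct, propagation-of-errors SE."""
    if not (total.se > 0 and direct.se > 0):
        raise ValueError("standard errors must be positive")
    est = total.est - direct.est
    se = float(np.sqrt(total.se**2 + direct.se**2))
    return IntervalEstimate(est, se, est - _Z95 * se, est + _Z95 * se)


def indirect_product(step1: Estimate, step2: Estimate) -> IntervalEstimate:
    """Product-method indirect effect: step1 x step2, delta-method (Sobel) SE."""
    if not (step1.se > 0 and step2.se > 0):
        raise ValueError("standard errors must be positive")
    est = step1.est * step2.est
    se = float(np.sqrt(step1.est**2 * step2.se**2 + step2.est**2 * step1.se**2))
    return IntervalEstimate(est, se, est - _Z95 * se, est + _Z95 * se)


def proportion_mediated(indirect: Estimate, total: Estimate) -> tuple[float, tuple[float, float], bool]:
    """Proportion mediated = indirect/total with a ratio delta-method CI.

    Returns (estimate, (ci_low, ci_high), outside_unit_interval_flag). The
    delta SE is |PM|·sqrt(se_i²/i² + se_t²/t²), with the covariance term
    taken as zero.
    """
    if total.est == 0:
        raise ZeroDivisionError("proportion mediated undefined for a zero total effect")
    est = indirect.est / total.est
    if indirect.est == 0:
        se = abs(indirect.se / total.est)
    else:
        se = abs(est) * float(
            np.sqrt(indirect.se**2 / indirect.est**2 + total.se**2 / total.est**2)
        )
    ci = (est - _Z95 * se, est + _Z95 * se)
    return est, ci, not (0.0 <= est <= 1.0)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with both indirect estimators.

    All effects share the outcome scale (log-odds for a binary outcome). The
    identities ``indirect_difference.est == total.est - direct.est`` and
    ``indirect_product.est == step1.est * step2.est`` hold exactly.
    """

    total: Estimate
    direct: Estimate
    step1: Estimate  # exposure -> mediator (univariable MR)
    step2: Estimate  # mediator -> outcome direct effect (MVMR)
    indirect_difference: IntervalEstimate
    indirect_product: IntervalEstimate
    proportion_mediated: float
    proportion_mediated_ci: tuple[float, float]
    pm_outside_unit: bool
    total_mr: MRResults | None = None
    step1_mr: MRResults | None = None
    mvmr: MvmrResults | None = None

    def to_dict(self) -> dict:
        return {
            "total": self.total._asdict(),
            "direct": self.direct._asdict(),
            "step1": self.step1._asdict(),
            "step2": self.step2._asdict(),
            "indirect_difference": self.indirect_difference._asdict(),
            "indirect_product": self.indirect_product._asdict(),
            "proportion_mediated": self.proportion_mediated,
            "proportion_mediated_ci": list(self.proportion_mediated_ci),
            "pm_outside_unit": self.pm_outside_unit,
        }

    def summary(self) -> str:
        def row(name: str, est: float, se: float) -> str:
            return f"{name:<28}{est:>10.4f}{se:>10.4f}"

        lines = [
            f"{'effect':<28}{'estimate':>10}{'se':>10}",
            row("total (exposure->outcome)", *self.total),
            row("direct (MVMR)", *self.direct),
            row("exposure->mediator", *self.step1),
            row("mediator->outcome (MVMR)", *self.step2),
            row("indirect (difference)", self.indirect_difference.est, self.indirect_difference.se),
            row("indirect (product)", self.indirect_product.est, self.indirect_product.se),
            f"{'proportion mediated':<28}{self.proportion_mediated:>10.3f}"
            f"   [{self.proportion_mediated_ci[0]:.3f}, {self.proportion_mediated_ci[1]:.3f}]",
        ]
        width = max(len(s) for s in lines)
        rule = "=" * width
        return "\n".join([rule, "MR mediation analysis", rule, *lines, rule])


class MediationMR:
    """Two-step MR mediation model over three summary-statistics collections.

    Parameters
    ----------
    exposure, mediator, outcome : full summary-statistics collections
        (not pre-filtered); instruments are selected at ``pval_threshold``.
    outcome_is_binary : combine effects on the log-odds scale when True.
    conditional_step1 : use the MVMR-conditional exposure→mediator estimate
        for the product method instead of the univariable two-step
        convention (off by default).
    """

    def __init__(
        self,
        exposure: Sequence[SnpAssociation],
        mediator: Sequence[SnpAssociation],
        outcome: Sequence[SnpAssociation],
        outcome_is_binary: bool = True,
        pval_threshold: float = 5e-8,
        palindromic_eaf_window: float = 0.08,
        conditional_step1: bool = False,
    ):
        self.exposure = list(exposure)
        self.mediator = list(mediator)
        self.outcome = list(outcome)
        self.outcome_is_binary = outcome_is_binary
        self.pval_threshold = pval_threshold
        self.palindromic_eaf_window = palindromic_eaf_window
        self.conditional_step1 = conditional_step1

    def fit(self, seed: int = 0) -> MediationResult:
        exp_inst = select_instruments(self.exposure, self.pval_threshold)
        med_inst = select_instruments(self.mediator, self.pval_threshold)

        # Total effect: exposure -> outcome, univariable IVW (MRE).
        h_total = harmonize(
            exp_inst, self.outcome,
            palindromic_eaf_window=self.palindromic_eaf_window,
            outcome_is_binary=self.outcome_is_binary,
        )
        total_mr = MRModel(h_total).fit("ivw")

        # Step 1: exposure -> mediator, univariable IVW.
        h_step1 = harmonize(
            exp_inst, self.mediator,
            palindromic_eaf_window=self.palindromic_eaf_window,
            outcome_is_binary=False,
        )
        step1_mr = MRModel(h_step1).fit("ivw")

        # MVMR of exposure + mediator on the outcome over the union of
        # instruments; exposure/mediator betas for all union SNPs come from
        # the full per-trait tables.
        union_ids = {r.snp_id for r in exp_inst} | {r.snp_id for r in med_inst}
        exp_union = [r for r in self.exposure if r.snp_id in union_ids]
        med_union = [r for r in self.mediator if r.snp_id in union_ids]
        h_mvmr = harmonize(
            [exp_union, med_union], self.outcome,
            palindromic_eaf_window=self.palindromic_eaf_window,
            outcome_is_binary=self.outcome_is_binary,
            exposure_names=["exposure", "mediator"],
        )
        mvmr_res = MVMRModel(h_mvmr).fit()

        total = Estimate(total_mr.theta, total_mr.se)
        direct = Estimate(float(mvmr_res.thetas[0]), float(mvmr_res.ses[0]))
        step2 = Estimate(float(mvmr_res.thetas[1]), float(mvmr_res.ses[1]))
        if self.conditional_step1:
            # Alternative behind a flag: evaluate the exposure->mediator
            # effect on exactly the instruments entering the joint (MVMR)
            # design, rather than on the full exposure-instrument set.
            exp_ids = {r.snp_id for r in exp_inst}
            joint_ids = [s for s in h_mvmr.snp_ids if s in exp_ids]
            step1_cond = MRModel(h_step1.subset(joint_ids)).fit("ivw")
            step1 = Estimate(step1_cond.theta, step1_cond.se)
        else:
            step1 = Estimate(step1_mr.theta, step1_mr.se)

        diff = indirect_difference(total, direct)
        prod = indirect_product(step1, step2)
        pm, pm_ci, outside = proportion_mediated(Estimate(prod.est, prod.se), total)
        return MediationResult(
            total=total,
            direct=direct,
            step1=step1,
            step2=step2,
            indirect_difference=diff,
            indirect_product=prod,
            proportion_mediated=pm,
            proportion_mediated_ci=pm_ci,
            pm_outside_unit=outside,
            total_mr=total_mr,
            step1_mr=step1_mr,
            mvmr=mvmr_res,
        )


def mediate(
    exposure: Sequence[SnpAssociation],
    mediator: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    outcome_is_binary: bool = True,
    pval_threshold: float = 5e-8,
    seed: int = 0,
) -> MediationResult:
    """Functional wrapper around :class:`MediationMR`."""
    return MediationMR(
        exposure, mediator, outcome,
        outcome_is_binary=outcome_is_binary,
        pval_threshold=pval_threshold,
    ).fit(seed=seed)
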