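"""Selection, LD pruning and direction filtering of genetic instruments.

Instruments are variants robustly associated with the exposure
(p < 5e-8 genome-wide threshold by default), pruned so that no retained pair
is in linkage disequilibrium above ``clump_r2`` under a user-supplied LD
matrix, and optionally filtered by the Steiger criterion (a variant must
explain more variance in the exposure than in the outcome, guarding against
reverse causation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_io import HarmonizedSet, SnpAssociation

__all__ = [
    "InstrumentSet",
    "NoInstrumentsError",
    "LdMatrixError",
    "select_instruments",
    "clump",
    "variance_explained",
    "steiger_filter",
    "apply_proxies",
]


class NoInstrumentsError(ValueError):
    """No variant passed the instrument-selection threshold."""


class LdMatrixError(KeyError):
    """A candidate SNP is missing from the supplied LD matrix."""


@dataclass
class InstrumentSet:
    """Selected instruments with their selection audit trail."""

    harmonized: HarmonizedSet
    selection_log: pd.DataFrame
    pval_threshold: float
    clump_r2: float = field(default=0.001)


def select_instruments(
    exposure: Sequence[SnpAssociation],
    pval_threshold: float = 5e-8,
    allow_empty: bool = False,
) -> list[SnpAssociation]:
    """Retain exactly the variants with exposure p-value strictly below threshold."""
    if not exposure:
        raise NoInstrumentsError("empty input collection")
    kept = [r for r in exposure if r.pval < pval_threshold]
    if not kept and not allow_empty:
        raise NoInstrumentsError(
            f"no variant passes p < {pval_threshold:g} (min observed p = "
            f"{min(r.pval for r in exposure):.3g})"
        )
    return kept


def clump(
    candidates: Sequence[SnpAssociation],
    ld: pd.DataFrame,
    clump_r2: float = 0.001,
) -> list[SnpAssociation]:
    """Greedy LD pruning: keep the most significant variant per correlated group.

    Candidates are visited in order of ascending p-value (ties broken by
    lexicographic SNP id, for determinism) and accepted iff their r² with
    every already-accepted variant is at most ``clump_r2``. ``ld`` is a square
    DataFrame of r² values indexed by SNP id with unit diagonal.
    """
    for rec in candidates:
        if rec.snp_id not in ld.index or rec.snp_id not in ld.columns:
            raise LdMatrixError(f"SNP {rec.snp_id!r} missing from LD matrix")
    ordered = sorted(candidates, key=lambda r: (r.pval, r.snp_id))
    accepted: list[SnpAssociation] = []
    for rec in ordered:
        if all(float(ld.loc[rec.snp_id, a.snp_id]) <= clump_r2 for a in accepted):
            accepted.append(rec)
    return accepted


def variance_explained(assoc: SnpAssociation, trait_is_binary: bool = False) -> float:
    """Per-variant R² from the t-statistic: R² = t²/(t² + n - 2).

    For binary traits the same formula is applied on the log-odds scale,
    which is an approximation (it treats the logistic score like a linear
    one); callers that care should carry the ``trait_is_binary`` flag forward.
    """
    if assoc.n < 3:
        raise ValueError("variance_explained needs n >= 3")
    t2 = (assoc.beta / assoc.se) ** 2
    return t2 / (t2 + assoc.n - 2)


def _r2_from_arrays(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(h: HarmonizedSet) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Flag and remove instruments that explain more outcome than exposure variance.

    Uses point R² on each side (no uncertainty test): a SNP is
    "correct-direction" iff R²_exposure > R²_outcome. Returns the filtered
    set and a per-SNP flag table with both R² values.
    """
    if h.n_exposures != 1:
        raise ValueError("steiger_filter expects a single-exposure HarmonizedSet")
    r2_exp = _r2_from_arrays(h.bx, h.bx_se, h.exposure_ns[:, 0])
    r2_out = _r2_from_arrays(h.by, h.by_se, h.outcome_ns)
    correct = r2_exp > r2_out
    flags = pd.DataFrame(
        {
            "snp": h.snp_ids,
            "r2_exposure": r2_exp,
            "r2_outcome": r2_out,
            "correct_direction": correct,
        }
    )
    return h.subset(correct), flags


def apply_proxies(
    wanted_ids: Sequence[str],
    available_ids: Sequence[str],
    proxy_table: pd.DataFrame | None = None,
    min_r2: float = 0.8,
) -> dict[str, str]:
    """Resolve missing SNPs to proxies from a user-supplied table.

    ``proxy_table`` has columns ``snp``, ``proxy``, ``r2``. For each wanted
    SNP absent from ``available_ids``, the highest-r² proxy with
    r² >= ``min_r2`` that *is* available is substituted. Returns a mapping
    wanted-id -> resolved-id (identity for SNPs already available); SNPs with
    no usable proxy are omitted. This is a policy hook: no remote LD lookup
    is performed.
    """
    available = set(available_ids)
    resolved: dict[str, str] = {}
    for sid in wanted_ids:
        if sid in available:
            resolved[sid] = sid
            continue
        if proxy_table is None:
            continue
        cand = proxy_table[(proxy_table["snp"] == sid) & (proxy_table["r2"] >= min_r2)]
        cand = cand[cand["proxy"].isin(available)].sort_values(["r2", "proxy"], ascending=[False, True])
        if len(cand):
            resolved[sid] = str(cand.iloc[0]["proxy"])
    return resolved
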