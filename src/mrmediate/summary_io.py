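"""Reading, writing, validation and harmonization of GWAS summary statistics.

Summary-statistics tables are tab-separated with the canonical header
``snp, effect_allele, other_allele, eaf, beta, se, pval, n``. Betas are per
effect-allele copies, on the standard-deviation scale for continuous traits
and on the log-odds scale for binary (case/control) outcomes. Missing
effect-allele frequencies are serialized as the sentinel ``NA``.

Harmonization aligns one or more exposure collections and one outcome
collection to a common effect allele (the first exposure's coding), flipping
betas and reflecting frequencies where codings are swapped or on the
opposite strand, and dropping palindromic (A/T, C/G) variants whose
frequency is too close to 0.5 to resolve the strand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpAssociation",
    "HarmonizedSet",
    "SummaryStatsFormatError",
    "EmptyInputError",
    "HarmonizationError",
    "CANONICAL_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
]

CANONICAL_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


class SummaryStatsFormatError(ValueError):
    """A summary-statistics file does not conform to the expected format."""


class EmptyInputError(ValueError):
    """A summary-statistics file contains no data rows."""


class HarmonizationError(ValueError):
    """No SNP survived harmonization; carries per-SNP drop reasons."""

    def __init__(self, message: str, drop_reasons: Mapping[str, str] | None = None):
        super().__init__(message)
        self.drop_reasons = dict(drop_reasons or {})


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary association with one trait.

    Parameters
    ----------
    snp_id : variant identifier (e.g. an rsID).
    effect_allele, other_allele : single-base alleles, A/C/G/T, distinct.
    eaf : effect-allele frequency in [0, 1], or None when unavailable.
    beta : per-allele effect (trait SD units, or log-odds for binary traits).
    se : standard error of ``beta``; strictly positive.
    pval : association p-value in (0, 1].
    n : sample size; positive integer.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele must differ")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.snp_id}: se must be positive and finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf must lie in [0, 1]")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval must lie in (0, 1]")
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValueError(f"{self.snp_id}: n must be a positive integer")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        # Consistency check: p should match the two-sided normal p implied by
        # beta/se within a factor of 2; warn rather than fail, since published
        # tables round aggressively.
        implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if implied > 0 and self.pval > 1e-290:
            ratio = self.pval / implied if implied > 0 else math.inf
            if ratio > 2.0 or ratio < 0.5:
                warnings.warn(
                    f"{self.snp_id}: reported p={self.pval:.3g} inconsistent with "
                    f"|beta/se| (implies {implied:.3g})",
                    UserWarning,
                    stacklevel=2,
                )

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in _PALINDROMIC_PAIRS

    def flipped(self) -> "SnpAssociation":
        """Return the same association coded for the opposite allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )


def _coerce_row(row: Mapping[str, object]) -> SnpAssociation:
    eaf_raw = row["eaf"]
    if eaf_raw is None or (isinstance(eaf_raw, float) and math.isnan(eaf_raw)) or str(eaf_raw).upper() in ("NA", "NAN", ""):
        eaf = None
    else:
        eaf = float(eaf_raw)  # type: ignore[arg-type]
    return SnpAssociation(
        snp_id=str(row["snp"]),
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        eaf=eaf,
        beta=float(row["beta"]),  # type: ignore[arg-type]
        se=float(row["se"]),  # type: ignore[arg-type]
        pval=float(row["pval"]),  # type: ignore[arg-type]
        n=int(float(row["n"])),  # type: ignore[arg-type]
    )


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SnpAssociation], int]:
    """Read a tab-separated summary-statistics table.

    ``column_map`` maps canonical column names to the names used in the file
    (e.g. ``{"snp": "rsid", "pval": "p"}``). Rows that fail type coercion or
    violate the per-record invariants are dropped and counted.

    Returns
    -------
    (records, n_dropped)
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    records: list[SnpAssociation] = []
    n_dropped = 0
    for row in df.to_dict("records"):
        try:
            records.append(_coerce_row(row))
        except (ValueError, TypeError):
            n_dropped += 1
    return records, n_dropped


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    return f"{x:.12g}"


def write_summary_stats(records: Sequence[SnpAssociation], path) -> None:
    """Write records as a canonical tab-separated table (12 significant digits)."""
    if not records:
        raise ValueError("cannot write an empty collection of records")
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        str(r.n),
                    ]
                )
                + "\n"
            )


@dataclass
class HarmonizedSet:
    """Exposure and outcome associations aligned to a common effect allele.

    ``exposure_betas``/``exposure_ses``/``exposure_ns`` are (J, K) arrays over
    J instruments and K exposures; outcome arrays have length J. ``provenance``
    records one action (kept / flipped / dropped-with-reason) per SNP per
    collection.
    """

    snp_ids: np.ndarray
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    exposure_ns: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    outcome_ns: np.ndarray
    outcome_is_binary: bool
    exposure_names: list[str]
    provenance: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, dtype=float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, dtype=float))
        self.exposure_ns = np.atleast_2d(np.asarray(self.exposure_ns, dtype=float))
        self.outcome_betas = np.asarray(self.outcome_betas, dtype=float)
        self.outcome_ses = np.asarray(self.outcome_ses, dtype=float)
        self.outcome_ns = np.asarray(self.outcome_ns, dtype=float)
        j = len(self.snp_ids)
        for arr in (self.exposure_betas, self.exposure_ses, self.exposure_ns):
            if arr.shape[0] != j:
                raise ValueError("exposure matrices must have one row per SNP")
        for arr in (self.outcome_betas, self.outcome_ses, self.outcome_ns):
            if arr.shape != (j,):
                raise ValueError("outcome vectors must have one entry per SNP")
        if np.any(~np.isfinite(self.exposure_betas)) or np.any(~np.isfinite(self.outcome_betas)):
            raise ValueError("harmonized sets may not contain missing values")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]

    @property
    def bx(self) -> np.ndarray:
        """First (or only) exposure's betas."""
        return self.exposure_betas[:, 0]

    @property
    def bx_se(self) -> np.ndarray:
        return self.exposure_ses[:, 0]

    @property
    def by(self) -> np.ndarray:
        return self.outcome_betas

    @property
    def by_se(self) -> np.ndarray:
        return self.outcome_ses

    def subset(self, mask_or_ids) -> "HarmonizedSet":
        """Restrict to a boolean mask or an iterable of SNP ids (order preserved)."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            mask = mask_or_ids
        else:
            wanted = set(mask_or_ids)
            mask = np.array([s in wanted for s in self.snp_ids], dtype=bool)
        return HarmonizedSet(
            snp_ids=self.snp_ids[mask],
            exposure_betas=self.exposure_betas[mask],
            exposure_ses=self.exposure_ses[mask],
            exposure_ns=self.exposure_ns[mask],
            outcome_betas=self.outcome_betas[mask],
            outcome_ses=self.outcome_ses[mask],
            outcome_ns=self.outcome_ns[mask],
            outcome_is_binary=self.outcome_is_binary,
            exposure_names=list(self.exposure_names),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"snp": self.snp_ids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.exposure_betas[:, k]
            data[f"se_{name}"] = self.exposure_ses[:, k]
        data["beta_outcome"] = self.outcome_betas
        data["se_outcome"] = self.outcome_ses
        return pd.DataFrame(data)


def _align_to_reference(
    rec: SnpAssociation,
    ref: SnpAssociation,
    window: float,
) -> tuple[SnpAssociation | None, str, str]:
    """Align ``rec`` to ``ref``'s allele coding.

    Returns (aligned record or None, action, reason).
    """
    ra, ro = ref.effect_allele, ref.other_allele
    ea, oa = rec.effect_allele, rec.other_allele

    if rec.is_palindromic or ref.is_palindromic:
        if {ea, oa} != {ra, ro}:
            return None, "dropped", "allele-mismatch"
        if rec.eaf is None or ref.eaf is None:
            return None, "dropped", "palindromic-missing-eaf"
        if abs(rec.eaf - 0.5) <= window or abs(ref.eaf - 0.5) <= window:
            return None, "dropped", "palindromic-ambiguous"
        # Nominal orientation from allele letters, then resolve strand by
        # requiring frequency concordance with the reference.
        aligned = rec if ea == ra else rec.flipped()
        if (aligned.eaf < 0.5) != (ref.eaf < 0.5):  # type: ignore[operator]
            aligned = aligned.flipped()
            action = "flipped" if ea == ra else "kept"
        else:
            action = "kept" if ea == ra else "flipped"
        return aligned, action, ""

    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (ea, oa) == (ra, ro) or (cea, coa) == (ra, ro):
        return rec, "kept", ""
    if (ea, oa) == (ro, ra) or (cea, coa) == (ro, ra):
        return rec.flipped(), "flipped", ""
    return None, "dropped", "allele-mismatch"


def harmonize(
    exposures: Sequence[SnpAssociation] | Sequence[Sequence[SnpAssociation]],
    outcome: Sequence[SnpAssociation],
    palindromic_eaf_window: float = 0.08,
    outcome_is_binary: bool = False,
    exposure_names: Sequence[str] | None = None,
) -> HarmonizedSet:
    """Align exposure(s) and outcome to the first exposure's effect allele.

    ``exposures`` may be a single association collection or a list of
    collections (for multivariable analyses). SNPs absent from any collection
    are dropped; palindromic SNPs with EAF within ``palindromic_eaf_window``
    of 0.5 in any sample are dropped as strand-ambiguous. Output rows are
    sorted by SNP id so downstream estimates are order-invariant.
    """
    if exposures and isinstance(exposures[0], SnpAssociation):
        exposure_lists: list[Sequence[SnpAssociation]] = [exposures]  # type: ignore[list-item]
    else:
        exposure_lists = list(exposures)  # type: ignore[arg-type]
    if not exposure_lists or not outcome:
        raise HarmonizationError("need at least one exposure and one outcome collection")
    k = len(exposure_lists)
    if exposure_names is None:
        exposure_names = [f"exposure_{i + 1}" for i in range(k)] if k > 1 else ["exposure"]
    exposure_names = list(exposure_names)

    maps = [{r.snp_id: r for r in coll} for coll in exposure_lists]
    outcome_map = {r.snp_id: r for r in outcome}
    all_ids = set(maps[0])
    shared = sorted(set.intersection(*[set(m) for m in maps], set(outcome_map)))

    prov_rows: list[dict] = []
    drop_reasons: dict[str, str] = {}
    for sid in sorted(all_ids - set(shared)):
        prov_rows.append({"snp": sid, "collection": "any", "action": "dropped", "reason": "absent-in-some-collection"})
        drop_reasons[sid] = "absent-in-some-collection"
    if not shared:
        raise HarmonizationError("no SNP shared across all collections", drop_reasons)

    rows: list[tuple[str, list[SnpAssociation], SnpAssociation]] = []
    for sid in shared:
        ref = maps[0][sid]
        aligned_exp: list[SnpAssociation] = []
        ok = True
        for ci, m in enumerate(maps):
            rec = m[sid]
            if ci == 0:
                # Reference exposure; a palindromic reference too close to 0.5
                # is ambiguous for everyone.
                if ref.is_palindromic and (
                    ref.eaf is None or abs(ref.eaf - 0.5) <= palindromic_eaf_window
                ):
                    reason = "palindromic-missing-eaf" if ref.eaf is None else "palindromic-ambiguous"
                    prov_rows.append({"snp": sid, "collection": exposure_names[0], "action": "dropped", "reason": reason})
                    drop_reasons[sid] = reason
                    ok = False
                    break
                aligned_exp.append(rec)
                prov_rows.append({"snp": sid, "collection": exposure_names[0], "action": "kept", "reason": ""})
                continue
            aligned, action, reason = _align_to_reference(rec, ref, palindromic_eaf_window)
            prov_rows.append({"snp": sid, "collection": exposure_names[ci], "action": action, "reason": reason})
            if aligned is None:
                drop_reasons[sid] = reason
                ok = False
                break
            aligned_exp.append(aligned)
        if not ok:
            continue
        aligned_out, action, reason = _align_to_reference(outcome_map[sid], ref, palindromic_eaf_window)
        prov_rows.append({"snp": sid, "collection": "outcome", "action": action, "reason": reason})
        if aligned_out is None:
            drop_reasons[sid] = reason
            continue
        rows.append((sid, aligned_exp, aligned_out))

    if not rows:
        raise HarmonizationError(
            "no SNP survived harmonization: " + "; ".join(f"{s}={r}" for s, r in sorted(drop_reasons.items())),
            drop_reasons,
        )

    j = len(rows)
    exposure_betas = np.empty((j, k))
    exposure_ses = np.empty((j, k))
    exposure_ns = np.empty((j, k))
    outcome_betas = np.empty(j)
    outcome_ses = np.empty(j)
    outcome_ns = np.empty(j)
    snp_ids = np.empty(j, dtype=object)
    for i, (sid, exps, out) in enumerate(rows):
        snp_ids[i] = sid
        for ci, rec in enumerate(exps):
            exposure_betas[i, ci] = rec.beta
            exposure_ses[i, ci] = rec.se
            exposure_ns[i, ci] = rec.n
        outcome_betas[i] = out.beta
        outcome_ses[i] = out.se
        outcome_ns[i] = out.n

    return HarmonizedSet(
        snp_ids=snp_ids,
        exposure_betas=exposure_betas,
        exposure_ses=exposure_ses,
        exposure_ns=exposure_ns,
        outcome_betas=outcome_betas,
        outcome_ses=outcome_ses,
        outcome_ns=outcome_ns,
        outcome_is_binary=outcome_is_binary,
        exposure_names=exposure_names,
        provenance=pd.DataFrame(prov_rows, columns=["snp", "collection", "action", "reason"]),
    )
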