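"""End-to-end pipeline: instruments → harmonization → MR → MVMR → outliers →
clustering → mediation, driven by a YAML config, with tidy per-stage outputs.

Every stage writes a TSV (or JSON) under the configured output directory, a
single ``summary.json`` collects the headline numbers, and ``pipeline.log``
records the fully resolved configuration, package versions and seed so any
number in the summary can be reproduced by calling the corresponding module
operation directly.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_ratios, per_cluster_ivw
from .instruments import clump, select_instruments, steiger_filter
from .mediation import MediationMR
from .mr import MRModel, mean_f_statistic, per_snp_ratios
from .mvmr import MVMRModel
from .outliers import presso, radial_ivw
from .summary_io import harmonize, read_summary_stats

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    exposure: str
    outcome: str
    outdir: str
    mediator: str | None = None
    ld_matrix: str | None = None
    outcome_is_binary: bool = True
    pval_threshold: float = 5e-8
    clump_r2: float = 0.001
    palindromic_eaf_window: float = 0.08
    prob_threshold: float = 0.9
    outlier_alpha: float = 0.05
    nsim: int = 1000
    k_max: int = 10
    n_boot: int = 1000
    seed: int = 1
    column_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        roles = [cfg.exposure, cfg.outcome] + ([cfg.mediator] if cfg.mediator else [])
        if len(set(roles)) != len(roles):
            raise ValueError("exposure/mediator/outcome roles must point at distinct files")
        for p in roles:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.generic):
        return _round_floats(obj.item(), ndigits)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every applicable stage and return the summary bundle.

    Stage failures raise :class:`PipelineStageError`; outputs of completed
    stages are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"mrmediate {__version__} (python {sys.version.split()[0]}, numpy {np.__version__})",
        "resolved config:",
    ]
    for f in dataclasses.fields(config):
        log_lines.append(f"  {f.name}: {getattr(config, f.name)}")
    summary: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def _write_log() -> None:
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            log_lines.append(f"stage {name}: FAILED ({exc})")
            _write_log()
            raise PipelineStageError(name, exc) from exc
        log_lines.append(f"stage {name}: ok")
        summary["stages"][name] = result
        return result

    exposure, exp_dropped = read_summary_stats(config.exposure, config.column_map or None)
    outcome, out_dropped = read_summary_stats(config.outcome, config.column_map or None)
    mediator = None
    if config.mediator:
        mediator, _ = read_summary_stats(config.mediator, config.column_map or None)
    ld = None
    if config.ld_matrix:
        ld = pd.read_csv(config.ld_matrix, sep="\t", index_col=0)

    def _instruments():
        selected = select_instruments(exposure, config.pval_threshold)
        if ld is not None:
            selected = clump(selected, ld, config.clump_r2)
        pd.DataFrame(
            {"snp": [r.snp_id for r in selected], "pval": [r.pval for r in selected]}
        ).to_csv(outdir / "instruments.tsv", sep="\t", index=False)
        return {"n_candidates": len(exposure), "n_selected": len(selected),
                "rows_dropped_on_read": exp_dropped + out_dropped,
                "_records": selected}

    inst = run_stage("instruments", _instruments).pop("_records")

    def _harmonization():
        hset = harmonize(
            inst, outcome,
            palindromic_eaf_window=config.palindromic_eaf_window,
            outcome_is_binary=config.outcome_is_binary,
        )
        hset.to_frame().to_csv(outdir / "harmonized.tsv", sep="\t", index=False)
        hset.provenance.to_csv(outdir / "harmonization_provenance.tsv", sep="\t", index=False)
        filtered, flags = steiger_filter(hset)
        flags.to_csv(outdir / "steiger.tsv", sep="\t", index=False)
        return {"n_snps": hset.n_snps,
                "n_steiger_removed": int((~flags["correct_direction"]).sum()),
                "_harmonized": filtered}

    h = run_stage("harmonization", _harmonization).pop("_harmonized")

    def _mr():
        model = MRModel(h)
        results = model.fit_all(seed=config.seed, n_boot=config.n_boot)
        rows = [r.to_dict() for r in results]
        pd.DataFrame(rows).to_csv(outdir / "mr_results.tsv", sep="\t", index=False)
        ratios = per_snp_ratios(h)
        pd.DataFrame(
            {"snp": ratios.snp_ids, "ratio": ratios.ratio, "ratio_se": ratios.ratio_se, "weight": ratios.weight}
        ).to_csv(outdir / "forest_plot_data.tsv", sep="\t", index=False)
        return {
            "mean_f": mean_f_statistic(h),
            "estimates": {r["method"]: r for r in rows},
        }

    run_stage("mr", _mr)

    if mediator is not None:
        def _mvmr():
            med_inst = select_instruments(mediator, config.pval_threshold)
            union_ids = {r.snp_id for r in inst} | {r.snp_id for r in med_inst}
            exp_union = [r for r in exposure if r.snp_id in union_ids]
            med_union = [r for r in mediator if r.snp_id in union_ids]
            hm = harmonize(
                [exp_union, med_union], outcome,
                palindromic_eaf_window=config.palindromic_eaf_window,
                outcome_is_binary=config.outcome_is_binary,
                exposure_names=["exposure", "mediator"],
            )
            res = MVMRModel(hm).fit()
            pd.DataFrame(
                {
                    "exposure": res.exposure_names,
                    "theta": res.thetas,
                    "se": res.ses,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "pval": res.pvals,
                    "conditional_f": res.conditional_f,
                }
            ).to_csv(outdir / "mvmr_results.tsv", sep="\t", index=False)
            return res.to_dict()

        run_stage("mvmr", _mvmr)
    else:
        log_lines.append("stage mvmr: skipped (no mediator configured)")

    def _outliers():
        out: dict = {}
        if h.n_snps >= 4:
            rep = presso(h, nsim=config.nsim, seed=config.seed, outlier_alpha=config.outlier_alpha)
            pd.DataFrame({"snp": rep.snp_ids, "p_adj": rep.per_snp}).to_csv(
                outdir / "presso_per_snp.tsv", sep="\t", index=False
            )
            out["presso"] = {
                "global_pval": rep.global_pval,
                "outliers": rep.outlier_ids,
                "distortion_pval": rep.distortion_pval,
                "corrected": rep.corrected.to_dict(),
            }
        rep_r = radial_ivw(h)
        pd.DataFrame({"snp": rep_r.snp_ids, "q_j": rep_r.per_snp}).to_csv(
            outdir / "radial_per_snp.tsv", sep="\t", index=False
        )
        out["radial"] = {
            "global_stat": rep_r.global_stat,
            "global_pval": rep_r.global_pval,
            "outliers": rep_r.outlier_ids,
            "corrected": rep_r.corrected.to_dict(),
        }
        return out

    run_stage("outliers", _outliers)

    def _clustering():
        ratios = per_snp_ratios(h)
        sol = cluster_ratios(ratios, k_max=config.k_max, prob_threshold=config.prob_threshold, seed=config.seed)
        pd.DataFrame(
            {
                "snp": sol.snp_ids,
                "ratio": ratios.ratio,
                "ratio_se": ratios.ratio_se,
                "cluster": sol.cluster_assignments,
                "inclusion_prob": sol.inclusion_probs,
            }
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        cluster_estimates = {lab: r.to_dict() for lab, r in per_cluster_ivw(h, sol).items()}
        return {
            "k_best": sol.k_best,
            "cluster_means": sol.cluster_means.tolist(),
            "bic_trace": {str(k): v for k, v in sol.bic_trace.items()},
            "per_cluster_ivw": cluster_estimates,
        }

    run_stage("clustering", _clustering)

    if mediator is not None:
        def _mediation():
            model = MediationMR(
                exposure, mediator, outcome,
                outcome_is_binary=config.outcome_is_binary,
                pval_threshold=config.pval_threshold,
                palindromic_eaf_window=config.palindromic_eaf_window,
            )
            res = model.fit(seed=config.seed)
            _dump_json(res.to_dict(), outdir / "mediation.json")
            return res.to_dict()

        run_stage("mediation", _mediation)
    else:
        log_lines.append("stage mediation: skipped (no mediator configured)")

    _dump_json(summary, outdir / "summary.json")
    _write_log()
    return summary
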