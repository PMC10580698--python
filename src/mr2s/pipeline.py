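"""Full-study orchestration: per-stage MR across exposures, then meta-analysis.

A pipeline run mirrors a two-stage MR study design: for each stage
(discovery, replication) and each exposure, instruments are selected,
harmonized against the outcome, and run through IVW, MR-Egger, weighted
median, RAPS and MR-PRESSO with both Cochran Q flavors; the primary
significance decision compares the IVW p-value with the Bonferroni
threshold alpha/m for m exposures. With two or more stages the per-exposure
IVW log-ORs are pooled by DerSimonian–Laird random effects.

Every seed is derived from the master seed and the (stage, exposure)
labels, so reruns are byte-identical; the instrument accounting (selected =
analyzed + excluded by reason) is preserved in the report and logs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import estimators, presso
from .errors import ConfigurationError, MRError
from .harmonize import DEFAULT_AF_BAND, harmonize_tables
from .instruments import LdMatrix, SelectionParams, build_instrument_set
from .io import read_summary_stats
from .meta import MetaResult, StageEstimate, dl_pool, meta_report


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Multiple-testing threshold alpha/m (full precision; round for display)."""
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return alpha / m


@dataclass
class StageSpec:
    """Input files for one stage: one outcome, one or more exposures."""

    outcome: str
    exposures: dict[str, str]
    ld: Optional[str] = None


@dataclass
class PipelineConfig:
    stages: dict[str, StageSpec]
    selection: SelectionParams = field(default_factory=SelectionParams)
    af_band: tuple[float, float] = DEFAULT_AF_BAND
    n_exposures: int = 3
    alpha: float = 0.05
    presso_nsim: int = 1000
    wm_boot: int = 1000
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        if not self.stages:
            raise ConfigurationError("at least one stage is required")
        if self.n_exposures < 1:
            raise ConfigurationError("n_exposures must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stages = {
            label: StageSpec(
                outcome=spec["outcome"],
                exposures=dict(spec["exposures"]),
                ld=spec.get("ld"),
            )
            for label, spec in raw["stages"].items()
        }
        sel = SelectionParams(**raw.get("selection", {}))
        return cls(
            stages=stages,
            selection=sel,
            af_band=tuple(raw.get("af_band", DEFAULT_AF_BAND)),
            n_exposures=raw.get("n_exposures", 3),
            alpha=raw.get("alpha", 0.05),
            presso_nsim=raw.get("presso_nsim", 1000),
            wm_boot=raw.get("wm_boot", 1000),
            seed=raw.get("seed", 0),
            output_dir=raw.get("output_dir"),
        )


def _derive_seed(master: int, *labels: str) -> int:
    digest = hashlib.sha256(("/".join(map(str, labels))).encode()).digest()
    return (master + int.from_bytes(digest[:4], "big")) % (2**31)


def run_stage(config: PipelineConfig, stage_label: str) -> dict[str, dict]:
    """Run every exposure of one stage; failures are isolated per exposure."""
    spec = config.stages[stage_label]
    outcome = read_summary_stats(spec.outcome, trait="outcome")
    ld = LdMatrix.from_tsv(spec.ld) if spec.ld else None
    threshold = bonferroni_threshold(config.n_exposures, config.alpha)

    results: dict[str, dict] = {}
    for exposure_name, path in spec.exposures.items():
        entry: dict = {"stage": stage_label, "exposure": exposure_name}
        try:
            table = read_summary_stats(path, trait=exposure_name)
            inst = build_instrument_set(table, ld, config.selection)
            hset = harmonize_tables(inst, outcome, config.af_band)
            counts = hset.exclusion_counts()
            entry["accounting"] = {
                "selected": len(inst),
                "absent_in_outcome": counts.get("absent_in_outcome", 0),
                "palindromic_intermediate": counts.get("palindromic_intermediate_af", 0),
                "allele_mismatch": counts.get("allele_mismatch", 0),
                "analyzed": hset.n_snp,
            }
            entry["mean_f"] = inst.mean_f
            entry["exclusions"] = hset.exclusions

            seed = _derive_seed(config.seed, stage_label, exposure_name)
            ivw_est = estimators.ivw(hset)
            egger_res = estimators.egger(hset)
            entry["estimates"] = {
                "IVW": ivw_est,
                "MR-Egger": egger_res.slope,
                "Weighted median": estimators.weighted_median(
                    hset, n_boot=config.wm_boot, seed=seed
                ),
                "MR.RAPS": estimators.raps(hset),
            }
            entry["egger_intercept"] = {
                "intercept": egger_res.intercept,
                "se": egger_res.intercept_se,
                "pval": egger_res.intercept_pval,
            }
            entry["q_ivw"] = estimators.cochran_q(hset, "ivw")
            entry["q_egger"] = estimators.cochran_q(hset, "egger")
            if hset.n_snp >= 4:
                pres = presso.run_presso(hset, n_sim=config.presso_nsim,
                                         seed=seed + 1)
                entry["presso"] = pres
                entry["estimates"]["MR-PRESSO"] = (
                    pres.corrected_estimate or pres.raw_estimate
                )
            entry["significant"] = ivw_est.pval < threshold
            entry["threshold"] = threshold
        except MRError as exc:
            entry["error"] = str(exc)
        results[exposure_name] = entry
    return results


def run_full(config: PipelineConfig) -> dict:
    """All stages, then DL pooling of IVW log-ORs per exposure across stages."""
    report: dict = {"stages": {}, "meta": {}, "meta_note": None}
    for label in config.stages:
        report["stages"][label] = run_stage(config, label)

    stage_labels = list(config.stages)
    if len(stage_labels) < 2:
        report["meta_note"] = "meta-analysis skipped: fewer than 2 stages"
    else:
        exposures: list[str] = []
        for label in stage_labels:
            for exp in report["stages"][label]:
                if exp not in exposures:
                    exposures.append(exp)
        stage_inputs: dict[str, list[StageEstimate]] = {}
        for exp in exposures:
            ests = []
            for label in stage_labels:
                entry = report["stages"][label].get(exp, {})
                if "estimates" in entry:
                    ivw_est = entry["estimates"]["IVW"]
                    ests.append(StageEstimate(label=label,
                                              log_or=ivw_est.beta_hat,
                                              se=ivw_est.se))
            if len(ests) >= 2:
                stage_inputs[exp] = ests
                report["meta"][exp] = dl_pool(ests)
        report["meta_inputs"] = stage_inputs

    if config.output_dir:
        write_report(report, config)
    return report


# --- report serialization ---------------------------------------------------

_FMT = "%.10g"


def _estimates_frame(report: dict) -> pd.DataFrame:
    rows = []
    for stage, entries in report["stages"].items():
        for exp, entry in entries.items():
            if "error" in entry:
                rows.append({"stage": stage, "exposure": exp, "method": "NA",
                             "error": entry["error"]})
                continue
            for method, est in entry["estimates"].items():
                rows.append({
                    "stage": stage, "exposure": exp, "method": method,
                    "n_snp": est.n_snp, "beta": est.beta_hat, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "pval": est.pval, "or": est.or_, "or_low": est.or_low,
                    "or_high": est.or_high,
                    "significant": entry["significant"] if method == "IVW" else "",
                })
    return pd.DataFrame(rows)


def _heterogeneity_frame(report: dict) -> pd.DataFrame:
    rows = []
    for stage, entries in report["stages"].items():
        for exp, entry in entries.items():
            if "q_ivw" not in entry:
                continue
            for q in (entry["q_ivw"], entry["q_egger"]):
                rows.append({"stage": stage, "exposure": exp, "method": q.method,
                             "Q": q.Q, "Q_df": q.df, "pval": q.pval})
    return pd.DataFrame(rows)


def _pleiotropy_frame(report: dict) -> pd.DataFrame:
    rows = []
    for stage, entries in report["stages"].items():
        for exp, entry in entries.items():
            if "egger_intercept" not in entry:
                continue
            row = {"stage": stage, "exposure": exp,
                   "egger_intercept": entry["egger_intercept"]["intercept"],
                   "egger_intercept_se": entry["egger_intercept"]["se"],
                   "egger_intercept_pval": entry["egger_intercept"]["pval"]}
            pres = entry.get("presso")
            if pres is not None:
                row.update({
                    "presso_global_rss": pres.global_rss,
                    "presso_global_pval": pres.global_p,
                    "presso_outliers": ",".join(pres.outliers) or "NA",
                })
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: dict, config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _estimates_frame(report).to_csv(outdir / "estimates.tsv", sep="\t",
                                    index=False, float_format=_FMT)
    _heterogeneity_frame(report).to_csv(outdir / "heterogeneity.tsv", sep="\t",
                                        index=False, float_format=_FMT)
    _pleiotropy_frame(report).to_csv(outdir / "pleiotropy.tsv", sep="\t",
                                     index=False, float_format=_FMT)
    excl_rows = []
    for stage, entries in report["stages"].items():
        for exp, entry in entries.items():
            for rsid, reason in entry.get("exclusions", []):
                excl_rows.append({"stage": stage, "exposure": exp,
                                  "rsid": rsid, "reason": reason})
    pd.DataFrame(excl_rows, columns=["stage", "exposure", "rsid", "reason"]).to_csv(
        outdir / "exclusions.tsv", sep="\t", index=False)
    if report["meta"]:
        meta_report(report["meta"], report.get("meta_inputs")).to_csv(
            outdir / "meta.tsv", sep="\t", index=False, float_format=_FMT)
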