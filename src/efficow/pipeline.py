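"""End-to-end orchestration: herd scoring → quantification → differential
abundance → enrichment → (optional) qPCR, from a single config.

Every stage writes its tables under the run directory and the run ends
with a ``manifest.json`` recording parameters, per-stage counts and a
SHA-256 hash of every output file — identical inputs and config yield
identical hashes, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from efficow import diff_abundance, enrichment, feed_efficiency, lfq, qpcr

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("efficow")

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Paths, thresholds and labels for a full run.

    ``ct`` and ``gmt`` are optional: without a Ct table the qPCR stage
    is skipped; without a GMT the enrichment stage is skipped.
    """

    cow_days: str | None = None
    peptides: str | None = None
    samples: str | None = None
    gmt: str | None = None
    ct: str | None = None
    out_dir: str = "run"
    window_days: int = 35
    fraction: float = 0.20
    p_thresh: float = 0.05
    fc_thresh: float = 1.5
    case_group: str = "HEF"
    control_group: str = "LEF"
    target_genes: list[str] = field(default_factory=list)
    reference_candidates: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("cow_days", "peptides", "samples", "gmt", "ct"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.p_thresh <= 0 or self.fc_thresh <= 0 or self.fraction <= 0:
            raise ValueError("thresholds must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages in order; returns the manifest dict.

    Stage order: rfi → classify → quantify → diffabund → enrich →
    qpcr (if a Ct table is configured). Any stage failure raises with
    the stage name prefixed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in vars(config).items()},
                    "stages": {}, "files": {}}
    stage = "setup"

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / name
        _write(df, path, index=index)
        report["files"][name] = _sha256(path)

    try:
        if config.cow_days:
            stage = "rfi"
            log.info("stage %s: scoring herd", stage)
            cow_days = feed_efficiency.read_cow_days(config.cow_days)
            scores = feed_efficiency.score_herd(cow_days, config.window_days)
            stage = "classify"
            scores = feed_efficiency.classify_efficiency(scores, config.fraction)
            emit("efficiency.tsv", scores.sort_values(["rfi", "cow_id"]))
            counts = scores["efficiency_class"].value_counts().to_dict()
            report["stages"]["rfi"] = {"n_cows": len(scores), **counts}

        diff = None
        proteins = None
        if config.peptides:
            stage = "quantify"
            log.info("stage %s: TIC normalization + top-3 rollup", stage)
            peptides = lfq.read_peptides(config.peptides)
            groups = lfq.read_samples(config.samples)
            normed, norm_report = lfq.tic_normalize(peptides)
            proteins = lfq.rollup_top3(normed)
            emit("proteins.tsv", proteins)
            emit("normalization_report.tsv", norm_report)
            logged = lfq.log_transform(proteins.dropna(
                subset=lfq.sample_columns(proteins), how="all"))
            pca_scores, var_pct = lfq.pca_summary(logged)
            pca_scores["group"] = pca_scores["sample_id"].map(groups)
            emit("pca.tsv", pca_scores)
            report["stages"]["quantify"] = {
                "n_peptides": len(peptides),
                "n_proteins": len(proteins),
                "pc1_variance_pct": float(var_pct[0]),
                "pc2_variance_pct": float(var_pct[1]) if len(var_pct) > 1 else 0.0,
            }

            stage = "diffabund"
            log.info("stage %s: differential abundance", stage)
            diff = diff_abundance.differential_table(
                proteins, groups, case=config.case_group,
                control=config.control_group, p_thresh=config.p_thresh,
                fc_thresh=config.fc_thresh)
            diff, counts = diff_abundance.call_daps(
                diff, config.p_thresh, config.fc_thresh)
            emit("differential.tsv", diff)
            volcano = diff.loc[diff["status"] == "ok",
                               ["protein_id", "log2fc", "p", "pi_score", "is_dap"]]
            emit("volcano.tsv", volcano)
            if counts.total:
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    heat = diff_abundance.export_heatmap_matrix(diff, proteins)
                emit("heatmap.tsv", heat, index=True)
            report["stages"]["diffabund"] = {
                "n_tested": int((diff["status"] == "ok").sum()),
                "dap_total": counts.total, "dap_up": counts.up,
                "dap_down": counts.down,
                "dap_percent": counts.percent_of_universe,
            }

        if config.gmt and diff is not None:
            stage = "enrich"
            log.info("stage %s: hypergeometric enrichment", stage)
            sets = enrichment.read_gmt(config.gmt)
            daps = set(diff.loc[diff["is_dap"], "protein_id"])
            background = set(diff["protein_id"])
            enr = enrichment.hypergeom_enrich(daps, background, sets)
            emit("enrichment.tsv", enr)
            if daps:
                frac = enrichment.category_fractions(daps, sets)
                emit("fractions.tsv", frac)
            report["stages"]["enrich"] = {
                "n_terms": len(sets),
                "n_significant": int((enr["p_adj"] <= 0.05).sum()),
            }

        if config.ct:
            stage = "qpcr"
            log.info("stage %s: ddCt relative quantification", stage)
            records = qpcr.read_ct(config.ct)
            candidates = config.reference_candidates or sorted(
                set(records["gene"]) - set(config.target_genes))
            ref_gene, ref_report = qpcr.select_reference(records, candidates)
            emit("reference_report.tsv", ref_report)
            targets = config.target_genes or sorted(
                set(records["gene"]) - set(candidates))
            rq_frames, comparisons = [], []
            for gene in targets:
                rq = qpcr.ddct_rq(records, gene, ref_gene, config.control_group)
                rq_frames.append(rq)
                comparisons.append(qpcr.compare_rq(
                    rq, config.case_group, config.control_group))
            emit("rq.tsv", pd.concat(rq_frames, ignore_index=True))
            emit("rq_summary.tsv", pd.DataFrame(comparisons))
            report["stages"]["qpcr"] = {"reference_gene": ref_gene,
                                        "n_targets": len(targets)}
        else:
            report["stages"]["qpcr"] = {"skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                        default=str) + "\n", encoding="utf-8")
    log.info("run complete: %d files, manifest at %s",
             len(report["files"]), manifest_path)
    return report
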