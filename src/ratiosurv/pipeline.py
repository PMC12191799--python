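"""End-to-end orchestration: simulate -> preprocess -> screen -> calibrate ->
classify -> enrich -> score, driven by one declarative YAML config.

Every stage writes a plain-text artifact into the run directory, and a
manifest records the config hash, seed, package version and the SHA-256 of
every output, so a rerun with the same config and seed is byte-identical and
any stage can be re-run from its on-disk inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate, classify_groups
from .containers import ExpressionMatrix, SchemaError
from .enrich import (
    annotate_composition,
    cluster_functions,
    dedup_functions,
    enrich_collection,
    label_majority,
)
from .io import (
    read_clinical_tsv,
    read_counts_tsv,
    read_gmt,
    write_calibration_json,
    write_clinical_tsv,
    write_counts_tsv,
    write_gmt,
    write_screen_tsv,
)
from .preprocess import (
    align_subjects,
    filter_cohort,
    log2p4_transform,
    remove_anchor_outliers,
)
from .relevance import CitationTable, triage
from .screen import RatioSurvivalScreen
from .simulate import (
    SimulationConfig,
    generate_citation_counts,
    generate_expression,
    generate_gene_sets,
    generate_survival,
)

__all__ = ["RunConfig", "run_all", "StageError"]

log = logging.getLogger("ratiosurv")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (YAML round-trippable)."""

    out_dir: str = "ratiosurv_run"
    seed: int = 0
    # inputs: either file paths, or a `simulate` block to generate them
    expr_path: str | None = None
    clinical_path: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    counts_path: str | None = None
    simulate: dict = field(default_factory=dict)
    # analysis parameters
    anchor: str = "OPCML"
    stage_filter: str | None = "IIIC"
    min_days: int = 0
    max_days: int = 3650
    z_threshold: float = 6.0
    improvement_factor: float = 0.9
    iterations: int = 25
    thresholds: str = "empirical"  # or "fixed_2"
    alpha: float = 0.05
    k_clusters: int = 20
    top_n: int = 30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def content_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name):
        log.info("stage %s", name)
        return name

    # -- simulate / load -----------------------------------------------------
    stage = _stage("inputs")
    try:
        if config.expr_path:
            expr = ExpressionMatrix.from_tsv(config.expr_path)
            cohort = read_clinical_tsv(config.clinical_path)
            collections = [read_gmt(p) for p in config.gmt_paths]
            counts_df = (
                read_counts_tsv(config.counts_path) if config.counts_path else None
            )
        else:
            sim = SimulationConfig(**{"seed": config.seed, **config.simulate})
            expr = generate_expression(sim)
            cohort = generate_survival(sim, expr)
            collections = [generate_gene_sets(sim)]
            counts_df = generate_citation_counts(sim)
            expr.to_tsv(out / "expression.tsv")
            write_clinical_tsv(cohort, out / "clinical.tsv")
            write_gmt(collections[0], out / "gene_sets.gmt")
            write_counts_tsv(counts_df, out / "citation_counts.tsv")
            outputs |= {
                "expression": out / "expression.tsv",
                "clinical": out / "clinical.tsv",
                "gene_sets": out / "gene_sets.gmt",
                "citation_counts": out / "citation_counts.tsv",
            }
    except SchemaError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named reraise
        raise StageError(f"{stage}: {exc}") from exc

    # -- preprocess ----------------------------------------------------------
    stage = _stage("preprocess")
    try:
        cohort = filter_cohort(
            cohort, config.stage_filter, config.min_days, config.max_days
        )
        expr, outlier_report = remove_anchor_outliers(
            expr, config.anchor, config.z_threshold
        )
        expr, cohort = align_subjects(expr, cohort)
        log.info(
            "preprocess: %d subjects retained, %d anchor outlier(s) removed",
            len(cohort), len(outlier_report),
        )
        expr_log = log2p4_transform(expr)
        outlier_report.to_csv(out / "anchor_outliers.tsv", sep="\t", index=False,
                              float_format="%.10g")
        outputs["anchor_outliers"] = out / "anchor_outliers.tsv"
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc

    # -- screen --------------------------------------------------------------
    stage = _stage("screen")
    try:
        screen = RatioSurvivalScreen(
            anchor=config.anchor, improvement_factor=config.improvement_factor
        ).fit(expr_log, cohort)
        records = screen.records_
        n_skipped = records["skipped_reason"].notna().sum()
        log.info("screen: %d features, %d skipped", len(records), n_skipped)
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc

    # -- calibrate + classify ------------------------------------------------
    stage = _stage("calibrate")
    try:
        calibration = calibrate(
            expr_log, cohort, config.anchor,
            n_iterations=config.iterations, rng_seed=config.seed,
        )
        write_calibration_json(calibration, out / "calibration.json")
        pd.DataFrame({"hr_z": calibration.hrz_samples}).to_csv(
            out / "null_hrz.tsv", sep="\t", index=False, float_format="%.10g"
        )
        records = classify_groups(records, calibration.thresholds(config.thresholds))
        write_screen_tsv(records, out / "screen.tsv")
        outputs |= {
            "calibration": out / "calibration.json",
            "null_hrz": out / "null_hrz.tsv",
            "screen": out / "screen.tsv",
        }
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc

    # -- enrich --------------------------------------------------------------
    stage = _stage("enrich")
    try:
        tested = records.loc[records["skipped_reason"].isna(), "feature_id"]
        significant = records.loc[records["group"] != "ns", "feature_id"]
        log.info("enrich: %d significant of %d tested features",
                 len(significant), len(tested))
        frames = []
        for coll in collections:
            frames.append(
                enrich_collection(significant, coll, tested, alpha=config.alpha)
            )
        functions = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
        if len(functions):
            functions = functions.loc[functions["significant"]].reset_index(drop=True)
        functions = dedup_functions(functions) if len(functions) else functions
        if len(functions):
            groups = records.set_index("feature_id")["group"]
            functions = annotate_composition(functions, groups)
            functions = label_majority(functions)
            if len(functions) >= 2:
                functions = cluster_functions(
                    functions, k=min(config.k_clusters, len(functions))
                )
            else:
                functions["cluster_id"] = 1
        _write_functions(functions, out / "functions.tsv")
        outputs["functions"] = out / "functions.tsv"
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc

    # -- score / triage ------------------------------------------------------
    stage = _stage("score")
    try:
        counts = (
            CitationTable.from_frame(counts_df)
            if counts_df is not None
            else CitationTable(counts={})
        )
        ranked = (
            triage(functions, counts, top_n=config.top_n)
            if len(functions)
            else functions.assign(ovca_score=pd.Series(dtype=float))
        )
        _write_functions(ranked, out / "triage.tsv")
        outputs["triage"] = out / "triage.tsv"
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc

    # -- manifest ------------------------------------------------------------
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _write_functions(functions: pd.DataFrame, path: Path) -> None:
    df = functions.copy()
    if "member_hits" in df.columns:
        df["member_hits"] = [",".join(h) for h in df["member_hits"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
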