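"""Readers and writers for the pipeline's plain-text interchange formats.

All stage outputs are tab-separated text (or JSON for the calibration
report) so that every intermediate is diffable and re-runnable on its own.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import GeneSet, GeneSetCollection, NullCalibration, validate_cohort

__all__ = [
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_gmt",
    "write_gmt",
    "read_screen_tsv",
    "write_screen_tsv",
    "write_calibration_json",
    "read_counts_tsv",
    "write_counts_tsv",
]


def read_clinical_tsv(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))


def write_clinical_tsv(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Blank lines are skipped.  The description column is preserved (which is
    why this is not delegated to parsers that return bare name->genes dicts).
    """
    sets: list[GeneSet] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, desc, *genes = fields
        sets.append(GeneSet(name, desc, tuple(g for g in genes if g)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([s.set_id, s.description, *s.members]) for s in collection.sets
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


SCREEN_COLUMNS = [
    "feature_id",
    "cox_hr",
    "cox_p_wald",
    "km_p_single",
    "km_p_ratio",
    "hr_sym",
    "hr_z",
    "passes_improvement",
    "group",
    "skipped_reason",
]


def write_screen_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.10g",
                   columns=[c for c in SCREEN_COLUMNS if c in records.columns])


def read_screen_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["feature_id"] = df["feature_id"].astype(str)
    return df


def write_calibration_json(calibration: NullCalibration, path) -> None:
    Path(path).write_text(json.dumps(calibration.to_dict(), indent=2) + "\n")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "count"} <= set(df.columns):
        raise ValueError("citation table needs columns gene_id, count")
    df["gene_id"] = df["gene_id"].astype(str)
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)
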