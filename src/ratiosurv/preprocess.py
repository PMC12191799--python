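"""Cohort filters, anchor outlier removal, log2(x+4) scaling, ratio construction.

The inclusion rules mirror a survival study that keeps one stage label and
subjects with an observed integer days-to-death strictly inside (min_days,
max_days).  Expression is rescaled as log2(x+4), which floors every value at
2.0 and thereby keeps the denominator of every anchor/gene ratio away from
zero; ratios are computed on the transformed scale (transform first, then
divide).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    LOG2P4,
    NORMALIZED,
    ExpressionMatrix,
    RatioMatrix,
    SchemaError,
    validate_cohort,
)

__all__ = [
    "filter_cohort",
    "remove_anchor_outliers",
    "log2p4_transform",
    "compute_ratios",
    "align_subjects",
    "median_of_ratios_normalize",
]


def filter_cohort(
    cohort: pd.DataFrame,
    stage_filter: str | None = "IIIC",
    min_days: int = 0,
    max_days: int = 3650,
) -> pd.DataFrame:
    """Keep subjects matching the stage label with min_days < days < max_days.

    Both day bounds are strict; subject order is preserved.  An empty result
    is allowed but warned about.  Idempotent for fixed arguments.
    """
    cohort = validate_cohort(cohort)
    keep = (cohort["days_to_death"] > min_days) & (cohort["days_to_death"] < max_days)
    if stage_filter is not None:
        keep &= cohort["stage"] == stage_filter
    out = cohort.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("cohort filter retained no subjects", stacklevel=2)
    return out


def remove_anchor_outliers(
    expr: ExpressionMatrix, anchor: str, z_threshold: float = 6.0
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop subjects whose anchor expression Z-score magnitude >= z_threshold.

    Z-scores use the sample sd (ddof=1) of the anchor row on the normalized
    scale.  Returns the reduced matrix and a report of dropped subjects with
    their Z-scores.  A zero-variance anchor row leaves Z undefined and drops
    nobody.
    """
    if expr.transform_state != NORMALIZED:
        raise SchemaError("outlier removal operates on the normalized scale")
    if anchor not in expr.values.index:
        raise KeyError(f"anchor feature {anchor!r} not in expression matrix")
    row = expr.values.loc[anchor].to_numpy(dtype=float)
    sd = row.std(ddof=1) if row.size > 1 else 0.0
    if sd == 0.0 or not np.isfinite(z_threshold):
        drop_mask = np.zeros(row.size, dtype=bool)
        z = np.full(row.size, np.nan)
    else:
        z = (row - row.mean()) / sd
        drop_mask = np.abs(z) >= z_threshold
    report = pd.DataFrame(
        {
            "subject_id": np.asarray(expr.subject_ids)[drop_mask],
            "anchor_value": row[drop_mask],
            "z_score": z[drop_mask],
        }
    )
    keep = [s for s, d in zip(expr.subject_ids, drop_mask) if not d]
    return expr.subset_subjects(keep), report


def log2p4_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 4); minimum possible output is 2.0."""
    if expr.transform_state != NORMALIZED:
        raise SchemaError("log2p4_transform expects a normalized matrix")
    arr = expr.values.to_numpy(dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative expression value")
    out = pd.DataFrame(
        np.log2(arr + 4.0), index=expr.values.index, columns=expr.values.columns
    )
    return ExpressionMatrix(out, transform_state=LOG2P4)


def compute_ratios(expr: ExpressionMatrix, anchor: str) -> RatioMatrix:
    """Per-subject anchor/gene ratios on the log2(x+4) scale.

    Row i equals ``expr[anchor, s] / expr[i, s]``; the anchor row is dropped.
    Because transformed values are >= 2, every ratio lies in
    ``[2/log2(M+4), log2(M+4)/2]`` for inputs bounded by M.
    """
    if expr.transform_state != LOG2P4:
        raise SchemaError("ratios are defined on the log2p4 scale")
    if anchor not in expr.values.index:
        raise KeyError(f"anchor feature {anchor!r} not in expression matrix")
    anchor_row = expr.values.loc[anchor]
    ratios = expr.values.drop(index=anchor).rdiv(anchor_row, axis=1)
    return RatioMatrix(ratios, anchor_feature_id=anchor)


def align_subjects(
    expr: ExpressionMatrix, cohort: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Restrict both inputs to their common subjects (warn on any drop).

    Expression column order defines the common ordering.
    """
    cohort = validate_cohort(cohort)
    clinical_ids = set(cohort["subject_id"])
    common = [s for s in expr.subject_ids if s in clinical_ids]
    n_dropped = (len(expr.subject_ids) - len(common)) + (len(clinical_ids) - len(common))
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} subject(s) absent from one of the inputs",
            stacklevel=2,
        )
    if not common:
        raise SchemaError("no subjects shared between expression and clinical tables")
    cohort_aligned = (
        cohort.set_index("subject_id").loc[common].reset_index()
    )
    return expr.subset_subjects(common), cohort_aligned


def median_of_ratios_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Optional library-size normalizer (median-of-ratios to the geometric
    reference sample), for inputs that arrive as raw counts.  Plumbing only —
    upstream normalization is normally accepted as given."""
    if expr.transform_state != NORMALIZED:
        raise SchemaError("normalization operates on the normalized/count scale")
    arr = expr.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError("no feature expressed in every subject; cannot normalize")
    ref = logs[usable].mean(axis=1, keepdims=True)  # per-feature geometric mean
    size_factors = np.exp(np.median(logs[usable] - ref, axis=0))
    out = pd.DataFrame(
        arr / size_factors, index=expr.values.index, columns=expr.values.columns
    )
    return ExpressionMatrix(out, transform_state=NORMALIZED)
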