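"""Per-feature median-stratified survival screening.

For every feature the cohort is split at the median of the anchor/gene ratio
(and, as a baseline, at the median of the single gene's own expression), and
the two groups are contrasted with a log-rank test and a univariate Cox
proportional-hazards fit whose single covariate is the high-group indicator.
The hazard ratio is always high-ratio relative to low-ratio.

Because a screen fits one Cox model per feature (thousands per cohort, and
again inside every Monte Carlo replicate), the log-rank statistic and the
Cox partial-likelihood Newton solver are implemented here vectorized across
features: risk-set counts for all features are obtained from reverse
cumulative sums over the time-sorted subject axis, and the scalar Newton
iteration for the binary-covariate Cox model runs on all features at once.
Ties are handled with the Efron approximation.  The same code path serves
single-feature calls, so stored screen results are exactly reproducible from
stored group assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import (
    ExpressionMatrix,
    RatioMatrix,
    validate_cohort,
)
from .hrstats import hr_sym, z_standardize
from .preprocess import compute_ratios

__all__ = [
    "StratifiedGroups",
    "median_stratify",
    "km_logrank",
    "cox_hr",
    "improvement_filter",
    "screen_all",
    "RatioSurvivalScreen",
]

_MAX_ABS_BETA = 10.0  # |log HR| beyond this is treated as separation


@dataclass
class StratifiedGroups:
    """Median bifurcation of a cohort: low (value <= median) vs high (> median)."""

    low_ids: list[str]
    high_ids: list[str]
    median_value: float


class DegenerateStratification(ValueError):
    """All values identical (or a group empty): no median split exists."""


def median_stratify(values: pd.Series) -> StratifiedGroups:
    """Split subjects at the sample median; ties go to the low group.

    Requires >= 4 subjects and at least two distinct values, otherwise a
    :class:`DegenerateStratification` is raised (screens record these as
    skipped, they never abort).
    """
    if len(values) < 4:
        raise DegenerateStratification("need at least 4 subjects")
    arr = values.to_numpy(dtype=float)
    med = float(np.median(arr))
    high = arr > med
    if not high.any() or high.all():
        raise DegenerateStratification("degenerate")
    idx = values.index
    return StratifiedGroups(
        low_ids=list(idx[~high]), high_ids=list(idx[high]), median_value=med
    )


# ---------------------------------------------------------------------------
# vectorized survival statistics


@dataclass
class _RiskSets:
    """Time-ordered event structure shared by every feature of one cohort."""

    order: np.ndarray        # subject permutation sorting days ascending
    event_sorted: np.ndarray  # bool, per sorted subject
    starts: np.ndarray       # first sorted index of each distinct time
    n_at_risk: np.ndarray    # per distinct time
    d: np.ndarray            # events per distinct time
    # flattened (distinct event time j, tie index l) pairs for Efron terms
    jj: np.ndarray
    frac: np.ndarray         # l / d_j per flattened pair


def _build_risk_sets(days: np.ndarray, event: np.ndarray) -> _RiskSets:
    order = np.argsort(days, kind="stable")
    t = days[order]
    e = event[order].astype(float)
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_at_risk = n - starts
    d = np.add.reduceat(e, starts) if n else np.array([])
    # Efron inner terms: for each distinct time with d_j events, l = 0..d_j-1
    ev_times = np.flatnonzero(d > 0)
    jj = np.repeat(ev_times, d[ev_times].astype(int))
    ll = np.concatenate(
        [np.arange(int(d[j])) for j in ev_times]
    ) if ev_times.size else np.array([], dtype=int)
    frac = ll / d[jj] if jj.size else np.array([])
    return _RiskSets(order, event[order], starts, n_at_risk, d, jj, frac)


def _group_counts(rs: _RiskSets, Z: np.ndarray):
    """Risk-set and event counts in the high group, per feature x distinct time.

    Z is (n_features, n_subjects) boolean in original subject order.
    """
    Zs = Z[:, rs.order].astype(float)
    rev = np.cumsum(Zs[:, ::-1], axis=1)[:, ::-1]
    n1 = rev[:, rs.starts]                       # at risk in high group
    d1 = np.add.reduceat(Zs * rs.event_sorted, rs.starts, axis=1)
    return n1, d1


def _rowsum(arr: np.ndarray) -> np.ndarray:
    """Sequential left-to-right sum along the last axis.

    numpy's ``.sum(axis=1)`` picks different reduction orders depending on
    the number of rows; screening records must be bit-identical whether a
    feature is evaluated alone or inside a batch, so all floating
    accumulations over risk sets go through this fixed order.
    """
    out = np.zeros(arr.shape[0])
    for j in range(arr.shape[1]):
        out += arr[:, j]
    return out


def _logrank_vectorized(rs: _RiskSets, n1: np.ndarray, d1: np.ndarray) -> np.ndarray:
    """Two-sided log-rank p per feature from precomputed group counts."""
    d = rs.d
    n = rs.n_at_risk.astype(float)
    ev = d > 0
    frac1 = n1[:, ev] / n[ev]
    de = d[ev]
    ne = n[ev]
    O1 = d1[:, ev].sum(axis=1)  # integer-valued: order-independent
    E1 = _rowsum(de * frac1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = de * frac1 * (1.0 - frac1) * (ne - de) / np.maximum(ne - 1.0, 1.0)
    V = _rowsum(var_terms)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / V, np.nan)
    return np.where(np.isfinite(chi2), stats.chi2.sf(chi2, df=1), np.nan)


def _cox_binary_efron(
    rs: _RiskSets,
    n1: np.ndarray,
    d1: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 60,
):
    """Newton solve of the Efron partial likelihood, one binary covariate,
    vectorized across features.

    Returns (beta, se, converged).  Features with monotone likelihood
    (complete separation) are reported unconverged.
    """
    n0 = rs.n_at_risk[None, :] - n1
    s1 = d1
    s0 = rs.d[None, :] - d1
    jj, frac = rs.jj, rs.frac
    # per flattened Efron term: A(beta) = a + e^beta * b
    a = n0[:, jj] - frac[None, :] * s0[:, jj]
    b = n1[:, jj] - frac[None, :] * s1[:, jj]
    D1 = s1[:, rs.d > 0].sum(axis=1)

    F = n1.shape[0]
    beta = np.zeros(F)
    converged = np.zeros(F, dtype=bool)
    for _ in range(max_iter):
        u = np.exp(beta)[:, None] * b
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(a + u > 0, u / (a + u), 1.0)
        grad = D1 - _rowsum(q)
        info = _rowsum(q * (1.0 - q))
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, grad / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -1.0, 1.0)  # damp early overshoot
        active = ~converged & (np.abs(beta) <= _MAX_ABS_BETA) & (info > 0)
        beta = np.where(active, beta + step, beta)
        converged |= active & (np.abs(step) < tol)
        if converged.all():
            break
    u = np.exp(beta)[:, None] * b
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(a + u > 0, u / (a + u), 1.0)
    info = _rowsum(q * (1.0 - q))
    ok = converged & (np.abs(beta) < _MAX_ABS_BETA) & (info > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    return np.where(ok, beta, np.nan), se, ok


def _cohort_arrays(cohort: pd.DataFrame, subject_ids) -> tuple[np.ndarray, np.ndarray]:
    cohort = validate_cohort(cohort)
    indexed = cohort.set_index("subject_id")
    missing = [s for s in subject_ids if s not in indexed.index]
    if missing:
        raise KeyError(f"subjects missing from clinical table: {missing[:5]}")
    sub = indexed.loc[list(subject_ids)]
    return sub["days_to_death"].to_numpy(int), sub["event"].to_numpy(bool)


def _groups_to_indicator(groups: StratifiedGroups) -> tuple[list[str], np.ndarray]:
    subjects = groups.low_ids + groups.high_ids
    z = np.zeros((1, len(subjects)), dtype=bool)
    z[0, len(groups.low_ids):] = True
    return subjects, z


def km_logrank(groups: StratifiedGroups, cohort: pd.DataFrame) -> float:
    """Two-sided log-rank test p-value contrasting the two survival curves."""
    if not groups.low_ids or not groups.high_ids:
        raise ValueError("both groups must be nonempty")
    subjects, z = _groups_to_indicator(groups)
    days, event = _cohort_arrays(cohort, subjects)
    if not event.any():
        raise ValueError("need at least one event")
    rs = _build_risk_sets(days, event)
    n1, d1 = _group_counts(rs, z)
    return float(_logrank_vectorized(rs, n1, d1)[0])


def cox_hr(groups: StratifiedGroups, cohort: pd.DataFrame) -> float:
    """Hazard ratio of the high group vs the low group (Efron ties).

    Exponentiated coefficient of a proportional-hazards fit with the single
    binary covariate indicator(high group).  Raises on non-convergence or
    complete separation.
    """
    subjects, z = _groups_to_indicator(groups)
    days, event = _cohort_arrays(cohort, subjects)
    rs = _build_risk_sets(days, event)
    n1, d1 = _group_counts(rs, z)
    beta, _, ok = _cox_binary_efron(rs, n1, d1)
    if not ok[0]:
        raise ValueError("Cox fit did not converge (separation or degenerate groups)")
    return float(np.exp(beta[0]))


def improvement_filter(
    p_ratio: float, p_single: float, factor: float = 0.9
) -> bool:
    """True iff the ratio stratification is at least 10% more significant
    than the single-gene baseline: ``p_ratio <= factor * p_single``."""
    if not (0 <= p_ratio <= 1 and 0 <= p_single <= 1):
        raise ValueError("p-values must lie in [0, 1]")
    return bool(p_ratio <= factor * p_single)


def _median_indicators(values: np.ndarray):
    """High-group indicator matrix (> per-row median) plus degeneracy mask."""
    med = np.median(values, axis=1, keepdims=True)
    Z = values > med
    n_high = Z.sum(axis=1)
    degenerate = (n_high == 0) | (n_high == values.shape[1])
    return Z, degenerate


def screen_all(
    ratios: RatioMatrix,
    expr: ExpressionMatrix,
    cohort: pd.DataFrame,
    improvement_factor: float = 0.9,
) -> pd.DataFrame:
    """Run the full per-feature screen; one record per non-anchor feature.

    Columns: ``feature_id, cox_hr, cox_p_wald, km_p_single, km_p_ratio,
    hr_sym, hr_z, passes_improvement, group, skipped_reason``.  ``hr_z`` is
    standardized over all non-skipped features of this screen;  ``group`` is
    initialized to ``"ns"`` (see ``calibration.classify_groups``).  Per-feature
    failures are recorded as skips, never raised.
    """
    subjects = ratios.subject_ids
    if expr.subject_ids != subjects:
        expr = expr.subset_subjects(subjects)
    days, event = _cohort_arrays(cohort, subjects)
    rs = _build_risk_sets(days, event)

    feature_ids = ratios.feature_ids
    order = np.argsort(feature_ids, kind="stable")  # deterministic output order
    rvals = ratios.values.to_numpy(dtype=float)[order]
    evals = expr.values.loc[[feature_ids[i] for i in order]].to_numpy(dtype=float)

    Zr, degen_r = _median_indicators(rvals)
    Ze, degen_e = _median_indicators(evals)

    n1r, d1r = _group_counts(rs, Zr)
    n1e, d1e = _group_counts(rs, Ze)
    p_ratio = _logrank_vectorized(rs, n1r, d1r)
    p_single = _logrank_vectorized(rs, n1e, d1e)
    beta, se, ok = _cox_binary_efron(rs, n1r, d1r)

    skipped = np.where(
        degen_r,
        "degenerate",
        np.where(~ok, "cox_nonconvergence", ""),
    )
    usable = skipped == ""
    hr = np.where(usable, np.exp(beta), np.nan)
    with np.errstate(invalid="ignore"):
        wald = np.where(usable, 2.0 * stats.norm.sf(np.abs(beta) / se), np.nan)

    hsym = np.full(hr.size, np.nan)
    hsym[usable] = hr_sym(hr[usable])
    hz = np.full(hr.size, np.nan)
    if usable.sum() >= 2 and np.nanstd(hsym[usable]) > 0:
        hz[usable] = z_standardize(hsym[usable]).hr_z

    p_single_eff = np.where(degen_e, np.nan, p_single)
    passes = (
        usable
        & np.isfinite(p_ratio)
        & np.isfinite(p_single_eff)
        & (p_ratio <= improvement_factor * p_single_eff)
    )
    records = pd.DataFrame(
        {
            "feature_id": [feature_ids[i] for i in order],
            "cox_hr": hr,
            "cox_p_wald": wald,
            "km_p_single": p_single_eff,
            "km_p_ratio": np.where(usable, p_ratio, np.nan),
            "hr_sym": hsym,
            "hr_z": hz,
            "passes_improvement": passes,
            "group": "ns",
            "skipped_reason": pd.array(
                [s if s else None for s in skipped], dtype="string"
            ),
        }
    )
    return records


class RatioSurvivalScreen(BaseEstimator):
    """Estimator wrapper for the anchor-ratio survival screen.

    Parameters
    ----------
    anchor : str
        Feature ID used as the numerator of every ratio.
    improvement_factor : float, default 0.9
        The ratio stratification's log-rank p must be <= this factor times
        the single-gene baseline p to pass the improvement filter.

    Attributes
    ----------
    records_ : pandas.DataFrame
        One screening record per non-anchor feature.
    ratios_ : RatioMatrix
        The anchor/gene ratio matrix actually screened.
    """

    def __init__(self, anchor: str = "OPCML", improvement_factor: float = 0.9):
        self.anchor = anchor
        self.improvement_factor = improvement_factor

    def fit(self, expr: ExpressionMatrix, cohort: pd.DataFrame):
        """Screen a log2(x+4)-scale expression matrix against a cohort."""
        self.ratios_ = compute_ratios(expr, self.anchor)
        self.records_ = screen_all(
            self.ratios_, expr, cohort, improvement_factor=self.improvement_factor
        )
        return self

    def significant_features(self) -> list[str]:
        """Features classified into either tail group (after classification)."""
        rec = self.records_
        return list(rec.loc[rec["group"] != "ns", "feature_id"])
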