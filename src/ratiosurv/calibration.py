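"""Monte Carlo null calibration of the HRz statistic.

Ratios that share one anchor numerator are mutually dependent, so analytic
per-feature false-positive arithmetic does not apply to the screen as a
whole.  Instead the screen is re-run on fully randomized inputs — each
feature's values permuted independently across subjects, and the survival
records permuted across subjects — which preserves every marginal
distribution and the shared-anchor dependence structure while breaking all
feature-survival linkage.  Pooling the HRz values across replicates yields
empirical two-tailed significance boundaries (the 0.025 / 0.975 quantiles)
and the false-positive rate at the fixed +/-2.0 cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import (
    ExpressionMatrix,
    GroupThresholds,
    NullCalibration,
    validate_cohort,
)
from .preprocess import compute_ratios, log2p4_transform
from .screen import screen_all

__all__ = [
    "randomize_inputs",
    "calibrate",
    "classify_groups",
    "NullCalibrator",
]


def randomize_inputs(
    expr: ExpressionMatrix,
    cohort: pd.DataFrame,
    rng_seed: int | np.random.SeedSequence,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Permute each expression row independently and the survival records.

    Marginal distributions are preserved exactly; survival days and event
    flags travel together so censored records stay coherent.
    """
    rng = np.random.default_rng(rng_seed)
    cohort = validate_cohort(cohort)
    vals = rng.permuted(expr.values.to_numpy(dtype=float), axis=1)
    shuffled_expr = ExpressionMatrix(
        pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns),
        transform_state=expr.transform_state,
    )
    perm = rng.permutation(len(cohort))
    shuffled_cohort = cohort.copy()
    shuffled_cohort[["days_to_death", "event"]] = (
        cohort[["days_to_death", "event"]].to_numpy()[perm]
    )
    return shuffled_expr, shuffled_cohort


def calibrate(
    expr: ExpressionMatrix,
    cohort: pd.DataFrame,
    anchor: str,
    n_iterations: int = 25,
    rng_seed: int = 0,
    threshold: float = 2.0,
) -> NullCalibration:
    """Build the empirical HRz null by re-screening randomized replicates.

    Each replicate re-runs the full ratio screen (transform, ratios, median
    stratification, Cox HR, symmetrization, Z-standardization within the
    replicate) on independently permuted inputs.  Pools HRz across
    replicates; reports the 0.025/0.975 quantiles, the pooled and
    per-iteration fractions beyond ``+/-threshold``, and a Shapiro-Wilk
    normality p-value of the pooled statistic (subsampled to 5000 values for
    larger pools).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if expr.transform_state == "normalized":
        expr = log2p4_transform(expr)
    seeds = np.random.SeedSequence(rng_seed).spawn(n_iterations + 1)
    pooled: list[np.ndarray] = []
    per_iter_fp = np.empty(n_iterations)
    for i in range(n_iterations):
        shuffled_expr, shuffled_cohort = randomize_inputs(expr, cohort, seeds[i])
        ratios = compute_ratios(shuffled_expr, anchor)
        records = screen_all(ratios, shuffled_expr, shuffled_cohort)
        hrz = records["hr_z"].to_numpy(dtype=float)
        hrz = hrz[np.isfinite(hrz)]
        pooled.append(hrz)
        per_iter_fp[i] = np.mean(np.abs(hrz) > threshold) if hrz.size else np.nan
    samples = np.concatenate(pooled)
    if samples.size < 2:
        raise ValueError("no usable HRz values from the randomized replicates")
    q025, q975 = np.quantile(samples, [0.025, 0.975])
    sw_sample = samples
    if sw_sample.size > 5000:
        sw_rng = np.random.default_rng(seeds[n_iterations])
        sw_sample = sw_rng.choice(sw_sample, size=5000, replace=False)
    normality_p = float(stats.shapiro(sw_sample).pvalue)
    return NullCalibration(
        n_iterations=n_iterations,
        hrz_samples=samples,
        q025=float(q025),
        q975=float(q975),
        fp_rate_at_2=float(np.mean(np.abs(samples) > threshold)),
        per_iteration_fp=per_iter_fp,
        normality_p=normality_p,
        seed=int(rng_seed),
    )


def classify_groups(
    records: pd.DataFrame, thresholds: GroupThresholds
) -> pd.DataFrame:
    """Assign each screened feature to OPCML_plus / GENEi_plus / ns.

    ``OPCML_plus``: HRz below the lower threshold (high anchor/gene ratio is
    protective) AND the improvement filter passed; ``GENEi_plus``: HRz above
    the upper threshold AND the filter passed; everything else (including
    records without an HRz) stays ``ns``.
    """
    out = records.copy()
    hz = out["hr_z"].to_numpy(dtype=float)
    passes = out["passes_improvement"].to_numpy(dtype=bool)
    valid = np.isfinite(hz)
    group = np.where(
        valid & passes & (hz < thresholds.lower),
        "OPCML_plus",
        np.where(valid & passes & (hz > thresholds.upper), "GENEi_plus", "ns"),
    )
    out["group"] = group
    missing = ~valid & out["skipped_reason"].isna()
    if missing.any():
        out.loc[missing, "skipped_reason"] = "no_hrz"
    return out


class NullCalibrator(BaseEstimator):
    """Estimator wrapper for the Monte Carlo null calibration.

    Attributes (after ``fit``)
    --------------------------
    calibration_ : NullCalibration
    q025_, q975_ : float
        Empirical two-tailed significance boundaries of the pooled null HRz.
    fp_rate_at_2_ : float
        Pooled fraction of null HRz values beyond +/-2.
    """

    def __init__(
        self,
        anchor: str = "OPCML",
        n_iterations: int = 25,
        threshold: float = 2.0,
        seed: int = 0,
    ):
        self.anchor = anchor
        self.n_iterations = n_iterations
        self.threshold = threshold
        self.seed = seed

    def fit(self, expr: ExpressionMatrix, cohort: pd.DataFrame):
        self.calibration_ = calibrate(
            expr,
            cohort,
            anchor=self.anchor,
            n_iterations=self.n_iterations,
            rng_seed=self.seed,
            threshold=self.threshold,
        )
        self.q025_ = self.calibration_.q025
        self.q975_ = self.calibration_.q975
        self.fp_rate_at_2_ = self.calibration_.fp_rate_at_2
        return self

    def thresholds(self, source: str = "empirical") -> GroupThresholds:
        return self.calibration_.thresholds(source)
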