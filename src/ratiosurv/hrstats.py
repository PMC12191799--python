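"""Symmetrization and Z-standardization of Cox hazard ratios.

A raw hazard ratio is bounded below by 0, centered at 1, and unbounded above,
so its two tails are not comparable.  ``hr_sym`` maps HR -> HR - 1 for
HR >= 1 and HR -> 1 - 1/HR for HR < 1, which is antisymmetric under
HR -> 1/HR and places "no effect" at 0.  ``z_standardize`` then rescales a
screen's vector of symmetrized values to mean 0 / sd 1 (the HRz statistic),
so two-tailed significance boundaries can be read off one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["hr_sym", "z_standardize", "HrzVector"]


@dataclass
class HrzVector:
    feature_ids: list[str]
    hr_sym: np.ndarray
    hr_z: np.ndarray
    mean_used: float
    sd_used: float


def hr_sym(cox_hr):
    """Symmetrized hazard ratio: ``HR - 1`` if HR >= 1 else ``-(1/HR) + 1``.

    Accepts a scalar or array of strictly positive hazard ratios.  The result
    is 0 exactly when HR = 1, and satisfies ``hr_sym(1/x) == -hr_sym(x)``.
    """
    arr = np.asarray(cox_hr, dtype=float)
    if arr.size and np.nanmin(arr) <= 0:
        raise ValueError("cox_hr must be strictly positive")
    out = np.where(arr < 1.0, -1.0 / arr + 1.0, arr - 1.0)
    if np.isscalar(cox_hr) or np.ndim(cox_hr) == 0:
        return float(out)
    return out


def z_standardize(values, feature_ids=None) -> HrzVector:
    """Z-score a vector of symmetrized hazard ratios (sample sd, ddof=1).

    The standardization population is the full vector supplied — by
    convention all non-skipped features of one screen, never a mixture of
    screens.  Raises on fewer than two finite values or zero variance.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values")
    mean = float(np.mean(arr[finite]))
    sd = float(np.std(arr[finite], ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: HRz undefined")
    z = (arr - mean) / sd
    if feature_ids is None:
        feature_ids = [str(i) for i in range(arr.size)]
    return HrzVector(list(feature_ids), arr, z, mean, sd)
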