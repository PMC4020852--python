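"""Xenograft intervention-arm computations.

Two-group (vehicle vs treated) comparison of a positive measurement —
tumor-normalized mRNA ratio or a serum concentration — summarized as the
percent decrease of the treated group mean relative to vehicle, with a
two-sided unpaired t-test. Tumor volume follows the ellipsoid
approximation TV = L * W^2 / 2 with L the longer axis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VEHICLE = "vehicle"
TREATED = "treated"


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    sem: float


@dataclass
class InterventionSummary:
    vehicle: GroupSummary
    treated: GroupSummary
    percent_decrease: float  # 100*(mean_vehicle - mean_treated)/mean_vehicle
    t_statistic: float
    p_value: float
    welch: bool
    degenerate_variance: bool = False  # zero pooled variance, p=1 by convention

    @property
    def percent_decrease_rounded(self) -> int:
        """Display rounding to the nearest integer percent."""
        return int(round(self.percent_decrease))


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid tumor volume TV = L * W^2 / 2 in mm^3.

    Convention: L is the longer caliper axis; W > L is computed normally
    but warned about.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if (length_mm < 0).any() or (width_mm < 0).any():
        raise ValueError("tumor dimensions must be non-negative")
    if (width_mm > length_mm).any():
        warnings.warn("width exceeds length; convention is L >= W",
                      stacklevel=2)
    out = length_mm * width_mm ** 2 / 2.0
    return float(out) if out.ndim == 0 else out


def percent_decrease(mean_treated: float, mean_vehicle: float) -> float:
    """Percent decrease of the treated mean relative to vehicle.

    Negative when the treated mean exceeds the vehicle mean.
    """
    if mean_vehicle <= 0:
        raise ValueError("vehicle mean must be positive")
    return 100.0 * (mean_vehicle - mean_treated) / mean_vehicle


def unpaired_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test.

    Default is the classical pooled-variance Student test on
    n_a + n_b - 2 degrees of freedom; ``welch=True`` drops the
    equal-variance assumption. Zero pooled variance with equal means
    returns (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def _summarize(values: np.ndarray) -> GroupSummary:
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return GroupSummary(n=int(values.size), mean=float(values.mean()),
                        sd=sd, sem=sd / np.sqrt(values.size))


def run_intervention_analysis(table: pd.DataFrame,
                              welch: bool = False) -> InterventionSummary:
    """Summarize a vehicle/treated animal table.

    ``table`` needs ``group`` (vehicle|treated) and ``measurement``
    columns; measurements must be positive.
    """
    for col in ("group", "measurement"):
        if col not in table.columns:
            raise ValueError(f"intervention table lacks column {col!r}")
    groups = set(table["group"])
    missing = {VEHICLE, TREATED} - groups
    if missing:
        raise ValueError(f"missing group(s): {sorted(missing)}")
    unknown = groups - {VEHICLE, TREATED}
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    meas = table["measurement"].astype(float)
    if (meas <= 0).any():
        raise ValueError("measurements must be positive")
    veh = meas[table["group"] == VEHICLE].to_numpy()
    trt = meas[table["group"] == TREATED].to_numpy()
    degenerate = veh.var(ddof=1) == 0 and trt.var(ddof=1) == 0 \
        and veh.mean() == trt.mean()
    t, p = unpaired_t_test(veh, trt, welch=welch)
    return InterventionSummary(
        vehicle=_summarize(veh), treated=_summarize(trt),
        percent_decrease=percent_decrease(trt.mean(), veh.mean()),
        t_statistic=t, p_value=p, welch=welch,
        degenerate_variance=bool(degenerate))
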