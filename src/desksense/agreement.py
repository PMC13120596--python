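"""Bland–Altman agreement between sensor and ground-truth bout durations.

For paired durations (in minutes) the analysis reports the mean of the
sensor-minus-truth differences (bias), the 95% limits of agreement
(bias ± 1.96·SD of the differences, SD with the n−1 denominator), and a
proportional-bias check: the OLS slope of the differences on the pair
means with its two-sided t-test p-value. A slope indistinguishable from
zero means measurement error does not grow with bout duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .validation import UndefinedMetricError


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary; durations and limits in minutes."""

    mean_bias_min: float
    loa_half_width_min: float
    loa_lower_min: float
    loa_upper_min: float
    slope: float | None
    slope_p: float | None
    n: int


def bland_altman(
    sensor_durations_min: Sequence[float],
    truth_durations_min: Sequence[float],
) -> BlandAltmanResult:
    """Bland–Altman analysis of paired duration measurements.

    Requires n >= 2; with n < 3 (or degenerate variance) the
    proportional-bias slope test is reported as undefined (None).
    """
    sensor = np.asarray(sensor_durations_min, dtype=float)
    truth = np.asarray(truth_durations_min, dtype=float)
    if sensor.shape != truth.shape:
        raise ValueError("paired sequences must have equal length")
    n = sensor.size
    if n < 2:
        raise UndefinedMetricError("Bland–Altman requires at least 2 pairs")
    diffs = sensor - truth
    means = (sensor + truth) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    half = 1.96 * sd
    slope: float | None = None
    slope_p: float | None = None
    if n >= 3 and np.ptp(means) > 0:
        if np.ptp(diffs) == 0:
            slope, slope_p = 0.0, None
        else:
            fit = stats.linregress(means, diffs)
            slope = float(fit.slope)
            slope_p = float(fit.pvalue) if math.isfinite(fit.pvalue) else None
    return BlandAltmanResult(
        mean_bias_min=bias,
        loa_half_width_min=half,
        loa_lower_min=bias - half,
        loa_upper_min=bias + half,
        slope=slope,
        slope_p=slope_p,
        n=n,
    )
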