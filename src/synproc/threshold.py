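"""Calibration of the wear-probability threshold T^p.

The optimal T^p for a record correlates with how often zero counts occur
during sedentary time: the more zeros sitting produces, the lower the wear
probability dips during true wear, so the threshold must drop. The rate
r_sedentary_zero = (zero-count epochs) / (epochs at <= 1.5 METs, zeros
included) drives a linear calibration fitted by Huber robust regression;
the shipped default is the line T^p = -0.61 * r + 0.66.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import HuberRegressor

from .probability import ParameterError, probability_labels, wear_probability
from .records import SEDENTARY_MAX_METS, EpochSeries, LabelSeries, ValidationError

logger = logging.getLogger(__name__)

#: Calibration-line coefficients shipped with the method.
DEFAULT_SLOPE = -0.61
DEFAULT_INTERCEPT = 0.66
#: Standard 95%-efficiency Huber constant.
DEFAULT_HUBER_DELTA = 1.35
#: Above this sedentary zero rate the calibrated T^p becomes so low that
#: noise spikes during non-wear start slipping through; warn the user.
HIGH_RATE_WARNING_LEVEL = 0.70


class HighZeroRateWarning(UserWarning):
    """Sedentary zero rate exceeds the range the calibration was built for."""


class DegenerateInputError(ValueError):
    """The record contains no sedentary-range epochs."""


class FitError(ValueError):
    """Not enough distinct calibration pairs to fit a line."""


@dataclass(frozen=True)
class ThresholdModel:
    """Linear model T^p = slope * r_sedentary_zero + intercept, clamped to [0,1]."""

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    huber_delta: float = DEFAULT_HUBER_DELTA
    fitted_on: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "huber_delta": self.huber_delta,
                    "fitted_on": self.fitted_on,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ThresholdModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["slope"], d["intercept"], d.get("huber_delta", DEFAULT_HUBER_DELTA),
                   d.get("fitted_on", 0))


def sedentary_zero_rate(series: EpochSeries) -> float:
    """Zero-count epochs as a fraction of sedentary-range epochs (<= 1.5 METs).

    Zero counts themselves sit inside the sedentary range, so they appear in
    both numerator and denominator; the rate is computable on a raw record
    without truth labels.
    """
    sedentary = series.values <= SEDENTARY_MAX_METS
    n_sed = int(np.count_nonzero(sedentary))
    if n_sed == 0:
        raise DegenerateInputError("record has no epochs at or below 1.5 METs")
    n_zero = int(np.count_nonzero(series.is_zero()))
    return n_zero / n_sed


def optimal_threshold_search(series: EpochSeries, truth: LabelSeries,
                             grid_step: float = 0.01, window: int = 60,
                             aggregation: str = "endpoints") -> float:
    """Grid-search the T^p maximizing epoch accuracy against a truth label.

    The grid is {0, grid_step, 2*grid_step, ..., <=1}; ties resolve to the
    smallest maximizer.
    """
    if len(truth) != len(series):
        raise ValidationError("truth labels must align with the series")
    if not 0 < grid_step <= 1:
        raise ParameterError("grid_step must lie in (0, 1]")
    k = int(np.floor(1.0 / grid_step + 1e-9))
    grid = grid_step * np.arange(k + 1)
    r = wear_probability(series, window=window, aggregation=aggregation).r_wear
    t = truth.as_bool()
    # accuracy(Tp) = mean( (r >= Tp) == truth ); vectorised over the grid
    pred = r[None, :] >= grid[:, None]
    acc = (pred == t[None, :]).mean(axis=1)
    return float(grid[int(np.argmax(acc))])


def fit_threshold_model(pairs, huber_delta: float = DEFAULT_HUBER_DELTA) -> ThresholdModel:
    """Fit the calibration line threshold ~ rate by Huber robust regression.

    ``pairs`` is an iterable of (sedentary zero rate, optimal threshold).
    Requires at least two distinct rates.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("pairs must be (rate, threshold) tuples")
    rates, thresholds = arr[:, 0], arr[:, 1]
    if np.unique(rates).size < 2:
        raise FitError("need at least 2 pairs with distinct rates")
    reg = HuberRegressor(epsilon=huber_delta, alpha=0.0, tol=1e-12, max_iter=10000)
    reg.fit(rates.reshape(-1, 1), thresholds)
    return ThresholdModel(float(reg.coef_[0]), float(reg.intercept_),
                          huber_delta, int(arr.shape[0]))


def predict_threshold(model: ThresholdModel, rate: float) -> float:
    """Predict T^p for a record's sedentary zero rate, clamped to [0, 1].

    Rates above 0.70 are outside the range the calibration was developed
    for; a :class:`HighZeroRateWarning` is emitted (logged, non-fatal).
    """
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(f"rate must lie in [0, 1], got {rate}")
    if rate > HIGH_RATE_WARNING_LEVEL:
        msg = (f"sedentary zero rate {rate:.3f} exceeds "
               f"{HIGH_RATE_WARNING_LEVEL}; expect degraded classification")
        logger.warning(msg)
        warnings.warn(msg, HighZeroRateWarning, stacklevel=2)
    return float(np.clip(model.slope * rate + model.intercept, 0.0, 1.0))
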