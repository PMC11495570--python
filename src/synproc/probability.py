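"""Sliding-window wear probability and the probability criterion label.

A zero count during true wear is intermittent; during non-wear it is
sustained. The wear probability r_wear at an epoch averages the fraction of
nonzero epochs seen by 60-minute windows anchored before and after that
epoch, so a zero embedded in active surroundings keeps a high r_wear while
an epoch deep inside a non-wear block does not. Thresholding r_wear at the
calibrated T^p yields the probability label L_p (1 = wear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import EpochSeries, LabelSeries

DEFAULT_WINDOW_MINUTES = 60

_AGGREGATIONS = ("endpoints", "covering")


class ParameterError(ValueError):
    """A tuning parameter is outside its legal range."""


@dataclass(frozen=True)
class WearProbabilitySeries:
    """Per-epoch wear probability in [0, 1], aligned with an EpochSeries."""

    r_wear: np.ndarray
    window_minutes: int = DEFAULT_WINDOW_MINUTES
    aggregation: str = "endpoints"

    def __post_init__(self) -> None:
        r = np.asarray(self.r_wear, dtype=float)
        object.__setattr__(self, "r_wear", r)
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("wear probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.r_wear.size)


def _window_epochs(series: EpochSeries, window_minutes: int) -> int:
    # thresholds are stated in minutes; convert to epochs rounding up
    return max(1, -(-int(window_minutes) // series.epoch_minutes))


def window_nonzero_fraction(series: EpochSeries, t: int, direction: str,
                            window: int = DEFAULT_WINDOW_MINUTES) -> float:
    """Fraction of nonzero epochs in the window anchored at epoch ``t``.

    ``direction='forward'`` uses epochs ``[t, t+w-1]``; ``'backward'`` uses
    ``[t-w+1, t]``. Windows are clipped to the recording and the clipped
    length is the denominator.
    """
    n = len(series)
    if not 0 <= t < n:
        raise IndexError(f"epoch index {t} out of range for series of length {n}")
    if window < 1:
        raise ParameterError("window must be at least 1 minute")
    w = _window_epochs(series, window)
    if direction == "forward":
        lo, hi = t, min(t + w - 1, n - 1)
    elif direction == "backward":
        lo, hi = max(t - w + 1, 0), t
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    seg = series.values[lo : hi + 1]
    return float(np.count_nonzero(seg) / seg.size)


def _endpoint_fractions(nonzero: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward- and backward-anchored nonzero fractions at every epoch, O(N)."""
    n = nonzero.size
    cum = np.concatenate(([0], np.cumsum(nonzero)))
    idx = np.arange(n)
    f_hi = np.minimum(idx + w, n)
    fwd = (cum[f_hi] - cum[idx]) / (f_hi - idx)
    b_lo = np.maximum(idx - w + 1, 0)
    bwd = (cum[idx + 1] - cum[b_lo]) / (idx + 1 - b_lo)
    return fwd, bwd


def wear_probability(series: EpochSeries, window: int = DEFAULT_WINDOW_MINUTES,
                     aggregation: str = "endpoints") -> WearProbabilitySeries:
    """Compute the per-epoch wear probability r_wear.

    ``aggregation='endpoints'`` (default) averages, at each epoch, the
    nonzero fraction of the window starting there (forward pass) and of the
    window ending there (backward pass). ``'covering'`` instead averages the
    fractions of every clipped window that covers the epoch, pooling the
    forward and backward enumerations.
    """
    if window < 1:
        raise ParameterError("window must be at least 1 minute")
    if aggregation not in _AGGREGATIONS:
        raise ParameterError(f"aggregation must be one of {_AGGREGATIONS}")
    nonzero = (series.values != 0).astype(np.int64)
    n = nonzero.size
    w = _window_epochs(series, window)
    fwd, bwd = _endpoint_fractions(nonzero, w)
    if aggregation == "endpoints":
        r = (fwd + bwd) / 2.0
    else:
        # each anchored window broadcasts its fraction to every epoch it
        # covers; accumulate with difference arrays, then normalise by the
        # number of covering windows
        total = np.zeros(n + 1)
        count = np.zeros(n + 1)
        idx = np.arange(n)
        f_hi = np.minimum(idx + w - 1, n - 1)
        b_lo = np.maximum(idx - w + 1, 0)
        for lo, hi, frac in ((idx, f_hi, fwd), (b_lo, idx, bwd)):
            np.add.at(total, lo, frac)
            np.add.at(total, hi + 1, -frac)
            np.add.at(count, lo, 1.0)
            np.add.at(count, hi + 1, -1.0)
        r = np.cumsum(total[:-1]) / np.cumsum(count[:-1])
    return WearProbabilitySeries(np.clip(r, 0.0, 1.0), int(window), aggregation)


def probability_labels(probs: WearProbabilitySeries, Tp: float) -> LabelSeries:
    """Threshold r_wear at T^p into the probability label L_p.

    Equality counts as wear: label 1 iff ``r_wear >= Tp``.
    """
    if not 0.0 <= Tp <= 1.0:
        raise ParameterError(f"T^p must lie in [0, 1], got {Tp}")
    return LabelSeries((probs.r_wear >= Tp).astype(np.int8), role="probability")
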