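"""Zero-run continuity criterion and the baseline classifiers.

Zero counts during true non-wear come in long unbroken runs; during wear
they are short and intermittent. The continuity label L_c marks an epoch
non-wear when the maximal consecutive-zero run containing it exceeds T^c
(default 10 minutes). The conventional "current method" (only runs longer
than 60 minutes are non-wear) and the raw >= 1.0 METs rule serve as
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probability import ParameterError
from .records import ClassifiedSeries, EpochSeries, LabelSeries, SEDENTARY_MIN_METS

DEFAULT_TC_MINUTES = 10
DEFAULT_CURRENT_MIN_RUN_MINUTES = 60


@dataclass(frozen=True)
class ZeroRunAnnotation:
    """Length of the maximal consecutive-zero run containing each epoch.

    ``run_length_at[t]`` is 0 for nonzero epochs; every epoch of one maximal
    run shares that run's length (in epochs).
    """

    run_length_at: np.ndarray

    def __len__(self) -> int:
        return int(self.run_length_at.size)

    def histogram(self) -> dict[int, int]:
        """Run-length -> number of maximal runs of that length."""
        lengths = self.run_lengths()
        uniq, counts = np.unique(lengths, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    def run_lengths(self) -> np.ndarray:
        """Lengths of the distinct maximal zero runs, in series order."""
        r = self.run_length_at
        z = r > 0
        rise = z & ~np.concatenate(([False], z[:-1]))
        return r[rise].astype(int)


def zero_run_lengths(series: EpochSeries) -> ZeroRunAnnotation:
    """Maximal-run decomposition of the zero-count indicator."""
    z = series.is_zero()
    n = z.size
    out = np.zeros(n, dtype=np.int64)
    bounded = np.concatenate(([False], z, [False]))
    starts = np.nonzero(bounded[1:-1] & ~bounded[:-2])[0]
    ends = np.nonzero(bounded[1:-1] & ~bounded[2:])[0]
    for s, e in zip(starts, ends):
        out[s : e + 1] = e - s + 1
    return ZeroRunAnnotation(out)


def _minutes_to_epochs(minutes: float, epoch_minutes: int) -> int:
    # thresholds are stated in minutes; convert rounding up
    return int(-(-minutes // epoch_minutes))


def continuity_labels(series: EpochSeries, Tc: float = DEFAULT_TC_MINUTES) -> LabelSeries:
    """Continuity label L_c: wear iff the containing zero run is <= T^c minutes.

    Nonzero epochs are always wear; equality counts as wear.
    """
    if Tc < 1:
        raise ParameterError("T^c must be at least 1 minute")
    tc_epochs = _minutes_to_epochs(Tc, series.epoch_minutes)
    runs = zero_run_lengths(series).run_length_at
    return LabelSeries((runs <= tc_epochs).astype(np.int8), role="continuity")


def _correct_wear_zeros(series: EpochSeries, wear: LabelSeries) -> np.ndarray:
    corrected = series.values.copy()
    corrected[series.is_zero() & wear.as_bool()] = SEDENTARY_MIN_METS
    return corrected


def classify_current(series: EpochSeries,
                     min_nonwear_run: float = DEFAULT_CURRENT_MIN_RUN_MINUTES,
                     strict: bool = True) -> ClassifiedSeries:
    """The conventional long-zero-run rule.

    Zero runs longer than ``min_nonwear_run`` minutes (``strict=True``; with
    ``strict=False`` runs of at least that length) are non-wear; every other
    epoch — including shorter zero runs — is wear, and wear-labeled zeros
    are restored to 1.0 METs.
    """
    if min_nonwear_run < 0:
        raise ParameterError("min_nonwear_run must be non-negative")
    thr = _minutes_to_epochs(min_nonwear_run, series.epoch_minutes)
    runs = zero_run_lengths(series).run_length_at
    nonwear = (runs > thr) if strict else (runs >= max(thr, 1))
    wear = LabelSeries((~nonwear).astype(np.int8), role="baseline")
    return ClassifiedSeries(series, wear, _correct_wear_zeros(series, wear),
                            metadata={"method": "current", "min_nonwear_run": min_nonwear_run,
                                      "strict": strict})


def classify_raw(series: EpochSeries) -> ClassifiedSeries:
    """No correction: wear iff the recorded value is at least 1.0 METs."""
    wear = LabelSeries((series.values >= SEDENTARY_MIN_METS).astype(np.int8),
                       role="baseline")
    return ClassifiedSeries(series, wear, series.values.copy(),
                            metadata={"method": "raw"})
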