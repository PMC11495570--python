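"""Domain types and CSV I/O for epoch-level activity records.

The package works on per-epoch activity-intensity series (METs at a fixed
epoch length, typically 1 minute) in which the value 0 — a "zero count" —
is ambiguous between motionless sitting and the device not being worn.
Self-reported non-wear intervals serve as ground truth for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Upper bound of the sedentary intensity band in METs.
SEDENTARY_MAX_METS = 1.5
#: Lower bound of the sedentary intensity band, also the value substituted
#: for zero counts reclassified as wear.
SEDENTARY_MIN_METS = 1.0


class FormatError(ValueError):
    """A file is missing required columns or is otherwise malformed."""


class GapError(ValueError):
    """Epoch timestamps are not regularly spaced."""


class ValidationError(ValueError):
    """A domain invariant is violated (negative intensity, bad interval...)."""


@dataclass(frozen=True)
class EpochSeries:
    """A contiguous, regularly sampled activity-intensity time series.

    Parameters
    ----------
    start_time
        Wall-clock timestamp of the first epoch.
    values
        Per-epoch intensity in METs; non-negative finite reals. An exact 0
        encodes a zero count.
    epoch_minutes
        Epoch length in minutes (default 1).
    """

    start_time: pd.Timestamp
    values: np.ndarray
    epoch_minutes: int = 1

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValidationError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("intensity values must be finite (no missing values)")
        if np.any(vals < 0):
            raise ValidationError("intensity values must be non-negative")
        if int(self.epoch_minutes) < 1:
            raise ValidationError("epoch_minutes must be a positive integer")
        object.__setattr__(self, "epoch_minutes", int(self.epoch_minutes))
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> pd.DatetimeIndex:
        """Epoch start timestamps."""
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(minutes=self.epoch_minutes)
        )

    @property
    def end_time(self) -> pd.Timestamp:
        """End of the recording span (exclusive)."""
        return self.start_time + pd.Timedelta(minutes=self.epoch_minutes * len(self))

    def is_zero(self) -> np.ndarray:
        """Boolean mask of zero-count epochs."""
        return self.values == 0.0

    def replace_values(self, values: np.ndarray) -> "EpochSeries":
        return EpochSeries(self.start_time, np.asarray(values, dtype=float), self.epoch_minutes)


@dataclass(frozen=True)
class BehaviorLog:
    """Self-reported non-wear intervals, half-open ``[start, end)``.

    Intervals are sorted, non-overlapping and non-adjacent; adjacent
    intervals are merged on construction.
    """

    intervals: tuple

    def __init__(self, intervals: Iterable) -> None:
        pairs = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in intervals]
        for s, e in pairs:
            if e <= s:
                raise ValidationError(f"interval end {e} is not after start {s}")
        pairs.sort()
        merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        for s, e in pairs:
            if merged and s < merged[-1][1]:
                raise ValidationError(
                    f"interval starting {s} overlaps interval ending {merged[-1][1]}"
                )
            if merged and s == merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        object.__setattr__(self, "intervals", tuple(merged))

    def __len__(self) -> int:
        return len(self.intervals)

    def total_minutes(self) -> int:
        return int(
            sum((e - s).total_seconds() for s, e in self.intervals) // 60
        )


@dataclass(frozen=True)
class LabelSeries:
    """Per-epoch binary wear (1) / non-wear (0) labels.

    ``role`` records the label's provenance: ``truth`` (behavior record),
    ``probability`` (L_p), ``continuity`` (L_c), ``synthesized`` (L_s) or
    ``baseline``.
    """

    labels: np.ndarray
    role: str = "truth"

    _ROLES = frozenset({"truth", "probability", "continuity", "synthesized", "baseline"})

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int8)
        if lab.ndim != 1 or lab.size < 1:
            raise ValidationError("labels must be a non-empty 1-D sequence")
        if not np.isin(lab, (0, 1)).all():
            raise ValidationError("labels must contain only 0 and 1")
        if self.role not in self._ROLES:
            raise ValidationError(f"unknown label role {self.role!r}")
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return int(self.labels.size)

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


@dataclass(frozen=True)
class ClassifiedSeries:
    """The outcome of a wear/non-wear classification of one record.

    ``corrected_values`` differs from the source values only at zero-count
    epochs whose final label is wear; those epochs are set to 1.0 METs (the
    sedentary minimum). Non-wear epochs keep their recorded value but are
    excluded from activity summaries.
    """

    source: EpochSeries
    wear: LabelSeries
    corrected_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        corr = np.asarray(self.corrected_values, dtype=float)
        object.__setattr__(self, "corrected_values", corr)
        if not (len(self.source) == len(self.wear) == corr.size):
            raise ValidationError("source, labels and corrected values must align")
        changed = corr != self.source.values
        legal = self.source.is_zero() & self.wear.as_bool()
        if np.any(changed & ~legal) or not np.allclose(corr[changed], 1.0):
            raise ValidationError(
                "corrected values may differ from the source only at wear-labeled "
                "zero counts, and only by substituting 1.0"
            )


def _align_labels(a: Sequence, b: Sequence, what: str = "labels") -> None:
    if len(a) != len(b):
        raise ValidationError(f"misaligned {what}: {len(a)} vs {len(b)} epochs")


DEFAULT_COLUMNS: Mapping[str, str] = {"timestamp": "timestamp", "mets": "mets"}


def _parse_times(raw: pd.Series) -> pd.DatetimeIndex:
    # HH:MM times get today's date attached by pandas; only regularity matters.
    try:
        return pd.DatetimeIndex(pd.to_datetime(raw, format="mixed"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from exc


def read_epoch_csv(path, column_map: Mapping[str, str] | None = None) -> EpochSeries:
    """Read an epoch CSV (``timestamp,mets`` by default) into an EpochSeries.

    The epoch length is inferred from consecutive timestamps; irregular
    spacing raises :class:`GapError` naming the first offending timestamp.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    for key in ("timestamp", "mets"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column {cols[key]!r} in {path}")
    times = _parse_times(df[cols["timestamp"]])
    mets = pd.to_numeric(df[cols["mets"]], errors="raise")
    if mets.isna().any():
        raise ValidationError("missing intensity values are not allowed")
    if len(times) > 1:
        deltas = np.diff(times.asi8)
        step = deltas[0]
        bad = np.nonzero(deltas != step)[0]
        if step <= 0:
            raise GapError(f"non-increasing timestamp at {times[1]}")
        if bad.size:
            raise GapError(f"irregular epoch spacing at {times[bad[0] + 1]}")
        epoch_minutes = step / 60e9
        if epoch_minutes != int(epoch_minutes) or int(epoch_minutes) < 1:
            raise GapError(f"epoch spacing {epoch_minutes} min is not a whole minute")
        epoch_minutes = int(epoch_minutes)
    else:
        epoch_minutes = 1
    return EpochSeries(times[0], mets.to_numpy(dtype=float), epoch_minutes)


def read_behavior_log(path) -> BehaviorLog:
    """Read a non-wear interval CSV with ``start,end`` columns."""
    df = pd.read_csv(path)
    for col in ("start", "end"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    starts = _parse_times(df["start"])
    ends = _parse_times(df["end"])
    return BehaviorLog(list(zip(starts, ends)))


def log_to_labels(log: BehaviorLog, series: EpochSeries) -> LabelSeries:
    """Convert a behavior log to per-epoch truth labels (0 = non-wear).

    An epoch is non-wear iff its start time lies inside a logged interval
    (half-open convention).
    """
    times = series.times
    labels = np.ones(len(series), dtype=np.int8)
    for s, e in log.intervals:
        if s < series.start_time or e > series.end_time:
            raise ValidationError(
                f"interval [{s}, {e}) lies outside the recording span "
                f"[{series.start_time}, {series.end_time})"
            )
        labels[(times >= s) & (times < e)] = 0
    return LabelSeries(labels, role="truth")


def labels_to_log(truth: LabelSeries, series: EpochSeries) -> BehaviorLog:
    """Inverse of :func:`log_to_labels`: non-wear label runs become intervals."""
    _align_labels(truth, series)
    lab = truth.labels
    times = series.times
    step = pd.Timedelta(minutes=series.epoch_minutes)
    intervals = []
    start = None
    for i, v in enumerate(lab):
        if v == 0 and start is None:
            start = times[i]
        elif v == 1 and start is not None:
            intervals.append((start, times[i]))
            start = None
    if start is not None:
        intervals.append((start, times[-1] + step))
    return BehaviorLog(intervals)


def write_classified_csv(path, classified: ClassifiedSeries,
                         label_p: LabelSeries | None = None,
                         label_c: LabelSeries | None = None) -> None:
    """Write a classified record as CSV.

    Columns: ``timestamp, mets, wear, corrected_mets`` plus ``label_p`` /
    ``label_c`` when the criterion labels are supplied.
    """
    src = classified.source
    out = pd.DataFrame(
        {
            "timestamp": src.times,
            "mets": src.values,
            "wear": classified.wear.labels,
            "corrected_mets": classified.corrected_values,
        }
    )
    if label_p is not None:
        out["label_p"] = label_p.labels
    if label_c is not None:
        out["label_c"] = label_c.labels
    out.to_csv(path, index=False)
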