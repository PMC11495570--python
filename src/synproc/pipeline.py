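"""End-to-end SynProC classification.

SynProC ("synthesize probability and continuity") declares an epoch wear
only when both criteria agree: the surrounding-window wear probability is at
or above the calibrated threshold T^p, and the consecutive-zero run
containing the epoch is no longer than T^c. Zero counts reclassified as
wear are corrected to 1.0 METs, the sedentary minimum; non-wear epochs keep
their recorded value but are excluded from summaries.
"""

from __future__ import annotations

import warnings

import numpy as np

from .continuity import DEFAULT_TC_MINUTES, continuity_labels
from .probability import DEFAULT_WINDOW_MINUTES, probability_labels, wear_probability
from .records import (
    SEDENTARY_MAX_METS,
    SEDENTARY_MIN_METS,
    ClassifiedSeries,
    EpochSeries,
    LabelSeries,
    ValidationError,
)
from .threshold import ThresholdModel, predict_threshold, sedentary_zero_rate


def synthesize(series: EpochSeries, Lp: LabelSeries, Lc: LabelSeries,
               corrected_value: float = SEDENTARY_MIN_METS) -> ClassifiedSeries:
    """Combine the two criterion labels into the final classification.

    The final label is the epoch-wise AND of L_p and L_c (for nonzero
    epochs L_c is always wear, so a noise spike inside a non-wear block is
    vetoed by L_p alone). Zero counts whose final label is wear are
    corrected to ``corrected_value`` METs.
    """
    if not (len(series) == len(Lp) == len(Lc)):
        raise ValidationError("criterion labels must align with the series")
    final = LabelSeries(Lp.labels & Lc.labels, role="synthesized")
    corrected = series.values.copy()
    corrected[series.is_zero() & final.as_bool()] = corrected_value
    return ClassifiedSeries(series, final, corrected)


def classify_synproc(series: EpochSeries, model: ThresholdModel | None = None,
                     window_minutes: int = DEFAULT_WINDOW_MINUTES,
                     aggregation: str = "endpoints",
                     Tc_minutes: float = DEFAULT_TC_MINUTES) -> ClassifiedSeries:
    """Run the full SynProC pipeline on one record.

    Computes the sedentary zero rate, derives T^p from the calibration
    ``model`` (the shipped default line if None), thresholds the wear
    probability into L_p, computes the continuity label L_c, and returns the
    synthesized classification. The rate, T^p and any high-rate warnings
    are recorded in ``metadata``.
    """
    if model is None:
        model = ThresholdModel()
    rate = sedentary_zero_rate(series)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        tp = predict_threshold(model, rate)
    probs = wear_probability(series, window=window_minutes, aggregation=aggregation)
    lp = probability_labels(probs, tp)
    lc = continuity_labels(series, Tc=Tc_minutes)
    out = synthesize(series, lp, lc)
    out.metadata.update(
        {
            "method": "synproc",
            "sedentary_zero_rate": rate,
            "Tp": tp,
            "Tc_minutes": Tc_minutes,
            "window_minutes": window_minutes,
            "aggregation": aggregation,
            "warnings": [str(w.message) for w in caught],
            "label_p": lp,
            "label_c": lc,
        }
    )
    return out


def sedentary_minutes(classified: ClassifiedSeries) -> int:
    """Total sedentary time: wear epochs with corrected value in [1.0, 1.5] METs."""
    v = classified.corrected_values
    sed = classified.wear.as_bool() & (v >= SEDENTARY_MIN_METS) & (v <= SEDENTARY_MAX_METS)
    return int(np.count_nonzero(sed)) * classified.source.epoch_minutes
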