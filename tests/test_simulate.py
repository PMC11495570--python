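"""Synthetic-day generator and zero-count augmentation."""

import numpy as np
import pytest
from scipy import stats

import synproc as sp
from synproc.records import SEDENTARY_MAX_METS, ValidationError
from synproc.simulate import CapacityError, ConfigError, truncated_geometric_pmf

from conftest import make_series


class TestGenerateDay:
    def test_pure_sedentary_no_zeros(self):
        cfg = sp.DayConfig(sedentary_fraction=1.0, zero_rate=0.0, nonwear_bouts=())
        series, log = sp.generate_day(cfg)
        assert len(series) == 420 and len(log) == 0
        assert (series.values >= 1.0).all() and (series.values <= 1.5).all()
        assert sp.sedentary_zero_rate(series) == 0.0

    def test_deterministic_under_seed(self):
        a, la = sp.generate_day(sp.DayConfig(seed=42))
        b, lb = sp.generate_day(sp.DayConfig(seed=42))
        np.testing.assert_array_equal(a.values, b.values)
        assert la.intervals == lb.intervals
        c, _ = sp.generate_day(sp.DayConfig(seed=43))
        assert not np.array_equal(a.values, c.values)

    def test_bouts_planted_exactly(self):
        series, log = sp.generate_day(sp.DayConfig(seed=1, nonwear_bouts=(45, 20)))
        assert log.total_minutes() == 65
        truth = sp.log_to_labels(log, series)
        assert (series.values[~truth.as_bool()] == 0.0).all()
        # bout zero runs are exactly the planted lengths (no merging with
        # sitting zeros across the bout boundary)
        runs = sp.zero_run_lengths(series).run_length_at
        bout_runs = {int(r) for r in np.unique(runs[~truth.as_bool()])}
        assert bout_runs == {45, 20}

    def test_sitting_runs_respect_max_run(self):
        series, log = sp.generate_day(sp.DayConfig(seed=2, zero_rate=0.4, max_run=10))
        truth = sp.log_to_labels(log, series)
        runs = sp.zero_run_lengths(series).run_length_at
        assert runs[truth.as_bool()].max() <= 10

    def test_oversized_bout_rejected(self):
        with pytest.raises(ConfigError):
            sp.generate_day(sp.DayConfig(duration_minutes=60, nonwear_bouts=(59,)))

    def test_run_length_distribution_matches_truncated_geometric(self):
        # long single-span day; run lengths should follow the configured pmf
        cfg = sp.DayConfig(duration_minutes=60000, sedentary_fraction=1.0,
                           zero_rate=0.25, zero_run_mean=2.5, max_run=10,
                           nonwear_bouts=(), seed=8)
        series, _ = sp.generate_day(cfg)
        lengths = sp.zero_run_lengths(series).run_lengths()
        observed = np.bincount(lengths, minlength=11)[1:]
        expected = truncated_geometric_pmf(2.5, 10) * observed.sum()
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.001


class TestAugmentZeroRate:
    def _day(self):
        series, log = sp.generate_day(sp.DayConfig(seed=3, zero_rate=0.15))
        return series, log, sp.log_to_labels(log, series)

    def test_identity_when_target_met(self):
        series, _, truth = self._day()
        rate = sp.sedentary_zero_rate(series)
        out = sp.augment_zero_rate(series, truth, rate, seed=0)
        np.testing.assert_array_equal(out.values, series.values)

    def test_exact_insertion_count(self):
        # 100 sedentary epochs, 10 zeros, target 0.25 -> 15 insertions
        vals = np.concatenate([np.zeros(10), np.full(90, 1.2)])
        series = make_series(vals)
        truth = sp.LabelSeries(np.ones(100, dtype=int))
        out = sp.augment_zero_rate(series, truth, 0.25, seed=1)
        assert int(out.is_zero().sum()) == 25
        assert sp.sedentary_zero_rate(out) == 0.25

    def test_saturation_and_capacity(self):
        vals = np.full(50, 1.2)
        series = make_series(vals)
        truth = sp.LabelSeries(np.ones(50, dtype=int))
        out = sp.augment_zero_rate(series, truth, 1.0, seed=1)
        assert out.is_zero().all()
        # non-wear truth makes every epoch ineligible
        nonwear = sp.LabelSeries(np.zeros(50, dtype=int))
        with pytest.raises(CapacityError) as exc:
            sp.augment_zero_rate(series, nonwear, 0.5, seed=1)
        assert exc.value.max_achievable == 0.0

    def test_only_sedentary_wear_epochs_touched(self):
        series, log, truth = self._day()
        out = sp.augment_zero_rate(series, truth, 0.5, seed=7)
        changed = out.values != series.values
        assert (out.values[changed] == 0.0).all()  # only zeroing, never un-zeroing
        eligible = (series.values > 0) & (series.values <= SEDENTARY_MAX_METS) \
            & truth.as_bool()
        assert not changed[~eligible].any()
        # non-wear bouts byte-identical
        assert (out.values[~truth.as_bool()] == series.values[~truth.as_bool()]).all()

    def test_achieved_rate_within_one_epoch_resolution(self):
        series, _, truth = self._day()
        S = int((series.values <= SEDENTARY_MAX_METS).sum())
        current = sp.sedentary_zero_rate(series)
        for target in (0.35, 0.45, 0.61):
            assert target >= current  # precondition of the augmentation
            out = sp.augment_zero_rate(series, truth, target, seed=11)
            achieved = sp.sedentary_zero_rate(out)
            assert target <= achieved <= target + 1.0 / S

    def test_misaligned_truth(self):
        series, _, _ = self._day()
        with pytest.raises(ValidationError):
            sp.augment_zero_rate(series, sp.LabelSeries(np.ones(3, dtype=int)), 0.5)


class TestBuildAugmentedCorpus:
    def _records(self, n=2):
        return [sp.generate_day(sp.DayConfig(seed=100 + i, zero_rate=0.2))
                for i in range(n)]

    def test_pattern_count(self):
        records = self._records(2)
        aug = sp.AugmentationConfig(target_rates=(0.4, 0.5, 0.6), reps_per_target=10)
        corpus = sp.build_augmented_corpus(records, aug)
        assert len(corpus) == 2 + 2 * 3 * 10
        originals = [p for p in corpus if p.target_rate is None]
        assert len(originals) == 2

    def test_reps_zero_gives_originals_only(self):
        corpus = sp.build_augmented_corpus(
            self._records(2), sp.AugmentationConfig(target_rates=(0.5,), reps_per_target=0))
        assert [p.target_rate for p in corpus] == [None, None]

    def test_byte_reproducible_under_seed(self):
        records = self._records(2)
        aug = sp.AugmentationConfig(target_rates=(0.4, 0.6), reps_per_target=3, seed=9)
        c1 = sp.build_augmented_corpus(records, aug)
        c2 = sp.build_augmented_corpus(records, aug)
        assert len(c1) == len(c2)
        for p, q in zip(c1, c2):
            assert p.series.values.tobytes() == q.series.values.tobytes()
            assert (p.source_id, p.target_rate, p.rep, p.seed) == \
                   (q.source_id, q.target_rate, q.rep, q.seed)

    def test_infeasible_targets_skipped(self):
        records = self._records(1)
        aug = sp.AugmentationConfig(target_rates=(0.1,), reps_per_target=5)
        corpus = sp.build_augmented_corpus(records, aug)  # below current rate
        assert len(corpus) == 1
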