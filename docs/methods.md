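# Methods

## Model and assumptions

The classifier targets one-day, epoch-level intensity records (METs, one
value per minute) from waist-worn accelerometers whose firmware emits
exactly 0 when no supra-threshold acceleration is seen in an epoch. Two
empirical regularities drive the design:

* during true wear, zero counts are *intermittent* — short runs embedded
  in activity — while during non-wear they are *sustained*;
* the surroundings of a worn epoch are active on the scale of an hour,
  while the surroundings of a non-worn epoch are not.

The continuity criterion encodes the first regularity (run length of the
containing zero run vs. `T^c`), the probability criterion the second
(mean nonzero fraction of the 60-minute windows before and after the
epoch vs. `T^p`). An epoch is wear only when **both** agree. The AND is
applied at every epoch, not only at zeros: a nonzero epoch always has
`L_c = 1`, so isolated noise spikes during non-wear can only be rejected
by the probability criterion. Zero counts relabelled wear are assigned
1.0 METs — the floor of the sedentary band — so that restored sitting
time enters sedentary summaries; this deliberately floors, and therefore
slightly underestimates, intensity during restored epochs.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `window_minutes` | 60 | min | sliding-window length for `r_wear` |
| `aggregation` | `endpoints` | — | how window fractions map to epochs (below) |
| `T^c` (`Tc_minutes`) | 10 | min | max zero-run length still considered wear |
| calibration line | slope −0.61, intercept 0.66 | — | `T^p` from `r_sed^zero`, clamped to [0, 1] |
| `huber_delta` | 1.35 | — | Huber loss constant for refitting the line (95% Gaussian efficiency) |
| `current_min_run_minutes` | 60, strict `>` | min | baseline rule boundary |
| sedentary band | 1.0–1.5 | METs | denominator of `r_sed^zero`; band counted by `sedentary_minutes` |

`r_sed^zero` divides the zero-count epochs by all epochs at ≤ 1.5 METs
*including the zeros themselves*, so it is computable on a raw record at
application time without truth labels. Rates above 0.70 trigger a
non-fatal `HighZeroRateWarning`: the calibrated `T^p` becomes so low
there that non-wear noise spikes start passing the probability criterion.

Thresholds are stated in minutes and converted to epochs rounding up, so
records with epochs longer than one minute reuse the same settings.

### Open choices made here

* **Window aggregation.** "One fraction per window, assigned to the
  epochs of that window" admits two readings. The default (`endpoints`)
  averages, per epoch, the fraction of the window *starting* there and of
  the window *ending* there. The alternative (`covering`) averages the
  fractions of every clipped window containing the epoch, forward and
  backward enumerations pooled. Both are implemented and oracle-tested;
  the choice is a config flag, not an assertion about the original
  implementation.
* **Edge handling.** Windows are clipped at the recording boundaries and
  the clipped length is the denominator — no padding, since ~7-hour
  recordings are far shorter than a full day and padding would bias edge
  probabilities downward.
* **Tie-breaks.** The optimal-threshold grid search (step 0.01 on [0, 1])
  returns the *smallest* accuracy maximizer, making calibration runs
  deterministic.
* **Equality conventions.** `r_wear = T^p` is wear; a zero run of exactly
  `T^c` is wear. The 60-minute baseline defaults to strict (`> 60`), with
  a `strict=False` flag for the `≥ 60` convention, since both circulate.
* **Accuracy formula.** One circulating formulation of "accuracy" equals
  the predicted-positive rate (TP+FP)/N. We compute standard accuracy
  (TP+TN)/N; `compute_metrics(..., printed_accuracy_variant=True)`
  exposes the other quantity for forensic comparison. Metrics with zero
  denominators are NaN markers, excluded (and counted) in corpus
  summaries.
* **Half-open intervals.** A behavior-log interval `[start, end)` covers
  an epoch iff the epoch's start time lies inside it, so minute-resolution
  reports never double-count boundary epochs.

## Synthetic data generator

`generate_day` emulates a working-hours office recording: block-structured
intensity (5–30-minute blocks, 70% sedentary at 1.0–1.5 METs, the rest
light 1.6–2.9 / moderate 3.0–5.9), planted all-zero non-wear bouts (45 and
20 minutes by default, positions random, recorded exactly in the returned
behavior log), and intermittent sitting zeros produced by a renewal
process: run lengths truncated-geometric (mean 2.5, max 10 epochs),
nonzero gaps geometric with mean tuned to the configured sitting zero
rate (default 0.30, inside the empirically observed 16–69% range). The
epochs immediately flanking a bout are kept nonzero so sitting runs never
merge with bout runs and the planted run lengths stay exact. One optional
noise-spike epoch per bout models accidental movement of the unworn
device (off by default).

`augment_zero_rate` raises a record's `r_sed^zero` to a target by zeroing
uniformly chosen nonzero sedentary wear epochs — insertion only, never
deletion, never touching non-wear bouts; the achieved rate lands within
one epoch's resolution above the target. `build_augmented_corpus` sweeps
each record across a target grid (record's own rate rounded up to 0.05,
through 0.70, step 0.05; 10 repetitions per target) with per-pattern
seeds derived from one corpus seed, so corpora are byte-reproducible.

What the generator does **not** emulate: physiological METs dynamics
(values are uniform within bands), posture, multi-day recordings, device
idiosyncrasies, or zero runs correlated with time of day. Passing tests
on generated days therefore demonstrate the algorithm's behavior under
the stated zero-count structure, not its field performance on any
particular device.

## Numerical choices

* Window fractions use cumulative sums (exact integer counts divided by
  clipped window lengths); the covering aggregation uses difference-array
  accumulation. Both are tested to 1e-12 against explicit enumeration.
* The calibration refit uses scikit-learn's `HuberRegressor`
  (`epsilon = huber_delta`, no regularisation, `tol = 1e-12`), which
  recovers noiseless lines to ~1e-10 and resists gross outliers where
  ordinary least squares does not.
* Degenerate inputs: a record with no epoch ≤ 1.5 METs has no defined
  `r_sed^zero` and raises; an all-zero record classifies as all non-wear;
  a single-epoch record is legal.

## Known limitations

* **Probability separation on short bouts.** Inside a 45-minute bout the
  60-minute windows still see ~15–37 minutes of surrounding activity, so
  bout-interior `r_wear` (≈ 0.4–0.6) often exceeds the calibrated `T^p`.
  Detection of such bouts rests on the continuity criterion; consequently
  a noise spike inside a *short* bout frequently survives (only `L_p` can
  veto a nonzero epoch). The veto is reliable once the zero context
  approaches the window length — e.g. a spike at the center of a
  90-minute block has `r_wear ≈ 0.27`, well under typical `T^p`.
* **Degenerate calibration days.** On roughly a third of generated
  protocol days no probability threshold beats all-wear labeling, so the
  grid search returns 0 — an uninformative calibration point. The shipped
  line should be refit when moving to a new device or population, using
  records where the search optimum is positive.
* Consecutive sedentary zeros longer than `T^c` during true wear (e.g.
  motionless reclining) are unavoidably classified non-wear; this is the
  known failure mode of the method, not of the implementation.
* The default calibration line was established for waist-worn,
  1-minute-epoch, METs-emitting devices on desk-working adults;
  transferring it unexamined to other devices, epoch lengths or
  populations is unsupported.
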