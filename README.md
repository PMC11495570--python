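# synproc

Wear/non-wear classification for epoch-level accelerometer records by
**syn**thesis of the **pro**bability and **c**ontinuity of zero counts.

## The problem

Waist-worn activity trackers summarise raw acceleration into per-epoch
intensity (METs at 1-minute epochs here). An epoch of exactly 0 — a *zero
count* — is ambiguous: it appears both when the device is off and during
motionless sitting. The conventional rule ("zero runs longer than 60
minutes are non-wear") restores sitting zeros well but misclassifies every
shorter non-wear bout as wear, inflating sedentary-time estimates; simply
shortening the run threshold instead throws away genuine sitting time.
This matters most for sedentary-behavior research on office workers,
older adults and patients, where short device removals are common and
sedentary minutes are the outcome of interest.

## The algorithm

For each epoch *n* of a record:

1. **Probability criterion.** Slide a 60-minute window forward and
   backward through the record; each pass yields the fraction of nonzero
   epochs `r_n^nonzero` seen from epoch *n*. Their mean is the wear
   probability `r_n^wear`. The label is

   `L_p^wear(n) = 1 if r_n^wear ≥ T^p else 0`

   where the threshold is calibrated per record-day from the zero-count
   rate during sedentary time, `r_sed^zero = (#zero epochs) / (#epochs ≤
   1.5 METs)`, via the robust-regression line

   `T^p = −0.61 · r_sed^zero + 0.66`.

2. **Continuity criterion.** With `C_n^zero` the length of the maximal
   consecutive-zero run containing epoch *n* (0 for nonzero epochs),

   `L_c^wear(n) = 1 if C_n^zero ≤ T^c else 0`, with `T^c = 10` minutes.

3. **Synthesis.** The final label is `L_s^wear = L_p^wear AND L_c^wear`.
   Zero counts reclassified as wear are corrected to 1.0 METs, the
   sedentary minimum; non-wear epochs keep their value but are excluded
   from summaries.

The package also provides the baselines (raw ≥ 1.0 METs rule and the
60-minute current method), a synthetic office-day generator with planted
non-wear bouts, a zero-count augmentation simulator for calibration
studies, and validation metrics (recall, specificity, precision,
accuracy) against behavioral records.

## Worked example

```python
import synproc as sp

cfg = sp.DayConfig(seed=7, nonwear_bouts=(45, 20), zero_rate=0.3)
series, log = sp.generate_day(cfg)          # 7-hour synthetic office day
truth = sp.log_to_labels(log, series)

print("bouts:", [(str(s.time())[:5], str(e.time())[:5]) for s, e in log.intervals])
print("sedentary zero rate:", round(sp.sedentary_zero_rate(series), 3))
result = sp.classify_synproc(series)
print("T^p:", round(result.metadata["Tp"], 3))
for name, c in [("raw", sp.classify_raw(series)),
                ("current", sp.classify_current(series)),
                ("synproc", result)]:
    m = sp.evaluate(truth, c.wear)
    print(f"{name:8s} accuracy={m.accuracy:.3f} specificity={m.specificity:.3f} "
          f"sedentary_minutes={sp.sedentary_minutes(c)}")
```

prints

```
bouts: [('09:33', '09:53'), ('11:40', '12:25')]
sedentary zero rate: 0.433
T^p: 0.396
raw      accuracy=0.817 specificity=1.000 sedentary_minutes=186
current  accuracy=0.845 specificity=0.000 sedentary_minutes=328
synproc  accuracy=0.993 specificity=1.000 sedentary_minutes=260
```

The day contains 43% zero counts during sitting plus a 20- and a 45-minute
non-wear bout. The raw rule drops every sitting zero (underestimating
sedentary time), the 60-minute rule restores them but swallows both bouts
as wear (specificity 0, overestimating), and the synthesis restores the
sitting zeros while rejecting both bouts — its 260 sedentary minutes are
closest to the truth of the generated day.

There is also a CLI:

```bash
synproc classify day.csv --method synproc --out out.csv
synproc validate --truth log.csv --pred out.csv --report report.json
```

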