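# ecgsync

Streaming conversion of single-channel ECG traces into TTL trigger trains
for prospective cardiac gating, plus everything needed to exercise it
offline: a seeded synthetic ECG generator with ground-truth annotations,
an independent whole-array reference engine, and an evaluation harness for
false-positive/false-negative rates and trigger-timing precision.

## How it works

The detector runs on a fixed 5 ms tick. Each tick it

1. estimates the ECG derivative as the raw two-point difference
   `ecg(t + tick) − ecg(t)` (not divided by the tick),
2. compares it with an adaptive threshold: a crossing outside the 20 ms
   refractory window registers an R-wave detection, re-arms the threshold at
   the crossing value, and updates the beat-period estimate
   `Tj = ti − ti−1` (`HR = 60/Tj`); otherwise the threshold decays by
   `thr ← thr·(1 − x)` with `x = 0.0014` by default (a literal
   `thr·exp(−thr·x)` variant is available as `decay_law=true_exponential`),
3. schedules the next TTL rising edge at the first tick strictly after
   `ti + (Tj − dtMP)` — `dtMP` selects the trigger phase and absorbs
   instrument delays — and
4. drops the TTL line low once it has been high for 25 ms.

Output stays low until two detections have established a period estimate.
Scheduled edges arriving while the line is still high are dropped, which is
exactly the "stuck-high" false-negative mode the evaluation layer reports.

## Layout

| module                | contents |
|-----------------------|----------|
| `ecgsync.detector_core` | `UniformSignal`, `EventSeries`, `DetectorConfig`, `DetectorState`; the per-tick `step`, `run_streaming`, and the independent `run_batch` oracle |
| `ecgsync.simulator`     | Gaussian-bump P-QRS-T generator with heart-rate variability, noise, sinusoidal baseline wander, and step/burst motion artifacts |
| `ecgsync.evaluation`    | edge/annotation matching, FP/FN/error rates, ex-post ideal-edge construction and timing statistics, overlay plotting |
| `ecgsync.io_cli`        | delimited-text signal/TTL/annotation formats, optional WFDB reader, YAML config, run manifests, `ecgsync` CLI |

## CLI

```bash
# emit a seeded fixture (ecg.csv + truth.csv + manifest.json)
ecgsync simulate --preset wander --seed 1 --beats 20 --out runs/sim

# ECG -> TTL (+ detections, edges, config snapshot)
ecgsync detect --ecg runs/sim/ecg.csv --dtmp 50 --out runs/det

# score a TTL trace against the annotations
ecgsync evaluate --ttl runs/det/ttl.csv --truth runs/sim/truth.csv \
    --ecg runs/sim/ecg.csv --dtmp 50 --out runs/eval

# or everything in one go
ecgsync pipeline --preset wander --seed 1 --out runs/all --plot
```

All numeric flags default to the `DetectorConfig` values; a flat YAML file
(`tick`, `decay_rate`, `refractory`, `pulse_width`, `dt_mp`, `decay_law`,
`warmup_policy`) can be passed with `--config`, with flags winning.

## Notes and caveats

* The exponential decay variant is implemented exactly as
  `thr·exp(−thr·x)`, i.e. with the threshold in the exponent, matching its
  printed definition even though the units are odd; pass
  `decay_law=first_order` (the default) for the production law.
* Evaluation excludes the first two cardiac cycles: before two detections
  no period estimate exists, so no compliant trigger can be emitted.
  Timing comparisons start one cycle later still, because the first
  scheduled edge inherits a warm-up period estimate.
* Detection times are invariant under positive amplitude scaling as long
  as the first tick's difference is non-zero (the threshold is seeded from
  the signal itself; an absolute floor of 1e-9 guards flat lead-ins).
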