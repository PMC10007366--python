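# pulsewave

Desk-scale reimplementation of a wrist wearable's complete PPG processing
chain: pulse-rate and SpO2 estimation from raw photoplethysmogram buffers,
ultra-short-term (30 s) pulse-rate-variability feature extraction, and binary
stress classification with an embedded-style flattened linear-SVM inference
path. A ground-truthed synthetic generator makes every stage testable without
hardware or dataset downloads.

It is written for signal-processing and ML engineers who want to prototype,
test or port this kind of on-device pipeline without the device.

## The pipeline

A 30 s buffer is acquired at an effective 50 Hz (200 Hz native rate with
4-sample averaging), i.e. 1500 samples. Then:

1. **DC removal** — a trailing moving average over 64 samples (the smallest
   power of two spanning one maximal heartbeat at 50 Hz) is subtracted from
   the input delayed by half the window.
2. **Band-pass FIR** — an equiripple linear-phase Parks–McClellan design with
   cut-offs 0.7–3.5 Hz (the 42–210 bpm pulse band), 111 taps at 50 Hz.
3. **Systolic peak detection** — streaming local-maxima search: a sample that
   exceeds its 7 preceding samples (the rising-edge span at 220 bpm) at a
   rising-to-falling monotony change is a candidate; candidates closer than
   the 220 bpm minimum spacing or weaker than half the running median of
   recent peaks are rejected.
4. **Pulse rate** — beat count × 2 for the 30 s window.
5. **SpO2** — from red/IR channel pairs via the ratio of ratios
   `R = (AC_red/DC_red) / (AC_ir/DC_ir)` and the quadratic calibration
   `SpO2 = aR² + bR + c` (defaults a = −45.060, b = 30.354, c = 94.845).
6. **PRV features** — interbeat intervals (ms) from peak locations, ectopic
   beats replaced by the window median when |z| > 3, then the frozen
   6-feature vector: mean IBI, IBI standard deviation, peak count, RMSSD,
   excess kurtosis, skewness.
7. **Stress classification** — a standard scaler + linear-kernel SVM trained
   with SMOTE balancing and stratified shuffle-split cross-validation,
   exported as four flat arrays (w, c, u, p) so one inference costs
   2d multiplications, 2d−1 additions and a single comparison:
   `x̄[i] = p[i](x[i] − u[i])`, label 1 iff `wᵀx̄ > c`.

## Worked example

```
$ pulsewave simulate --mean-bpm 72 --duration-s 30 --seed 1 --target-r 0.6 --out sim
wrote sim.csv (36 beats)

$ pulsewave train --seed 0 --out model.json
{"holdout": {"accuracy": 1.0, "f1": 1.0, "confusion": {"tn": 60, "fp": 0, "fn": 0, "tp": 60}}, "model": "model.json"}

$ pulsewave infer sim.csv model.json
{
  "window_s": 30.0,
  "quality": [],
  "pulse_rate_bpm": 72.00000000000153,
  "n_peaks": 36,
  "spo2_pct": 96.8,
  "R": 0.6034032457221608,
  "features": {
    "mean_ibi": 838.2857142856963,
    "std_ibi": 40.10598204655135,
    "no_of_peaks": 36.0,
    "rmssd": 60.09795924889795,
    "kurtosis_ibi": -0.3433522589872151,
    "skewness_ibi": -0.11617036319855098
  },
  "stress": 0
}
```

The simulated subject beats 36 times in 30 s, so the device rule (count × 2)
reports 72 bpm. The rendered red/IR pair was prescribed a ratio-of-ratios of
0.6; the pipeline measures R = 0.603 and maps it through the calibration
curve to SpO2 = 96.8%. The PRV features (mean IBI ≈ 838 ms, RMSSD ≈ 60 ms)
sit in the relaxed regime, and the flattened SVM labels the window
unstressed (`"stress": 0`).

Other subcommands: `vitals`, `spo2`, `features` (single-stage outputs),
`evaluate` (flat-array inference over a labeled feature table) and `export`
(print a model's w, c, u, p arrays). All accept `--seed`, and identical
flags always produce identical outputs.

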