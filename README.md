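# gazestab

Quantification pipeline for compensatory head-roll (gaze-stabilization)
responses to imposed sinusoidal body roll. From a per-trial angle time series
(thorax roll and head-relative-to-thorax roll, degrees, uniformly sampled) it
computes the response **gain** (Fourier amplitude ratio at the stimulus
frequency), **phase** (two estimators: cross-correlation lag and FFT angle
difference; 180° = perfect anti-phase compensation), the polar
**compensation error** ε = √(1 + r² + 2r·cosθ) (distance from the perfect
point (1, 180°)), and the **magnitude-squared coherence** between stimulus
and response. Condition-level aggregation provides medians, circular medians
of phase, median ± SEM of ε, 95% confidence ellipses of polar point clouds,
and non-parametric comparisons (paired Wilcoxon signed-rank, Wilcoxon
rank-sum, Kruskal–Wallis with Nemenyi post hoc), plus free-flight bout
duration / collision-rate metrics.

A seeded synthetic-trial generator produces stimuli (±30°, 2 or 6 Hz,
8 cycles at 1200 Hz, with quarter-cycle linear endpoint ramps) and responses
with known ground-truth gain/phase plus ~30 Hz wingbeat contamination,
~12 Hz head wobble and broadband noise, so the whole pipeline is testable
without recorded data. A simple two-delay (visual + mechanosensory)
first-order feedback simulator with an exact analytic frequency-response
oracle is included as a declared extrapolation.

## Layout

| module | contents |
|---|---|
| `gazestab.synthetic_data` | `StimulusSpec`, `ResponseModel`, `FeedbackModel`, `Trial`; stimulus/response/feedback-loop generation |
| `gazestab.preprocess` | marker-to-angle conversion, zero-phase 7th-order Butterworth low-pass (25 Hz cutoff), ramp-window exclusion |
| `gazestab.response_metrics` | per-trial gain, phase (xcorr + FFT), ε, coherence; `analyze_trial` composition |
| `gazestab.group_stats` | circular median, confidence ellipses, condition summaries, signed-rank / rank-sum / Kruskal–Wallis + Nemenyi, flight-bout metrics |
| `gazestab.pipeline`, `gazestab.cli` | `RunConfig` (YAML), end-to-end `run_pipeline`, fixture cohort, `gazestab` CLI |

## CLI

```sh
# one synthetic trial -> CSV (angles in degrees, metadata in '#' header lines)
gazestab simulate --freq 2 --amp 30 --gain 0.6 --phase 177.6 --seed 1 --out trial.csv

# per-trial metrics table
gazestab analyze --in trial.csv --out metrics.csv

# demo cohort (2 treatments x 2 lights x 2 frequencies, 32 trials)
gazestab fixtures --seed 0 --out-dir cohort/

# group comparisons from a metrics table + design table
gazestab compare --metrics cohort/metrics.csv --design cohort/design.csv --out stats.csv

# full simulate -> analyze -> compare run from a YAML config
gazestab run --config cohort/config.resolved.yaml --out-dir out/
```

All randomness is seeded; identical configs give byte-identical outputs.

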