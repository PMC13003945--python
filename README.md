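# djpls

Drop-jump biomechanics analysis and PLS regression, end to end: from raw
marker trajectories (250 Hz) and dual force-plate signals (1 kHz) to the
phase-specific variable set (contact time, jump height, reactive strength
index plus ~50 phase-tagged kinetic/kinematic predictors), and from there
to filtered, cross-validated partial least squares regression models with
VIP scores.

A first-class synthetic-data module generates dynamically consistent
drop-jump trials (plate force equals `m·(a_com + g)` at every sample, with
known contact time, jump height, joint-angle profiles and joint kinetics)
and tabular datasets with known latent structure, so the entire pipeline is
testable without any recorded data.

## Layout

| module | role |
| --- | --- |
| `djpls.synthetic_data` | synthetic trials + latent-structure PLS datasets, with ground truth |
| `djpls.signal_processing` | zero-lag Butterworth filtering, residual-analysis cutoff, timebase alignment |
| `djpls.events_phases` | contact/take-off/landing detection (20 N threshold), eccentric/concentric split at the COM minimum |
| `djpls.body_model` | 15-segment model: whole-body COM, Cardan joint angles, bottom-up inverse dynamics |
| `djpls.features` | outcomes + predictor computation, feature-table assembly (CSV with a units header row) |
| `djpls.pls_stats` | z-scoring, \|r\|>0.95 and VIF>10 filters, NIPALS PLS, 10-fold RMSECV/Q² selection, VIP, F-test p-values, noncentral-F power analysis |
| `djpls.pipeline_cli` | orchestration, `RunConfig` (YAML), the `djpls` CLI |

## CLI

```sh
# synthesize a 43-athlete cohort, analyze every trial, write the feature table
djpls simulate --n 43 --seed 1 --out out/sim        # add --write-trials for raw TRC/CSV

# run descriptive summary + the three PLS models (CT, Ht, RSI)
djpls analyze --features out/sim/features.csv --out out/reports

# or analyze raw trial directories (markers.trc + forces.csv + meta.json each)
djpls analyze --trials out/sim/trials --response rsi --out out/reports
```

Outputs: `descriptive_summary.csv` (mean/SD/max/min per variable),
`pls_report_{CT,Ht,RSI}.csv` (variable, component, VIP, weight), and
`metrics.json` (R²Y, Q², RMSECV, p-values, filter log). Runs are
deterministic under a fixed seed; `--config run.yaml` overrides any
`RunConfig` field (filter cutoff, force threshold, CV folds/seed,
thresholds, trial aggregation, leak-free vs global filtering).

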