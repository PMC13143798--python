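# volcap

A volumetric capnography analysis toolkit: from synchronized airflow/PCO₂
samples to segmented breaths, per-cycle ventilatory parameters, volumetric
capnograms with phase III slopes, static-bench sensor calibration, and
two-device statistical comparison — plus a seeded spontaneous-breathing
simulator that makes every stage testable without hardware.

## What it does

The pipeline input is a two-channel time series on a uniform 10 ms grid
(100 Hz): signed airflow in L/min (positive = expiration) and CO₂ partial
pressure in mmHg, stored as CSV with header `t_ms,flow_lpm,pco2_mmhg`.

| Module | Purpose |
|---|---|
| `volcap.signal_io` | `SampleSeries` record, CSV read/write, 0.5 ms → 10 ms window-mean downsampling of a native flow stream |
| `volcap.segmentation` | Breath-by-breath segmentation by flow reversal (Schmitt trigger with deadband + minimum phase duration, apnea cutoff, zero-crossing boundary refinement) |
| `volcap.metrics` | Per-cycle Ti, Te, Vi, Ve, ETCO₂, PEF and VCO₂/br (rectangular-rule flow·PCO₂/Patm integral) |
| `volcap.capnogram` | Expired-volume-vs-PCO₂ curve per expiration; phase III slope by OLS on the 40–80 % tidal-volume window; experimental phase II slope; across-cycle slope variability (CV %) |
| `volcap.calibration` | Linear static-bench calibration (measured on reference) with R², Fisher-z 95 % CI on R², 95 % prediction band; the canonical flow slope-correction factor 1.438; a seeded bench emulator (flow design 10 levels × 5 reps × 2 directions = 100 points; CO₂ design 11 levels × 5 flows × 3 reps = 165 points) |
| `volcap.comparison` | Unpaired two-sided Mann-Whitney U per parameter (exact enumeration for small tie-free samples, tie/continuity-corrected normal approximation otherwise), mean ± SD tables |
| `volcap.simulator` | Ground-truth-labeled spontaneous breathing: half-sine flow phases, sigmoid phase II + volume-linear phase III CO₂ morphology, cycle-to-cycle variability, Gaussian sensor noise, bit-for-bit seed reproducibility |

## CLI

Single entry point `volcap` with file-only round-trips and a JSON provenance
sidecar in every output directory. Exit codes: 0 success, 2 config error,
3 data-format error, 4 numeric/fit error.

```bash
# synthetic 60-breath record plus ground truth
volcap simulate --n-breaths 60 --seed 7 --out rec.csv --truth truth.csv

# cycles from flow reversal
volcap segment --in rec.csv --deadband 0.5 --min-phase-ms 150 --out cycles.csv

# per-cycle ventilatory parameters
volcap metrics --in rec.csv --patm 760 --out metrics.csv

# volumetric capnogram + phase III fit for one cycle (JSON sidecar with the fit)
volcap capnogram --in rec.csv --cycle 2 --window 0.40,0.80 --out capno.csv --plot capno.png

# static-bench calibration (CSV with reference,measured columns)
volcap calibrate --design flow --in bench.csv --out model.json

# Mann-Whitney comparison of two metrics tables (CSV + Markdown rendering)
volcap compare --a metrics_a.csv --b metrics_b.csv --out table.csv --markdown table.md

# end-to-end demo: simulate -> segment -> metrics -> slopes -> compare
volcap pipeline --seed 7 --n-breaths 20 --outdir demo/
```

`volcap simulate --config sim.yaml` accepts any `SimConfig` field as a YAML
key; `volcap pipeline --config pipe.yaml` takes `simulate:` and `pipeline:`
sections (`PipelineConfig` keys: `dt_ms`, `invert_flow`, `patm_mmhg`,
`deadband_lpm`, `min_phase_ms`, `apnea_ms`, `slope3_window`, `columns`).

## Library example

```python
from volcap import SimConfig, simulate, segment, metrics_for_record
from volcap import build_capnogram, fit_slope3, slope3_variability

series, truth = simulate(SimConfig(n_breaths=30, seed=1))
cycles = [c for c in segment(series) if c.complete]
table = metrics_for_record(series, cycles, patm=760.0)
fits = [fit_slope3(build_capnogram(series, c)) for c in cycles]
print(table[["ti_s", "te_s", "ve_ml", "etco2_mmhg", "vco2_ml"]].describe())
print(slope3_variability(fits))
```

## Conventions worth knowing

- Positive flow = expiration; use `invert_flow` if your recording is the
  opposite polarity.
- Integrals use the left rectangular rule at the record's own `dt` (the
  acquisition firmware's fixed-step convention); flow L/min → mL/ms via 1/60.
- ETCO₂ is PCO₂ at the sample of maximal cumulative expired volume, ties to
  the earliest such sample.
- Ti/Te are last-minus-first sample times of each phase.
- Phase III window bounds are inclusive on sample volumes (no interpolation
  onto the exact 40 %/80 % volumes).
- `r²` of a zero-variance response is 0 by convention (with a warning).
- Default Patm is 760 mmHg; no BTPS/ATPS correction is applied.

## Tests and acceptance report

```bash
python -m pytest -q tests/          # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` re-runs the seven acceptance criteria from scratch
(closed-form VCO₂/br, simulator parameter recovery, slope III window
fidelity and variability, segmentation conservation, calibration recovery,
Mann-Whitney correctness, sampling-rate robustness) and prints the measured
quantities with a PASS/FAIL verdict per criterion. There are no named
numeric acceptance targets, so the JSON written to `--out` is an empty
object; the printed report carries the numbers.
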