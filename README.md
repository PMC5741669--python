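# varivent

Toolkit for analysing variable mechanical ventilation experiments in small
animals. It covers the full computational chain of a variable tidal-volume
(V_T) study:

- **vtgen** — breath-to-breath Gaussian V_T sequences at a set coefficient of
  variation (CV), plus volume-controlled flow/volume waveforms.
- **simulator** — forward simulation of airway pressure from the linear
  equation of motion (`Paw = E·V + R·V̇ + P0`), with an optional parallel
  second compartment to emulate time-constant inhomogeneity.
- **mechanics** — per-breath ordinary-least-squares estimation of elastance
  E, resistance R, and pressure offset P0 from pressure/flow/volume traces.
- **morphometry** — mean linear intercept (Lm), the moment-ratio airspace
  heterogeneity statistic D2 (= E[d³]/E[d²]), and the homogeneity index
  1/β = Lm/D2, plus a calibrated synthetic airspace-sample generator.
- **qpcr** — 2^−ΔΔCt relative expression with triplicate handling, 36B4
  housekeeping normalization, and group-mean calibration.
- **stats** — paired t, balanced two-way repeated-measures (split-plot)
  ANOVA, one-way ANOVA, Kruskal–Wallis with Dunn's pairwise rank tests,
  Holm–Šídák step-down adjustment, Spearman correlation, Bonferroni level
  splitting, exact noncentral-t power/sample-size analysis, and per-animal
  percent-change tables.
- **cohort** — a synthetic-cohort generator (one non-ventilated control
  group plus four ventilated groups at CV 0/15/22.5/30%, n = 7 each) and an
  end-to-end `run_study` driver that chains every stage and emits report
  tables.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (power analysis,
generator calibration, estimator recovery, morphometry identities, type-I
error simulations, end-to-end determinism).

## CLI

```sh
# generate a 1200-breath V_T sequence at 22.5% CV
varivent vtgen --mean-vt 6 --cv 22.5 --n 1200 --seed 1 --out seq.csv

# fit E/R/P0 to a recorded signal (columns: time_s, paw_cmH2O, flow_mL_s, vol_mL)
varivent mechanics fit signal.csv --per-breath --agg median --out fit.json

# per-animal Lm / D2 / 1/beta from long-format intercepts
varivent morpho compute diameters.csv --form moment --out morpho.csv

# sample-size for a two-sided two-sample t-test (exact noncentral t)
varivent stats power --d 2.21 --alpha 0.008 --power 0.8

# repeated-measures ANOVA on a long cohort CSV
varivent stats rm-anova cohort.csv --dv E --out results.json

# full synthetic study
varivent run --config study.json --seed 7 --out results/
```

## Notes

- D2 is computed in the self-consistent moment form by default
  (`E[d³]/E[d²]`, identical to `Σd³/Σd²` on raw intercepts); the literal
  two-factor product form is available via `form="literal"` for comparison —
  it returns `2μ` for perfectly uniform airspaces and is retained only to
  document that discrepancy.
- Generated V_T sequences are rescaled to the nominal mean by default
  (`normalize_mean=True`), holding delivered mean V_T and minute ventilation
  at their targets; clipping is at ±3 SD with a positivity floor at 10% of
  the mean, both configurable.
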