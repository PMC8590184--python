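# cgmrisk

Temporal risk profiling of hypoglycemia from continuous glucose monitoring
(CGM) data.

Children with congenital hyperinsulinism (HI) — and, as a contrast, those
with idiopathic ketotic hypoglycemia (IKH) — suffer recurrent hypoglycemia
whose *timing* matters clinically: the pre-waking early hours (3 AM–7 AM)
combine high cerebral glucose demand with suppressed counter-regulation, so
knowing *when* in the day hypoglycemia concentrates directs monitoring and
treatment. `cgmrisk` is for clinical researchers working with
Dexcom-style CGM exports who want that temporal phenotype quantified
reproducibly.

## What it computes

Given traces of glucose readings $g_t$ at nominal 5-minute epochs, a
**hypoglycemia event** is a maximal run of consecutive readings with
$g_t < \theta$ (default $\theta = 3.5$ mmol/L; a gap $> 7.5$ min breaks a
run). Each reading stands for one epoch, so event duration is
$5 \times (\text{number of below-threshold readings})$ minutes.

Monitored and hypoglycemic minutes are binned by clock hour, and any
half-open clock window $W$ (wrapping midnight if needed) is summarised by

- percent time hypoglycemic inside/outside:
  $p_W = 100\,\frac{\text{hypo min in } W}{\text{monitored min in } W}$,
- the share of all hypoglycemic minutes inside $W$ versus its expected
  share $100\,|W|/24$,
- the risk ratio $p_W / p_{\bar W}$, and
- Pearson chi-square tests on the inside/outside × hypo/not-hypo minute
  table $\chi^2 = N(ad-bc)^2/((a{+}b)(c{+}d)(a{+}c)(b{+}d))$, plus a
  calibrated variant that counts event starts rather than minutes.

Subgroup comparisons (age ≷ 10 months, mutation status, medication,
diagnosis), Mann–Whitney U for continuous variables, and a threshold sweep
(3.9 / 3.5 / 3.0 mmol/L) round out the analysis. A synthetic cohort
generator — a two-state semi-Markov process with an AR(1) normoglycemic
baseline, lognormal event durations, truncated-normal nadirs, patient
frailty and a configurable early-hours hazard multiplier — provides ground
truth for end-to-end validation.

## Worked example

```python
from cgmrisk import HypoglycemiaTemporalModel, SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_patients=23, seed=7)          # HI-like synthetic cohort
traces, records, truth = simulate_cohort(cfg)
model = HypoglycemiaTemporalModel(traces, metadata=records,
                                  thresholds=[3.9, 3.5, 3.0])
results = model.fit()
print(results.summary())
```

prints

```
Hypoglycemia temporal risk analysis
===================================================
Patients:                 23
Threshold:                < 3.5 mmol/L
Monitored minutes:        207,635
Hypoglycemic minutes:     7,040 (3.4%)
Events:                   217 (mean 9.4/patient, SD 8.6)
Event duration (min):     mean 32, SD 42
Event nadir (mmol/L):     mean 3.2, SD 0.29
Prolonged events (>30 min): 66

Window early hours [03:00-07:00]
  inside:  2,230/34,580 min (6.4%)
  outside: 4,810/173,055 min (2.8%)
  hypo-minute share inside: 31.68% (expected 16.7%)
  risk ratio: 2.32   tendency: +
  minute chi2(1) = 1184.7, p = 1.31e-259
  event-start chi2(1) = 25.8, p = 3.85e-07
...
Threshold sweep
  < 3.9 mmol/L: 632 events, 11,050 hypo min, share inside 26%
  < 3.5 mmol/L: 217 events, 7,040 hypo min, share inside 32%
  < 3.0 mmol/L: 63 events, 815 hypo min, share inside 39%
```

Reading it: this simulated HI-like cohort spent 3.4% of monitored time
below 3.5 mmol/L; 6.4% of early-hours time was hypoglycemic versus 2.8%
of the rest of the day (risk ratio 2.32, close to the generator's
configured 2.5× onset hazard), and 31.68% of all hypoglycemic minutes fell
in a window covering 16.7% of the day. Lowering the threshold concentrates
the remaining hypoglycemia further into the early hours (26% → 39% share).
`results.plot_hourly()` draws the percent-per-hour bar chart with the
window highlighted.

Real data enter the same way via
`HypoglycemiaTemporalModel.from_csv([...], metadata_path=..., dialect="clarity")`,
or through the CLI:

```sh
cgmrisk parse export.csv --dialect clarity --patient-id P01 --out p01.csv
cgmrisk profile p01.csv ... --threshold 3.5 --window 03:00-07:00 --out out/
cgmrisk sweep p01.csv ... --thresholds 3.9,3.5,3.0
cgmrisk run --config run.yaml     # full report bundle
```

## Layout

| module              | contents                                              |
|---------------------|-------------------------------------------------------|
| `cgmrisk.io`        | CSV dialects, units, exclusion intervals, demographics |
| `cgmrisk.events`    | episode detection, prolonged events, cohort statistics |
| `cgmrisk.profiles`  | hourly binning, clock windows, threshold sweep         |
| `cgmrisk.stats`     | chi-square, Mann–Whitney U, subgroup comparisons       |
| `cgmrisk.simulate`  | synthetic cohorts with ground truth, recovery checks   |
| `cgmrisk.model`     | `HypoglycemiaTemporalModel` / `TemporalRiskResults`    |
| `cgmrisk.pipeline`  | YAML-driven full-analysis report bundle                |
| `cgmrisk.cli`       | `cgmrisk` command-line tool                            |

See `docs/methods.md` for the model, its assumptions and limitations.
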