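# akialert

Simulation and analysis engine for a randomized trial of electronic acute
kidney injury (AKI) alerts in hospitalized adults.

Electronic AKI alerts watch the stream of inpatient serum-creatinine (SCr)
results, flag probable AKI the moment the KDIGO creatinine criteria are
met, and page the treating clinician with a care bundle.  Whether that
changes patient outcomes is a trial question; answering it requires a stack
of computational machinery that this package implements end to end:

* **`akialert.kdigo`** — KDIGO creatinine-criteria detection and staging
  over irregular longitudinal SCr series, plus CKD-EPI eGFR.  AKI is an
  increase in SCr ≥ 0.3 mg/dL within 48 h, or SCr ≥ 1.5 × the lowest SCr
  of the previous 7 days (the rolling baseline).  Stages: 1 for a 1.5–1.9×
  rise (or the 0.3 mg/dL rule), 2 for 2.0–2.9×, 3 for ≥ 3.0×, SCr ≥ 4.0
  mg/dL, or initiation of kidney replacement therapy.
* **`akialert.alerts`** — trial eligibility screening (seven exclusions,
  e.g. baseline eGFR < 15 mL/min/1.73 m², baseline SCr < 0.5 mg/dL, stay
  < 24 h), seeded 1:1 randomization within four strata (medical/surgical ×
  ICU/ward; stratum *k* draws from a generator seeded 20180101 + *k*), and
  templated alert messages capped at three per admission.
* **`akialert.outcomes`** — the trial's outcome definitions.  Primary:
  maximum change in eGFR within 7 days of randomization,
  Δ = eGFR_AKI − min eGFR_7d, with eGFR imputed to 0 on death; relative
  form Δ / eGFR at randomization.  Secondary mortality/dialysis/progression
  outcomes and 2/3/7-day care-process flags.
* **`akialert.stats`** — two-proportion risk differences in percentage
  points with Wald 95% CIs and Pearson χ² p-values, Mann-Whitney U (exact
  permutation for small samples, tie-corrected normal approximation
  otherwise), Hodges-Lehmann shift estimates with rank-sum-inverted CIs,
  univariate logistic subgroup analysis with interaction, and the classical
  two-sample power formula
  n = 2σ²(z₁₋α/₂ + z₁₋β)²/Δ².
* **`akialert.synth`** — a synthetic EHR generator producing admissions
  with controllable AKI incidence (default 1.4/100 admissions), stage mix
  (50/25/25%), mortality/dialysis rates, and arm-dependent care-process
  event rates, with exact per-patient ground truth.
* **`akialert.io` / `akialert.cli`** — CSV tables (ISO-8601 timestamps,
  µmol/L auto-conversion) and the `akialert` command with subcommands
  `simulate`, `screen`, `outcomes`, `analyze`, `run`.

## Worked example

```python
from akialert import LabSeries, Demographics, detect_aki, egfr

series = LabSeries.from_arrays([0, 36, 60], [0.8, 1.1, 1.7])
ep = detect_aki(series, Demographics(age=60, sex="male"))
print(ep.onset_time, ep.criterion, ep.baseline_scr, round(ep.egfr_at_aki, 1))
```

prints `36.0 delta048 0.8 72.6`: the 1.1 mg/dL value at +36 h is a rise of
exactly 0.3 mg/dL above the 48-hour minimum, so detection fires there (the
delta criterion), the frozen baseline is the 7-day minimum 0.8 mg/dL, and
the eGFR at AKI for a 60-year-old man is 72.6 mL/min/1.73 m².

End-to-end on a synthetic cohort:

```bash
akialert run --seed 5 --out results/demo
```

writes `assignments.csv` (stratum, arm, seed, draw index or exclusion
reason for every detected episode), `outcomes.csv` (one row per randomized
patient), `analysis.csv` (per-outcome per-arm counts, risk difference with
95% CI and p-value, or median (IQR) with Hodges-Lehmann difference), a
throttled `messages.log`, and `run_log.json` with the config hash and
Figure-style patient accounting.

The table arithmetic itself is a one-liner:

```python
from akialert import ContingencyCounts, risk_difference_ci
est = risk_difference_ci(ContingencyCounts(927, 1123, 670, 1085))
print(round(est.difference, 1), round(est.ci_low, 1), round(est.ci_high, 1))
# 20.8 17.1 24.4
```

## Layout

```
src/akialert/     kdigo.py alerts.py outcomes.py stats.py synth.py
                  io.py config.py pipeline.py cli.py
tests/            unit, property and acceptance tests
scripts/          acceptance.py
docs/methods.md   models, conventions, and design notes
```
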