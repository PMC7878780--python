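# metsmarkov

Multistate modelling of metabolic-syndrome progression and its cardiovascular
sequelae from panel-observed screening cohorts.

Community screening programmes observe a participant's metabolic state only at
irregular visits, while cardiovascular events and deaths arrive with exact
dates from registry linkage. `metsmarkov` is a Python package for
epidemiologists and biostatisticians analysing such data. It implements:

* the **refined MetS-related classification (RMRC)** from raw biomarkers:
  free of metabolic disorder (FMD, no positive criterion), mild metabolic
  disorder (MMD, 1–2 criteria) and metabolic syndrome (MetS, ≥3 of the five
  harmonised criteria — central obesity, high triglycerides, low HDL, elevated
  blood pressure, elevated fasting glucose — with treatment history counting
  toward the corresponding criterion);
* a **six-state continuous-time Markov model** of the natural course:

  ```
        FMD (1) <──> MMD (2) ──> MetS (3)        (MetS entered only via MMD;
          │            │            │             no regression out of MetS)
          └────────────┼────────────┘
                       v
                    CVD (4) ──> CVD death (5)
          (every living state) ──> other-cause death (6)
  ```

  with transition intensities in proportional-hazards form

  λ<sub>rs</sub>(age, sex) = λ⁰<sub>rs</sub> · exp(β<sup>age</sup><sub>g</sub>(age − age₀) + β<sup>sex</sup><sub>g</sub>·1[male]),

  eleven baseline intensities and per-transition (age, sex) rate-ratio pairs,
  the four other-cause-death transitions sharing one pooled pair
  (27 parameters; baselines refer to a female aged age₀ = 50 by default);
* the **panel likelihood**: interval-censored RMRC transitions through
  P(t) = exp(Qt), exactly dated CVD onsets and deaths through
  transition-probability × intensity terms, censoring of event-free
  survivors — maximised with an analytic gradient (eigendecomposition of the
  living-metabolic block with the divided-difference matrix), observed
  information by differentiating that gradient;
* **model comparison** by likelihood-ratio test (severity-specific versus
  common CVD incidence), **cumulative-risk prediction** (hitting probability
  of CVD, probability of CVD death, by age and sex), and
* a **cohort simulator** generating trajectories, screens and registry-style
  event dates under the same conventions the likelihood assumes, so every
  stage is testable by parameter recovery without any cohort download.

## Worked example

```python
from metsmarkov import (CohortSpec, generate_cohort, compile_cohort, fit,
                        likelihood_ratio_test, report_tables, cumulative_risk)

spec = CohortSpec(n_subjects=5000, seed=20210211)   # reference scenario
cohort = generate_cohort(spec)
compiled = compile_cohort(cohort.histories)

full = fit(compiled)
reduced = fit(compiled, variant="equal_cvd_risk", compute_vcov=False)
lrt = likelihood_ratio_test(full, reduced)

print(report_tables(full)[0])
print(f"LRT equal-CVD vs full: chi2({lrt.df}) = {lrt.statistic:.1f}, "
      f"p = {lrt.p_value:.3g}")
risk = cumulative_risk(full.params_hat, 3, "cvd_death", 65, "male", 10.0)
print(f"10-year CVD-death risk from MetS, male aged 65: {risk.risk[-1]:.3f}")
```

prints (abridged):

```
Baseline transition intensities (% per year, female, age 50)
transition        estimate  95% CI
fmd_mmd              42.18  (39.27, 45.32)
mmd_fmd              29.67  (27.37, 32.17)
mmd_mets              6.90  (6.03, 7.88)
fmd_cvd               1.07  (0.59, 1.93)
mmd_cvd               5.12  (4.31, 6.07)
mets_cvd             20.04  (17.81, 22.54)
cvd_cvd_death         0.47  (0.19, 1.19)
...
fmd_mmd       sex           1.36  (1.22, 1.52)
mmd_fmd       sex           0.64  (0.56, 0.73)
...
LRT equal-CVD vs full: chi2(2) = 391.6, p = 9.19e-86
10-year CVD-death risk from MetS, male aged 65: 0.153
```

Reading the output: this synthetic cohort was generated under the package's
reference intensities (44.82 %/yr FMD→MMD, 29.11 %/yr back, 6.15 %/yr
MMD→MetS, CVD incidence 1.62/4.74/20.22 %/yr by severity, CVD case fatality
6.1 per 1,000/yr), and the refit recovers them within sampling error at
n = 5,000 — e.g. 42.18 (39.27, 45.32) %/yr for FMD→MMD. The likelihood-ratio
test overwhelmingly rejects the model in which all three metabolic states
carry the same CVD risk, reproducing the qualitative severity gradient the
model is built to quantify.

The same pipeline is available from the shell:

```bash
metsmarkov simulate --spec docs/example_cohort.yaml --out panel.csv --truth truth.yaml
metsmarkov fit      --data panel.csv --variant full --out fit.json
metsmarkov predict  --params fit.json --start mets --target cvd-death \
                    --age 65 --sex male --horizon 10 --out curve.csv
metsmarkov classify --in screens.csv --out states.csv
metsmarkov pipeline --outdir results/        # simulate -> fit -> LRT -> curves
```

## Layout

| module | contents |
| --- | --- |
| `metsmarkov.rmrc` | five-criteria evaluation, treatment overrides, RMRC staging |
| `metsmarkov.states` / `model` | state space, topology, generator Q, P(t)=exp(Qt) |
| `metsmarkov.likelihood` | panel observations, validation, fast log-likelihood + gradient |
| `metsmarkov.estimation` | MLE (L-BFGS-B), model variants, LRT, rate/RR tables |
| `metsmarkov.simulate` | trajectory + observation simulator, biomarker synthesis |
| `metsmarkov.predict` | cumulative-risk curves, formatted reports |
| `metsmarkov.recovery` | simulate-and-refit calibration harness |

See `docs/methods.md` for the model's assumptions, conventions and
limitations.
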