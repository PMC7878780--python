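# Methods notes

## Model

A subject moves through six states: three living metabolic states defined by
the refined MetS-related classification — FMD (no positive criterion), MMD
(1–2), MetS (≥3 of five harmonised criteria) — plus incident CVD, death from
CVD, and death from other causes (OCD). The process is a time-homogeneous
continuous-time Markov chain given the covariates, with eleven allowed
transitions: FMD↔MMD, MMD→MetS, each living metabolic state →CVD, CVD→CVD
death, and every living state →OCD. Two structural restrictions encode the
natural-course interpretation: MetS can only be entered from MMD (never
directly from FMD), and regression out of MetS is not modelled — observed
regressions are attributed to intervention rather than natural course and are
carried forward as MetS by the data loader (the retain-as-MetS rule, on by
default).

Covariates act proportionally on each intensity,

    lambda_rs(age, sex) = lambda0_rs * exp(beta_age_g * (age - age_ref)
                                           + beta_sex_g * male),

with one (beta_age, beta_sex) pair per transition except the four OCD exits,
which share a pooled pair. The baseline intensities refer to a female of age
`age_ref`; no published convention fixes that reference, so the package makes
it explicit (default 50 years) and carries it through all I/O, so a simulation
truth and a fit are always comparable. Whether OCD-from-CVD shares the pooled
OCD covariate pair was genuinely open; it does by default (it is a mortality
process like the others and the alternative adds two weakly identified
parameters on the rarest stratum).

Full model: 11 log-intensities + 8×2 covariate effects = 27 free parameters.
Variants tie the three CVD baselines (`equal_cvd_risk`, −2 df, matching the
conventional 2-df comparison of severity-specific versus common CVD risk) or
additionally their covariate pairs (`equal_cvd_risk_shared_cov`, −6 df).

## Classification

Thresholds are applied exactly as written: waist ≥ 80 cm (women) / 90 cm
(men), triglycerides ≥ 150 mg/dL, HDL < 50/40 mg/dL (women/men), SBP ≥ 130 or
DBP ≥ 85 mmHg, fasting glucose ≥ 100 mg/dL; values at a "≥" cutoff are
positive, at a "<" boundary negative. Treatment for hypertension, diabetes or
hyperlipidemia forces the corresponding criterion positive; hyperlipidemia
treatment maps to the triglyceride criterion only (the treated category is
"hyperlipidemia", a single entity), with an opt-in flag to cover low HDL as
well. "MetS" means ≥3 positive criteria, exposed as a configurable constant.
A missing biomarker without a covering treatment flag is a hard error naming
the criterion; a permissive mode counts only observed criteria and flags the
record, mirroring the practice of excluding incomplete screens.

## Likelihood

RMRC states are panel-observed; CVD onset and deaths carry registry dates;
a censor record marks a subject alive and event-free at end of follow-up.
Contributions per interval from state r over dt, with P(t) = exp(Qt):

* panel state s: log P[r,s](dt);
* exact CVD onset: log Σ_m P[r,m](dt)·λ_{m,CVD}, m over living metabolic
  states;
* exact death d before any CVD record: log Σ_m P[r,m](dt)·λ_{m,d}, m over
  living metabolic states — because events are exactly dated, a subject with
  no CVD record cannot have passed through CVD, so paths through state 4 are
  excluded (summing over all living states would understate the information
  that no onset occurred);
* censoring from a metabolic state: log Σ_{m∈{1,2,3}} P[r,m](dt), the
  probability of being alive *and event-free* (same registry-completeness
  argument);
* within the CVD track the chain is scalar (two competing exits), so survival
  and death densities are computed directly from the hazards.

A sensitivity switch (`events_as_panel=True`) treats events as panel-observed
at their recorded times instead.

Age conventions. Age is piecewise constant: within each metabolic-track
interval it is fixed at the interval's start (exact under annual screens,
a documented approximation when screens are missed), and within the CVD track
it refreshes at yearly anniversaries of onset (CVD survival intervals
routinely span years, and the scalar hazards make the exact piecewise
treatment free). Anchoring the CVD-track refresh at onset rather than at
calendar entry keeps the likelihood invariant to time-origin shifts. The
simulator uses the same conventions, so simulation and inference agree
exactly under the default observation design.

Caching/rounding tolerances: ages are rounded to whole years and interval
lengths to 1/365 y for grouping, collapsing a cohort's intervals to a few
hundred weighted terms per covariate cell; the induced rate perturbation is
below 0.3 % for every default effect size and mean-zero to first order.

Fast path. The living-metabolic block is a 3×3 sub-generator A whose
exponential equals the corresponding block of exp(Qt) (no return from the
illness/death states), computed by batched eigendecomposition; its parameter
derivatives use the divided-difference (Loewner) matrix,
dP = V((V⁻¹ dA V) ∘ F)V⁻¹ with F_ij = (e^{w_i t} − e^{w_j t})/(w_i − w_j).
The block's eigenvalues are real and almost surely distinct (the 1↔2 exchange
block symmetrises; the MetS exit rate is a third, separate eigenvalue); near
ties fall back to the limit t·e^{wt}, and a near-defective decomposition is
retried with a 1e-9 diagonal perturbation. `scipy.linalg.expm` remains the
reference implementation in `model.py`; the test suite asserts agreement of
the two routes to ~1e-12 and checks the analytic gradient against finite
differences and `expm` against an independent ODE integration of the
Kolmogorov forward equation.

## Estimation

L-BFGS-B on the free vector (log baselines, raw betas) with the analytic
gradient. Safety box: log λ0 ∈ [−14, 2], beta_age ∈ [−0.5, 0.5], beta_sex ∈
[−6, 6] — generous on the scale of epidemiological rates but tight enough
that exp(beta_age·(age−ref)) cannot overflow at extreme trial points. The
beta_age coordinates are rescaled by 1/12 inside the optimiser (age spans
roughly 12 SD-years, giving those directions ~150× the curvature of the
rest); this pure reparametrisation cuts iteration counts about five-fold.
Starting values are count-based crude rates (observed transitions over
person-time) with zero covariate effects. A single start suffices in every
calibration run — the likelihood is smooth and the crude initialiser lands in
its basin — so `n_starts=1` is the default, with jittered multi-start
available as an option. Convergence requires the L-BFGS-B relative-reduction
and projected-gradient criteria (ftol 1e-9, pgtol 1e-5); non-convergence is
reported in the result, never silently.

The observed information is the central finite difference of the analytic
gradient (step 1e-5, relative); its inverse is the variance–covariance
matrix, with singularity flagged as "CIs unavailable" rather than guessed.
Confidence intervals for rates are Wald intervals on the log scale,
exponentiated (positive bounds, the familiar asymmetry); a natural-scale
delta-method variant is available. Rate ratios are exp(beta) with log-scale
Wald intervals. The likelihood-ratio statistic is 2·Δloglik against the
chi-square with df equal to the difference in free-parameter counts; a
reduced model out-scoring the full one beyond tolerance raises a
"refit needed" error instead of reporting a negative statistic.

## Simulator

Trajectories are competing-exponential simulations of the six-state chain
with the age-refresh conventions above. Observation mimics a screening
programme with registry linkage: screens annually over 3 years of follow-up
(four screens) or at irregular 1–4-year gaps (uniform on {1,2,3,4} — the gap
law is an invention, the source design states only the range), per-screen
attendance probability, event dates rounded to day resolution, censoring of
event-free survivors at end of follow-up. Defaults mirror a large community
screening cohort: baseline state mix 35.55/47.33/17.12 % (FMD/MMD/MetS), 60 %
women, a six-band adult age mix (20–79), and the reference intensity set of
`example_parameters()`.

What the simulator does *not* emulate: self-selection into screening beyond
the attendance probability, dependence between baseline age/sex and baseline
metabolic state (they are drawn independently, though the real joint
distribution is strongly dependent), misclassification of the RMRC state, and
treatment-induced regression. Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions — not
robustness to the selection and measurement problems of real screening data.

The optional biomarker layer draws the five criterion flags from a one-factor
Gaussian copula calibrated to class-conditional prevalences (the margins are
data-anchored; the joint dependence is an invention, ρ = 0.2 by default) and
places biomarker values on the correct side of each threshold, enabling
end-to-end classifier round-trips.

## Prediction

Cumulative CVD risk is the hitting probability of the CVD state (the state is
made absorbing for the computation), which counts subjects who subsequently
die of any cause; this is monotone by construction. The occupancy sum
P(in CVD) + P(CVD death) is available as a "prevalent" curve — it can decline
as cases die of other causes and is exempt from the monotonicity check.
CVD-death risk is the occupancy of that absorbing state. The occupancy vector
is propagated in 0.1-year matrix-exponential steps with the generator
refreshed at integer ages. Absolute risk levels depend on the covariate
reference chosen for the baselines; published curve levels based on an
unstated reference are therefore reproduced qualitatively (ordering by
severity, age gradients), not numerically.

## Calibration-study sizes

Chosen once, as the package's own design: recovery harness at n = 20,000
subjects × 10 seeds for the full 11-baseline band (the rarest cell,
OCD-from-FMD at 0.11 %/yr, accrues only ~20 events per cohort even at that
size); the acceptance script uses n = 10,000 for the metabolic/CVD rates and
n = 20,000 for the rare-event CVD-death cells, 10 seeds each; LRT power at
n = 5,000 × 20 replicates; null calibration at n = 400 × 200 replicates
(Kolmogorov–Smirnov against chi-square(2)); CI coverage at n = 250 × 60
replicates on the high-count exchange rates. Every harness seed derives
deterministically from one master seed.

## Known limitations

* Wald intervals undercover for rare transitions at small n (no profile or
  bootstrap intervals; roadmap).
* Time-homogeneity given covariates: age enters only through the
  proportional-hazards term with piecewise refresh, not as analysis time; no
  frailty or misclassification layer.
* The metabolic-track interval-start age convention biases multi-year
  intervals slightly when screens are missed (attendance < 1); the default
  design has none.
* `equal_cvd_risk` ties baselines only; if the truth also differs in
  covariate effects the 2-df test is conservative about the full hypothesis.
* The carry-forward rule makes in-model sense only because MetS regression is
  excluded from the natural course; analyses of treated cohorts would need a
  different state definition.
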