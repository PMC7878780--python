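"""Synthetic screening cohorts with the structure the analysis assumes.

Trajectories follow the six-state model exactly: at each point the subject
holds competing exponential exit clocks whose rates depend on age and sex
through the proportional-hazards intensities. Age advances with time;
intensities are refreshed at yearly anniversaries of cohort entry while the
subject is in a metabolic state, and at yearly anniversaries of CVD onset
within the CVD track -- the same piecewise-constant-age convention the
likelihood uses, so simulation and inference are mutually consistent.

Observation mimics a community screening programme with registry linkage:
RMRC states are recorded only at (possibly missed or irregular) screens, CVD
onset and deaths carry exact dates rounded to day resolution, and survivors
are censored at the end of follow-up.

The default :class:`CohortSpec` mirrors a large Taiwanese community screening
cohort: baseline state mix 35.55 / 47.33 / 17.12 % (FMD/MMD/MetS), 60% women,
the empirical six-band age distribution of such programmes, annual screens
over three years of follow-up (four screens), and the reference intensity set
from :func:`metsmarkov.params.example_parameters`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import SpecError
from .likelihood import DAY, PanelObservation, SubjectHistory, histories_to_frame
from .params import IntensityParameters, example_parameters
from .rmrc import GLUCOSE_CUTOFF, HDL_CUTOFF, SBP_CUTOFF, TG_CUTOFF, WAIST_CUTOFF
from .states import ObsKind, sex_to_male

#: Exit transitions (indices into TRANSITIONS) available from each living state.
_EXITS = {1: (0, 3, 7), 2: (1, 2, 4, 8), 3: (5, 9), 4: (6, 10)}
#: Destination state of each transition index.
_DEST = (2, 1, 3, 4, 4, 4, 5, 6, 6, 6, 6)

#: Six-band adult age distribution (20-29 ... 70-79) of the reference cohort.
DEFAULT_AGE_BANDS = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80))
_AGE_COUNTS = (4775, 11788, 13493, 8511, 5938, 2990)
DEFAULT_AGE_WEIGHTS = tuple(c / sum(_AGE_COUNTS) for c in _AGE_COUNTS)

DEFAULT_BASELINE_MIX = (0.3555, 0.4733, 0.1712)


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort."""

    n_subjects: int = 5000
    baseline_state_probs: tuple = DEFAULT_BASELINE_MIX
    age_bands: tuple = DEFAULT_AGE_BANDS
    age_weights: tuple = DEFAULT_AGE_WEIGHTS
    prop_female: float = 0.60
    params: IntensityParameters = field(default_factory=example_parameters)
    screen_schedule: str = "annual"  # or "irregular" (1-4 year gaps)
    followup_years: float = 3.0
    attendance_prob: float = 1.0
    refresh_years: float = 1.0
    seed: int = 20210211

    def __post_init__(self):
        p = np.asarray(self.baseline_state_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise SpecError("baseline_state_probs must be a 3-simplex")
        w = np.asarray(self.age_weights, dtype=float)
        if len(w) != len(self.age_bands) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise SpecError("age_weights must be a simplex matching age_bands")
        if self.followup_years <= 0:
            raise SpecError("followup_years must be positive")
        if not (0.0 < self.attendance_prob <= 1.0):
            raise SpecError("attendance_prob must be in (0, 1]")
        if not (0.0 <= self.prop_female <= 1.0):
            raise SpecError("prop_female must be in [0, 1]")
        if self.screen_schedule not in ("annual", "irregular"):
            raise SpecError("screen_schedule must be 'annual' or 'irregular'")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        d["baseline_state_probs"] = list(map(float, self.baseline_state_probs))
        d["age_bands"] = [list(b) for b in self.age_bands]
        d["age_weights"] = list(map(float, self.age_weights))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "params" in d and d["params"] is not None:
            d["params"] = IntensityParameters.from_dict(d["params"])
        if "age_bands" in d:
            d["age_bands"] = tuple(tuple(b) for b in d["age_bands"])
        for k in ("baseline_state_probs", "age_weights"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def simulate_trajectory(
    state0: int,
    age0: float,
    sex,
    params: IntensityParameters,
    horizon: float,
    rng: np.random.Generator,
    refresh_years: float | None = 1.0,
) -> list[tuple[float, int]]:
    """One continuous-time trajectory as a list of (time, state) jumps.

    Competing exponential simulation: within each age-refresh window the total
    exit rate is constant; the jump time is exponential and the destination
    multinomial on the relative intensities. ``refresh_years=None`` freezes
    covariates at their entry values (useful for oracle checks against a
    time-homogeneous transition-probability matrix).
    """
    if horizon <= 0:
        raise SpecError(f"horizon must be positive, got {horizon}")
    if state0 not in (1, 2, 3):
        raise SpecError(f"initial state must be a metabolic state, got {state0}")
    male = sex_to_male(sex)
    refresh = np.inf if refresh_years is None else float(refresh_years)

    events = [(0.0, int(state0))]
    t, state, anchor = 0.0, int(state0), 0.0
    while state in _EXITS and t < horizon:
        if np.isinf(refresh):
            w_start, w_end = anchor, np.inf
        else:
            k = int(np.floor((t - anchor) / refresh + 1e-12))
            w_start = anchor + k * refresh
            w_end = anchor + (k + 1) * refresh
        rates = params.rates_at(age0 + w_start, male)[list(_EXITS[state])]
        total = float(rates.sum())
        stop = min(w_end, horizon)
        if total <= 0.0:
            t = stop
            continue
        jump = t + rng.exponential(1.0 / total)
        if jump >= stop:
            t = stop
            continue
        dest = _DEST[_EXITS[state][int(rng.choice(len(rates), p=rates / total))]]
        events.append((jump, dest))
        t, state = jump, dest
        if dest == 4:
            anchor = t
    return events


def _state_at(trajectory, t):
    s = trajectory[0][1]
    for time, state in trajectory:
        if time <= t:
            s = state
        else:
            break
    return s


def observe_panel(
    trajectory,
    subject_id,
    age0: float,
    sex: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> SubjectHistory:
    """Turn a latent trajectory into the observed screening + registry record.

    RMRC states are sampled at attended screens (the baseline screen is always
    attended); CVD onset and deaths become exactly dated events at day
    resolution; a censor row closes the record of anyone alive and unabsorbed
    at the end of follow-up. The retain-as-MetS carry-forward rule is applied
    to the observed states.
    """
    T = spec.followup_years
    if spec.screen_schedule == "annual":
        screens = [float(k) for k in range(int(np.floor(T + 1e-9)) + 1)]
    else:
        screens, t = [0.0], 0.0
        while True:
            t += float(rng.integers(1, 5))
            if t > T + 1e-9:
                break
            screens.append(t)
    attended = [screens[0]] + [
        s for s in screens[1:] if rng.random() < spec.attendance_prob
    ]

    cvd_time = next((tt for tt, s in trajectory if s == 4), None)
    death = next(((tt, s) for tt, s in trajectory if s in (5, 6)), None)

    obs = []
    seen_mets = False
    for s_t in attended:
        if cvd_time is not None and s_t >= cvd_time:
            break
        if death is not None and s_t >= death[0]:
            break
        st = _state_at(trajectory, s_t)
        if st == 3:
            seen_mets = True
        obs.append(
            PanelObservation(subject_id, s_t, 3 if seen_mets else st,
                             ObsKind.PANEL.value, age0 + s_t, sex)
        )

    def emit_exact(t_true, state):
        t_r = max(round(t_true / DAY), 1) * DAY
        if obs and t_r <= obs[-1].time:
            t_r = obs[-1].time + DAY
        obs.append(PanelObservation(subject_id, t_r, state, ObsKind.EXACT.value,
                                    age0 + t_r, sex))

    if cvd_time is not None and cvd_time <= T:
        emit_exact(cvd_time, 4)
    if death is not None and death[0] <= T:
        emit_exact(death[0], death[1])
    else:
        if T > obs[-1].time + 1e-12:  # alive, unabsorbed, last seen before end
            obs.append(PanelObservation(subject_id, T, obs[-1].state,
                                        ObsKind.CENSOR.value, age0 + T, sex))
    return SubjectHistory(obs)


@dataclass
class SimulatedCohort:
    histories: list
    truth: IntensityParameters
    spec: CohortSpec
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        return histories_to_frame(self.histories)


def generate_cohort(spec: CohortSpec, out_csv=None, truth_out=None) -> SimulatedCohort:
    """Simulate a full cohort; optionally write the panel CSV and truth YAML.

    Reproducible: a given spec (including its seed) yields byte-identical
    output files across runs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    states0 = rng.choice([1, 2, 3], size=n, p=np.asarray(spec.baseline_state_probs))
    female = rng.random(n) < spec.prop_female
    bands = rng.choice(len(spec.age_bands), size=n, p=np.asarray(spec.age_weights))
    u = rng.random(n)
    lo = np.array([b[0] for b in spec.age_bands], dtype=float)
    hi = np.array([b[1] for b in spec.age_bands], dtype=float)
    ages = lo[bands] + u * (hi[bands] - lo[bands])

    histories = []
    counts = {"cvd": 0, "cvd_death": 0, "ocd": 0, "censored": 0}
    width = len(str(n))
    for i in range(n):
        sex = "female" if female[i] else "male"
        traj = simulate_trajectory(
            int(states0[i]), float(ages[i]), sex, spec.params,
            spec.followup_years, rng, spec.refresh_years,
        )
        h = observe_panel(traj, f"S{i:0{width}d}", float(ages[i]), sex, spec, rng)
        last = h.observations[-1]
        if any(o.state == 4 for o in h):
            counts["cvd"] += 1
        if last.state == 5 and last.obs_kind == ObsKind.EXACT.value:
            counts["cvd_death"] += 1
        elif last.state == 6 and last.obs_kind == ObsKind.EXACT.value:
            counts["ocd"] += 1
        else:
            counts["censored"] += 1
        histories.append(h)

    summary = {
        "n_subjects": n,
        "baseline_mix": {s: int((states0 == s).sum()) for s in (1, 2, 3)},
        "n_female": int(female.sum()),
        "events": counts,
    }
    cohort = SimulatedCohort(histories, spec.params, spec, summary)
    if out_csv is not None:
        cohort.to_frame().to_csv(out_csv, index=False)
    if truth_out is not None:
        spec.params.save(truth_out)
    return cohort


# ---------------------------------------------------------------------------
# Biomarker-level synthesis (optional layer for end-to-end classifier tests)
# ---------------------------------------------------------------------------

#: Per-criterion prevalence conditional on RMRC class in the reference cohort
#: (order: central obesity, high TG, low HDL, high BP, hyperglycemia).
MMD_CRITERION_PREV = (0.2696, 0.2141, 0.2140, 0.5423, 0.1624)
METS_CRITERION_PREV = (0.7634, 0.7332, 0.5329, 0.8413, 0.5719)


def _draw_flags(rng, prev, lo, hi, rho):
    """Correlated criterion flags via a one-factor Gaussian copula, rejected
    until the positive count falls in [lo, hi]. The joint dependence beyond
    the margins is a modelling invention (the margins are calibrated)."""
    thr = stats.norm.ppf(prev)
    sr, sc = np.sqrt(rho), np.sqrt(1 - rho)
    while True:
        z = sr * rng.standard_normal() + sc * rng.standard_normal(5)
        flags = z < thr
        if lo <= flags.sum() <= hi:
            return flags


def synthesize_screen_records(
    n: int,
    seed: int = 20210211,
    rho: float = 0.2,
    baseline_state_probs=DEFAULT_BASELINE_MIX,
    prop_female: float = 0.60,
) -> pd.DataFrame:
    """Biomarker tables whose true criterion flags and RMRC class are known.

    Criterion flags are drawn from a one-factor Gaussian copula calibrated to
    the class-conditional prevalences above; biomarker values are then placed
    on the correct side of each threshold. Columns ``true_*`` carry the
    generating flags, count and class for round-trip testing.
    """
    rng = np.random.default_rng(seed)
    states = rng.choice([1, 2, 3], size=n, p=np.asarray(baseline_state_probs))
    female = rng.random(n) < prop_female
    rows = []
    for i in range(n):
        sex = "female" if female[i] else "male"
        if states[i] == 1:
            flags = np.zeros(5, dtype=bool)
        elif states[i] == 2:
            flags = _draw_flags(rng, MMD_CRITERION_PREV, 1, 2, rho)
        else:
            flags = _draw_flags(rng, METS_CRITERION_PREV, 3, 5, rho)
        ob, tg, hdl, bp, glu = flags
        waist_cut, hdl_cut = WAIST_CUTOFF[sex], HDL_CUTOFF[sex]
        row = {
            "subject_id": f"B{i}",
            "sex": sex,
            "age": float(rng.uniform(20, 80)),
            "waist": waist_cut + rng.uniform(0, 15) if ob else waist_cut - rng.uniform(1, 20),
            "triglycerides": TG_CUTOFF + rng.uniform(0, 200) if tg else TG_CUTOFF - rng.uniform(10, 100),
            "hdl": hdl_cut - rng.uniform(1, 15) if hdl else hdl_cut + rng.uniform(0, 25),
            "sbp": SBP_CUTOFF + rng.uniform(0, 40) if bp else SBP_CUTOFF - rng.uniform(5, 30),
            "dbp": 60.0 + rng.uniform(0, 20),
            "fasting_glucose": GLUCOSE_CUTOFF + rng.uniform(0, 80) if glu else GLUCOSE_CUTOFF - rng.uniform(5, 30),
            "on_hypertension_treatment": False,
            "on_diabetes_treatment": False,
            "on_hyperlipidemia_treatment": False,
            "screen_time": 0.0,
            "true_central_obesity": bool(ob),
            "true_hypertriglyceridemia": bool(tg),
            "true_low_hdl": bool(hdl),
            "true_high_bp": bool(bp),
            "true_hyperglycemia": bool(glu),
            "true_n_positive": int(flags.sum()),
            "true_state": int(states[i]),
        }
        rows.append(row)
    return pd.DataFrame(rows)
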