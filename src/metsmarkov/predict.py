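"""Cumulative-risk curves and human-readable result tables.

Risk curves propagate the state-occupancy vector through short matrix-
exponential steps, with age held piecewise constant and updated at integer
ages. The cumulative risk of CVD from a metabolic state counts current CVD
cases plus CVD deaths (every CVD death passed through CVD); optionally CVD
deaths can be excluded to give prevalent-CVD occupancy instead. Subjects who
develop CVD and later die of other causes are not separable from other-cause
deaths in the six-state occupancy and are not counted (a known, small
undercount discussed in the methods notes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exceptions import ParameterError
from .estimation import FitResult, rate_ratio_table, rates_table
from .model import build_generator
from .params import IntensityParameters

TARGETS = ("cvd", "cvd_death")


@dataclass(frozen=True)
class RiskCurve:
    """Risk of an endpoint over time from a starting metabolic state.

    Cumulative curves (the default) are validated to start at zero, never
    decrease and stay below one; prevalence-style occupancy curves are only
    bounded.
    """

    start_state: int
    target: str
    age: float
    sex: str
    times: np.ndarray
    risk: np.ndarray
    cumulative: bool = True

    def __post_init__(self):
        r = np.asarray(self.risk)
        if np.any(r < -1e-9) or np.any(r > 1 + 1e-9):
            raise ParameterError("risk must lie in [0, 1]")
        if self.cumulative and (r[0] > 1e-12 or np.any(np.diff(r) < -1e-9)):
            raise ParameterError("cumulative risk must start at 0 and be nondecreasing")

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.risk))


def cumulative_risk(
    params: IntensityParameters,
    start_state: int,
    target: str,
    age: float,
    sex: str,
    horizon: float,
    grid_step: float = 0.1,
    prevalent: bool = False,
) -> RiskCurve:
    """Risk of CVD or CVD death over ``horizon`` years.

    ``target='cvd'`` gives the cumulative incidence of CVD onset -- the
    probability of having entered the CVD state by each grid time, counting
    subjects who subsequently died (of CVD or other causes). It is computed by
    making the CVD state absorbing, which is exactly the hitting probability.
    ``target='cvd_death'`` gives P(CVD death by t) (an absorbing state, hence
    already a cumulative incidence). With ``prevalent=True`` the CVD target
    returns the occupancy sum P(in CVD) + P(CVD death) instead; that curve can
    decline as CVD cases die of other causes and is not validated as
    cumulative. Age advances along the grid; the generator is refreshed at
    integer ages.
    """
    if start_state not in (1, 2, 3):
        raise ParameterError("start_state must be a living metabolic state (1-3)")
    if target not in TARGETS:
        raise ParameterError(f"target must be one of {TARGETS}")
    if horizon <= 0:
        raise ParameterError("horizon must be positive")

    absorb_cvd = target == "cvd" and not prevalent
    v = np.zeros(6)
    v[start_state - 1] = 1.0
    times = [0.0]
    risks = [0.0]
    cache: dict[tuple[int, float], np.ndarray] = {}
    t = 0.0
    while t < horizon - 1e-12:
        h = min(grid_step, horizon - t)
        a = math.floor(age + t)
        key = (a, round(h, 12))
        if key not in cache:
            Q = build_generator(params, a, sex)
            if absorb_cvd:
                Q[3, :] = 0.0
            cache[key] = expm(Q * h)
        v = v @ cache[key]
        t += h
        times.append(t)
        if target == "cvd":
            risks.append(v[3] if absorb_cvd else v[3] + v[4])
        else:
            risks.append(v[4])
    return RiskCurve(start_state, target, age, sex, np.asarray(times),
                     np.asarray(risks), cumulative=not prevalent)


def report_tables(fit_result: FitResult):
    """Formatted estimate tables: (text, rates DataFrame, rate-ratio DataFrame).

    Rates are printed in %/yr and rate ratios with their CIs, both to two
    decimals for side-by-side comparison with published tables.
    """
    rdf = rates_table(fit_result)
    rrdf = rate_ratio_table(fit_result)
    lines = ["Baseline transition intensities (% per year, female, "
             f"age {fit_result.params_hat.reference_age:g})",
             f"{'transition':<16}{'estimate':>10}  95% CI"]
    for _, row in rdf.iterrows():
        ci = (f"({row.ci_low:.2f}, {row.ci_high:.2f})"
              if np.isfinite(row.ci_low) else "(unavailable)")
        lines.append(f"{row.transition:<16}{row.rate_pct_per_year:>10.2f}  {ci}")
    lines += ["", "Rate ratios (age: per additional year; sex: male vs female)",
              f"{'group':<14}{'covariate':<10}{'RR':>8}  95% CI"]
    for _, row in rrdf.iterrows():
        ci = (f"({row.ci_low:.2f}, {row.ci_high:.2f})"
              if row.ci_available and np.isfinite(row.ci_low) else "(unavailable)")
        lines.append(f"{row.group:<14}{row.covariate:<10}{row.rate_ratio:>8.2f}  {ci}")
    lines.append("")
    lines.append(f"log-likelihood {fit_result.loglik:.2f} | "
                 f"{fit_result.n_subjects} subjects, {fit_result.n_intervals} intervals | "
                 f"converged: {fit_result.converged}")
    return "\n".join(lines), rdf, rrdf
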