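"""Log-likelihood of panel-observed six-state histories.

Observation scheme
------------------
RMRC states (FMD/MMD/MetS) are seen only at screening visits, so transitions
between them are interval-censored; CVD onset and both kinds of death carry
exact registry dates; a final censor record marks a subject known alive and
event-free. Contributions per interval from observation ``prev`` (state r) to
``next``:

* panel state s:                 log P[r,s](dt)
* exact CVD onset:               log sum_m P[r,m](dt) * lambda_{m,CVD}
* exact death d (pre-CVD):       log sum_m P[r,m](dt) * lambda_{m,d}
* censor:                        log sum_m P[r,m](dt)

with m running over the living *metabolic* states: because events are exactly
dated, a subject without a CVD record cannot have passed through the CVD
state. Within the CVD track the model is scalar (two competing exits), so
survival and death densities are computed directly with the age-specific
hazards updated at yearly anniversaries of onset.

Age is treated as piecewise constant within each metabolic-track interval,
evaluated at the interval's start and rounded to whole years for caching
(documented approximation; exact for annual screens).

Two implementations are provided: :func:`interval_loglik`, a per-interval
reference built on ``scipy.linalg.expm``, and a fast vectorised path used by
:func:`cohort_loglik` and the optimiser, based on batched eigendecompositions
of the 3x3 metabolic sub-generator with analytic gradients via the
divided-difference (Loewner) matrix. The two paths agree to close to machine
precision and the test suite asserts this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .exceptions import DataError
from .model import build_generator, metabolic_generator
from .params import IntensityParameters, N_PARAMS
from .states import (
    N_GROUPS,
    N_TRANSITIONS,
    ObsKind,
    TRANS_GROUP,
    TRANSITIONS,
    sex_to_male,
)

DAY = 1.0 / 365.0

#: Transition indices of the exits from the metabolic states
_CVD_COLS = np.array([3, 4, 5])   # 1->4, 2->4, 3->4
_OCD_COLS = np.array([7, 8, 9])   # 1->6, 2->6, 3->6
_I_CVD_DEATH = 6                  # 4->5
_I_CVD_OCD = 10                   # 4->6
_G_CVD_DEATH = 6
_G_OCD = 7

_GROUP_ARR = np.asarray(TRANS_GROUP)

# Mapping tensor: A = sum_j rate_j * M[j] builds the 3x3 metabolic sub-generator
_M = np.zeros((N_TRANSITIONS, 3, 3))
for _j, (_r, _s) in enumerate(TRANSITIONS):
    if _r <= 3:
        _M[_j, _r - 1, _r - 1] -= 1.0
        if _s <= 3:
            _M[_j, _r - 1, _s - 1] += 1.0


# ---------------------------------------------------------------------------
# Observations and histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelObservation:
    """One (time, state) observation of a subject."""

    subject_id: object
    time: float
    state: int
    obs_kind: str
    age_at_obs: float
    sex: str

    def __post_init__(self):
        object.__setattr__(self, "obs_kind", ObsKind(self.obs_kind).value)
        object.__setattr__(self, "state", int(self.state))
        if self.state not in (1, 2, 3, 4, 5, 6):
            raise DataError(f"state must be 1..6, got {self.state}")
        if self.time < 0:
            raise DataError(f"observation time must be >= 0, got {self.time}")


class SubjectHistory:
    """Validated, time-ordered observations of one subject.

    Raises :class:`DataError` on construction if the observation-scheme
    invariants are violated (non-increasing times, panel observation of a
    death state, CVD death without a prior CVD onset, observation after an
    absorbing state, regression out of MetS, ...).
    """

    __slots__ = ("subject_id", "sex", "baseline_age", "observations")

    def __init__(self, observations):
        obs = tuple(observations)
        if not obs:
            raise DataError("a subject history needs at least one observation")
        first = obs[0]
        if first.obs_kind != ObsKind.PANEL.value or first.state not in (1, 2, 3):
            raise DataError(
                f"subject {first.subject_id}: first observation must be a panel "
                f"RMRC state, got kind={first.obs_kind} state={first.state}"
            )
        seen_cvd = False
        seen_mets = first.state == 3
        for i in range(1, len(obs)):
            p, n = obs[i - 1], obs[i]
            if n.time <= p.time:
                raise DataError(
                    f"subject {n.subject_id}: times not strictly increasing at t={n.time}"
                )
            if n.sex != p.sex:
                raise DataError(f"subject {n.subject_id}: sex changes over time")
            if p.state in (5, 6):
                raise DataError(
                    f"subject {n.subject_id}: observation after an absorbing state"
                )
            if n.obs_kind == ObsKind.PANEL.value:
                if n.state not in (1, 2, 3):
                    raise DataError(
                        f"subject {n.subject_id}: states 4-6 must be exact events"
                    )
                if seen_cvd:
                    raise DataError(
                        f"subject {n.subject_id}: panel RMRC observation after CVD onset"
                    )
                if seen_mets and n.state != 3:
                    raise DataError(
                        f"subject {n.subject_id}: regression out of MetS observed at "
                        f"t={n.time} (carry-forward not applied?)"
                    )
            elif n.obs_kind == ObsKind.EXACT.value:
                if n.state not in (4, 5, 6):
                    raise DataError(
                        f"subject {n.subject_id}: exact events are CVD onset or deaths"
                    )
                if n.state == 4 and seen_cvd:
                    raise DataError(f"subject {n.subject_id}: more than one CVD onset")
                if n.state == 5 and not seen_cvd:
                    raise DataError(
                        f"subject {n.subject_id}: CVD death without prior CVD onset"
                    )
                if n.state == 4:
                    seen_cvd = True
            elif n.obs_kind == ObsKind.CENSOR.value:
                if i != len(obs) - 1:
                    raise DataError(f"subject {n.subject_id}: censor must be last")
            if n.state == 3:
                seen_mets = True
        self.observations = obs
        self.subject_id = first.subject_id
        self.sex = first.sex
        self.baseline_age = first.age_at_obs

    def __len__(self):
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def intervals(self):
        """Consecutive observation pairs."""
        o = self.observations
        return zip(o[:-1], o[1:])


# ---------------------------------------------------------------------------
# Long-format panel I/O
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ("subject_id", "time_years", "state", "obs_kind", "age", "sex")


def histories_from_frame(
    df: pd.DataFrame, carry_forward_mets: bool = True
) -> tuple[list[SubjectHistory], dict]:
    """Build validated histories from a long-format panel table.

    ``carry_forward_mets`` (default) applies the retain-as-MetS rule: once a
    subject has screened as MetS, later screens that show fewer criteria are
    recorded as MetS, reflecting that regression under intervention is not
    part of the natural course being modelled. With the rule disabled,
    subjects with forbidden backward observations are dropped and counted.

    Returns ``(histories, report)`` where the report counts carried-forward
    observations and rejected subjects.
    """
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"panel table lacks columns {missing}; expected {PANEL_COLUMNS}")
    report = {"n_subjects": 0, "n_carried_forward": 0, "n_rejected": 0, "rejected": []}
    histories = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_years")
        obs = []
        seen_mets = False
        for idx, row in grp.iterrows():
            try:
                o = PanelObservation(
                    subject_id=sid,
                    time=float(row["time_years"]),
                    state=int(row["state"]),
                    obs_kind=str(row["obs_kind"]),
                    age_at_obs=float(row["age"]),
                    sex=str(row["sex"]),
                )
            except (DataError, ValueError) as err:
                raise DataError(f"line {idx}: {err}") from None
            if o.obs_kind == ObsKind.PANEL.value:
                if seen_mets and o.state != 3 and carry_forward_mets:
                    o = PanelObservation(sid, o.time, 3, o.obs_kind, o.age_at_obs, o.sex)
                    report["n_carried_forward"] += 1
                if o.state == 3:
                    seen_mets = True
            obs.append(o)
        try:
            histories.append(SubjectHistory(obs))
            report["n_subjects"] += 1
        except DataError as err:
            report["n_rejected"] += 1
            report["rejected"].append(str(err))
    if report["n_rejected"] and carry_forward_mets:
        # carry-forward should have repaired all topology-forbidden sequences
        raise DataError(
            f"{report['n_rejected']} subjects failed validation: {report['rejected'][:5]}"
        )
    return histories, report


def histories_to_frame(histories) -> pd.DataFrame:
    rows = [
        (o.subject_id, o.time, o.state, o.obs_kind, o.age_at_obs, o.sex)
        for h in histories
        for o in h
    ]
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def read_panel(path, carry_forward_mets: bool = True):
    """Read a long-format panel CSV; returns (histories, report)."""
    return histories_from_frame(pd.read_csv(path), carry_forward_mets)


def write_panel(histories, path) -> None:
    histories_to_frame(histories).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Compilation: histories -> flat arrays for the vectorised likelihood
# ---------------------------------------------------------------------------

class CompiledCohort:
    """Grouped interval data keyed by (rounded age, sex) covariate cells.

    Metabolic-track intervals are grouped by (covariate key, dt, source state,
    outcome), which collapses a cohort's panel intervals to a few hundred
    weighted terms; exact-event and censor intervals group on the day-rounded
    dt. CVD-track intervals are expanded into yearly exposure windows with
    exact ages (scalar hazards, no matrix exponential).
    """

    def __init__(self, histories):
        key_index: dict[tuple[int, int], int] = {}
        pg: dict[tuple, float] = {}
        ev: dict[tuple, float] = {}
        cz: dict[tuple, float] = {}
        cw_age, cw_male, cw_dur = [], [], []
        cd_age, cd_male, cd_cvd = [], [], []
        n_intervals = 0
        n_subjects = 0

        for h in histories:
            n_subjects += 1
            male = sex_to_male(h.sex)
            for prev, nxt in h.intervals():
                n_intervals += 1
                dt = nxt.time - prev.time
                if dt <= 0:
                    raise DataError(f"subject {h.subject_id}: non-positive interval")
                if prev.state <= 3:
                    dt_r = max(round(dt / DAY), 1) * DAY
                    a = int(round(prev.age_at_obs))
                    k = key_index.setdefault((a, male), len(key_index))
                    r = prev.state - 1
                    if nxt.obs_kind == ObsKind.PANEL.value:
                        pg[(k, dt_r, r, nxt.state - 1)] = pg.get((k, dt_r, r, nxt.state - 1), 0.0) + 1.0
                    elif nxt.obs_kind == ObsKind.EXACT.value:
                        if nxt.state == 5:
                            raise DataError(
                                f"subject {h.subject_id}: CVD death without prior onset"
                            )
                        d = 0 if nxt.state == 4 else 1
                        ev[(k, dt_r, r, d)] = ev.get((k, dt_r, r, d), 0.0) + 1.0
                    else:  # censor
                        cz[(k, dt_r, r)] = cz.get((k, dt_r, r), 0.0) + 1.0
                else:  # prev.state == 4: scalar CVD track
                    if nxt.obs_kind == ObsKind.PANEL.value:
                        raise DataError(
                            f"subject {h.subject_id}: panel observation after CVD onset"
                        )
                    j = 0
                    while j < dt - 1e-12:
                        cw_age.append(prev.age_at_obs + j)
                        cw_male.append(male)
                        cw_dur.append(min(1.0, dt - j))
                        j += 1
                    if nxt.obs_kind == ObsKind.EXACT.value:
                        jd = max(int(math.floor(dt - 1e-9)), 0)
                        cd_age.append(prev.age_at_obs + jd)
                        cd_male.append(male)
                        cd_cvd.append(nxt.state == 5)

        self.n_subjects = n_subjects
        self.n_intervals = n_intervals
        keys = sorted(key_index, key=key_index.get)
        self.key_age = np.array([a for a, _ in keys], dtype=float)
        self.key_male = np.array([m for _, m in keys], dtype=float)

        def _unpack(d, nfields):
            if not d:
                return tuple(np.zeros(0) for _ in range(nfields + 1))
            ks = list(d.keys())
            cols = tuple(np.array([k[i] for k in ks]) for i in range(nfields))
            return cols + (np.array([d[k] for k in ks], dtype=float),)

        self.pg_key, self.pg_dt, self.pg_r, self.pg_s, self.pg_cnt = _unpack(pg, 4)
        self.ev_key, self.ev_dt, self.ev_r, self.ev_d, self.ev_cnt = _unpack(ev, 4)
        self.cz_key, self.cz_dt, self.cz_r, self.cz_cnt = _unpack(cz, 3)
        for name in ("pg_key", "pg_r", "pg_s", "ev_key", "ev_r", "ev_d", "cz_key", "cz_r"):
            setattr(self, name, getattr(self, name).astype(int))
        self.cw_age = np.array(cw_age, dtype=float)
        self.cw_male = np.array(cw_male, dtype=float)
        self.cw_dur = np.array(cw_dur, dtype=float)
        self.cd_age = np.array(cd_age, dtype=float)
        self.cd_male = np.array(cd_male, dtype=float)
        self.cd_cvd = np.array(cd_cvd, dtype=bool)


def compile_cohort(histories) -> CompiledCohort:
    """Pre-aggregate histories for repeated likelihood evaluation."""
    return CompiledCohort(histories)


# ---------------------------------------------------------------------------
# Fast likelihood with analytic gradient
# ---------------------------------------------------------------------------

def _eig_guarded(A: np.ndarray):
    """Batched eigendecomposition with a perturbation retry for near-defective Q."""
    w, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    bad = np.abs(Vinv).max(axis=(1, 2)) > 1e8
    if np.any(bad):
        A = A.copy()
        A[bad] += np.diag([0.0, 1e-9, 2e-9])
        w2, V2 = np.linalg.eig(A[bad])
        w[bad], V[bad] = w2, V2
        Vinv[bad] = np.linalg.inv(V2)
    return w, V, Vinv


def _loewner(wk: np.ndarray, dt: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Divided-difference matrix F[i,j] = (e^{wi t} - e^{wj t}) / (wi - wj)."""
    wi = wk[:, :, None]
    wj = wk[:, None, :]
    diff = wi - wj
    small = np.abs(diff) < 1e-7
    safe = np.where(small, 1.0, diff)
    F = (E[:, :, None] - E[:, None, :]) / safe
    mid = dt[:, None, None] * np.exp(0.5 * (wi + wj) * dt[:, None, None])
    return np.where(small, mid, F)


def _metabolic_rows(w, V, Vinv, G, key, dt, r):
    """P[r,:] rows and their parameter gradients for a batch of intervals.

    Returns (Prow (n,3), dProw (n, N_PARAMS, 3)), real parts.
    """
    wk = w[key]
    E = np.exp(wk * dt[:, None])
    a = V[key, r, :]
    Vi = Vinv[key]
    Prow = np.matmul((a * E)[:, None, :], Vi)[:, 0, :].real
    F = _loewner(wk, dt, E)
    AF = a[:, :, None] * F
    # dP[r,:] = sum_ij AF[i,j] G[p,i,j] Vinv[j,:], batched over intervals
    S = (AF[:, None, :, :] * G[key]).sum(axis=2)      # (n, P, 3)
    dProw = np.matmul(S, Vi)                          # (n, P, 3)
    return Prow, dProw.real


def _nll_and_grad(theta: np.ndarray, c: CompiledCohort, reference_age: float):
    """Negative cohort log-likelihood and its gradient over the full 27-vector."""
    theta = np.asarray(theta, dtype=float)
    ba = theta[N_TRANSITIONS : N_TRANSITIONS + N_GROUPS]
    bs = theta[N_TRANSITIONS + N_GROUPS :]
    g = _GROUP_ARR
    ll = 0.0
    grad = np.zeros(N_PARAMS)

    K = len(c.key_age)
    if K:
        da = (c.key_age - reference_age)[:, None]
        male = c.key_male[:, None]
        logR = theta[:N_TRANSITIONS][None, :] + ba[g][None, :] * da + bs[g][None, :] * male
        R = np.exp(logR)  # (K, 11)

        dR = np.zeros((K, N_PARAMS, N_TRANSITIONS))
        j_idx = np.arange(N_TRANSITIONS)
        dR[:, j_idx, j_idx] = R
        dR[:, N_TRANSITIONS + g, j_idx] = R * da
        dR[:, N_TRANSITIONS + N_GROUPS + g, j_idx] = R * male

        A = np.tensordot(R, _M, axes=([1], [0]))
        dA = np.tensordot(dR, _M, axes=([2], [0]))
        w, V, Vinv = _eig_guarded(A)
        G = np.matmul(np.matmul(Vinv[:, None, :, :], dA.astype(complex)), V[:, None, :, :])

        if len(c.pg_key):
            Prow, dProw = _metabolic_rows(w, V, Vinv, G, c.pg_key, c.pg_dt, c.pg_r)
            n = np.arange(len(c.pg_key))
            p = np.maximum(Prow[n, c.pg_s], 1e-300)
            dp = dProw[n, :, c.pg_s]
            ll += float(c.pg_cnt @ np.log(p))
            grad += (c.pg_cnt / p) @ dp

        if len(c.ev_key):
            Prow, dProw = _metabolic_rows(w, V, Vinv, G, c.ev_key, c.ev_dt, c.ev_r)
            is_cvd = (c.ev_d == 0)[:, None]
            lam = np.where(is_cvd, R[c.ev_key][:, _CVD_COLS], R[c.ev_key][:, _OCD_COLS])
            dlam = np.where(
                is_cvd[:, None, :],
                dR[c.ev_key][:, :, _CVD_COLS],
                dR[c.ev_key][:, :, _OCD_COLS],
            )
            u = np.maximum(np.einsum("nm,nm->n", Prow, lam), 1e-300)
            du = np.einsum("npm,nm->np", dProw, lam) + np.einsum("nm,npm->np", Prow, dlam)
            ll += float(c.ev_cnt @ np.log(u))
            grad += (c.ev_cnt / u) @ du

        if len(c.cz_key):
            Prow, dProw = _metabolic_rows(w, V, Vinv, G, c.cz_key, c.cz_dt, c.cz_r)
            u = np.maximum(Prow.sum(axis=1), 1e-300)
            du = dProw.sum(axis=2)
            ll += float(c.cz_cnt @ np.log(u))
            grad += (c.cz_cnt / u) @ du

    # CVD track: competing exponential exits with yearly age refresh from onset
    if len(c.cw_age):
        for jt, gt in ((_I_CVD_DEATH, _G_CVD_DEATH), (_I_CVD_OCD, _G_OCD)):
            daw = c.cw_age - reference_age
            rate = np.exp(theta[jt] + ba[gt] * daw + bs[gt] * c.cw_male)
            exposure = rate * c.cw_dur
            ll -= float(exposure.sum())
            grad[jt] -= exposure.sum()
            grad[N_TRANSITIONS + gt] -= float(exposure @ daw)
            grad[N_TRANSITIONS + N_GROUPS + gt] -= float(exposure @ c.cw_male)
    if len(c.cd_age):
        for is_cvd, jt, gt in ((True, _I_CVD_DEATH, _G_CVD_DEATH), (False, _I_CVD_OCD, _G_OCD)):
            m = c.cd_cvd == is_cvd
            if not m.any():
                continue
            dad = c.cd_age[m] - reference_age
            ll += float(
                np.sum(theta[jt] + ba[gt] * dad + bs[gt] * c.cd_male[m])
            )
            grad[jt] += m.sum()
            grad[N_TRANSITIONS + gt] += float(dad.sum())
            grad[N_TRANSITIONS + N_GROUPS + gt] += float(c.cd_male[m].sum())

    if not (np.isfinite(ll) and np.all(np.isfinite(grad))):
        # overflow region (rates like exp(200) at extreme trial points):
        # return a huge value so line searches back off; gradient uninformative
        return 1e15, np.zeros(N_PARAMS)
    return -ll, -grad


# ---------------------------------------------------------------------------
# Public likelihood API
# ---------------------------------------------------------------------------

def cohort_loglik(data, params: IntensityParameters, events_as_panel: bool = False) -> float:
    """Total log-likelihood of a cohort.

    ``data`` is a list of :class:`SubjectHistory`, a :class:`CompiledCohort`,
    or a long-format panel DataFrame. ``events_as_panel`` is a sensitivity
    switch that treats exact events as if panel-observed at their recorded
    times (slow reference path only).
    """
    if isinstance(data, pd.DataFrame):
        data, _ = histories_from_frame(data)
    if isinstance(data, CompiledCohort):
        if events_as_panel:
            raise DataError("events_as_panel needs raw histories, not a compiled cohort")
        compiled = data
    else:
        data = list(data)
        if not data:
            raise DataError("empty cohort")
        if events_as_panel:
            return float(
                sum(
                    interval_loglik(p, n, params, events_as_panel=True)
                    for h in data
                    for p, n in h.intervals()
                )
            )
        compiled = compile_cohort(data)
    if compiled.n_subjects == 0:
        raise DataError("empty cohort")
    nll, _ = _nll_and_grad(params.to_vector(), compiled, params.reference_age)
    return -nll


def cohort_loglik_and_grad(theta, compiled: CompiledCohort, reference_age: float = 50.0):
    """(negative log-likelihood, gradient) over the full parameter vector."""
    return _nll_and_grad(theta, compiled, reference_age)


def interval_loglik(
    prev: PanelObservation,
    nxt: PanelObservation,
    params: IntensityParameters,
    events_as_panel: bool = False,
    diagnostics: list | None = None,
) -> float:
    """Reference log-likelihood contribution of one observation interval.

    A structurally impossible observation (probability zero under the
    topology) returns ``-inf`` and, when ``diagnostics`` is a list, appends a
    dict describing the offending interval; it never raises for that case.
    Genuine data errors (non-positive dt, observation after death) do raise.
    """
    dt = nxt.time - prev.time
    if dt <= 0:
        raise DataError(f"non-positive interval dt={dt} (subject {prev.subject_id})")
    if prev.state in (5, 6):
        raise DataError(f"observation after absorbing state (subject {prev.subject_id})")
    male = sex_to_male(prev.sex)
    age = round(prev.age_at_obs)

    def impossible(reason):
        if diagnostics is not None:
            diagnostics.append(
                {"subject_id": prev.subject_id, "time": nxt.time, "from": prev.state,
                 "to": nxt.state, "kind": nxt.obs_kind, "reason": reason}
            )
        return float("-inf")

    if events_as_panel:
        P = expm(build_generator(params, age, prev.sex) * dt)
        if nxt.obs_kind == ObsKind.CENSOR.value:
            return float(np.log(max(P[prev.state - 1, :4].sum(), 1e-300)))
        p = P[prev.state - 1, nxt.state - 1]
        return float(np.log(p)) if p > 1e-300 else impossible("zero transition probability")

    if prev.state <= 3:
        A = metabolic_generator(params, age, male)
        P3 = expm(A * dt)
        r = prev.state - 1
        rates = params.rates_at(age, male)
        if nxt.obs_kind == ObsKind.PANEL.value:
            if nxt.state > 3:
                raise DataError("states 4-6 must be exact events (or use events_as_panel)")
            p = P3[r, nxt.state - 1]
            return float(np.log(p)) if p > 1e-300 else impossible("forbidden regression")
        if nxt.obs_kind == ObsKind.EXACT.value:
            if nxt.state == 5:
                return impossible("CVD death without prior CVD onset")
            cols = _CVD_COLS if nxt.state == 4 else _OCD_COLS
            u = float(P3[r, :] @ rates[cols])
            return float(np.log(u)) if u > 1e-300 else impossible("zero event density")
        return float(np.log(max(P3[r, :].sum(), 1e-300)))

    # prev.state == 4: scalar competing-risk track, yearly age refresh from onset
    if nxt.obs_kind == ObsKind.PANEL.value:
        raise DataError("panel RMRC observation after CVD onset")
    total = 0.0
    j = 0
    while j < dt - 1e-12:
        a = prev.age_at_obs + j
        dur = min(1.0, dt - j)
        total += (params.intensity((4, 5), a, prev.sex) + params.intensity((4, 6), a, prev.sex)) * dur
        j += 1
    ll = -total
    if nxt.obs_kind == ObsKind.EXACT.value:
        jd = max(int(math.floor(dt - 1e-9)), 0)
        a = prev.age_at_obs + jd
        target = (4, 5) if nxt.state == 5 else (4, 6)
        ll += float(np.log(params.intensity(target, a, prev.sex)))
    return float(ll)
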