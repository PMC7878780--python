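"""Panel likelihood: closed-form oracles, invariants, fast-vs-reference path."""

import numpy as np
import pytest

from metsmarkov import (
    IntensityParameters,
    PanelObservation,
    SubjectHistory,
    cohort_loglik,
    compile_cohort,
    histories_from_frame,
    histories_to_frame,
    interval_loglik,
)
from metsmarkov.exceptions import DataError
from metsmarkov.likelihood import cohort_loglik_and_grad
from metsmarkov.states import TRANSITION_NAMES


def obs(t, state, kind="panel", age=50.0, sex="female", sid="s"):
    return PanelObservation(sid, t, state, kind, age, sex)


def single_rate_params(name: str, rate: float) -> IntensityParameters:
    ll = np.full(11, -745.0)
    ll[TRANSITION_NAMES.index(name)] = np.log(rate)
    return IntensityParameters(ll)


# -- per-interval oracles ----------------------------------------------------

def test_two_state_toy_survival_closed_form():
    """Only FMD->MMD active: staying in FMD over dt has log-prob -lambda*dt."""
    p = single_rate_params("fmd_mmd", 0.3)
    ll = interval_loglik(obs(0.0, 1), obs(2.0, 1), p)
    assert ll == pytest.approx(-0.3 * 2.0, abs=1e-12)


def test_exact_cvd_death_exponential_density():
    """Only CVD death active from CVD: density is mu * exp(-mu*dt)."""
    mu = 0.02
    p = single_rate_params("cvd_cvd_death", mu)
    ll = interval_loglik(obs(1.0, 4, "exact_event"), obs(1.75, 5, "exact_event"), p)
    assert ll == pytest.approx(-mu * 0.75 + np.log(mu), abs=1e-12)


def test_exact_onset_density_single_path():
    """Only FMD->CVD active: onset at dt from FMD is a pure exponential."""
    lam = 0.05
    p = single_rate_params("fmd_cvd", lam)
    ll = interval_loglik(obs(0.0, 1), obs(0.6, 4, "exact_event"), p)
    assert ll == pytest.approx(-lam * 0.6 + np.log(lam), abs=1e-12)


def test_interval_data_errors(truth):
    with pytest.raises(DataError):
        interval_loglik(obs(0.0, 5, "exact_event"), obs(1.0, 6, "exact_event"), truth)
    with pytest.raises(DataError):
        interval_loglik(obs(1.0, 1), obs(1.0, 2), truth)


def test_impossible_observation_returns_neg_inf_with_diagnostic(truth):
    diag = []
    ll = interval_loglik(obs(0.0, 3), obs(1.0, 1), truth, diagnostics=diag)
    assert ll == float("-inf")
    assert diag and diag[0]["from"] == 3 and diag[0]["to"] == 1
    # CVD death without onset is likewise impossible, not an exception
    assert interval_loglik(obs(0.0, 2), obs(1.0, 5, "exact_event"), truth) == float("-inf")


def test_panel_next_state_probabilities_sum_to_one(truth):
    """Treating all six states as panel-observable, the next-state law is a
    probability distribution (row-stochasticity pushed through the likelihood)."""
    prev = obs(0.0, 2, age=61.0, sex="male")
    total = sum(
        np.exp(interval_loglik(prev, obs(1.4, s, "exact_event" if s > 3 else "panel"),
                               truth, events_as_panel=True))
        for s in range(1, 7)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_cvd_track_age_refresh_is_piecewise(truth):
    """A 2.5y CVD survival interval uses three age segments, not one."""
    prev = obs(0.0, 4, "exact_event", age=60.0, sex="male")
    ll = interval_loglik(prev, obs(2.5, 6, "exact_event"), truth)
    tot = 0.0
    for a, d in ((60.0, 1.0), (61.0, 1.0), (62.0, 0.5)):
        tot += (truth.intensity((4, 5), a, "male") + truth.intensity((4, 6), a, "male")) * d
    expected = -tot + np.log(truth.intensity((4, 6), 62.0, "male"))
    assert ll == pytest.approx(expected, abs=1e-12)


# -- cohort-level properties -------------------------------------------------

def test_cohort_additivity_and_empty(truth, small_cohort):
    hist = small_cohort.histories[:40]
    one = cohort_loglik(hist, truth)
    two = cohort_loglik(hist + hist, truth)
    assert two == pytest.approx(2 * one, rel=1e-12)
    with pytest.raises(DataError):
        cohort_loglik([], truth)


def test_single_observation_contributes_zero(truth):
    h = SubjectHistory([obs(0.0, 1)])
    assert cohort_loglik([h], truth) == 0.0


def test_time_origin_shift_invariance(truth, small_cohort):
    shifted = []
    for h in small_cohort.histories[:60]:
        shifted.append(SubjectHistory([
            PanelObservation(o.subject_id, o.time + 0.37, o.state, o.obs_kind,
                             o.age_at_obs, o.sex) for o in h
        ]))
    a = cohort_loglik(small_cohort.histories[:60], truth)
    b = cohort_loglik(shifted, truth)
    assert b == pytest.approx(a, rel=1e-12)


def test_fast_path_matches_reference(truth, small_cohort):
    hist = small_cohort.histories
    fast = cohort_loglik(hist, truth)
    slow = sum(interval_loglik(p, n, truth) for h in hist for p, n in h.intervals())
    assert fast == pytest.approx(slow, rel=1e-12)


def test_analytic_gradient_matches_finite_differences(truth, small_compiled):
    theta = truth.to_vector()
    _, grad = cohort_loglik_and_grad(theta, small_compiled, truth.reference_age)
    rng = np.random.default_rng(5)
    for point in (theta, theta + rng.normal(0, 0.1, len(theta))):
        _, g = cohort_loglik_and_grad(point, small_compiled, truth.reference_age)
        num = np.zeros_like(g)
        for i in range(len(point)):
            h = 1e-6 * max(1.0, abs(point[i]))
            tp, tm = point.copy(), point.copy()
            tp[i] += h
            tm[i] -= h
            fp, _ = cohort_loglik_and_grad(tp, small_compiled, truth.reference_age)
            fm, _ = cohort_loglik_and_grad(tm, small_compiled, truth.reference_age)
            num[i] = (fp - fm) / (2 * h)
        assert np.max(np.abs(g - num) / (1.0 + np.abs(num))) < 1e-5


def test_loglik_higher_at_truth_than_at_perturbations(truth, small_compiled):
    """Monte-Carlo consistency: the generating parameters beat perturbed ones
    on average (here: against several fixed distortions of the truth)."""
    base, _ = cohort_loglik_and_grad(truth.to_vector(), small_compiled, 50.0)
    rng = np.random.default_rng(9)
    worse = 0
    for _ in range(8):
        theta = truth.to_vector() + rng.normal(0, 0.4, 27)
        nll, _ = cohort_loglik_and_grad(theta, small_compiled, 50.0)
        worse += nll > base
    assert worse >= 6


# -- history validation and I/O ----------------------------------------------

def test_history_validation_rules():
    with pytest.raises(DataError):  # first observation must be a panel RMRC state
        SubjectHistory([obs(0.0, 4, "exact_event")])
    with pytest.raises(DataError):  # decreasing times
        SubjectHistory([obs(0.0, 1), obs(0.0, 2)])
    with pytest.raises(DataError):  # death states cannot be panel-observed
        SubjectHistory([obs(0.0, 1), obs(1.0, 5)])
    with pytest.raises(DataError):  # CVD death requires a prior onset
        SubjectHistory([obs(0.0, 1), obs(1.0, 5, "exact_event")])
    with pytest.raises(DataError):  # nothing after an absorbing state
        SubjectHistory([obs(0.0, 1), obs(1.0, 6, "exact_event"), obs(2.0, 6, "censor")])
    with pytest.raises(DataError):  # regression out of MetS forbidden
        SubjectHistory([obs(0.0, 3), obs(1.0, 2)])
    # a legal illness-death path
    SubjectHistory([obs(0.0, 2), obs(1.0, 3), obs(1.6, 4, "exact_event"),
                    obs(2.9, 5, "exact_event")])


def test_carry_forward_and_rejection(small_cohort):
    df = histories_to_frame(small_cohort.histories[:50])
    # inject a MetS regression: find a subject whose screens include MetS
    hist, report = histories_from_frame(df)
    assert report["n_subjects"] == 50 and report["n_rejected"] == 0

    bad = df.copy()
    sid = bad["subject_id"].iloc[0]
    rows = bad["subject_id"] == sid
    bad.loc[rows, "state"] = [3] + [1] * (rows.sum() - 1)
    bad.loc[rows, "obs_kind"] = "panel"
    hist2, report2 = histories_from_frame(bad)
    assert report2["n_carried_forward"] == rows.sum() - 1
    h = next(h for h in hist2 if h.subject_id == sid)
    assert all(o.state == 3 for o in h)
    _, report3 = histories_from_frame(bad, carry_forward_mets=False)
    assert report3["n_rejected"] == 1


def test_panel_csv_round_trip(tmp_path, small_cohort):
    from metsmarkov import read_panel, write_panel

    path = tmp_path / "panel.csv"
    write_panel(small_cohort.histories, path)
    hist, report = read_panel(path)
    assert report["n_subjects"] == len(small_cohort.histories)
    orig = histories_to_frame(small_cohort.histories)
    back = histories_to_frame(hist)
    assert np.allclose(back["time_years"], orig["time_years"])
    assert (back["state"] == orig["state"]).all()


def test_schema_validation_line_numbered(tmp_path):
    import pandas as pd

    df = pd.DataFrame({"subject_id": ["a"], "time_years": [0.0]})
    with pytest.raises(DataError, match="lacks columns"):
        histories_from_frame(df)
    df = pd.DataFrame({
        "subject_id": ["a"], "time_years": [0.0], "state": [9],
        "obs_kind": ["panel"], "age": [50.0], "sex": ["female"],
    })
    with pytest.raises(DataError, match="line 0"):
        histories_from_frame(df)
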