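"""Simulator: determinism, closed-form oracles, simulator-vs-analytic binding."""

import dataclasses
import filecmp

import numpy as np
import pytest

from metsmarkov import (
    CohortSpec,
    IntensityParameters,
    build_generator,
    generate_cohort,
    histories_from_frame,
    histories_to_frame,
    observe_panel,
    simulate_trajectory,
    transition_probability,
)
from metsmarkov.exceptions import SpecError
from metsmarkov.states import ObsKind
from metsmarkov.likelihood import DAY


def test_spec_validation():
    with pytest.raises(SpecError):
        CohortSpec(baseline_state_probs=(0.5, 0.2, 0.2))
    with pytest.raises(SpecError):
        CohortSpec(attendance_prob=0.0)
    with pytest.raises(SpecError):
        CohortSpec(followup_years=-1)


def test_spec_yaml_round_trip(tmp_path):
    spec = CohortSpec(n_subjects=123, seed=9, attendance_prob=0.8,
                      screen_schedule="irregular")
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = CohortSpec.from_yaml(path)
    assert back.n_subjects == 123 and back.screen_schedule == "irregular"
    assert np.array_equal(back.params.to_vector(), spec.params.to_vector())


def test_generate_cohort_deterministic(tmp_path, truth):
    spec = CohortSpec(n_subjects=150, seed=31, params=truth)
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    generate_cohort(spec, out_csv=a)
    generate_cohort(dataclasses.replace(spec), out_csv=b)
    assert filecmp.cmp(a, b, shallow=False)


def test_zero_intensities_survive_to_horizon(truth):
    frozen = IntensityParameters(np.full(11, -745.0))
    rng = np.random.default_rng(0)
    traj = simulate_trajectory(2, 50.0, "female", frozen, 10.0, rng)
    assert traj == [(0.0, 2)]
    with pytest.raises(SpecError):
        simulate_trajectory(2, 50.0, "female", frozen, 0.0, rng)
    with pytest.raises(SpecError):
        simulate_trajectory(4, 50.0, "female", frozen, 1.0, rng)


def test_single_exit_mean_jump_time():
    """Exponential-mean oracle on a single-exit toy (rate 0.5/yr)."""
    lam = 0.5
    ll = np.full(11, -745.0)
    ll[0] = np.log(lam)
    p = IntensityParameters(ll)
    rng = np.random.default_rng(314)
    times = []
    for _ in range(10000):
        traj = simulate_trajectory(1, 50.0, "female", p, 200.0, rng, refresh_years=None)
        assert len(traj) == 2 and traj[1][1] == 2
        times.append(traj[1][0])
    se = (1 / lam) / np.sqrt(len(times))
    assert abs(np.mean(times) - 1 / lam) < 3 * se


def test_occupancy_matches_yearly_refresh_product(truth):
    """Simulator vs analytic oracle: the state distribution two years in equals
    the product of two one-year transition-probability matrices (ages 60, 61)."""
    rng = np.random.default_rng(77)
    n = 12000
    counts = np.zeros(6)
    for _ in range(n):
        traj = simulate_trajectory(2, 60.0, "male", truth, 2.0, rng)
        s = traj[-1][1] if traj[-1][0] <= 2.0 else 2
        counts[s - 1] += 1
    P = transition_probability(build_generator(truth, 60.0, "male"), 1.0) @ \
        transition_probability(build_generator(truth, 61.0, "male"), 1.0)
    expected = P[1]
    for j in range(6):
        se = np.sqrt(max(expected[j] * (1 - expected[j]), 1e-12) / n)
        assert abs(counts[j] / n - expected[j]) <= 3 * se + 1e-9


def test_baseline_mix_matches_reference_cohort(truth):
    """At the full reference size the realised baseline counts stay within
    three multinomial SEs of the published-scale mix (16886/22480/8129)."""
    spec = CohortSpec(n_subjects=47495, seed=1999, params=truth)
    cohort = generate_cohort(spec)
    mix = cohort.summary["baseline_mix"]
    for s, target, p in ((1, 16886, 0.3555), (2, 22480, 0.4733), (3, 8129, 0.1712)):
        se = np.sqrt(47495 * p * (1 - p))
        assert abs(mix[s] - target) <= 3 * se
    prop_f = cohort.summary["n_female"] / 47495
    assert prop_f == pytest.approx(0.60, abs=0.01)


def test_observation_counts_annual_no_events(truth):
    frozen = IntensityParameters(np.full(11, -745.0))
    spec = CohortSpec(n_subjects=20, seed=4, params=frozen)
    cohort = generate_cohort(spec)
    for h in cohort.histories:
        assert len(h) == int(spec.followup_years) + 1  # screens at 0..3, no censor
        assert all(o.obs_kind == ObsKind.PANEL.value for o in h)
        states = [o.state for o in h]
        assert len(set(states)) == 1  # frozen dynamics: state never changes


def test_every_living_subject_has_two_observations(truth):
    cohort = generate_cohort(CohortSpec(n_subjects=300, seed=8, params=truth))
    for h in cohort.histories:
        last = h.observations[-1]
        died_first_year = last.obs_kind == ObsKind.EXACT.value and last.time <= 1.0
        if not died_first_year:
            assert len(h) >= 2


def test_absorbed_before_first_followup_screen(truth):
    """A trajectory absorbed into OCD before the year-1 screen yields exactly
    baseline + one exact event."""
    d = truth.to_dict()
    for k in ("fmd_ocd", "mmd_ocd", "mets_ocd"):
        d["lambda0"][k] = 50.0  # near-immediate other-cause death
    for k in ("fmd_cvd", "mmd_cvd", "mets_cvd"):
        d["lambda0"][k] = 1e-12  # keep CVD onset out of the race
    lethal = IntensityParameters.from_dict(d)
    cohort = generate_cohort(CohortSpec(n_subjects=30, seed=6, params=lethal))
    for h in cohort.histories:
        assert len(h) == 2
        assert h.observations[1].obs_kind == ObsKind.EXACT.value
        assert h.observations[1].state == 6
        assert h.observations[1].time < 1.0


def test_generated_histories_revalidate_and_event_grid(truth):
    cohort = generate_cohort(CohortSpec(n_subjects=400, seed=21, params=truth))
    df = histories_to_frame(cohort.histories)
    hist, report = histories_from_frame(df)
    assert report["n_rejected"] == 0 and report["n_subjects"] == 400
    events = df[df.obs_kind == "exact_event"]
    assert len(events) > 0
    # registry dates sit on the day grid
    assert np.allclose(np.round(events.time_years / DAY) * DAY, events.time_years,
                       atol=1e-9)


def test_absorbing_counts_nondecreasing(truth):
    cohort = generate_cohort(CohortSpec(n_subjects=600, seed=13, params=truth))
    df = histories_to_frame(cohort.histories)
    deaths = df[df.state.isin([5, 6]) & (df.obs_kind == "exact_event")]
    cum = [((deaths.time_years <= t).sum()) for t in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)]
    assert all(a <= b for a, b in zip(cum, cum[1:]))


def test_irregular_schedule_gaps(truth):
    spec = CohortSpec(n_subjects=200, seed=15, params=truth,
                      screen_schedule="irregular", followup_years=8.0)
    cohort = generate_cohort(spec)
    saw_gap = set()
    for h in cohort.histories:
        panels = [o.time for o in h if o.obs_kind == ObsKind.PANEL.value]
        gaps = np.diff(panels)
        assert np.all(gaps >= 1.0 - 1e-9) and np.all(gaps <= 8.0 + 1e-9)
        saw_gap.update(int(round(g)) for g in gaps if abs(g - round(g)) < 1e-9)
    assert {1, 2, 3, 4} <= saw_gap


def test_attendance_prob_thins_screens(truth):
    full = generate_cohort(CohortSpec(n_subjects=400, seed=33, params=truth))
    thin = generate_cohort(CohortSpec(n_subjects=400, seed=33, params=truth,
                                      attendance_prob=0.5))
    n_full = sum(sum(o.obs_kind == ObsKind.PANEL.value for o in h) for h in full.histories)
    n_thin = sum(sum(o.obs_kind == ObsKind.PANEL.value for o in h) for h in thin.histories)
    assert n_thin < 0.75 * n_full
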