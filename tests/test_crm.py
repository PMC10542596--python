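"""CRM engine: skeletons, posterior quadrature, allocation, stopping, restarts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import dosewalk as dw
from dosewalk.crm import (
    CONTINUE,
    RESTART_HIGHER,
    RESTART_LOWER,
    RestartRules,
    Skeleton,
    WorkingModel,
    allocate_next_dose,
    build_working_model,
    check_restart,
    plateau_reached,
    posterior_probabilities,
    run_crm_trial,
    shift_window,
    skeleton_for_target,
)
from dosewalk.testing import constant_curve


def brute_force_posterior(skeleton, sigma, history, step=1e-4, span=10.0):
    """Fine-grid trapezoid integration oracle for the posterior means.

    Direct evaluation of p_i = s_i ** exp(theta) under the binomial
    likelihood, independent of the cached-grid implementation.
    """
    theta = np.arange(-span, span + step / 2, step)
    prior = norm.pdf(theta, 0, sigma)
    s = np.asarray(skeleton)
    p = s[None, :] ** np.exp(theta)[:, None]
    lik = np.ones_like(theta)
    for pos, outcome in history:
        lik = lik * (p[:, pos] if outcome else 1 - p[:, pos])
    w = prior * lik
    den = np.trapezoid(w, theta)
    return np.array([np.trapezoid(w * p[:, i], theta) / den for i in range(s.size)])


# ------------------------------------------------------- working models

def test_study_skeletons():
    sk90 = skeleton_for_target(0.90)
    sk95 = skeleton_for_target(0.95)
    assert sk90.probs == (0.50, 0.60, 0.75, 0.90, 0.95, 0.98)
    assert sk95.probs == (0.50, 0.75, 0.90, 0.95, 0.98, 0.99)
    # the target prior sits at position 4 of 6 in both
    assert sk90.probs[sk90.target_position] == 0.90
    assert sk95.probs[sk95.target_position] == 0.95


@pytest.mark.parametrize(
    "start, target, expected_window",
    [
        (4, 0.95, (1, 2, 3, 4, 5, 6)),
        (1, 0.95, (-2, -1, 0, 1, 2, 3)),  # virtual doses below the grid
        (25, 0.90, (22, 23, 24, 25, 26, 27)),  # virtual doses above it
    ],
)
def test_window_places_start_at_target_position(start, target, expected_window):
    model = build_working_model(start, target)
    assert model.window == expected_window
    assert model.window[model.skeleton.target_position] == start


def test_invalid_skeletons_rejected():
    with pytest.raises(ValueError):
        Skeleton((0.5, 0.5, 0.9), 0)  # not strictly increasing
    with pytest.raises(ValueError):
        Skeleton((0.5, 1.0), 0)  # prior at 1
    with pytest.raises(ValueError):
        skeleton_for_target(0.5)


# ------------------------------------------------------------ posterior

def test_vanishing_prior_spread_returns_skeleton():
    model = build_working_model(10, 0.95, sigma=1e-7)
    post = posterior_probabilities(model, [(10, True), (10, False)])
    assert post == pytest.approx(model.skeleton.probs, abs=1e-5)


def test_posterior_preserves_skeleton_ordering(curves):
    model = build_working_model(13, 0.95)
    history = [(13, True), (13, True), (12, False), (14, True)]
    post = posterior_probabilities(model, history)
    assert np.all(np.diff(post) > 0)
    assert np.all((post > 0) & (post < 1))


def test_two_dose_posterior_matches_fine_grid_oracle():
    model = WorkingModel(window=(1, 2), skeleton=Skeleton((0.5, 0.9), 1), sigma=1.34)
    post = posterior_probabilities(model, [(2, True), (2, True)])
    oracle = brute_force_posterior((0.5, 0.9), 1.34, [(1, True), (1, True)])
    assert post == pytest.approx([0.57604767, 0.89366049], abs=1e-6)
    assert np.max(np.abs(post - oracle)) < 1e-6


@given(
    data=st.lists(
        st.tuples(st.integers(0, 5), st.booleans()), min_size=0, max_size=10
    ),
    sigma=st.sampled_from([0.8, 1.34, 2.0]),
)
def test_quadrature_matches_oracle_on_random_histories(data, sigma):
    skeleton = (0.50, 0.75, 0.90, 0.95, 0.98, 0.99)
    model = WorkingModel(
        window=tuple(range(8, 14)), skeleton=Skeleton(skeleton, 3), sigma=sigma
    )
    history = [(8 + pos, out) for pos, out in data]
    post = posterior_probabilities(model, history)
    oracle = brute_force_posterior(skeleton, sigma, data)
    assert np.max(np.abs(post - oracle)) < 1e-6


def test_history_outside_window_rejected():
    model = build_working_model(10, 0.95)
    with pytest.raises(ValueError, match="outside the window"):
        posterior_probabilities(model, [(20, True)])


# ----------------------------------------------------------- allocation

def test_allocation_picks_smallest_posterior_at_or_above_target():
    window = tuple(range(10, 16))
    post = (0.70, 0.88, 0.96, 0.99, 0.995, 0.999)
    assert allocate_next_dose(post, 0.95, window) == 12  # the 0.96 dose


def test_allocation_escalates_when_no_dose_qualifies():
    window = tuple(range(10, 16))
    post = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    assert allocate_next_dose(post, 0.95, window) == 15


def test_allocation_equality_counts_as_qualifying():
    window = tuple(range(10, 16))
    post = (0.5, 0.7, 0.95, 0.97, 0.98, 0.99)
    assert allocate_next_dose(post, 0.95, window) == 12


@given(
    post=st.lists(st.floats(0.01, 0.99), min_size=6, max_size=6),
    bump=st.floats(0.0, 0.2),
)
def test_allocation_monotone_in_posteriors(post, bump):
    window = tuple(range(1, 7))
    post = np.sort(np.asarray(post))
    if np.any(np.diff(post) <= 0):
        post = post + np.arange(6) * 1e-6
    higher = np.minimum(post + bump, 0.999)
    d1 = allocate_next_dose(post, 0.9, window)
    d2 = allocate_next_dose(higher, 0.9, window)
    assert d2 <= d1  # raising every posterior weakly lowers the allocation


# ------------------------------------------------------------- stopping

def test_plateau_requires_eight_consecutive_and_stable_recommendation():
    assert plateau_reached([11] * 3 + [12] * 8, 12) is True
    assert plateau_reached([12] * 7, 12) is False
    assert plateau_reached([11] + [12] * 7, 12) is False
    assert plateau_reached([12] * 8, 13) is False


def test_restart_rules():
    rules = RestartRules.for_target(0.95)
    high = np.full(6, 0.93)
    low = np.full(6, 0.5)
    mid = np.array([0.5, 0.7, 0.9, 0.95, 0.98, 0.99])
    # rule (c): all posteriors beyond the cuts
    assert check_restart(10, 1, high, rules, first_segment=False, segment_complete=False) == RESTART_LOWER
    assert check_restart(10, 1, low, rules, first_segment=False, segment_complete=False) == RESTART_HIGHER
    # rule (b): failure fraction above 25%
    assert check_restart(10, 3, mid, rules, first_segment=False, segment_complete=False) == RESTART_HIGHER
    # rule (a): completed first segment without any failure
    assert check_restart(36, 0, mid, rules, first_segment=True, segment_complete=True) == RESTART_LOWER
    assert check_restart(36, 0, mid, rules, first_segment=False, segment_complete=True) == CONTINUE
    # gate: too few patients for rules (b)/(c)
    assert check_restart(6, 6, low, rules, first_segment=True, segment_complete=False) == CONTINUE
    assert check_restart(10, 2, mid, rules, first_segment=False, segment_complete=False) == CONTINUE


def test_ed90_rules_use_lower_cuts():
    rules = RestartRules.for_target(0.90)
    assert rules.high_posterior_cut == 0.875
    assert rules.low_posterior_cut == 0.70


@pytest.mark.parametrize(
    "window, direction, expected",
    [
        ((1, 2, 3, 4, 5, 6), "higher", (4, 5, 6, 7, 8, 9)),
        ((20, 21, 22, 23, 24, 25), "higher", (23, 24, 25, 26, 27, 28)),
        ((1, 2, 3, 4, 5, 6), "lower", (-2, -1, 0, 1, 2, 3)),
    ],
)
def test_shift_window_translates(window, direction, expected):
    model = WorkingModel(window, skeleton_for_target(0.95))
    shifted = shift_window(model, direction, RestartRules.for_target(0.95))
    assert shifted.window == expected
    assert shifted.skeleton is model.skeleton


# ------------------------------------------------------------ full trial

@pytest.mark.parametrize("cohort", [2, 4])
@pytest.mark.parametrize("curve_id", [1, 3])
def test_trial_always_estimates_and_respects_segment_cap(curves, curve_id, cohort):
    for start in (1, 8, 16, 25):
        for rep in range(5):
            rng = dw.seed_stream(42, "crm", curve_id, 0.95, start, rep, cohort)
            result = run_crm_trial(curves[curve_id], start, 0.95, cohort, rng)
            assert result.estimate is not None
            assert all(size <= 36 for size in result.extras["segment_sizes"])
            assert sum(result.extras["segment_sizes"]) == result.n_patients
            assert result.extras["segments"] <= 5
            assert result.n_patients % cohort == 0


def test_all_success_first_crm_restarts_lower(rng):
    # on an all-success curve the first CRM can never localise the target,
    # so rule (a) must fire at least once
    result = run_crm_trial(constant_curve(1.0), 20, 0.95, 2, rng)
    assert result.extras["segments"] > 1
    assert result.n_failures == 0
    # the walk must have descended
    assert min(result.doses) < 20


def test_virtual_doses_respond_deterministically(rng):
    # starting at dose 1 targeting ED95 puts doses -2..0 in the window;
    # any patient treated there must fail
    result = run_crm_trial(dw.build_curve(1), 1, 0.95, 2, rng)
    for d, y in zip(result.doses, result.outcomes):
        if d < 1:
            assert y is False or y == 0


def test_invalid_cohort_rejected(curves, rng):
    with pytest.raises(ValueError):
        run_crm_trial(curves[1], 10, 0.95, 3, rng)
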