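"""Continual reassessment method (CRM) with restart random walk.

The CRM works on a window of six consecutive doses centred a little
above its starting dose, with a fixed skeleton of prior success
probabilities; the starting dose always occupies the window position
whose prior equals the target level (position 4 of 6).  Windows may
extend below dose 1 or above dose 25: such virtual doses respond
deterministically (certain failure below the grid, certain success
above it), which lets doses 1 and 25 themselves be candidate EDs.

Model: one-parameter power ("empiric") model ``p_i(theta) =
s_i ** exp(theta)`` with ``theta ~ Normal(0, sigma)``, the standard CRM
working model.  Posterior means of the ``p_i`` are computed by
deterministic trapezoid quadrature, so runs are exactly reproducible.

After each cohort (2 or 4 patients) the posterior is updated and the
next cohort is assigned the lowest window dose whose posterior success
probability is at or above the target.  A CRM segment stops on the
"8+1" plateau rule (eight consecutive patients at one dose and an
unchanged recommendation), or after 36 patients.  When the data say the
window is far from the target — no failure in a completed first
segment, a running failure fraction above 25%, or all posteriors beyond
the high/low cut-offs — the segment is abandoned and a new CRM opens on
a window shifted a few doses up or down (the restart random walk).  The
trial therefore always terminates with a recommendation: the dose that
would be assigned to a hypothetical next cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .dose_response import N_DOSES, success_probability
from .trials import TrialResult

__all__ = [
    "Skeleton",
    "WorkingModel",
    "RestartRules",
    "CONTINUE",
    "RESTART_HIGHER",
    "RESTART_LOWER",
    "skeleton_for_target",
    "build_working_model",
    "posterior_probabilities",
    "allocate_next_dose",
    "plateau_reached",
    "check_restart",
    "shift_window",
    "run_crm_trial",
]

CONTINUE = "continue"
RESTART_HIGHER = "restart_higher"
RESTART_LOWER = "restart_lower"

DEFAULT_SIGMA = 1.34
SEGMENT_CAP = 36  # patients per CRM segment
PLATEAU_RUN = 8  # consecutive patients at one dose for the 8+1 rule

_QUAD_NODES = 2001
_QUAD_HALF_WIDTH = 8.0  # integration range in units of sigma


@dataclass(frozen=True)
class Skeleton:
    """Ordered prior success probabilities for a CRM window."""

    probs: tuple
    target_position: int  # 0-based index of the prior equal to the target

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.size < 2:
            raise ValueError("skeleton needs at least two doses")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("skeleton priors must lie strictly in (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("skeleton priors must be strictly increasing")
        if not 0 <= self.target_position < p.size:
            raise ValueError("target position outside the skeleton")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))


_SKELETONS = {
    90: Skeleton((0.50, 0.60, 0.75, 0.90, 0.95, 0.98), 3),
    95: Skeleton((0.50, 0.75, 0.90, 0.95, 0.98, 0.99), 3),
}


def skeleton_for_target(target: float) -> Skeleton:
    """The study skeleton for a target of 0.90 or 0.95."""
    key = int(round(target * 100))
    try:
        return _SKELETONS[key]
    except KeyError:
        raise ValueError(f"supported targets are 0.90 and 0.95, got {target}") from None


@dataclass(frozen=True)
class WorkingModel:
    """A window of consecutive dose indices paired with a skeleton."""

    window: tuple
    skeleton: Skeleton
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        w = tuple(int(d) for d in self.window)
        if len(w) != len(self.skeleton.probs):
            raise ValueError("window and skeleton must have equal length")
        if any(b - a != 1 for a, b in zip(w, w[1:])):
            raise ValueError("window doses must be consecutive and increasing")
        if self.sigma <= 0:
            raise ValueError("prior spread sigma must be positive")
        object.__setattr__(self, "window", w)

    def position(self, dose: int) -> int:
        try:
            return self.window.index(int(dose))
        except ValueError:
            raise ValueError(f"dose {dose} lies outside the window {self.window}") from None


@dataclass(frozen=True)
class RestartRules:
    """Cut-offs of the between-CRM restart random walk."""

    failure_fraction_cut: float = 0.25
    high_posterior_cut: float = 0.925
    low_posterior_cut: float = 0.75
    window_shift: int = 3
    max_segments: int = 5
    min_patients: int = 8  # patients in a segment before rules (b)/(c) apply

    def __post_init__(self) -> None:
        if not self.low_posterior_cut < self.high_posterior_cut:
            raise ValueError("low cut must lie below high cut")
        if self.window_shift < 1 or self.max_segments < 1:
            raise ValueError("window_shift and max_segments must be >= 1")

    @classmethod
    def for_target(cls, target: float, **overrides) -> "RestartRules":
        key = int(round(target * 100))
        cuts = {95: (0.925, 0.75), 90: (0.875, 0.70)}
        if key not in cuts:
            raise ValueError(f"supported targets are 0.90 and 0.95, got {target}")
        high, low = cuts[key]
        return cls(high_posterior_cut=high, low_posterior_cut=low, **overrides)


def build_working_model(
    start: int, target: float, sigma: float = DEFAULT_SIGMA
) -> WorkingModel:
    """Window of six consecutive doses with ``start`` at the target position."""
    if not 1 <= start <= N_DOSES:
        raise ValueError(f"starting dose must lie in [1, {N_DOSES}], got {start}")
    sk = skeleton_for_target(target)
    lo = start - sk.target_position
    window = tuple(range(lo, lo + len(sk.probs)))
    return WorkingModel(window, sk, sigma)


@lru_cache(maxsize=64)
def _quadrature_grid(skeleton_probs: tuple, sigma: float):
    """Cached theta grid and per-node quantities for one skeleton/prior.

    Returns (log_prior + trapezoid log-weights, p, log_p, log_1mp) where
    p has shape (nodes, k).  The Gaussian normalising constant and the
    node spacing cancel in the posterior-mean ratio and are omitted.
    """
    theta = np.linspace(-_QUAD_HALF_WIDTH * sigma, _QUAD_HALF_WIDTH * sigma, _QUAD_NODES)
    log_prior = -0.5 * (theta / sigma) ** 2
    trap = np.zeros(_QUAD_NODES)
    trap[0] = trap[-1] = np.log(0.5)
    log_p = np.outer(np.exp(theta), np.log(np.asarray(skeleton_probs)))  # < 0
    p = np.exp(log_p)
    log_1mp = np.log(-np.expm1(log_p))
    return log_prior + trap, p, log_p, log_1mp


def _posterior_from_counts(
    model: WorkingModel, trials: np.ndarray, successes: np.ndarray
) -> np.ndarray:
    base, p, log_p, log_1mp = _quadrature_grid(model.skeleton.probs, float(model.sigma))
    loglik = log_p @ successes + log_1mp @ (trials - successes)
    w = np.exp(base + loglik - np.max(base + loglik))
    return (w @ p) / np.sum(w)


def posterior_probabilities(
    model: WorkingModel, history: Iterable[tuple]
) -> np.ndarray:
    """Posterior mean success probability for every window dose.

    ``history`` is an iterable of ``(dose, outcome)`` pairs from the
    current CRM segment; every dose must lie inside the model window.
    In the limit of a vanishing prior spread the result collapses to the
    skeleton itself.
    """
    k = len(model.window)
    trials = np.zeros(k)
    successes = np.zeros(k)
    for dose, outcome in history:
        i = model.position(dose)
        trials[i] += 1
        successes[i] += bool(outcome)
    return _posterior_from_counts(model, trials, successes)


def allocate_next_dose(
    posteriors: Sequence[float], target: float, window: Sequence[int]
) -> int:
    """Lowest window dose whose posterior success probability is >= target.

    Because the power model preserves the skeleton's ordering, this is
    the qualifying dose whose posterior sits closest to the target.  If
    no dose qualifies the highest window dose is returned (escalation).
    """
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.size != len(window):
        raise ValueError("posteriors and window must have equal length")
    idx = int(np.searchsorted(posteriors, target, side="left"))
    if idx == len(window):
        return int(window[-1])
    return int(window[idx])


def plateau_reached(
    segment_doses: Sequence[int], next_recommendation: int, run: int = PLATEAU_RUN
) -> bool:
    """The 8+1 rule: eight consecutive patients at one dose, recommendation unchanged."""
    if len(segment_doses) < run:
        return False
    tail = segment_doses[-run:]
    level = tail[0]
    return all(d == level for d in tail) and next_recommendation == level


def check_restart(
    n_segment: int,
    n_failures_segment: int,
    posteriors: Sequence[float],
    rules: RestartRules,
    *,
    first_segment: bool,
    segment_complete: bool,
) -> str:
    """Decide whether the current CRM should continue or be restarted.

    Rule (a): a first segment that ends (plateau or patient cap) without
    a single failure indicates the start was too high -> restart lower;
    an all-success CRM cannot localise the target quantile, so its
    recommendation is not trusted as an estimate.  Rule (b): a running
    failure fraction above the cut -> restart higher.  Rule (c): all
    posteriors beyond the high (low) cut -> restart lower (higher).
    Rules (b) and (c) are evaluated only once the segment has accrued
    ``rules.min_patients`` patients, so a single early failure cannot
    abort a segment.
    """
    if segment_complete and first_segment and n_failures_segment == 0:
        return RESTART_LOWER
    if n_segment >= rules.min_patients:
        if n_failures_segment / n_segment > rules.failure_fraction_cut:
            return RESTART_HIGHER
        posteriors = np.asarray(posteriors, dtype=float)
        if np.all(posteriors > rules.high_posterior_cut):
            return RESTART_LOWER
        if np.all(posteriors < rules.low_posterior_cut):
            return RESTART_HIGHER
    return CONTINUE


def shift_window(model: WorkingModel, direction: str, rules: RestartRules) -> WorkingModel:
    """Translate the window by ``rules.window_shift`` doses up or down."""
    if direction == "higher":
        delta = rules.window_shift
    elif direction == "lower":
        delta = -rules.window_shift
    else:
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    return replace(model, window=tuple(d + delta for d in model.window))


def run_crm_trial(
    curve,
    start: int,
    target: float,
    cohort_size: int,
    rng: np.random.Generator,
    *,
    rules: RestartRules | None = None,
    sigma: float = DEFAULT_SIGMA,
    n_doses: int = N_DOSES,
    replicate: int = -1,
) -> TrialResult:
    """Simulate one CRM trial (possibly several restarted segments).

    Patients are treated in cohorts at the allocated dose; virtual doses
    outside [1, n_doses] respond deterministically but count as patients
    and enter the likelihood.  A restart rule firing when a segment
    would otherwise stop takes precedence over the stop, so e.g. a
    zero-failure first CRM restarts lower rather than returning its
    plateau dose.  The returned estimate is the dose that would be
    allocated to a hypothetical next cohort at termination, so every
    trial yields an estimate.  Patients and failures accumulate across
    all segments.
    """
    if cohort_size not in (2, 4):
        raise ValueError(f"cohort size must be 2 or 4, got {cohort_size}")
    if rules is None:
        rules = RestartRules.for_target(target)

    model = build_working_model(start, target, sigma)
    k = len(model.window)
    all_doses: list[int] = []
    all_outcomes: list[bool] = []
    total_failures = 0
    segment = 1
    segment_sizes: list[int] = []
    seg_trials = np.zeros(k)
    seg_successes = np.zeros(k)
    seg_doses: list[int] = []
    seg_failures = 0
    current = start
    estimate: int | None = None

    while True:
        pos = model.position(current)
        p_true = success_probability(curve, current, virtual=True)
        for _ in range(cohort_size):
            if p_true <= 0.0:
                y = False
            elif p_true >= 1.0:
                y = True
            else:
                y = bool(rng.random() < p_true)
            all_doses.append(current)
            all_outcomes.append(y)
            seg_doses.append(current)
            seg_trials[pos] += 1
            seg_successes[pos] += y
            if not y:
                seg_failures += 1
                total_failures += 1

        posteriors = _posterior_from_counts(model, seg_trials, seg_successes)
        nxt = allocate_next_dose(posteriors, target, model.window)
        plateau = plateau_reached(seg_doses, nxt)
        complete = len(seg_doses) >= SEGMENT_CAP
        # a segment ending by plateau or cap counts as a completed CRM for
        # rule (a): a zero-failure first CRM is not trusted as an estimate
        action = check_restart(
            len(seg_doses),
            seg_failures,
            posteriors,
            rules,
            first_segment=segment == 1,
            segment_complete=complete or plateau,
        )
        if action == CONTINUE:
            if plateau or complete:
                estimate = nxt
                break
            current = nxt
        else:
            if segment >= rules.max_segments:
                estimate = nxt
                break
            direction = "lower" if action == RESTART_LOWER else "higher"
            model = shift_window(model, direction, rules)
            segment += 1
            segment_sizes.append(len(seg_doses))
            seg_trials = np.zeros(k)
            seg_successes = np.zeros(k)
            seg_doses = []
            seg_failures = 0
            current = model.window[model.skeleton.target_position]

    segment_sizes.append(len(seg_doses))
    return TrialResult(
        design="crm",
        estimate=float(estimate),
        n_patients=len(all_doses),
        n_failures=total_failures,
        doses=all_doses,
        outcomes=all_outcomes,
        replicate=replicate,
        extras={
            "segments": segment,
            "cohort_size": cohort_size,
            "segment_sizes": segment_sizes,
        },
    )
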