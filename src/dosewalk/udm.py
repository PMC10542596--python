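"""Classic up-and-down method (UDM).

A success at dose D sends the next patient to D-1, a failure to D+1, so
the walk equilibrates around the ED50.  The study protocol simulated
here runs a 40-patient phase (nominally pinning down the ED50) followed
by 50 further patients, and estimates the target quantile (ED90/ED95) by
centred isotonic regression on all 90 observations.  Because the walk
concentrates near the ED50, the high quantile often lies above the
fitted range and the trial returns no estimate; when it does estimate,
it tends to underestimate the true ED.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .cir import DoseOutcomeTable, estimate_ed
from .dose_response import success_probability
from .trials import TrialResult

PHASE1_PATIENTS = 40
PHASE2_PATIENTS = 50
TOTAL_PATIENTS = PHASE1_PATIENTS + PHASE2_PATIENTS

__all__ = [
    "PHASE1_PATIENTS",
    "PHASE2_PATIENTS",
    "TOTAL_PATIENTS",
    "udm_next_dose",
    "run_udm_trial",
    "proportion_test",
]


def udm_next_dose(current: int, outcome: bool, n_doses: int = 25) -> int:
    """Next dose after observing ``outcome`` at ``current`` (truncated to the grid)."""
    nxt = current - 1 if outcome else current + 1
    return min(max(nxt, 1), n_doses)


def _walk(curve, start, n_steps, rng, n_doses):
    draws = rng.random(n_steps)
    doses = np.empty(n_steps, dtype=int)
    outcomes = np.empty(n_steps, dtype=bool)
    d = start
    for i in range(n_steps):
        y = draws[i] < success_probability(curve, d)
        doses[i] = d
        outcomes[i] = y
        d = udm_next_dose(d, y, n_doses)
    return doses, outcomes, d


def run_udm_trial(
    curve,
    start: int,
    target: float,
    rng: np.random.Generator,
    *,
    phase2: str = "continue",
    n_doses: int = 25,
    replicate: int = -1,
) -> TrialResult:
    """Simulate one 90-patient up-and-down trial and estimate the target ED.

    ``phase2`` selects how the second 50-patient phase is seeded:
    ``"continue"`` (default) carries the walk on from the phase-1 end
    dose; ``"restart_ed50"`` restarts it at the nearest grid dose to the
    phase-1 CIR estimate of the ED50 (falling back to continuation when
    that estimate does not exist).  Both variants use all 90 observations
    for the final fit.
    """
    if not 1 <= start <= n_doses:
        raise ValueError(f"starting dose must lie in [1, {n_doses}], got {start}")
    if phase2 not in ("continue", "restart_ed50"):
        raise ValueError(f"unknown phase2 mode: {phase2!r}")

    d1, o1, end_dose = _walk(curve, start, PHASE1_PATIENTS, rng, n_doses)
    start2 = end_dose
    if phase2 == "restart_ed50":
        ed50 = estimate_ed(DoseOutcomeTable.from_history(d1, o1), 0.5)
        if ed50 is not None:
            start2 = min(max(int(round(ed50)), 1), n_doses)
    d2, o2, _ = _walk(curve, start2, PHASE2_PATIENTS, rng, n_doses)

    doses = np.concatenate([d1, d2])
    outcomes = np.concatenate([o1, o2])
    table = DoseOutcomeTable.from_history(doses, outcomes)
    estimate = estimate_ed(table, target)

    extras: dict = {"phase2": phase2}
    if estimate is not None:
        # one-sample proportion test on the data at the level nearest the estimate
        levels = np.asarray(table.levels)
        k = int(np.argmin(np.abs(levels - estimate)))
        est, lo, hi = proportion_test(table.successes[k], table.trials[k])
        extras["proportion_test"] = {
            "level": float(levels[k]),
            "estimate": est,
            "ci95": [lo, hi],
        }

    return TrialResult(
        design="udm",
        estimate=estimate,
        n_patients=int(doses.size),
        n_failures=int(np.sum(~outcomes)),
        doses=doses.tolist(),
        outcomes=outcomes.tolist(),
        replicate=replicate,
        extras=extras,
    )


def proportion_test(successes: int, trials: int) -> tuple[float, float, float]:
    """Point estimate and 95% Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise ValueError("proportion test requires at least one trial")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="wilson")
    return successes / trials, float(lo), float(hi)
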