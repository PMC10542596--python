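"""Biased-coin up-and-down design (BCD).

The biased-coin walk targets a quantile Gamma above 0.5 (here 0.90 or
0.95).  A failure always raises the next dose by one step.  After a
success a biased coin is tossed: with probability Gamma the same dose is
repeated, otherwise the dose is lowered by one step.  The stationary
dose distribution then centres near the ED_Gamma, and the target ED is
read off a centred isotonic regression fit of all observations.

The trial sizes follow the study protocol: 100 observations when
targeting the ED95 and 60 when targeting the ED90.

Two coin rules are available.  The default ``"paper"`` rule is the
literal stay-with-probability-Gamma rule above.  The classic
Durham-Flournoy construction instead stays with probability
``(2*Gamma - 1)/Gamma`` and moves down with ``(1 - Gamma)/Gamma``, which
makes the walk's stationary median sit exactly at the target quantile;
it is exposed as ``coin_rule="classic"``.
"""

from __future__ import annotations

import numpy as np

from .cir import DoseOutcomeTable, estimate_ed
from .dose_response import success_probability
from .trials import TrialResult

#: observations per trial, keyed by target level (percent)
TRIAL_SIZES = {90: 60, 95: 100}

__all__ = ["TRIAL_SIZES", "bcd_next_dose", "run_bcd_trial"]


def bcd_next_dose(
    current: int,
    outcome: bool,
    gamma: float,
    rng: np.random.Generator,
    *,
    coin_rule: str = "paper",
    n_doses: int = 25,
) -> int:
    """Next dose after ``outcome`` at ``current`` (truncated to the grid).

    Failure always escalates.  After a success the biased coin decides
    between repeating and de-escalating, according to ``coin_rule``.
    """
    if not outcome:
        return min(current + 1, n_doses)
    if coin_rule == "paper":
        stay = rng.random() < gamma
    elif coin_rule == "classic":
        stay = rng.random() >= (1.0 - gamma) / gamma
    else:
        raise ValueError(f"unknown coin rule: {coin_rule!r}")
    return current if stay else max(current - 1, 1)


def run_bcd_trial(
    curve,
    start: int,
    target: float,
    rng: np.random.Generator,
    *,
    coin_rule: str = "paper",
    n_doses: int = 25,
    replicate: int = -1,
) -> TrialResult:
    """Simulate one biased-coin trial and estimate the target ED by CIR."""
    if not 1 <= start <= n_doses:
        raise ValueError(f"starting dose must lie in [1, {n_doses}], got {start}")
    key = int(round(target * 100))
    if key not in TRIAL_SIZES:
        raise ValueError(f"supported targets are 0.90 and 0.95, got {target}")
    n_steps = TRIAL_SIZES[key]

    outcome_draws = rng.random(n_steps)
    coin_draws = rng.random(n_steps)  # consumed only on success, fixed layout
    doses = np.empty(n_steps, dtype=int)
    outcomes = np.empty(n_steps, dtype=bool)
    d = start
    for i in range(n_steps):
        y = outcome_draws[i] < success_probability(curve, d)
        doses[i] = d
        outcomes[i] = y
        if y:
            if coin_rule == "paper":
                stay = coin_draws[i] < target
            else:
                stay = coin_draws[i] >= (1.0 - target) / target
            d = d if stay else max(d - 1, 1)
        else:
            d = min(d + 1, n_doses)

    table = DoseOutcomeTable.from_history(doses, outcomes)
    estimate = estimate_ed(table, target)
    return TrialResult(
        design="bcd",
        estimate=estimate,
        n_patients=n_steps,
        n_failures=int(np.sum(~outcomes)),
        doses=doses.tolist(),
        outcomes=outcomes.tolist(),
        replicate=replicate,
        extras={"coin_rule": coin_rule},
    )
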