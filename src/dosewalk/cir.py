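"""Centred isotonic regression (CIR) on binary dose-outcome data.

The up-and-down designs estimate the target ED by inverse regression:
per-dose success rates are made monotone with weighted isotonic
regression (pool-adjacent-violators, weights = number of trials), every
maximal flat stretch of the monotone fit is collapsed to a single point
at the trial-weighted mean of its dose indices, and the target level is
read off the strictly increasing centred curve by linear interpolation.

When the target level falls outside the fitted probability range no
estimate is returned: extrapolating an ED95 from data concentrated
around the ED50 would be unbounded, and a walk whose fitted curve never
reaches the target genuinely carries no information about that quantile
(for the biased-coin design this is also how monotonicity violations
surface).  "No estimate" is a value (``None``), not an error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "DoseOutcomeTable",
    "IsotonicFit",
    "pava",
    "centre",
    "dose_find",
    "estimate_ed",
    "dump_cir_debug",
]

_FLAT_TOL = 1e-12  # fitted probs inside one PAVA block are equal up to fp noise


@dataclass(frozen=True)
class DoseOutcomeTable:
    """Per-dose-level counts of trials and successes from one trial's walk."""

    levels: tuple
    trials: tuple
    successes: tuple

    def __post_init__(self) -> None:
        lev = np.asarray(self.levels, dtype=float)
        tri = np.asarray(self.trials, dtype=int)
        suc = np.asarray(self.successes, dtype=int)
        if not (lev.size == tri.size == suc.size):
            raise ValueError("levels, trials and successes must have equal length")
        if lev.size == 0:
            raise ValueError("dose-outcome table must contain at least one level")
        if np.any(np.diff(lev) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(tri < 1):
            raise ValueError("every listed level must carry at least one trial")
        if np.any(suc < 0) or np.any(suc > tri):
            raise ValueError("successes must lie in [0, trials] at every level")
        object.__setattr__(self, "levels", tuple(lev.tolist()))
        object.__setattr__(self, "trials", tuple(tri.tolist()))
        object.__setattr__(self, "successes", tuple(suc.tolist()))

    @classmethod
    def from_history(
        cls, doses: Sequence[float], outcomes: Sequence[bool]
    ) -> "DoseOutcomeTable":
        """Tabulate a walk's (dose, outcome) sequence into per-level counts."""
        doses = np.asarray(doses, dtype=float)
        outcomes = np.asarray(outcomes, dtype=bool)
        levels, inverse = np.unique(doses, return_inverse=True)
        trials = np.bincount(inverse, minlength=levels.size)
        successes = np.bincount(inverse, weights=outcomes, minlength=levels.size)
        return cls(tuple(levels), tuple(trials), tuple(successes.astype(int)))

    @property
    def rates(self) -> np.ndarray:
        return np.asarray(self.successes, dtype=float) / np.asarray(self.trials)


@dataclass(frozen=True)
class IsotonicFit:
    """Strictly increasing (dose, probability) points of the centred fit."""

    doses: tuple
    probs: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if d.size != p.size or d.size == 0:
            raise ValueError("fit needs matching, non-empty doses and probs")
        if np.any(np.diff(d) <= 0):
            raise ValueError("centred doses must be strictly increasing")
        if np.any(np.diff(p) <= 0):
            raise ValueError("centred probabilities must be strictly increasing")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def interpolate(self, dose: float) -> float:
        """Forward evaluation of the centred curve (clamped at the ends)."""
        return float(np.interp(dose, self.doses, self.probs))


def pava(table: DoseOutcomeTable) -> np.ndarray:
    """Weighted monotone (isotonic) fit to the per-level success rates.

    Pool-adjacent-violators with weights equal to the trial counts; the
    returned array is the weighted-least-squares non-decreasing fit,
    one value per table level.
    """
    levels = np.asarray(table.levels, dtype=float)
    weights = np.asarray(table.trials, dtype=float)
    if levels.size == 1:
        return table.rates.copy()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(levels, table.rates, sample_weight=weights)


def centre(pava_fit: np.ndarray, table: DoseOutcomeTable) -> IsotonicFit:
    """Collapse each maximal flat stretch to its trial-weighted mean dose.

    Strictly increasing values pass through unchanged, so the returned
    points form a strictly increasing, interpolable curve.
    """
    probs = np.asarray(pava_fit, dtype=float)
    levels = np.asarray(table.levels, dtype=float)
    weights = np.asarray(table.trials, dtype=float)
    if probs.size != levels.size:
        raise ValueError("PAVA output does not match the table's levels")
    out_doses: list[float] = []
    out_probs: list[float] = []
    i = 0
    n = probs.size
    while i < n:
        j = i
        while j + 1 < n and probs[j + 1] - probs[i] <= _FLAT_TOL:
            j += 1
        block = slice(i, j + 1)
        out_doses.append(float(np.average(levels[block], weights=weights[block])))
        out_probs.append(float(np.average(probs[block], weights=weights[block])))
        i = j + 1
    return IsotonicFit(tuple(out_doses), tuple(out_probs))


def dose_find(fit: IsotonicFit, target: float) -> float | None:
    """Inverse estimation: the dose at which the centred curve hits ``target``.

    Returns ``None`` (no estimate) when the target lies outside the
    fitted probability range, or when a single-point fit does not hit the
    target exactly.
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must lie strictly in (0, 1), got {target}")
    probs = np.asarray(fit.probs, dtype=float)
    doses = np.asarray(fit.doses, dtype=float)
    if probs.size == 1:
        return float(doses[0]) if abs(probs[0] - target) <= _FLAT_TOL else None
    if target < probs[0] or target > probs[-1]:
        return None
    return float(np.interp(target, probs, doses))


def estimate_ed(table: DoseOutcomeTable, target: float) -> float | None:
    """PAVA -> centring -> inverse interpolation, in one call."""
    return dose_find(centre(pava(table), table), target)


def dump_cir_debug(table: DoseOutcomeTable, destination) -> None:
    """Write (level, trials, successes, pava, centred point) rows as CSV."""
    fit_vals = pava(table)
    fit = centre(fit_vals, table)
    centred = {round(d, 12): p for d, p in zip(fit.doses, fit.probs)}
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "trials", "successes", "pava", "centred_dose", "centred_prob"])
        for lev, tri, suc, val in zip(table.levels, table.trials, table.successes, fit_vals):
            writer.writerow([lev, tri, suc, f"{val:.6g}", "", ""])
        for d, p in zip(fit.doses, fit.probs):
            writer.writerow(["", "", "", "", f"{d:.6g}", f"{p:.6g}"])
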