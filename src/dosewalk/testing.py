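"""Synthetic degenerate dose-response fixtures for exercising the designs.

These curves deliberately violate the strict monotonicity of the real
curve families (a constant curve, a hard step) to drive the random
walks into their boundary behaviour: all-success walks that pile up at
dose 1, all-failure walks that pile up at dose 25, and step curves with
a known jump location.  They duck-type the ``probability`` method used
by the simulators but have no closed-form inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dose_response import DoseGrid, N_DOSES

__all__ = ["SyntheticCurve", "constant_curve", "step_curve"]


@dataclass(frozen=True)
class SyntheticCurve:
    """A synthetic curve defined by an arbitrary dose -> probability rule."""

    name: str
    _fn: object
    grid: DoseGrid = DoseGrid()

    family = "synthetic"

    def probability(self, dose: float) -> float:
        return float(self._fn(dose))


def constant_curve(p: float, n_doses: int = N_DOSES) -> SyntheticCurve:
    """Every dose succeeds with the same probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return SyntheticCurve(f"constant({p})", lambda d: p, DoseGrid(n_doses=n_doses))


def step_curve(
    threshold: float, low: float = 0.0, high: float = 1.0, n_doses: int = N_DOSES
) -> SyntheticCurve:
    """Probability ``low`` strictly below ``threshold`` and ``high`` at or above it."""
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError("need 0 <= low <= high <= 1")
    return SyntheticCurve(
        f"step(@{threshold})",
        lambda d: high if d >= threshold else low,
        DoseGrid(n_doses=n_doses),
    )
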