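"""Dose-response curves on a 25-dose grid.

Dose-finding trials in anaesthesiology explore a discrete set of doses
(here 25, equally spaced in volume, indexed 1..25).  Each dose carries a
true probability of a successful response; the effective dose ``ED_x`` is
the (continuous) dose at which that probability equals ``x``.

Two curve families are supported:

``logistic-offset``
    ``p(dose) = 1 / (1 + exp(-(dose - offset)))`` — a unit-slope logistic
    whose midpoint (ED50) sits at ``offset``.

``log-logistic``
    a four-parameter logistic on a latent scale ``t = scale * dose``:
    ``p(dose) = (c/100) / (1 + a * exp(-b * t))``.  ``c`` is the upper
    asymptote in percent; ``d`` (lower asymptote) is carried for
    completeness but inert at its default of 0.

Both families admit closed-form inversion, so true ED levels are known
exactly rather than read off a grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

N_DOSES = 25

__all__ = [
    "N_DOSES",
    "DoseGrid",
    "DoseResponseCurve",
    "build_curve",
    "make_curve",
    "success_probability",
    "find_ed",
]


@dataclass(frozen=True)
class DoseGrid:
    """Affine map from 1-based dose indices to a curve's latent scale.

    ``latent = scale * dose + shift``; strictly increasing (``scale > 0``).
    Fractional dose values are meaningful on the continuous scale — ED
    estimates are reported as fractional doses.
    """

    n_doses: int = N_DOSES
    scale: float = 1.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("latent mapping must be strictly increasing (scale > 0)")
        if self.n_doses < 2:
            raise ValueError("a dose grid needs at least two doses")

    def to_latent(self, dose: float) -> float:
        return self.scale * dose + self.shift

    def from_latent(self, latent: float) -> float:
        return (latent - self.shift) / self.scale


@dataclass(frozen=True)
class DoseResponseCurve:
    """A strictly increasing success-probability curve over the dose grid."""

    family: str
    params: Mapping[str, float]
    grid: DoseGrid = field(default_factory=DoseGrid)

    def __post_init__(self) -> None:
        if self.family not in ("logistic-offset", "log-logistic"):
            raise ValueError(f"unknown curve family: {self.family!r}")
        object.__setattr__(self, "params", MappingProxyType(dict(self.params)))
        if self.family == "log-logistic":
            for key in ("a", "b", "c"):
                if key not in self.params:
                    raise ValueError(f"log-logistic curve requires parameter {key!r}")
            if self.params["a"] <= 0 or self.params["b"] <= 0 or self.params["c"] <= 0:
                raise ValueError("log-logistic parameters a, b, c must be positive")
        elif "offset" not in self.params:
            raise ValueError("logistic-offset curve requires parameter 'offset'")

    def probability(self, dose: float) -> float:
        """Success probability at a (possibly fractional) dose."""
        t = self.grid.to_latent(dose)
        if self.family == "logistic-offset":
            # expit written out to keep scalar math cheap in tight loops
            if t >= 0:
                return 1.0 / (1.0 + math.exp(-t))
            e = math.exp(t)
            return e / (1.0 + e)
        a, b, c = self.params["a"], self.params["b"], self.params["c"]
        return (c / 100.0) / (1.0 + a * math.exp(-b * t))

    def inverse(self, level: float) -> float:
        """Dose at which the success probability equals ``level`` (closed form)."""
        if not 0.0 < level < 1.0:
            raise ValueError(f"level must lie strictly in (0, 1), got {level}")
        if self.family == "logistic-offset":
            latent = math.log(level / (1.0 - level))
        else:
            a, b, c = self.params["a"], self.params["b"], self.params["c"]
            top = c / 100.0
            if level >= top:
                raise ValueError(
                    f"level {level} is at or above the curve's upper asymptote {top}"
                )
            latent = math.log(a * level / (top - level)) / b
        return self.grid.from_latent(latent)


_CURVES = {
    1: dict(
        family="logistic-offset",
        params={"offset": 13.5},
        grid=DoseGrid(scale=1.0, shift=-13.5),
    ),
    2: dict(
        family="log-logistic",
        params={"a": 20.0, "b": 0.1, "c": 100.0, "d": 0.0},
        grid=DoseGrid(scale=4.0, shift=0.0),
    ),
    3: dict(
        family="log-logistic",
        params={"a": 20.0, "b": 0.075, "c": 100.0, "d": 0.0},
        grid=DoseGrid(scale=4.0, shift=0.0),
    ),
}


def build_curve(curve_id: int) -> DoseResponseCurve:
    """Return one of the three study dose-response curves.

    Curve 1 is the unit logistic centred at dose 13.5; curves 2 and 3 are
    four-parameter log-logistic curves (a=20, c=100, d=0) with rate b=0.1
    and b=0.075 respectively, evaluated on the latent scale t = 4*dose.
    """
    try:
        spec = _CURVES[curve_id]
    except (KeyError, TypeError):
        raise ValueError(
            f"unknown curve id {curve_id!r}; expected one of 1, 2, 3"
        ) from None
    return DoseResponseCurve(**spec)


def make_curve(
    family: str,
    params: Mapping[str, float],
    *,
    scale: float = 1.0,
    shift: float = 0.0,
    n_doses: int = N_DOSES,
) -> DoseResponseCurve:
    """Build a custom curve from a family name and parameter block."""
    return DoseResponseCurve(
        family=family,
        params=params,
        grid=DoseGrid(n_doses=n_doses, scale=scale, shift=shift),
    )


def success_probability(curve, dose: float, *, virtual: bool = False) -> float:
    """Success probability at ``dose``, with optional virtual-dose clamping.

    CRM working models may extend below dose 1 or above dose 25; such
    virtual doses respond deterministically (certain failure below the
    grid, certain success above it).  Plain evaluation (``virtual=False``)
    always uses the curve formula.
    """
    if virtual:
        n_doses = getattr(getattr(curve, "grid", None), "n_doses", N_DOSES)
        if dose < 1:
            return 0.0
        if dose > n_doses:
            return 1.0
    return curve.probability(dose)


def find_ed(curve: DoseResponseCurve, level: float) -> float:
    """Continuous dose at which the curve attains ``level`` (e.g. 0.95 for ED95)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"ED level must lie strictly in (0, 1), got {level}")
    return curve.inverse(level)
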