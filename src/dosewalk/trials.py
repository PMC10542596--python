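"""Per-trial result container shared by the three design simulators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any


@dataclass
class TrialResult:
    """Outcome of one simulated dose-finding trial.

    ``estimate`` is the continuous dose estimate, or ``None`` when the
    design could not produce one (possible for the up-and-down designs,
    never for the CRM).  ``doses``/``outcomes`` record the full patient
    history in accrual order; ``extras`` carries design-specific
    diagnostics (segment counts, proportion-test intervals, ...).
    """

    design: str
    estimate: float | None
    n_patients: int
    n_failures: int
    doses: list
    outcomes: list
    replicate: int = -1
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_failures > self.n_patients:
            raise ValueError("failures cannot exceed patients")

    @property
    def estimated(self) -> bool:
        return self.estimate is not None

    def to_record(self, *, include_history: bool = False) -> dict[str, Any]:
        """JSON-safe flat record for trial logs."""
        rec: dict[str, Any] = {
            "design": self.design,
            "replicate": self.replicate,
            "estimate": None if self.estimate is None else float(self.estimate),
            "n_patients": int(self.n_patients),
            "n_failures": int(self.n_failures),
        }
        if include_history:
            rec["doses"] = [float(d) for d in self.doses]
            rec["outcomes"] = [int(o) for o in self.outcomes]
        rec.update({k: v for k, v in self.extras.items() if _json_safe(v)})
        return rec


def _json_safe(value: Any) -> bool:
    return isinstance(value, (str, int, float, bool, type(None), list, tuple))
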