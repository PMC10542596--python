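"""Summary serialisation and batch configuration handling.

One configuration file describes one batch (design x curve x target);
validation happens before any simulation so a typo never costs a run.
Summaries are written as deterministic CSV (fixed column order, rows
sorted by starting dose, floats at 6 significant digits) so re-running
a configuration with the same seed reproduces the file byte for byte.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .monte_carlo import DESIGNS, SUMMARY_COLUMNS, BatchSummary

__all__ = ["RunConfig", "write_summary", "read_summary", "load_config", "parse_starts"]

_TARGETS = (0.90, 0.95)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """A validated batch configuration with defaults applied."""

    design: str
    curve: int
    target: float
    seed: int
    reps: int = 5000
    starts: tuple = tuple(range(1, 26))
    cohort: int | None = None
    sigma: float = 1.34
    window_shift: int = 3
    max_segments: int = 5
    coin_rule: str = "paper"
    phase2: str = "continue"

    def design_kwargs(self) -> dict:
        """Simulator keyword arguments implied by this configuration."""
        if self.design == "crm":
            from .crm import RestartRules

            rules = RestartRules.for_target(
                self.target,
                window_shift=self.window_shift,
                max_segments=self.max_segments,
            )
            return {"cohort": self.cohort, "sigma": self.sigma, "rules": rules}
        if self.design == "bcd":
            return {"coin_rule": self.coin_rule}
        return {"phase2": self.phase2}


def parse_starts(spec) -> tuple:
    """Starting doses from a list, an int, or strings like ``"1-25"``/``"3,7,12"``."""
    if isinstance(spec, int):
        return (spec,)
    if isinstance(spec, str):
        parts = []
        for chunk in spec.split(","):
            chunk = chunk.strip()
            if "-" in chunk:
                lo, hi = chunk.split("-", 1)
                parts.extend(range(int(lo), int(hi) + 1))
            elif chunk:
                parts.append(int(chunk))
        starts = tuple(parts)
    else:
        starts = tuple(int(s) for s in spec)
    if not starts:
        raise ValueError("starts must name at least one dose")
    if any(not 1 <= s <= 25 for s in starts):
        raise ValueError(f"starting doses must lie in [1, 25], got {starts}")
    return starts


_CRM_ONLY = {"cohort", "sigma", "window_shift", "max_segments"}
_BCD_ONLY = {"coin_rule"}
_UDM_ONLY = {"phase2"}
_COMMON = {"design", "curve", "target", "seed", "reps", "starts"}


def load_config(path) -> RunConfig:
    """Read and validate a YAML batch configuration.

    Defaults: reps 5000, starts 1-25, sigma 1.34, window_shift 3,
    max_segments 5.  Keys that do not apply to the chosen design (e.g.
    ``cohort`` for the UDM) are rejected with a message naming the key.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a key-value mapping")

    known = _COMMON | _CRM_ONLY | _BCD_ONLY | _UDM_ONLY
    for key in raw:
        if key not in known:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
    for key in _COMMON - {"reps", "starts"}:
        if key not in raw:
            raise ValueError(f"{path}: missing required key {key!r}")

    design = raw["design"]
    if design not in DESIGNS:
        raise ValueError(f"{path}: design must be one of {DESIGNS}, got {design!r}")
    for key in (_CRM_ONLY if design != "crm" else set()) & raw.keys():
        raise ValueError(f"{path}: key {key!r} applies only to the CRM design")
    for key in (_BCD_ONLY if design != "bcd" else set()) & raw.keys():
        raise ValueError(f"{path}: key {key!r} applies only to the BCD design")
    for key in (_UDM_ONLY if design != "udm" else set()) & raw.keys():
        raise ValueError(f"{path}: key {key!r} applies only to the UDM design")

    curve = raw["curve"]
    if curve not in (1, 2, 3):
        raise ValueError(f"{path}: curve must be 1, 2 or 3, got {curve!r}")
    target = float(raw["target"])
    if not any(abs(target - t) < 1e-9 for t in _TARGETS):
        raise ValueError(f"{path}: supported targets are 0.90 and 0.95, got {target}")
    seed = int(raw["seed"])
    reps = int(raw.get("reps", 5000))
    if reps < 1:
        raise ValueError(f"{path}: reps must be >= 1")
    starts = parse_starts(raw.get("starts", "1-25"))

    kwargs: dict = {}
    if design == "crm":
        cohort = raw.get("cohort", 2)
        if cohort not in (2, 4):
            raise ValueError(f"{path}: cohort must be 2 or 4, got {cohort!r}")
        kwargs["cohort"] = cohort
        kwargs["sigma"] = float(raw.get("sigma", 1.34))
        if kwargs["sigma"] <= 0:
            raise ValueError(f"{path}: sigma must be positive")
        kwargs["window_shift"] = int(raw.get("window_shift", 3))
        kwargs["max_segments"] = int(raw.get("max_segments", 5))
    elif design == "bcd":
        rule = raw.get("coin_rule", "paper")
        if rule not in ("paper", "classic"):
            raise ValueError(f"{path}: coin_rule must be 'paper' or 'classic'")
        kwargs["coin_rule"] = rule
    else:
        phase2 = raw.get("phase2", "continue")
        if phase2 not in ("continue", "restart_ed50"):
            raise ValueError(f"{path}: phase2 must be 'continue' or 'restart_ed50'")
        kwargs["phase2"] = phase2

    return RunConfig(
        design=design, curve=curve, target=target, seed=seed,
        reps=reps, starts=starts, **kwargs,
    )


def write_summary(summary, destination) -> Path:
    """Write a batch summary as deterministic CSV and return the path."""
    table = summary.table if isinstance(summary, BatchSummary) else summary
    if list(table.columns) != SUMMARY_COLUMNS:
        raise ValueError(f"summary table must have columns {SUMMARY_COLUMNS}")
    destination = Path(destination)
    try:
        destination.parent.mkdir(parents=True, exist_ok=True)
        table.sort_values("start_dose").to_csv(
            destination, index=False, float_format="%.6g"
        )
    except OSError as exc:
        raise OSError(f"cannot write summary to {destination}: {exc}") from exc
    return destination


def read_summary(path) -> pd.DataFrame:
    """Read back a summary CSV with the canonical column order."""
    df = pd.read_csv(path)
    if list(df.columns) != SUMMARY_COLUMNS:
        raise ValueError(f"{path} is not a dosewalk summary file")
    return df
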