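"""Seeded Monte Carlo harness over designs, curves, targets and starting doses.

The study design calls for a full factorial sweep: every design (UDM,
BCD, CRM with cohorts of 2 or 4), every dose-response curve, both target
levels and all 25 starting doses, with thousands of replicates per cell.
Each replicate gets its own random stream derived from the master seed
and the configuration tuple, so cells can be run in any order (or in
parallel) and the whole batch is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bcd import run_bcd_trial
from .crm import RestartRules, run_crm_trial
from .dose_response import build_curve
from .trials import TrialResult
from .udm import run_udm_trial

DESIGNS = ("udm", "bcd", "crm")
_DESIGN_CODES = {name: i + 1 for i, name in enumerate(DESIGNS)}

SUMMARY_COLUMNS = [
    "start_dose",
    "n_reps",
    "n_no_estimate",
    "mean_est",
    "sd_est",
    "mean_n",
    "sd_n",
    "mean_fail",
    "sd_fail",
]

__all__ = [
    "DESIGNS",
    "SUMMARY_COLUMNS",
    "BatchSummary",
    "seed_stream",
    "run_trial",
    "run_batch",
    "summarize_records",
    "summarize_trial_log",
    "grand_mean",
]


def seed_stream(
    master_seed: int,
    design: str,
    curve_id: int,
    target: float,
    start: int,
    replicate: int,
    cohort: int = 0,
) -> np.random.Generator:
    """Independent, reproducible random stream for one replicate.

    The stream is keyed on the full configuration tuple through a
    ``SeedSequence``, so distinct replicates (or cells) never share a
    stream and identical arguments always reproduce the same draws.
    """
    if design not in _DESIGN_CODES:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if master_seed < 0:
        raise ValueError("master seed must be a non-negative integer")
    key = (
        int(master_seed),
        _DESIGN_CODES[design],
        int(curve_id),
        int(round(target * 100)),
        int(cohort or 0),
        int(start),
        int(replicate),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def run_trial(
    design: str,
    curve,
    start: int,
    target: float,
    rng: np.random.Generator,
    *,
    replicate: int = -1,
    cohort: int | None = None,
    coin_rule: str = "paper",
    phase2: str = "continue",
    sigma: float = 1.34,
    rules: RestartRules | None = None,
) -> TrialResult:
    """Dispatch one replicate to the requested design simulator."""
    if design == "udm":
        return run_udm_trial(curve, start, target, rng, phase2=phase2, replicate=replicate)
    if design == "bcd":
        return run_bcd_trial(curve, start, target, rng, coin_rule=coin_rule, replicate=replicate)
    if design == "crm":
        if cohort is None:
            raise ValueError("CRM runs require a cohort size (2 or 4)")
        return run_crm_trial(
            curve, start, target, cohort, rng,
            rules=rules, sigma=sigma, replicate=replicate,
        )
    raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")


@dataclass
class BatchSummary:
    """Per-starting-dose aggregates for one (design, curve, target) cell."""

    design: str
    curve_id: int
    target: float
    reps: int
    master_seed: int
    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    def grand(self, column: str) -> float:
        """Unweighted mean of the per-start values of ``column``."""
        return float(self.table[column].mean())


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trial records into the fixed per-start summary table.

    Mean and SD of the estimate condition on estimable replicates (the
    no-estimate count is reported separately); patient and failure
    moments run over all replicates.  SDs use the n-1 denominator.
    """
    rows = []
    for start, grp in records.groupby("start", sort=True):
        est = grp["estimate"].dropna()
        rows.append(
            {
                "start_dose": int(start),
                "n_reps": int(len(grp)),
                "n_no_estimate": int(grp["estimate"].isna().sum()),
                "mean_est": float(est.mean()) if len(est) else np.nan,
                "sd_est": float(est.std(ddof=1)) if len(est) > 1 else np.nan,
                "mean_n": float(grp["n_patients"].mean()),
                "sd_n": float(grp["n_patients"].std(ddof=1)) if len(grp) > 1 else np.nan,
                "mean_fail": float(grp["n_failures"].mean()),
                "sd_fail": float(grp["n_failures"].std(ddof=1)) if len(grp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def run_batch(
    design: str,
    curve_id: int,
    target: float,
    starts: Sequence[int] | None = None,
    reps: int = 5000,
    master_seed: int = 0,
    *,
    trial_log=None,
    log_history: bool = False,
    **design_config,
) -> BatchSummary:
    """Run ``reps`` independent trials per starting dose and aggregate.

    ``design_config`` passes through to the design simulator (``cohort``,
    ``coin_rule``, ``phase2``, ``sigma``, ``rules``).  ``trial_log`` may
    name a path or file object that receives one JSON line per trial.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    curve = build_curve(curve_id)  # validates curve_id before any simulation
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    starts = tuple(range(1, 26)) if starts is None else tuple(int(s) for s in starts)
    if any(not 1 <= s <= 25 for s in starts):
        raise ValueError("starting doses must lie in [1, 25]")
    cohort = design_config.get("cohort")

    own_handle = None
    sink = None
    if trial_log is not None:
        if hasattr(trial_log, "write"):
            sink = trial_log
        else:
            own_handle = open(trial_log, "w")
            sink = own_handle

    try:
        rows = []
        for start in starts:
            for rep in range(reps):
                rng = seed_stream(
                    master_seed, design, curve_id, target, start, rep, cohort or 0
                )
                result = run_trial(
                    design, curve, start, target, rng, replicate=rep, **design_config
                )
                rows.append(
                    (
                        start,
                        rep,
                        np.nan if result.estimate is None else result.estimate,
                        result.n_patients,
                        result.n_failures,
                    )
                )
                if sink is not None:
                    rec = result.to_record(include_history=log_history)
                    rec.update(
                        design=design, curve=curve_id, target=target, start=start
                    )
                    sink.write(json.dumps(rec) + "\n")
    finally:
        if own_handle is not None:
            own_handle.close()

    records = pd.DataFrame(
        rows, columns=["start", "replicate", "estimate", "n_patients", "n_failures"]
    )
    return BatchSummary(
        design=design,
        curve_id=curve_id,
        target=target,
        reps=reps,
        master_seed=master_seed,
        table=summarize_records(records),
        config=dict(design_config),
    )


def summarize_trial_log(path) -> pd.DataFrame:
    """Recompute the per-start summary table from a JSON-lines trial log."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    if not rows:
        raise ValueError(f"trial log {path} is empty")
    df = pd.DataFrame(rows)
    df["estimate"] = df["estimate"].astype(float)
    return summarize_records(df[["start", "replicate", "estimate", "n_patients", "n_failures"]])


def grand_mean(batches: Iterable[BatchSummary], column: str) -> float:
    """Unweighted grand mean of per-start means across several batches."""
    values = np.concatenate([np.asarray(b.table[column], dtype=float) for b in batches])
    return float(np.nanmean(values))
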