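"""Replicate harness: operating characteristics of a design under a scenario.

Each replicate is one simulated trial; aggregating many replicates yields the
design's frequency properties: probability of trial success (type I error
under the null scenario, power otherwise), proportions stopping early for
efficacy or futility, the distribution of the randomised sample size, mean
per-arm allocation proportions, mean square error of the declared-best-arm
estimate over successful trials, and the correct-selection rate.

Replicates receive independent counter-derived seed streams
(``SeedSequence(base_seed, spawn_key=(i,))``), so any subset is reproducible
in isolation and aggregation is independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcome_model import CONTROL_ARM
from .scenarios import RunConfig, Scenario
from .trial_engine import run_trial

__all__ = [
    "OCRow",
    "OCTable",
    "run_replicates",
    "power_or_type1",
    "mse_best_arm",
    "allocation_and_selection",
    "is_null_scenario",
]

logger = logging.getLogger(__name__)

#: Column order for per-replicate record tables.
_RECORD_COLUMNS = (
    "replicate",
    "stop_reason",
    "stop_due_count",
    "success",
    "declared_best",
    "declared_best_estimate",
    "declared_best_truth",
    "n_total",
)


def is_null_scenario(scenario: Scenario) -> bool:
    """True when no intervention arm beats the control in truth."""
    control_mean = scenario.mean(CONTROL_ARM)
    return all(
        scenario.mean(a) <= control_mean for a in scenario.arms if a != CONTROL_ARM
    )


@dataclass
class OCRow:
    """Aggregated operating characteristics for one design x scenario cell."""

    design_id: int
    scenario: str
    n_replicates: int
    p_success: float
    success_label: str  # "type I error" | "power"
    p_efficacy_stop: float
    p_futility_stop: float
    p_max_n: float
    mean_n: float
    sd_n: float
    mse_best: float  # NaN when no replicate succeeded
    mean_allocation: dict[str, float]
    correct_selection: float

    def to_series(self) -> pd.Series:
        d = {
            "design": self.design_id,
            "scenario": self.scenario,
            "n_replicates": self.n_replicates,
            "p_success": self.p_success,
            "success_label": self.success_label,
            "p_efficacy_stop": self.p_efficacy_stop,
            "p_futility_stop": self.p_futility_stop,
            "p_max_n": self.p_max_n,
            "mean_n": self.mean_n,
            "sd_n": self.sd_n,
            "mse_best": self.mse_best,
        }
        for arm, v in self.mean_allocation.items():
            d[f"alloc[{arm}]"] = v
        d["correct_selection"] = self.correct_selection
        return pd.Series(d)


class OCTable(list):
    """A list of :class:`OCRow` with tabular export mirroring the usual
    operating-characteristics layout."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([row.to_series() for row in self])


def run_replicates(
    cfg: RunConfig, *, record_trajectories: bool = False
) -> tuple[OCRow, pd.DataFrame]:
    """Simulate ``cfg.n_replicates`` independent trials and aggregate.

    Returns the aggregated :class:`OCRow` and the per-replicate record table
    (one row per trial) for audit.  Results depend only on the configuration
    and base seed, not on execution interleaving.
    """
    scenario = cfg.scenario
    arms = scenario.arms
    records = []
    alloc = np.zeros((cfg.n_replicates, len(arms)))
    for i in range(cfg.n_replicates):
        ss = np.random.SeedSequence(cfg.base_seed, spawn_key=(i,))
        res = run_trial(
            cfg.design,
            scenario,
            cfg.accrual,
            ss,
            n_draws=cfg.n_draws,
            record_trajectory=record_trajectories,
        )
        est = res.posterior_means[res.declared_best]
        records.append(
            (
                i,
                res.termination_reason,
                res.stop_due_count,
                res.success,
                res.declared_best,
                est,
                scenario.mean(res.declared_best),
                res.n_total,
            )
        )
        alloc[i] = [res.n_per_arm[a] / res.n_total for a in arms]
        if (i + 1) % 500 == 0:
            logger.info(
                "design %d / %s: %d/%d replicates",
                cfg.design.design_id,
                scenario.name,
                i + 1,
                cfg.n_replicates,
            )
    df = pd.DataFrame(records, columns=list(_RECORD_COLUMNS))

    p_success = power_or_type1(df, scenario)
    reasons = df["stop_reason"].value_counts(normalize=True)
    mean_alloc = {a: float(alloc[:, j].mean()) for j, a in enumerate(arms)}
    _, correct = allocation_and_selection(df, scenario, alloc)
    row = OCRow(
        design_id=cfg.design.design_id,
        scenario=scenario.name,
        n_replicates=cfg.n_replicates,
        p_success=p_success,
        success_label="type I error" if is_null_scenario(scenario) else "power",
        p_efficacy_stop=float(reasons.get("efficacy", 0.0)),
        p_futility_stop=float(reasons.get("futility", 0.0)),
        p_max_n=float(reasons.get("max-N", 0.0)),
        mean_n=float(df["n_total"].mean()),
        sd_n=float(df["n_total"].std(ddof=1)) if len(df) > 1 else 0.0,
        mse_best=mse_best_arm(df, scenario),
        mean_allocation=mean_alloc,
        correct_selection=correct,
    )
    return row, df


def power_or_type1(records: pd.DataFrame, scenario: Scenario) -> float:
    """Fraction of replicates declared successful: the type I error under a
    scenario with no superior arm, the power otherwise."""
    if records.empty:
        raise ValueError("no replicate records")
    return float(records["success"].mean())


def mse_best_arm(records: pd.DataFrame, scenario: Scenario) -> float:
    """Mean square error of the declared-best-arm estimate over successful
    trials; NaN when no trial succeeded (the estimate is then irrelevant)."""
    ok = records[records["success"]]
    if ok.empty:
        return float("nan")
    err = ok["declared_best_estimate"] - ok["declared_best_truth"]
    return float(np.mean(err**2))


def allocation_and_selection(
    records: pd.DataFrame,
    scenario: Scenario,
    alloc: np.ndarray | None = None,
) -> tuple[dict[str, float], float]:
    """Mean per-arm allocation proportions and the correct-selection rate.

    A replicate selects correctly when its declared best arm attains the
    scenario's maximal true mean (any maximal arm counts under ties).
    """
    if records.empty:
        raise ValueError("no replicate records")
    best = set(scenario.best_arms)
    correct = float(records["declared_best"].isin(best).mean())
    if alloc is None:
        mean_alloc = {}
    else:
        mean_alloc = {
            a: float(alloc[:, j].mean()) for j, a in enumerate(scenario.arms)
        }
    return mean_alloc, correct
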