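"""Discrete-event simulation of one adaptive trial.

A simulated trial proceeds on a calendar-week clock.  Patients arrive from a
Poisson process whose intensity ramps linearly from zero to the steady
recruitment rate over the first 12 weeks, are randomised on arrival using the
current allocation probabilities, and contribute their 12-week FAOS QoL
outcome one follow-up lag later unless they drop out (probability 0.20;
dropouts count towards the randomised total and the "patients due" clock but
never enter the likelihood).

Interim analyses trigger on the "patients due" count: the analysis scheduled
at ``m`` patients due fires at the calendar time when the m-th enrolled
patient passes their 12-week visit, and uses exactly the outcomes observable
by that time (the first m patients, dropouts excluded).  Allocation updates
(RAR or arm dropping, designs 3-6) occur at every analysis; efficacy/futility
verdicts only at the 200/400/600-due checks (designs 2-6).  On a stop verdict
enrolment halts immediately; patients already randomised are followed to
outcome and contribute to the final estimates.  Otherwise the trial runs to
the maximum sample size of 643 and the final success rule is applied once
every randomised patient has passed follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision_rules import (
    AllocationState,
    DesignSpec,
    InterimDecision,
    apply_arm_dropping,
    design6_decision,
    efficacy_stop,
    final_success,
    futility_stop,
    rar_probabilities,
)
from .outcome_model import (
    ARMS,
    CONTROL_ARM,
    ArmPrior,
    OutcomeData,
    PosteriorDraws,
    prob_best,
    prob_margin,
    update_posterior,
)

__all__ = [
    "AccrualSpec",
    "PatientRecord",
    "AnalysisRecord",
    "TrialResult",
    "generate_enrolment",
    "simulate_outcome",
    "interim_due",
    "run_trial",
]


@dataclass(frozen=True)
class AccrualSpec:
    """Recruitment, follow-up and retention assumptions.

    ``rate`` is the steady recruitment rate in patients/week (5 by default;
    25 and 56 were also examined), reached after a linear ramp of
    ``ramp_weeks``.  ``followup_weeks`` is the fixed lag from randomisation
    to the primary-outcome visit.  ``dropout`` is the probability that a
    randomised patient never provides an outcome.  ``spacing`` selects
    stochastic Poisson arrivals or deterministic equal-quantile spacing of
    the same cumulative-intensity curve (useful for variance-reduction
    checks).
    """

    rate: float = 5.0
    ramp_weeks: float = 12.0
    followup_weeks: float = 12.0
    dropout: float = 0.20
    max_n: int = 643
    spacing: str = "poisson"

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("recruitment rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.max_n <= 0:
            raise ValueError("max_n must be positive")
        if self.ramp_weeks < 0 or self.followup_weeks < 0:
            raise ValueError("durations must be non-negative")
        if self.spacing not in ("poisson", "deterministic"):
            raise ValueError(f"unknown spacing {self.spacing!r}")

    def cumulative_intensity_inverse(self, u: np.ndarray) -> np.ndarray:
        """Invert the integrated arrival intensity Lambda(t).

        Lambda(t) = rate * t^2 / (2 * ramp) during the ramp and
        rate * (t - ramp/2) afterwards.
        """
        u = np.asarray(u, dtype=float)
        if self.ramp_weeks == 0:
            return u / self.rate
        knee = self.rate * self.ramp_weeks / 2.0
        return np.where(
            u <= knee,
            np.sqrt(2.0 * self.ramp_weeks * u / self.rate),
            u / self.rate + self.ramp_weeks / 2.0,
        )


@dataclass
class PatientRecord:
    """One simulated patient."""

    id: int
    enrolment_week: float
    arm: str
    baseline: float | None
    outcome: float | None  # None iff dropout
    dropout: bool


@dataclass
class AnalysisRecord:
    """Snapshot of one interim (or final) analysis for audit export."""

    due_count: int
    time_weeks: float
    n_randomised: int
    n_per_arm: dict[str, int]
    allocation: dict[str, float]
    pi: dict[str, float]
    p_mcid: float | None
    p_superior: float | None
    verdict: str


@dataclass
class TrialResult:
    """Everything recorded about one simulated trial."""

    termination_reason: str  # efficacy | futility | max-N
    stop_due_count: int | None
    stop_check_index: int | None  # 1..3, None if max-N
    n_per_arm: dict[str, int]
    success: bool
    declared_best: str
    posterior_means: dict[str, float]
    dropped: tuple[str, ...]
    trajectory: list[AnalysisRecord] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(self.n_per_arm.values())

    def trajectory_frame(self):
        """One row per interim analysis, for CSV export/audit."""
        import pandas as pd

        rows = []
        for rec in self.trajectory:
            row = {
                "due_count": rec.due_count,
                "time_weeks": rec.time_weeks,
                "n_randomised": rec.n_randomised,
                "verdict": rec.verdict,
                "p_mcid": rec.p_mcid,
                "p_superior": rec.p_superior,
            }
            for arm, c in rec.n_per_arm.items():
                row[f"n[{arm}]"] = c
            for arm, p in rec.allocation.items():
                row[f"alloc[{arm}]"] = p
            for arm, p in rec.pi.items():
                row[f"pi[{arm}]"] = p
            rows.append(row)
        return pd.DataFrame(rows)


def generate_enrolment(
    accrual: AccrualSpec, seed: int | np.random.Generator | np.random.SeedSequence = 0
) -> np.ndarray:
    """Enrolment times (weeks) for ``max_n`` patients.

    Arrivals follow an inhomogeneous Poisson process with intensity rising
    linearly from 0 to ``rate`` over the ramp and constant thereafter,
    simulated by inverting the cumulative intensity; the sequence is
    truncated at ``max_n`` arrivals.
    """
    rng = np.random.default_rng(seed)
    if accrual.spacing == "deterministic":
        u = np.arange(1, accrual.max_n + 1) - 0.5
    else:
        u = np.cumsum(rng.exponential(size=accrual.max_n))
    return accrual.cumulative_intensity_inverse(u)


def simulate_outcome(
    scenario,
    arm: str,
    accrual: AccrualSpec,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> float | None:
    """One patient's 12-week outcome: ``None`` with the dropout probability,
    otherwise a normal draw with the scenario's arm mean and SD."""
    if arm not in scenario.arms:
        raise KeyError(f"unknown arm {arm!r}")
    rng = np.random.default_rng(seed)
    if rng.random() < accrual.dropout:
        return None
    return float(rng.normal(scenario.mean(arm), scenario.sd(arm)))


def interim_due(due_counts, spec: DesignSpec) -> list[int]:
    """Analysis milestones (patients-due counts) triggered by a
    non-decreasing sequence of cumulative due counts.

    Each multiple of the adaptation interval fires exactly once, at the first
    observation at which the running count has reached it; a jump across
    several milestones fires each of them once.
    """
    if spec.adaptation_interval is None:
        return []
    triggered: list[int] = []
    next_m = spec.adaptation_interval
    prev = -1
    for c in due_counts:
        if c < prev:
            raise ValueError("due counts must be non-decreasing")
        prev = c
        while next_m <= min(c, spec.max_n):
            triggered.append(next_m)
            next_m += spec.adaptation_interval
    return triggered


def _assign_arms(
    state: AllocationState,
    count: int,
    rng: np.random.Generator,
    blocked: bool,
) -> np.ndarray:
    """Arm indices for ``count`` new patients under the current allocation."""
    probs = state.as_vector()
    if count == 0:
        return np.empty(0, dtype=np.intp)
    active = np.flatnonzero(probs > 0)
    if blocked and np.allclose(probs[active], 1.0 / active.size):
        # permuted blocks of size 2 x (number of active arms)
        block = np.repeat(active, 2)
        n_blocks = -(-count // block.size)
        seq = np.concatenate([rng.permutation(block) for _ in range(n_blocks)])
        return seq[:count]
    return rng.choice(len(probs), size=count, p=probs)


def run_trial(
    spec: DesignSpec,
    scenario,
    accrual: AccrualSpec | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    *,
    n_draws: int = 5000,
    prior: ArmPrior | None = None,
    blocked_randomisation: bool = False,
    record_trajectory: bool = True,
) -> TrialResult:
    """Simulate one complete trial under a design and a true scenario."""
    accrual = accrual or AccrualSpec(max_n=spec.max_n)
    prior = prior or ArmPrior()
    rng = np.random.default_rng(seed)
    arms = tuple(scenario.arms)
    k = len(arms)
    lag = accrual.followup_weeks

    arrivals = generate_enrolment(accrual, rng)
    n_max = arrivals.size
    dropout = rng.random(n_max) < accrual.dropout
    noise = rng.standard_normal(n_max)
    arm_idx = np.full(n_max, -1, dtype=np.intp)
    means = np.asarray(scenario.means)
    sds = np.asarray(scenario.sds)

    state = AllocationState.equal(arms)
    assigned = 0
    trajectory: list[AnalysisRecord] = []
    stop_reason: str | None = None
    stop_due: int | None = None
    stop_idx: int | None = None
    n_randomised = n_max

    milestones = interim_due([n_max], spec)

    def observed_data(n_due: int, upto_assigned: int) -> OutcomeData:
        sel = np.arange(min(n_due, upto_assigned))
        sel = sel[~dropout[sel]]
        a = arm_idx[sel]
        y = means[a] + sds[a] * noise[sel]
        return OutcomeData({arm: y[a == j] for j, arm in enumerate(arms)}, arms=arms)

    for m in milestones:
        t_analysis = arrivals[m - 1] + lag
        n_rand = int(np.searchsorted(arrivals, t_analysis, side="right"))
        new = np.arange(assigned, n_rand)
        arm_idx[new] = _assign_arms(state, new.size, rng, blocked_randomisation)
        assigned = n_rand

        is_check = m in spec.stopping_checks
        if spec.adaptation == "none" and not is_check:
            continue

        draws = update_posterior(prior, observed_data(m, assigned), n_draws, rng)
        verdict = "continue"
        p_mcid: float | None = None
        p_sup: float | None = None

        if spec.design_id == 6 or spec.control_policy == "none":
            # suspended arms re-enter the candidate set at every analysis
            pb = prob_best(draws, tuple(a for a in arms if a not in state.dropped))
            if is_check:
                idx = spec.stopping_checks.index(m) + 1
                verdict = design6_decision(max(pb.values()), idx, spec)
            if verdict == "continue" and spec.adaptation == "rar":
                state = rar_probabilities(pb, spec, state)
        else:
            # best-arm probabilities are always over the full intervention
            # set: a dropped arm keeps its (frozen) posterior in the maximum
            candidates = tuple(a for a in arms if a != CONTROL_ARM)
            pb = prob_best(draws, candidates)
            best = max(pb, key=pb.get)
            if is_check:
                p_mcid = prob_margin(draws, best, CONTROL_ARM, spec.mcid)
                p_sup = prob_margin(draws, best, CONTROL_ARM, 0.0)
                idx = spec.stopping_checks.index(m) + 1
                if efficacy_stop(p_mcid, pb[best], idx, spec):
                    verdict = "stop-efficacy"
                elif futility_stop(p_sup, spec):
                    verdict = "stop-futility"
            if verdict == "continue" and spec.adaptation == "rar":
                state = rar_probabilities(pb, spec, state)
            elif verdict == "continue" and spec.adaptation == "drop":
                state = apply_arm_dropping(
                    {a: pb[a] for a in candidates if a not in state.dropped},
                    spec,
                    state,
                )

        if record_trajectory:
            counts_now = np.bincount(arm_idx[:assigned], minlength=k)
            trajectory.append(
                AnalysisRecord(
                    due_count=m,
                    time_weeks=float(t_analysis),
                    n_randomised=assigned,
                    n_per_arm={a: int(c) for a, c in zip(arms, counts_now)},
                    allocation=dict(state.probabilities),
                    pi=dict(pb),
                    p_mcid=p_mcid,
                    p_superior=p_sup,
                    verdict=verdict,
                )
            )
        if verdict != "continue":
            stop_reason = "efficacy" if verdict == "stop-efficacy" else "futility"
            stop_due = m
            stop_idx = spec.stopping_checks.index(m) + 1
            n_randomised = assigned
            break

    if stop_reason is None:
        # enrol to the maximum sample size under the last allocation state
        new = np.arange(assigned, n_max)
        arm_idx[new] = _assign_arms(state, new.size, rng, blocked_randomisation)
        assigned = n_max
        stop_reason = "max-N"

    # final analysis: all randomised patients followed to outcome
    final_data = observed_data(n_randomised, n_randomised)
    final_draws = update_posterior(prior, final_data, n_draws, rng)
    final_ok, declared = final_success(final_draws, spec)
    success = stop_reason == "efficacy" or (stop_reason == "max-N" and final_ok)

    counts = np.bincount(arm_idx[:n_randomised], minlength=k)
    n_per_arm = {arm: int(c) for arm, c in zip(arms, counts)}
    assert sum(n_per_arm.values()) == n_randomised <= spec.max_n

    post_means = {arm: float(final_draws.column(arm).mean()) for arm in arms}
    return TrialResult(
        termination_reason=stop_reason,
        stop_due_count=stop_due,
        stop_check_index=stop_idx,
        n_per_arm=n_per_arm,
        success=success,
        declared_best=declared,
        posterior_means=post_means,
        dropped=tuple(a for a in arms if a in state.dropped),
        trajectory=trajectory,
    )
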