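"""Allocation and stopping rules for the six candidate Bayesian designs.

The designs adapt a four-arm ankle-sprain trial (control: tubular bandage;
interventions: Bledsoe boot, Aircast brace, below-knee cast):

=======  ==========================  ==========================  ==================
Design   Adaptation (per 50 due)     Control allocation          Early stopping
=======  ==========================  ==========================  ==================
1        none (fixed 1:1:1:1)        equal                       none
2        none (checks per 200 due)   equal                       per 200 due
3        arm dropping                equal to remaining arms     per 200 due
4        RAR                         matched to best arm         per 200 due
5        RAR                         fixed at 40%                per 200 due
6        RAR over all four arms      none designated             per 200 due
=======  ==========================  ==========================  ==================

Response-adaptive randomisation (RAR) sets each candidate arm's allocation
probability proportional to ``Pr(arm is best | data)**gamma`` with gamma = 0.6
damping extreme allocations; arms whose resulting probability falls below 0.1
have enrolment suspended (reversibly).  Designs 2-5 stop early for efficacy
when the best intervention beats control by the MCID of 8 FAOS points with
posterior probability above a decreasing boundary (0.75/0.70/0.60 at
200/400/600 patients due) *and* is the best intervention with probability
above 0.9; they stop for futility when the superiority probability drops
below 0.05, and are successful at the final analysis when the MCID
probability exceeds 0.5.  Design 6 ranks all four arms by the probability of
being best and uses the ladder 0.975/0.95/0.925 for efficacy, 0.1 for
futility, and 0.9 for final success.

Everything in this module is a pure function of posterior summaries; the
simulation engine supplies those summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .outcome_model import ARMS, CONTROL_ARM, INTERVENTION_ARMS, PosteriorDraws, prob_best, prob_margin

__all__ = [
    "DesignSpec",
    "AllocationState",
    "InterimDecision",
    "design_preset",
    "rar_probabilities",
    "apply_arm_dropping",
    "efficacy_stop",
    "futility_stop",
    "design6_decision",
    "final_success",
]

_CONTROL_POLICIES = ("equal", "matched-to-best", "fixed-0.40", "none")
_ADAPTATIONS = ("none", "drop", "rar")


@dataclass(frozen=True)
class DesignSpec:
    """Full parameterisation of one candidate design."""

    design_id: int
    adaptation: str = "none"  # none | drop | rar
    adaptation_interval: int | None = None  # patients due (50 or 200)
    stopping_checks: tuple[int, ...] = ()  # patients due (200, 400, 600)
    gamma: float = 0.6
    suspension_threshold: float = 0.1
    drop_threshold: float = 0.1
    mcid: float = 8.0
    efficacy_boundaries: tuple[float, ...] = (0.75, 0.70, 0.60)
    best_arm_gate: float = 0.9
    futility_bound: float = 0.05
    final_success_bound: float = 0.5
    d6_efficacy_ladder: tuple[float, ...] = (0.975, 0.95, 0.925)
    d6_futility_bound: float = 0.1
    d6_final_bound: float = 0.9
    control_policy: str = "equal"
    fixed_control_alloc: float = 0.40
    max_n: int = 643
    iterate_suspension: bool = True

    def __post_init__(self) -> None:
        if self.design_id not in range(1, 7):
            raise ValueError(f"design_id must be 1..6, got {self.design_id}")
        if self.adaptation not in _ADAPTATIONS:
            raise ValueError(f"unknown adaptation {self.adaptation!r}")
        if self.control_policy not in _CONTROL_POLICIES:
            raise ValueError(f"unknown control_policy {self.control_policy!r}")
        for name in (
            "suspension_threshold",
            "drop_threshold",
            "best_arm_gate",
            "futility_bound",
            "final_success_bound",
            "d6_futility_bound",
            "d6_final_bound",
            "fixed_control_alloc",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for ladder in (self.efficacy_boundaries, self.d6_efficacy_ladder):
            if any(not 0 <= s <= 1 for s in ladder):
                raise ValueError("stopping boundaries must lie in [0, 1]")
            if any(a < b for a, b in zip(ladder, ladder[1:])):
                raise ValueError("stopping boundaries must be non-increasing")
        if not self.gamma >= 0:
            raise ValueError("gamma must be non-negative")
        if self.max_n <= 0:
            raise ValueError("max_n must be positive")
        if self.adaptation_interval is not None:
            if self.adaptation_interval <= 0:
                raise ValueError("adaptation_interval must be positive")
            if any(c % self.adaptation_interval for c in self.stopping_checks):
                raise ValueError(
                    "stopping checks must be multiples of the adaptation interval"
                )

    @property
    def is_rar(self) -> bool:
        return self.adaptation == "rar"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown DesignSpec keys: {sorted(unknown)}")
        kw = dict(d)
        for k in (
            "stopping_checks",
            "efficacy_boundaries",
            "d6_efficacy_ladder",
        ):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)


_PRESETS: dict[int, DesignSpec] = {
    1: DesignSpec(1, adaptation="none", adaptation_interval=None, stopping_checks=()),
    2: DesignSpec(2, adaptation="none", adaptation_interval=200, stopping_checks=(200, 400, 600)),
    3: DesignSpec(3, adaptation="drop", adaptation_interval=50, stopping_checks=(200, 400, 600)),
    4: DesignSpec(
        4,
        adaptation="rar",
        adaptation_interval=50,
        stopping_checks=(200, 400, 600),
        control_policy="matched-to-best",
    ),
    5: DesignSpec(
        5,
        adaptation="rar",
        adaptation_interval=50,
        stopping_checks=(200, 400, 600),
        control_policy="fixed-0.40",
    ),
    6: DesignSpec(
        6,
        adaptation="rar",
        adaptation_interval=50,
        stopping_checks=(200, 400, 600),
        control_policy="none",
    ),
}


def design_preset(design_id: int) -> DesignSpec:
    """The published parameterisation of design 1-6."""
    try:
        return _PRESETS[design_id]
    except KeyError:
        raise ValueError(f"design_id must be 1..6, got {design_id}") from None


@dataclass
class AllocationState:
    """Current randomisation probabilities plus suspension/drop bookkeeping."""

    probabilities: dict[str, float]
    suspended: frozenset[str] = frozenset()
    dropped: frozenset[str] = frozenset()
    arms: tuple[str, ...] = ARMS

    @classmethod
    def equal(cls, arms: tuple[str, ...] = ARMS) -> "AllocationState":
        return cls({a: 1.0 / len(arms) for a in arms}, arms=arms)

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(
            a for a in self.arms if a not in self.suspended and a not in self.dropped
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.probabilities.get(a, 0.0) for a in self.arms])

    def validate(self) -> None:
        v = self.as_vector()
        if not np.isclose(v.sum(), 1.0):
            raise AssertionError(f"allocation probabilities sum to {v.sum()}")
        for a in self.suspended | self.dropped:
            if self.probabilities.get(a, 0.0) != 0.0:
                raise AssertionError(f"inactive arm {a!r} has non-zero probability")


@dataclass
class InterimDecision:
    """Outcome of one interim analysis."""

    verdict: str  # continue | stop-efficacy | stop-futility
    state: AllocationState
    best_arm: str
    probabilities: dict[str, float] = field(default_factory=dict)  # pi_t per arm
    p_mcid: float | None = None
    p_superior: float | None = None


# ---------------------------------------------------------------------------
# allocation rules
# ---------------------------------------------------------------------------


def _suspend_and_renormalise(
    probs: dict[str, float],
    threshold: float,
    iterate: bool,
    renormalise_over: tuple[str, ...] | None = None,
    share: float = 1.0,
) -> tuple[dict[str, float], set[str]]:
    """Zero out arms below ``threshold`` and rescale the survivors to ``share``.

    ``renormalise_over`` restricts both the threshold test and the rescaling
    to a subset (used by the fixed-control policy, where only interventions
    share the non-control allocation).
    """
    pool = list(renormalise_over if renormalise_over is not None else probs)
    suspended: set[str] = set()
    while True:
        below = [a for a in pool if a not in suspended and probs[a] < threshold]
        if not below:
            break
        suspended.update(below)
        remaining = [a for a in pool if a not in suspended]
        if not remaining:
            raise AssertionError("all candidate arms suspended simultaneously")
        total = sum(probs[a] for a in remaining)
        for a in pool:
            probs[a] = share * probs[a] / total if a not in suspended else 0.0
        if not iterate:
            break
    return probs, suspended


def rar_probabilities(
    prob_best_map: Mapping[str, float],
    spec: DesignSpec,
    current_state: AllocationState,
) -> AllocationState:
    """Response-adaptive randomisation update.

    ``prob_best_map`` holds the posterior best-arm probabilities of the
    candidate arms: the non-dropped interventions for designs 4-5, all four
    arms for design 6.  Each probability is raised to the power ``gamma`` and
    renormalised; the control policy then fixes the control allocation, and
    arms falling below the suspension threshold are suspended (probability
    zero, reversible) with the remainder renormalised to a fixed point.
    Previously suspended arms re-enter the candidate set automatically because
    the caller recomputes ``prob_best_map`` over all non-dropped candidates.
    """
    candidates = [a for a in current_state.arms if a in prob_best_map]
    if not candidates:
        raise ValueError("no candidate arms")
    raw = np.array([prob_best_map[a] for a in candidates], dtype=float)
    if np.any(raw < 0):
        raise ValueError("negative best-arm probability")
    powered = raw**spec.gamma if spec.gamma > 0 else np.ones_like(raw)
    powered = powered / powered.sum()
    probs = {a: 0.0 for a in current_state.arms}
    for a, p in zip(candidates, powered):
        probs[a] = float(p)

    if spec.control_policy == "matched-to-best":
        probs[CONTROL_ARM] = max(probs[a] for a in candidates)
        total = sum(probs.values())
        probs = {a: p / total for a, p in probs.items()}
        probs, suspended = _suspend_and_renormalise(
            probs, spec.suspension_threshold, spec.iterate_suspension
        )
    elif spec.control_policy == "fixed-0.40":
        c = spec.fixed_control_alloc
        for a in candidates:
            probs[a] *= 1.0 - c
        probs[CONTROL_ARM] = c
        probs, suspended = _suspend_and_renormalise(
            probs,
            spec.suspension_threshold,
            spec.iterate_suspension,
            renormalise_over=tuple(candidates),
            share=1.0 - c,
        )
    elif spec.control_policy == "none":
        probs, suspended = _suspend_and_renormalise(
            probs, spec.suspension_threshold, spec.iterate_suspension
        )
    else:  # "equal" -- RAR not defined for the equal-allocation designs
        raise ValueError("rar_probabilities requires a RAR control policy")

    state = AllocationState(
        probs,
        suspended=frozenset(suspended),
        dropped=current_state.dropped,
        arms=current_state.arms,
    )
    state.validate()
    return state


def apply_arm_dropping(
    prob_best_map: Mapping[str, float],
    spec: DesignSpec,
    current_state: AllocationState,
) -> AllocationState:
    """Permanent arm dropping with equal allocation over the survivors.

    Any intervention whose posterior probability of being the best
    intervention falls below the drop threshold is removed for good; the
    control and the remaining interventions then share allocation equally.
    The control arm can never be dropped.
    """
    if CONTROL_ARM in prob_best_map:
        raise ValueError("the control arm cannot be a dropping candidate")
    dropped = set(current_state.dropped)
    for arm, p in prob_best_map.items():
        if arm in dropped:
            raise ValueError(f"arm {arm!r} already dropped")
        if p < spec.drop_threshold:
            dropped.add(arm)
    remaining = [a for a in current_state.arms if a not in dropped]
    probs = {a: (1.0 / len(remaining) if a in remaining else 0.0) for a in current_state.arms}
    state = AllocationState(
        probs, suspended=frozenset(), dropped=frozenset(dropped), arms=current_state.arms
    )
    state.validate()
    return state


# ---------------------------------------------------------------------------
# stopping rules
# ---------------------------------------------------------------------------


def efficacy_stop(
    p_mcid: float, p_best: float, interim_index: int, spec: DesignSpec
) -> bool:
    """Designs 2-5: stop early for efficacy iff the best intervention beats
    control by the MCID with probability above the interim's boundary *and*
    is the best intervention with probability above the 0.9 gate."""
    s_i = spec.efficacy_boundaries[interim_index - 1]
    return (p_mcid > s_i) and (p_best > spec.best_arm_gate)


def futility_stop(p_superior: float, spec: DesignSpec) -> bool:
    """Designs 2-5: stop for futility iff Pr(best intervention beats control)
    falls strictly below the futility bound (0.05)."""
    return p_superior < spec.futility_bound


def design6_decision(max_prob_best: float, interim_index: int, spec: DesignSpec) -> str:
    """Design 6 interim verdict from the maximum best-arm probability over
    all four arms: futility below 0.1, efficacy above the interim's ladder
    value (0.975/0.95/0.925), else continue."""
    if max_prob_best < spec.d6_futility_bound:
        return "stop-futility"
    if max_prob_best > spec.d6_efficacy_ladder[interim_index - 1]:
        return "stop-efficacy"
    return "continue"


def final_success(
    draws: PosteriorDraws,
    spec: DesignSpec,
) -> tuple[bool, str]:
    """Final-analysis verdict plus the declared best arm.

    Designs 1-5: success iff the best intervention beats control by the MCID
    with posterior probability above 0.5.  Design 6: success iff the maximum
    best-arm probability over all four arms exceeds 0.9.

    Candidate sets always span every arm: dropping and suspension constrain
    allocation, not the posterior — a dropped arm's posterior is simply
    frozen (no new data accrue) and it remains in the best-arm computations,
    exactly as the named-arm maximum in the decision rules reads.  The
    declared best arm (highest best-arm probability over all arms, the
    control included) is returned regardless of success.
    """
    pb_all = prob_best(draws, draws.arms)
    declared = max(pb_all, key=pb_all.get)
    if spec.design_id == 6 or spec.control_policy == "none":
        return pb_all[declared] > spec.d6_final_bound, declared
    interventions = tuple(a for a in draws.arms if a != CONTROL_ARM)
    pb_int = prob_best(draws, interventions)
    best_int = max(pb_int, key=pb_int.get)
    p_mcid = prob_margin(draws, best_int, CONTROL_ARM, spec.mcid)
    return p_mcid > spec.final_success_bound, declared
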