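"""Scenario registry and run-configuration parsing.

A :class:`Scenario` fixes the true outcome-generating distributions for the
four trial arms: per-arm mean 12-week FAOS QoL score and SD (20 points
throughout the built-in set).  The built-in scenarios span a null, single
superior arms at or below the MCID, graded effects, a harmful arm, two
similarly good arms, and an all-inferior configuration.

Run configurations are flat YAML files (``schema_version: 1``) binding a
design, a scenario, an accrual specification and replication settings;
unknown keys are rejected fail-fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .decision_rules import DesignSpec, design_preset
from .outcome_model import ARMS
from .trial_engine import AccrualSpec

__all__ = [
    "Scenario",
    "RunConfig",
    "builtin_scenarios",
    "load_config",
    "load_batch_config",
    "save_config",
]


@dataclass(frozen=True)
class Scenario:
    """True per-arm outcome distributions (normal mean and SD per arm)."""

    name: str
    means: tuple[float, float, float, float]
    sds: tuple[float, float, float, float] = (20.0, 20.0, 20.0, 20.0)
    arms: tuple[str, ...] = ARMS

    def __post_init__(self) -> None:
        if len(self.arms) != 4 or len(self.means) != 4 or len(self.sds) != 4:
            raise ValueError("a scenario has exactly four arms")
        if any(s <= 0 for s in self.sds):
            raise ValueError("scenario SDs must be positive")

    def mean(self, arm: str) -> float:
        return self.means[self.arms.index(arm)]

    def sd(self, arm: str) -> float:
        return self.sds[self.arms.index(arm)]

    @property
    def best_arms(self) -> tuple[str, ...]:
        """Arms attaining the maximal true mean (several if tied)."""
        top = max(self.means)
        return tuple(a for a, m in zip(self.arms, self.means) if m == top)


def builtin_scenarios() -> dict[str, Scenario]:
    """The scenario set used to evaluate the designs.

    Means are (tubular bandage, boot, brace, below-knee cast); SD is 20 FAOS
    points for every arm.
    """
    rows = {
        "Null": (50.0, 50.0, 50.0, 50.0),
        "One works, 10 more": (50.0, 50.0, 50.0, 60.0),
        "One works, 5 more": (50.0, 50.0, 50.0, 55.0),
        "Better, Best": (50.0, 55.0, 60.0, 65.0),
        "One worse, others work": (50.0, 45.0, 55.0, 60.0),
        "All work, two similar": (50.0, 55.0, 60.0, 60.0),
        "All inferior": (50.0, 45.0, 45.0, 45.0),
    }
    return {name: Scenario(name, means) for name, means in rows.items()}


@dataclass
class RunConfig:
    """One design x scenario simulation run."""

    design: DesignSpec
    scenario: Scenario
    accrual: AccrualSpec = field(default_factory=AccrualSpec)
    n_replicates: int = 1000
    base_seed: int = 0
    n_draws: int = 5000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


_SCHEMA_VERSION = 1
_TOP_KEYS = {
    "schema_version",
    "design",
    "scenario",
    "accrual",
    "n_replicates",
    "base_seed",
    "n_draws",
}
_BATCH_KEYS = (_TOP_KEYS - {"design", "scenario"}) | {"designs", "scenarios"}


def _parse_design(entry) -> DesignSpec:
    if isinstance(entry, int):
        return design_preset(entry)
    if isinstance(entry, Mapping):
        if "design_id" not in entry:
            raise ValueError("design mapping requires a design_id field")
        if set(entry) == {"design_id"}:
            return design_preset(int(entry["design_id"]))
        base = design_preset(int(entry["design_id"])).to_dict()
        unknown = set(entry) - set(base)
        if unknown:
            raise ValueError(f"unknown design keys: {sorted(unknown)}")
        base.update(entry)
        return DesignSpec.from_dict(base)
    raise ValueError(f"design must be an id (1-6) or a mapping, got {entry!r}")


def _parse_scenario(entry) -> Scenario:
    if entry is None:
        # YAML reads the bare scenario name "Null" as a null value
        return builtin_scenarios()["Null"]
    if isinstance(entry, str):
        registry = builtin_scenarios()
        if entry not in registry:
            raise ValueError(
                f"unknown scenario {entry!r}; built-ins: {sorted(registry)}"
            )
        return registry[entry]
    if isinstance(entry, Mapping):
        allowed = {"name", "means", "sds"}
        unknown = set(entry) - allowed
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        kw = dict(entry)
        kw["means"] = tuple(float(v) for v in kw["means"])
        if "sds" in kw:
            kw["sds"] = tuple(float(v) for v in kw["sds"])
        return Scenario(**kw)
    raise ValueError(f"scenario must be a name or a mapping, got {entry!r}")


def _parse_accrual(entry) -> AccrualSpec:
    if entry is None:
        return AccrualSpec()
    allowed = set(AccrualSpec.__dataclass_fields__)
    unknown = set(entry) - allowed
    if unknown:
        raise ValueError(f"unknown accrual keys: {sorted(unknown)}")
    return AccrualSpec(**entry)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} is not a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    version = raw.get("schema_version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    if "design" not in raw or "scenario" not in raw:
        raise ValueError("config requires 'design' and 'scenario' fields")
    for key in ("n_replicates", "base_seed", "n_draws"):
        if key in raw and int(raw[key]) != raw[key]:
            raise ValueError(f"{key} must be an integer")
        if key in raw and raw[key] < 0:
            raise ValueError(f"{key} must be non-negative")
    return RunConfig(
        design=_parse_design(raw["design"]),
        scenario=_parse_scenario(raw["scenario"]),
        accrual=_parse_accrual(raw.get("accrual")),
        n_replicates=int(raw.get("n_replicates", 1000)),
        base_seed=int(raw.get("base_seed", 0)),
        n_draws=int(raw.get("n_draws", 5000)),
    )


def load_batch_config(path: str | Path) -> list[RunConfig]:
    """Load a configuration naming one or several designs and scenarios.

    Accepts either the singular ``design``/``scenario`` keys of
    :func:`load_config` or plural ``designs``/``scenarios`` lists; returns
    one :class:`RunConfig` per design x scenario combination.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} is not a mapping")
    if "design" in raw and "scenario" in raw:
        return [load_config(path)]
    unknown = set(raw) - _BATCH_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    version = raw.get("schema_version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    designs = [_parse_design(d) for d in raw.get("designs", [])]
    scens = [_parse_scenario(s) for s in raw.get("scenarios", [])]
    if not designs or not scens:
        raise ValueError("batch config requires 'designs' and 'scenarios' lists")
    accrual = _parse_accrual(raw.get("accrual"))
    return [
        RunConfig(
            design=d,
            scenario=s,
            accrual=accrual,
            n_replicates=int(raw.get("n_replicates", 1000)),
            base_seed=int(raw.get("base_seed", 0)),
            n_draws=int(raw.get("n_draws", 5000)),
        )
        for d in designs
        for s in scens
    ]


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialise a RunConfig so that ``load_config`` round-trips it."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "design": cfg.design.to_dict(),
        "scenario": {
            "name": cfg.scenario.name,
            "means": list(cfg.scenario.means),
            "sds": list(cfg.scenario.sds),
        },
        "accrual": {
            k: getattr(cfg.accrual, k) for k in AccrualSpec.__dataclass_fields__
        },
        "n_replicates": cfg.n_replicates,
        "base_seed": cfg.base_seed,
        "n_draws": cfg.n_draws,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
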