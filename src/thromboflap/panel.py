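"""Thrombophilia panel and cohort-level model assumptions.

A :class:`Condition` bundles what the model needs to know about one
thrombophilia: its population prevalence, its relative risk of a first
venous thromboembolism (used as a proxy for the relative risk of a
thrombotic flap complication), the sensitivity of the screening assay, and
the assay's cost. A :class:`Panel` is an ordered collection of conditions
treated as mutually exclusive (at most one condition per patient), which is
why prevalences must sum below 1.

:class:`ModelParams` holds the cohort-level assumptions: cohort size, the
observed thrombotic complication rate the model is calibrated to, the
per-condition risk cap, and the costs/efficacy of prophylactic
anticoagulation.

File convention: CSV/YAML inputs carry percent units (as the printed
sources do); in-memory values are fractions. The loaders here are the only
place the factor of 100 appears.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .exceptions import ValidationError

__all__ = ["Condition", "Panel", "ModelParams", "read_panel_csv", "read_params_yaml"]


@dataclass(frozen=True)
class Condition:
    """One thrombophilia and its screening assay."""

    name: str
    prevalence: float
    relative_risk: float
    sensitivity: float
    assay_cost: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(
                f"{self.name}: prevalence {self.prevalence} outside (0, 1); "
                "did a percent value escape conversion?"
            )
        if self.relative_risk < 1.0:
            raise ValidationError(f"{self.name}: relative risk must be >= 1")
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValidationError(f"{self.name}: sensitivity must be in (0, 1]")
        if self.assay_cost < 0:
            raise ValidationError(f"{self.name}: assay cost must be >= 0")


@dataclass(frozen=True)
class Panel:
    """Ordered set of mutually exclusive thrombophilias."""

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValidationError("condition names must be unique within a panel")
        if self.total_prevalence >= 1.0:
            raise ValidationError(
                f"prevalences sum to {self.total_prevalence:.4f}; carriers are "
                "modelled as mutually exclusive so the sum must be < 1"
            )

    def __iter__(self) -> Iterator[Condition]:
        return iter(self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    @property
    def total_prevalence(self) -> float:
        return sum(c.prevalence for c in self.conditions)

    @property
    def panel_cost(self) -> float:
        """Cost of assaying every condition once, per patient."""
        return sum(c.assay_cost for c in self.conditions)

    def subset(self, names: Iterable[str]) -> "Panel":
        """Sub-panel with the given conditions, original order preserved."""
        wanted = set(names)
        unknown = wanted - set(self.names)
        if unknown:
            raise ValidationError(f"unknown condition names: {sorted(unknown)}")
        return Panel(tuple(c for c in self.conditions if c.name in wanted))

    def __getitem__(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [c.name for c in self.conditions],
                "prevalence": [c.prevalence for c in self.conditions],
                "relative_risk": [c.relative_risk for c in self.conditions],
                "sensitivity": [c.sensitivity for c in self.conditions],
                "assay_cost": [c.assay_cost for c in self.conditions],
            }
        )


@dataclass(frozen=True)
class ModelParams:
    """Cohort-level assumptions of the decision model.

    Parameters
    ----------
    cohort_size : int
        Size of the theoretical cohort (default 10 000 patients).
    complication_rate : float
        Observed thrombotic complication rate the model is calibrated to.
    risk_cap : float
        Ceiling on any single condition's per-carrier complication
        probability; a conservative constraint (default 0.5).
    therapy_efficacy : float
        Fraction of thrombotic complications prevented by prophylactic
        anticoagulation in treated patients (default 0.88).
    therapy_cost : float
        Cost of one prophylaxis course per treated patient (default $2100,
        a 30-day enoxaparin regimen).
    complication_cost : float
        Incremental direct cost of one thrombotic complication
        (default $23 246, from the matched billing comparison).
    cancellation_rate : float
        Fraction of positive screens that cancel surgery (fixed at 0).
    """

    cohort_size: int = 10_000
    complication_rate: float = 0.049
    risk_cap: float = 0.5
    therapy_efficacy: float = 0.88
    therapy_cost: float = 2100.0
    complication_cost: float = 23_246.0
    cancellation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValidationError("cohort_size must be positive")
        if not 0.0 < self.complication_rate < self.risk_cap <= 1.0:
            raise ValidationError(
                "need 0 < complication_rate < risk_cap <= 1 "
                f"(got r={self.complication_rate}, cap={self.risk_cap})"
            )
        if not 0.0 <= self.therapy_efficacy <= 1.0:
            raise ValidationError("therapy_efficacy must be in [0, 1]")
        if self.therapy_cost < 0 or self.complication_cost < 0:
            raise ValidationError("costs must be nonnegative")

    def with_(self, **kwargs) -> "ModelParams":
        """Copy with some fields replaced."""
        return replace(self, **kwargs)


def read_panel_csv(path: str | Path) -> Panel:
    """Read a panel CSV with percent-unit columns.

    Expected header: ``name,prevalence_pct,relative_risk,sensitivity_pct,
    assay_cost``. Prevalence and sensitivity are divided by 100 on load.
    """
    df = pd.read_csv(path)
    required = {"name", "prevalence_pct", "relative_risk", "sensitivity_pct", "assay_cost"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel CSV missing columns: {sorted(missing)}")
    return Panel(
        tuple(
            Condition(
                name=str(row["name"]),
                prevalence=float(row["prevalence_pct"]) / 100.0,
                relative_risk=float(row["relative_risk"]),
                sensitivity=float(row["sensitivity_pct"]) / 100.0,
                assay_cost=float(row["assay_cost"]),
            )
            for _, row in df.iterrows()
        )
    )


_PCT_KEYS = {
    "complication_rate_pct": "complication_rate",
    "therapy_efficacy_pct": "therapy_efficacy",
    "risk_cap_pct": "risk_cap",
    "flap_cancellation_rate_pct": "cancellation_rate",
}
_PLAIN_KEYS = {"cohort_size", "therapy_cost", "complication_cost"}


def read_params_yaml(path: str | Path) -> ModelParams:
    """Read cohort assumptions from YAML (percent-unit keys end in ``_pct``)."""
    with open(path) as fh:
        raw: Mapping[str, object] = yaml.safe_load(fh)
    kwargs: dict[str, float | int] = {}
    for key, value in raw.items():
        if key in _PCT_KEYS:
            kwargs[_PCT_KEYS[key]] = float(value) / 100.0
        elif key in _PLAIN_KEYS:
            kwargs[key] = type(ModelParams.__dataclass_fields__[key].default)(value)
        else:
            raise ValidationError(f"unknown model parameter key {key!r}")
    return ModelParams(**kwargs)
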