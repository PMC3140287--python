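"""Institutional free-flap registry analytics.

Computes the two institutional inputs the screening model needs:

* the thrombotic complication rate and flap failure rate of a free-flap
  registry (with a per-flap-type breakdown), and
* the incremental direct cost of a thrombotic complication, estimated from
  matched complicated/uncomplicated billing pairs.

A *thrombotic complication* is a reoperation for vascular compromise in
which the thrombosis was idiopathic, i.e. no mechanical cause (kinking,
stretch, compression) was documented. Matched billing pairs arrive
pre-matched by indication, year and flap type; no matching is performed
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import EmptyRegistryError, ValidationError

__all__ = [
    "FlapRecord",
    "CostPair",
    "RegistrySummary",
    "CostComparison",
    "summarize_registry",
    "cost_differential",
    "read_registry_csv",
    "read_cost_pairs_csv",
]

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


@dataclass(frozen=True)
class FlapRecord:
    """One free-flap case.

    ``thrombotic_idiopathic`` is only meaningful for cases reoperated for
    vascular compromise; the constructor enforces that implication.
    """

    flap_type: str
    year: int
    indication: str = ""
    reoperation_for_vascular_compromise: bool = False
    thrombotic_idiopathic: bool = False
    flap_loss: bool = False

    def __post_init__(self) -> None:
        if self.thrombotic_idiopathic and not self.reoperation_for_vascular_compromise:
            raise ValidationError(
                "thrombotic_idiopathic implies reoperation_for_vascular_compromise"
            )


@dataclass(frozen=True)
class CostPair:
    """A matched index (complicated) / comparator (uncomplicated) billing pair."""

    flap_type: str
    index_cost: float
    comparator_cost: float
    index_year: int = 0
    comparator_year: int = 0
    indication: str = ""

    def __post_init__(self) -> None:
        if self.index_cost < 0 or self.comparator_cost < 0:
            raise ValidationError("costs must be nonnegative")

    @property
    def differential(self) -> float:
        """Index minus comparator direct cost; may be negative."""
        return self.index_cost - self.comparator_cost


@dataclass(frozen=True)
class RegistrySummary:
    n_flaps: int
    n_thrombotic: int
    n_losses: int
    per_type: Mapping[str, tuple[int, int, float]] = field(default_factory=dict)

    @property
    def complication_rate(self) -> float:
        return self.n_thrombotic / self.n_flaps

    @property
    def failure_rate(self) -> float:
        return self.n_losses / self.n_flaps

    def to_frame(self) -> pd.DataFrame:
        """Per-type breakdown plus a Total row, unrounded rates."""
        rows = [
            {
                "flap_type": ft,
                "n_flaps": n,
                "n_thrombotic": k,
                "complication_rate": rate,
            }
            for ft, (n, k, rate) in sorted(self.per_type.items())
        ]
        rows.append(
            {
                "flap_type": "Total",
                "n_flaps": self.n_flaps,
                "n_thrombotic": self.n_thrombotic,
                "complication_rate": self.complication_rate,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CostComparison:
    mean_index: float
    mean_comparator: float
    mean_differential: float
    per_pair_differentials: tuple[float, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair_differentials)


def summarize_registry(records: Sequence[FlapRecord]) -> RegistrySummary:
    """Summarize a flap registry into complication/failure rates.

    Raises
    ------
    EmptyRegistryError
        If ``records`` is empty (no silent 0/0).
    """
    records = list(records)
    if not records:
        raise EmptyRegistryError("empty registry: no flap records to summarize")
    per_type: dict[str, list[int]] = {}
    for rec in records:
        n, k = per_type.setdefault(rec.flap_type, [0, 0])
        per_type[rec.flap_type][0] = n + 1
        per_type[rec.flap_type][1] = k + int(rec.thrombotic_idiopathic)
    return RegistrySummary(
        n_flaps=len(records),
        n_thrombotic=sum(r.thrombotic_idiopathic for r in records),
        n_losses=sum(r.flap_loss for r in records),
        per_type={ft: (n, k, k / n) for ft, (n, k) in per_type.items()},
    )


def cost_differential(pairs: Sequence[CostPair]) -> CostComparison:
    """Mean incremental direct cost of a thrombotic complication.

    Negative per-pair differentials are retained; the mean differential
    equals mean(index) - mean(comparator) by linearity.
    """
    pairs = list(pairs)
    if not pairs:
        raise EmptyRegistryError("empty cost-pair list")
    diffs = tuple(p.differential for p in pairs)
    mean_index = sum(p.index_cost for p in pairs) / len(pairs)
    mean_comp = sum(p.comparator_cost for p in pairs) / len(pairs)
    return CostComparison(
        mean_index=mean_index,
        mean_comparator=mean_comp,
        mean_differential=sum(diffs) / len(diffs),
        per_pair_differentials=diffs,
    )


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot parse boolean field value {value!r}")


def read_registry_csv(path: str | Path) -> list[FlapRecord]:
    """Read a per-case registry CSV.

    Expected header: ``flap_type,year,indication,reoperation_vascular,
    thrombotic_idiopathic,flap_loss`` with booleans as true/false or 1/0.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "flap_type",
        "year",
        "reoperation_vascular",
        "thrombotic_idiopathic",
        "flap_loss",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"registry CSV missing columns: {sorted(missing)}")
    return [
        FlapRecord(
            flap_type=row["flap_type"],
            year=int(row["year"]),
            indication=row.get("indication", ""),
            reoperation_for_vascular_compromise=_parse_bool(row["reoperation_vascular"]),
            thrombotic_idiopathic=_parse_bool(row["thrombotic_idiopathic"]),
            flap_loss=_parse_bool(row["flap_loss"]),
        )
        for _, row in df.iterrows()
    ]


def read_cost_pairs_csv(path: str | Path) -> list[CostPair]:
    """Read matched billing pairs.

    Expected header: ``flap_type,index_year,index_cost,comparator_year,
    comparator_cost,indication``.
    """
    df = pd.read_csv(path)
    required = {"flap_type", "index_cost", "comparator_cost"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cost-pair CSV missing columns: {sorted(missing)}")
    return [
        CostPair(
            flap_type=str(row["flap_type"]),
            index_cost=float(row["index_cost"]),
            comparator_cost=float(row["comparator_cost"]),
            index_year=int(row.get("index_year", 0) or 0),
            comparator_year=int(row.get("comparator_year", 0) or 0),
            indication=str(row.get("indication", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def write_records_csv(records: Iterable[FlapRecord], path: str | Path) -> None:
    """Write per-case records in the same dialect ``read_registry_csv`` reads."""
    records = list(records)
    df = pd.DataFrame(
        {
            "flap_type": [r.flap_type for r in records],
            "year": [r.year for r in records],
            "indication": [r.indication for r in records],
            "reoperation_vascular": [
                str(r.reoperation_for_vascular_compromise).lower() for r in records
            ],
            "thrombotic_idiopathic": [
                str(r.thrombotic_idiopathic).lower() for r in records
            ],
            "flap_loss": [str(r.flap_loss).lower() for r in records],
        }
    )
    df.to_csv(path, index=False)
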