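"""Synthetic data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here with
configurable true parameters, so parameter recovery can be checked
end-to-end without any institutional data:

* per-case flap registries with per-type complication probabilities,
* matched billing pairs with a configurable mean cost differential on top
  of a right-skewed (lognormal) comparator-cost distribution, and
* random thrombophilia panels for property-testing the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .panel import Condition, Panel
from .registry import CostPair, FlapRecord

__all__ = [
    "RegistryGenSpec",
    "CostGenSpec",
    "generate_registry",
    "generate_cost_pairs",
    "generate_random_panel",
]


@dataclass(frozen=True)
class RegistryGenSpec:
    """Ground truth for a synthetic flap registry.

    ``loss_given_complication`` is the conditional probability that a
    thrombotic complication ends in flap loss.
    """

    n_cases: int
    flap_type_weights: dict[str, float]
    per_type_complication_prob: dict[str, float]
    loss_given_complication: float = 0.4
    year_range: tuple[int, int] = (2004, 2009)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.flap_type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"flap type weights sum to {total}, expected 1")
        for ft, p in self.per_type_complication_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"complication probability for {ft} outside [0,1]")
        if not 0.0 <= self.loss_given_complication <= 1.0:
            raise ValidationError("loss_given_complication outside [0,1]")


@dataclass(frozen=True)
class CostGenSpec:
    """Ground truth for synthetic matched billing pairs.

    Comparator costs are lognormal (right-skewed, positive support) with
    the given location (median, dollars) and dispersion (sigma of the
    underlying normal). Differentials are normal around
    ``mean_differential`` so negative differentials occur, as they do in
    real matched pairs; index costs are truncated at zero.
    """

    n_pairs: int
    comparator_cost_location: float = 22_000.0
    comparator_cost_dispersion: float = 0.45
    mean_differential: float = 23_246.0
    differential_sd: float = 20_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.comparator_cost_dispersion < 0 or self.differential_sd < 0:
            raise ValidationError("dispersions must be >= 0")


def generate_registry(spec: RegistryGenSpec) -> list[FlapRecord]:
    """Draw a per-case registry; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    types = list(spec.flap_type_weights)
    weights = np.array([spec.flap_type_weights[t] for t in types])
    records = []
    for _ in range(spec.n_cases):
        ft = types[rng.choice(len(types), p=weights)]
        p = spec.per_type_complication_prob.get(ft, 0.0)
        thrombotic = bool(rng.random() < p)
        loss = thrombotic and bool(rng.random() < spec.loss_given_complication)
        records.append(
            FlapRecord(
                flap_type=ft,
                year=int(rng.integers(spec.year_range[0], spec.year_range[1] + 1)),
                indication="synthetic",
                reoperation_for_vascular_compromise=thrombotic,
                thrombotic_idiopathic=thrombotic,
                flap_loss=loss,
            )
        )
    return records


def generate_cost_pairs(spec: CostGenSpec) -> list[CostPair]:
    """Draw matched billing pairs; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    mu = np.log(spec.comparator_cost_location)
    comparator = rng.lognormal(mean=mu, sigma=spec.comparator_cost_dispersion,
                               size=spec.n_pairs)
    differential = rng.normal(spec.mean_differential, spec.differential_sd,
                              size=spec.n_pairs)
    index = np.maximum(comparator + differential, 0.0)
    return [
        CostPair(
            flap_type="synthetic",
            index_cost=float(i),
            comparator_cost=float(c),
        )
        for i, c in zip(index, comparator)
    ]


def generate_random_panel(m: int, seed: int) -> Panel:
    """Random valid panel for property-based testing of the solver.

    Prevalences are drawn and rescaled so their sum stays below 0.9;
    relative risks lie in [1, 40], sensitivities in (0.5, 1], assay costs
    in [20, 500].
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.001, 1.0, size=m)
    total_target = rng.uniform(0.05, 0.85)
    prevs = raw / raw.sum() * total_target
    return Panel(
        tuple(
            Condition(
                name=f"condition_{i:02d}",
                prevalence=float(prevs[i]),
                relative_risk=float(rng.uniform(1.0, 40.0)),
                sensitivity=float(rng.uniform(0.5, 1.0) + 1e-12),
                assay_cost=float(rng.uniform(20.0, 500.0)),
            )
            for i in range(m)
        )
    )
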