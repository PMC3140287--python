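"""Patient-level Monte-Carlo simulation of the screening model.

Simulates the same generative assumptions as the deterministic
expectations, patient by patient, and therefore serves as a brute-force
cross-check of the closed-form cohort quantities and as a tool for
exploring sampling variability:

1. each patient independently carries at most one condition, drawn from the
   categorical distribution ``{pi_1, ..., pi_m, 1 - sum(pi)}``;
2. a carrier of condition ``i`` has complication risk
   ``min(RR_i * p0, K)``; a non-carrier has risk ``p0``;
3. under a screening scenario a carrier of a screened condition tests
   positive with probability ``s_i`` (non-carriers never do — assay
   specificity is 1); under all-therapy everyone is treated;
4. treated patients have their risk multiplied by ``1 - e``;
5. the complication is a single Bernoulli draw per patient, and costs
   accumulate exactly as in the deterministic scenario accounting.

Each replicate uses its own generator seeded ``seed + replicate_index`` so
results are reproducible and replicates are independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BaselineRisk
from .exceptions import ValidationError
from .panel import ModelParams, Panel
from .scenarios import ScenarioSpec

__all__ = ["SimConfig", "SimResult", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_patients: int
    panel: Panel
    params: ModelParams
    scenario: ScenarioSpec
    baseline: BaselineRisk
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Replicate means and standard errors of the simulated cohort."""

    n_patients: int
    n_replicates: int
    complications_mean: float
    complications_se: float
    test_positive_mean: float
    test_positive_se: float
    treated_mean: float
    treated_se: float
    total_cost_mean: float
    total_cost_se: float
    per_condition_complications: dict[str, float] = field(default_factory=dict)


def _se(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def simulate_cohort(config: SimConfig) -> SimResult:
    """Run the patient-level simulation for ``n_replicates`` replicates."""
    panel, params, spec = config.panel, config.params, config.scenario
    m = len(panel)
    prevs = np.array([c.prevalence for c in panel])
    probs = np.append(prevs, 1.0 - prevs.sum())
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("condition probabilities do not form a distribution")
    rho = np.array(
        [
            min(c.relative_risk * config.baseline.p0, params.risk_cap)
            for c in panel
        ]
        + [config.baseline.p0]  # slot m = no condition
    )
    sens = np.array([c.sensitivity for c in panel] + [0.0])
    screened = np.array(
        [c.name in spec.screened_conditions for c in panel] + [False]
    )
    screen_cost = (
        panel.subset(spec.screened_conditions).panel_cost
        if spec.screened_conditions
        else 0.0
    )

    n = config.n_patients
    comp = np.zeros(config.n_replicates)
    pos = np.zeros(config.n_replicates)
    treated = np.zeros(config.n_replicates)
    cost = np.zeros(config.n_replicates)
    per_cond = np.zeros((config.n_replicates, m))
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + rep)
        if n == 0:
            continue
        cond = rng.choice(m + 1, size=n, p=probs)
        tests_pos = screened[cond] & (rng.random(n) < sens[cond])
        is_treated = tests_pos | spec.treat_all
        risk = rho[cond] * np.where(is_treated, 1.0 - params.therapy_efficacy, 1.0)
        event = rng.random(n) < risk
        comp[rep] = event.sum()
        pos[rep] = tests_pos.sum()
        treated[rep] = is_treated.sum()
        cost[rep] = (
            n * screen_cost
            + is_treated.sum() * params.therapy_cost
            + event.sum() * params.complication_cost
        )
        for i in range(m):
            per_cond[rep, i] = event[cond == i].sum()

    return SimResult(
        n_patients=n,
        n_replicates=config.n_replicates,
        complications_mean=float(comp.mean()),
        complications_se=_se(comp),
        test_positive_mean=float(pos.mean()),
        test_positive_se=_se(pos),
        treated_mean=float(treated.mean()),
        treated_se=_se(treated),
        total_cost_mean=float(cost.mean()),
        total_cost_se=_se(cost),
        per_condition_complications={
            c.name: float(per_cond[:, i].mean()) for i, c in enumerate(panel)
        },
    )
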