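"""Core calibration and per-condition predictions.

The model treats a cohort of ``N`` patients in which each patient carries at
most one thrombophilia (condition ``i`` with probability ``pi_i``, none with
probability ``1 - sum(pi)``). A non-carrier suffers a thrombotic flap
complication with unknown baseline probability ``p0``; a carrier of
condition ``i`` with probability ``rho_i = min(RR_i * p0, K)``, where ``K``
is a conservative per-condition risk cap. ``p0`` is fixed by requiring the
cohort-average risk to equal the observed institutional complication rate
``r``:

    sum_i pi_i * min(RR_i * p0, K) + (1 - sum_i pi_i) * p0 = r

The left side is continuous and strictly increasing in ``p0`` (the
non-carrier term always grows), so the root is unique. It is found by
Brent's method; the piecewise-linear kinks where a cap activates rule out a
single closed form but not bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.optimize import brentq

from ._rounding import round_to_int
from .exceptions import InfeasibleParametersError, ValidationError
from .panel import ModelParams, Panel

__all__ = [
    "BaselineRisk",
    "ConditionPrediction",
    "solve_baseline_risk",
    "predict_conditions",
    "total_test_positive",
    "attributable_summary",
    "select_limited_panel",
]

SOLVER_TOL = 1e-12


@dataclass(frozen=True)
class BaselineRisk:
    """Solved per-case thrombosis risk of a patient with no panel condition.

    ``cap_active`` lists conditions whose uncapped risk ``RR_i * p0`` reaches
    the cap ``K``; ``residual`` is the balance-equation mismatch at ``p0``.
    """

    p0: float
    cap_active: frozenset[str]
    residual: float


@dataclass(frozen=True)
class ConditionPrediction:
    """Expected cohort-level quantities for one condition.

    All values are unrounded expectations over the cohort:

    * ``per_carrier_risk``: ``min(RR_i * p0, K)``
    * ``expected_carriers``: ``N * pi_i``
    * ``expected_complications``: carriers times per-carrier risk
    * ``detected_complications``: complications among carriers the assay
      would catch (times sensitivity)
    * ``expected_test_positives``: ``N * pi_i * s_i``
    """

    name: str
    per_carrier_risk: float
    expected_carriers: float
    expected_complications: float
    detected_complications: float
    expected_test_positives: float
    assay_cost: float


def _balance(p0: float, panel: Panel, params: ModelParams) -> float:
    cap = params.risk_cap
    carriers = sum(c.prevalence * min(c.relative_risk * p0, cap) for c in panel)
    return carriers + (1.0 - panel.total_prevalence) * p0 - params.complication_rate


def solve_baseline_risk(
    panel: Panel, params: ModelParams, tol: float = SOLVER_TOL
) -> BaselineRisk:
    """Solve the balance equation for the baseline per-case risk ``p0``.

    With an empty panel the equation degenerates to ``p0 = r``. Otherwise
    the root is bracketed in ``[0, r / (1 - sum(pi))]``: at 0 the balance is
    ``-r`` and at the upper end every carrier term only adds risk, so the
    balance is nonnegative.
    """
    r = params.complication_rate
    if len(panel) == 0:
        return BaselineRisk(p0=r, cap_active=frozenset(), residual=0.0)
    hi = r / (1.0 - panel.total_prevalence)
    f_lo, f_hi = _balance(0.0, panel, params), _balance(hi, panel, params)
    if f_lo > 0 or f_hi < 0:  # cannot occur for valid inputs, but guarded
        raise InfeasibleParametersError(
            f"no baseline risk balances rate {r} under cap {params.risk_cap}"
        )
    p0 = float(brentq(_balance, 0.0, hi, args=(panel, params), xtol=tol, rtol=1e-15))
    residual = abs(_balance(p0, panel, params))
    cap_active = frozenset(
        c.name for c in panel if c.relative_risk * p0 >= params.risk_cap
    )
    return BaselineRisk(p0=p0, cap_active=cap_active, residual=residual)


def predict_conditions(
    panel: Panel, params: ModelParams, baseline: BaselineRisk
) -> list[ConditionPrediction]:
    """Apply the per-condition expectation formulas at the solved ``p0``."""
    n = params.cohort_size
    out = []
    for c in panel:
        rho = min(c.relative_risk * baseline.p0, params.risk_cap)
        carriers = n * c.prevalence
        complications = carriers * rho
        out.append(
            ConditionPrediction(
                name=c.name,
                per_carrier_risk=rho,
                expected_carriers=carriers,
                expected_complications=complications,
                detected_complications=c.sensitivity * complications,
                expected_test_positives=carriers * c.sensitivity,
                assay_cost=c.assay_cost,
            )
        )
    return out


def total_test_positive(panel: Panel, params: ModelParams) -> float:
    """Expected screen-positive patients, ``N * sum(pi_i * s_i)``, unrounded."""
    return params.cohort_size * sum(c.prevalence * c.sensitivity for c in panel)


def attributable_summary(
    predictions: Sequence[ConditionPrediction],
    params: ModelParams,
    detected: bool = True,
) -> tuple[float, float]:
    """Fraction and absolute rate of complications attributable to thrombophilia.

    By default both are computed on *detected* complications (expected
    complications times assay sensitivity), matching how the published
    per-condition column is totalled; ``detected=False`` uses all carrier
    complications regardless of detectability.
    """
    total = sum(
        p.detected_complications if detected else p.expected_complications
        for p in predictions
    )
    n = params.cohort_size
    return total / (n * params.complication_rate), total / n


def select_limited_panel(
    predictions: Sequence[ConditionPrediction],
    panel: Panel,
    k: int | None = None,
    capture_target: float | None = None,
) -> Panel:
    """Choose a cheaper sub-panel by predicted detected complications.

    Conditions are ranked by ``detected_complications`` descending (ties
    broken by lower assay cost, then name). With ``k`` the top-k conditions
    are returned; with ``capture_target`` the smallest prefix whose
    cumulative share of total detected complications reaches the target.
    """
    if (k is None) == (capture_target is None):
        raise ValidationError("specify exactly one of k or capture_target")
    ranked = sorted(
        predictions,
        key=lambda p: (-p.detected_complications, p.assay_cost, p.name),
    )
    if k is not None:
        if not 1 <= k <= len(ranked):
            raise ValidationError(f"k must be in [1, {len(ranked)}]")
        chosen = ranked[:k]
    else:
        if not 0.0 < capture_target <= 1.0:
            raise ValidationError("capture_target must be in (0, 1]")
        total = sum(p.detected_complications for p in ranked)
        chosen, cum = [], 0.0
        for p in ranked:
            chosen.append(p)
            cum += p.detected_complications
            if total > 0 and cum / total >= capture_target:
                break
    return panel.subset(p.name for p in chosen)


def predictions_frame(predictions: Sequence[ConditionPrediction]) -> pd.DataFrame:
    """Tabulate predictions; display counts use half-up integer rounding."""
    df = pd.DataFrame(
        {
            "name": [p.name for p in predictions],
            "per_carrier_risk": [p.per_carrier_risk for p in predictions],
            "expected_carriers": [p.expected_carriers for p in predictions],
            "expected_complications": [p.expected_complications for p in predictions],
            "detected_complications": [p.detected_complications for p in predictions],
            "expected_test_positives": [p.expected_test_positives for p in predictions],
            "assay_cost": [p.assay_cost for p in predictions],
        }
    )
    df["detected_complications_display"] = [
        round_to_int(x) for x in df["detected_complications"]
    ]
    return df
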