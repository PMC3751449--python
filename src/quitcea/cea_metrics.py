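"""Incremental cost-effectiveness statistics.

Given the discounted lifetime outcomes of the two arms, this module forms
the incremental deltas, the cost-per-quitter / per-LY / per-QALY ratios
with the conventional dominance flag (an intervention that improves health
and saves money has no meaningful ratio), the net monetary benefit

    NMB(lambda) = lambda * dQALY - dCost,

and the cost-effectiveness acceptability curve: the proportion of
probabilistic-sensitivity-analysis iterations with positive NMB at each
willingness-to-pay value.  Ties (NMB exactly 0) count as not
cost-effective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .markov_engine import Outcomes
from .params_io import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .sensitivity import PSAResults


@dataclass(frozen=True)
class Ratio:
    """An incremental cost-effectiveness ratio, or its dominance /
    undefined flag."""

    value: float | None
    dominant: bool = False
    undefined: bool = False

    def __str__(self) -> str:
        if self.dominant:
            return "dominant"
        if self.undefined:
            return "undefined"
        return f"{self.value:.6g}"


def _ratio(d_cost: float, d_effect: float) -> Ratio:
    if d_cost < 0.0 and d_effect > 0.0:
        return Ratio(None, dominant=True)
    if d_effect == 0.0:
        if d_cost == 0.0:
            return Ratio(0.0)
        return Ratio(None, undefined=True)
    return Ratio(d_cost / d_effect)


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention-minus-control deltas per 1,000 enrollees and the
    derived ratios."""

    d_cost: float
    d_ly: float
    d_qaly: float
    d_quitters: float
    cost_per_quitter: Ratio
    cost_per_ly: Ratio
    cost_per_qaly: Ratio


def incremental(intervention: Outcomes, control: Outcomes) -> IncrementalResult:
    """Incremental comparison of two arms on the same per-1,000 scale."""
    d_cost = intervention.total_cost - control.total_cost
    d_ly = intervention.life_years - control.life_years
    d_qaly = intervention.qalys - control.qalys
    d_quitters = intervention.quitters_6m - control.quitters_6m
    return IncrementalResult(
        d_cost=d_cost,
        d_ly=d_ly,
        d_qaly=d_qaly,
        d_quitters=d_quitters,
        cost_per_quitter=_ratio(d_cost, d_quitters),
        cost_per_ly=_ratio(d_cost, d_ly),
        cost_per_qaly=_ratio(d_cost, d_qaly),
    )


def nmb(inc: IncrementalResult, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` per QALY."""
    if wtp < 0.0:
        raise ValidationError(f"willingness to pay must be >= 0, got {wtp!r}")
    return wtp * inc.d_qaly - inc.d_cost


@dataclass(frozen=True)
class CEACCurve:
    """Cost-effectiveness acceptability curve on a willingness-to-pay grid."""

    lambda_grid: np.ndarray
    prob_ce: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise ValidationError("lambda grid must be strictly increasing")
        if np.any((self.prob_ce < 0) | (self.prob_ce > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambda_grid, "probability": self.prob_ce}
        )


def default_wtp_grid(wtp_max: float = 4000.0, step: float = 50.0) -> np.ndarray:
    return np.arange(0.0, wtp_max + step / 2, step)


def ceac(psa: "PSAResults", grid: np.ndarray | None = None) -> CEACCurve:
    """Acceptability curve over PSA iterations: at each lambda, the fraction
    of iterations with ``lambda * d_qaly - d_cost > 0`` (strict)."""
    if psa.n < 1 or len(psa.d_cost) == 0:
        raise ValidationError("empty PSA results")
    if grid is None:
        grid = default_wtp_grid()
    grid = np.asarray(grid, dtype=float)
    nmb_matrix = grid[:, None] * psa.d_qaly[None, :] - psa.d_cost[None, :]
    prob = (nmb_matrix > 0).mean(axis=1)
    return CEACCurve(lambda_grid=grid, prob_ce=prob)
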