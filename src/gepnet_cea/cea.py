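"""Comparative cost-effectiveness outcomes: ICER, dominance, NMB.

Two strategies are compared on an efficiency frontier: the higher-QALY
strategy's incremental cost per incremental QALY (the ICER) is judged
against a willingness-to-pay (WTP) threshold. If the higher-QALY strategy
is also cheaper it dominates and the ICER is undefined. Net monetary
benefit, ``NMB = WTP * QALY - cost``, gives the same verdict whenever the
ICER is defined and is the quantity behind acceptability curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["StrategyOutcome", "CEAResult", "compare", "nmb"]


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-strategy totals from one cohort run."""

    label: str
    cost: float           # discounted dollars
    ly: float             # undiscounted life-years
    qaly: float           # discounted, half-cycle-corrected QALYs
    net_death_pct: float | None = None  # % of deaths attributable to the tumour

    def __post_init__(self):
        if self.cost < 0 or self.ly < 0 or self.qaly < 0:
            raise ValueError("outcome totals must be non-negative")


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of the higher-QALY strategy over the other."""

    higher: StrategyOutcome
    lower: StrategyOutcome
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer: float | None        # $/QALY; None when undefined (dominance or tie)
    dominant: bool            # higher-QALY strategy is also cheaper
    tie: bool                 # equal QALYs, ICER undefined
    wtp: float
    cost_effective_at_wtp: bool

    @property
    def outcomes(self) -> tuple[StrategyOutcome, StrategyOutcome]:
        return (self.higher, self.lower)


def compare(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> CEAResult:
    """Efficiency-frontier comparison of two strategies.

    Orders the pair by QALY (ties broken by lower cost), computes the
    increments of the higher-QALY strategy over the lower, and flags
    dominance (more QALYs for less money). The higher-QALY strategy is
    cost-effective at ``wtp`` when it dominates or its ICER is <= wtp.
    """
    if a.label == b.label:
        raise ValueError("compare requires two distinct strategies")
    hi, lo = (a, b) if (a.qaly, -a.cost) > (b.qaly, -b.cost) else (b, a)
    d_cost = hi.cost - lo.cost
    d_qaly = hi.qaly - lo.qaly
    d_ly = hi.ly - lo.ly
    tie = math.isclose(d_qaly, 0.0, abs_tol=1e-12)
    dominant = (not tie) and d_cost < 0
    icer = None if (tie or dominant) else d_cost / d_qaly
    ce = dominant or (icer is not None and icer <= wtp)
    return CEAResult(higher=hi, lower=lo, incremental_cost=d_cost,
                     incremental_ly=d_ly, incremental_qaly=d_qaly,
                     icer=icer, dominant=dominant, tie=tie, wtp=wtp,
                     cost_effective_at_wtp=ce)


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * outcome.qaly - outcome.cost
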