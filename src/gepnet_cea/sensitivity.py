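"""Sensitivity analyses: one-way tornado, threshold price, and PSA/CEAC.

One-way deterministic analysis re-runs the full two-strategy comparison
at each parameter's low and high bound, holding everything else at base,
and sorts the resulting ICER bars by width (the tornado diagram).

The threshold-price analysis root-finds the monthly SSA cost at which the
immediate-start strategy's ICER exactly meets the willingness-to-pay
threshold.

The probabilistic sensitivity analysis (PSA) draws every parameter
simultaneously and independently — gamma distributions for costs, beta
for utilities and per-cycle probabilities — with means at the base values
and standard deviations chosen so that each deterministic sensitivity
range corresponds to a 95% interval (SD = range / 3.92). Clinical event
inputs are medians; they are mapped to per-cycle probabilities before the
beta draw and back afterwards, so the sampled quantity is the probability
itself. The cost-effectiveness acceptability curve (CEAC) reports, per
willingness-to-pay value, the fraction of iterations in which immediate
SSA has the higher net monetary benefit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cea import compare
from .lifetable import LifeTable
from .parameters import (ParameterSet, cycle_prob_to_median,
                         interval_prob_to_cycle_prob, median_to_cycle_prob)
from .strategies import evaluate_strategy

__all__ = [
    "TornadoEntry", "PSAResult", "CEACPoint",
    "icer_for", "one_way_dsa", "threshold_price",
    "draw_psa_sample", "run_psa", "ceac",
]

log = logging.getLogger(__name__)

#: Range-to-SD divisor: a (low, high) sensitivity range is read as a 95%
#: interval, SD = (high - low) / (2 * 1.96). The single place to change if
#: a different uncertainty magnitude is wanted.
RANGE_TO_SD = 2.0 * 1.96

_COST_PARAMS = ("cost_ssa_month", "cost_prrt_cycle")
_UTILITY_PARAMS = ("u_pre_ssa", "u_on_ssa", "u_progressed", "u_uncontrolled")
_MEDIAN_PARAMS = ("median_net_death_untreated", "median_net_death_on_ssa",
                  "median_net_death_on_prrt", "median_progression_off_ssa",
                  "median_progression_on_ssa", "median_progression_delayed_ssa")


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: the ICER at a parameter's low and high bound."""

    parameter: str
    low_input: float
    high_input: float
    icer_at_low: float | None   # None when the comparison degenerates
    icer_at_high: float | None
    dominant_at_low: bool = False
    dominant_at_high: bool = False

    @property
    def bar_width(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return math.inf
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_cost_effective: float


@dataclass(frozen=True)
class PSAResult:
    """Incremental outcomes (SSA minus DELAY) across PSA iterations."""

    n_iterations: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations where immediate SSA has higher NMB."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))


def icer_for(params: ParameterSet, lt: LifeTable):
    """Run both strategies and return ``(CEAResult, icer-or-None)``."""
    ssa = evaluate_strategy(params, "SSA", lt)
    delay = evaluate_strategy(params, "DELAY", lt)
    res = compare(ssa, delay, params.wtp)
    return res, res.icer


def one_way_dsa(params: ParameterSet, lt: LifeTable) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis over ``params.sa_ranges``.

    Returns tornado entries sorted by bar width, widest first. A bound at
    which the comparison degenerates (dominance or a QALY tie) keeps its
    entry with the corresponding ICER set to None and a dominance flag.
    """
    params.check_sa_ranges()
    entries = []
    for name, (lo, hi) in params.sa_ranges.items():
        results = {}
        for bound in (lo, hi):
            res, icer = icer_for(params.with_value(name, bound), lt)
            results[bound] = (icer, res.dominant)
        entries.append(TornadoEntry(
            parameter=name, low_input=lo, high_input=hi,
            icer_at_low=results[lo][0], icer_at_high=results[hi][0],
            dominant_at_low=results[lo][1], dominant_at_high=results[hi][1]))
    return sorted(entries, key=lambda e: e.bar_width, reverse=True)


def threshold_price(params: ParameterSet, lt: LifeTable, wtp: float,
                    target: str = "cost_ssa_month",
                    bracket: tuple[float, float] | None = None,
                    tol: float = 0.01) -> float:
    """Parameter value at which the ICER equals ``wtp`` (root-finding).

    Searches ``bracket`` (default ``[0, base value]``) with Brent's
    method to an absolute tolerance of ``tol`` dollars. Requires a sign
    change of ``ICER - wtp`` over the bracket; monotonicity is checked at
    the bracket midpoint.
    """
    base = getattr(params, target)
    lo, hi = bracket if bracket is not None else (0.0, base)

    def f(x: float) -> float:
        _, icer = icer_for(params.with_value(target, x), lt)
        if icer is None:
            raise ValueError(f"ICER undefined at {target}={x}")
        return icer - wtp

    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no threshold in [{lo}, {hi}]: ICER-wtp is {f_lo:.0f} at the "
            f"lower and {f_hi:.0f} at the upper end")
    f_mid = f(0.5 * (lo + hi))
    if not min(f_lo, f_hi) <= f_mid <= max(f_lo, f_hi):
        raise ValueError("ICER is not monotone over the search bracket")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def _gamma_draw(rng, mean: float, sd: float) -> float:
    if sd <= 0 or mean <= 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return float(rng.gamma(shape, scale))


def _beta_draw(rng, mean: float, sd: float, context: str) -> float:
    if sd <= 0 or not 0.0 < mean < 1.0:
        return mean
    bound = math.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        log.warning("infeasible beta SD %.4g for %s; shrunk to feasibility "
                    "bound", sd, context)
        sd = 0.99 * bound
    nu = mean * (1.0 - mean) / sd ** 2 - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return float(rng.beta(a, b))


def draw_psa_sample(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Draw one probabilistic parameter sample.

    Costs are gamma-distributed; utilities and per-cycle probabilities
    beta-distributed; moments are matched so the mean is the base value
    and the SD is the sensitivity range divided by 3.92. Draws are
    independent across parameters. Parameters without a sensitivity range
    stay at base.
    """
    updates: dict[str, float] = {}
    for name, (lo, hi) in params.sa_ranges.items():
        base = getattr(params, name)
        sd = (hi - lo) / RANGE_TO_SD
        if name in _COST_PARAMS:
            updates[name] = _gamma_draw(rng, base, sd)
        elif name in _UTILITY_PARAMS:
            updates[name] = _beta_draw(rng, base, sd, name)
        elif name in _MEDIAN_PARAMS:
            p_base = median_to_cycle_prob(base)
            # higher median -> lower monthly probability: the range flips
            p_lo, p_hi = median_to_cycle_prob(hi), median_to_cycle_prob(lo)
            p_sd = (p_hi - p_lo) / RANGE_TO_SD
            p = _beta_draw(rng, p_base, p_sd, name)
            updates[name] = cycle_prob_to_median(p)
        elif name == "p_complication_interval":
            months = params.complication_interval_months
            p_base = interval_prob_to_cycle_prob(base, months)
            p_lo = interval_prob_to_cycle_prob(lo, months)
            p_hi = interval_prob_to_cycle_prob(hi, months)
            p_sd = (p_hi - p_lo) / RANGE_TO_SD
            p = _beta_draw(rng, p_base, p_sd, name)
            updates[name] = 1.0 - (1.0 - p) ** months
        else:
            raise ValueError(f"no PSA distribution rule for parameter {name!r}")
    out = params
    for k, v in updates.items():
        out = out.with_value(k, v)
    return out


def run_psa(params: ParameterSet, lt: LifeTable, n_iterations: int,
            seed: int) -> PSAResult:
    """Monte Carlo PSA: per iteration, draw parameters and run both arms."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_iterations)
    d_qaly = np.empty(n_iterations)
    for i in range(n_iterations):
        sample = draw_psa_sample(params, rng)
        ssa = evaluate_strategy(sample, "SSA", lt)
        delay = evaluate_strategy(sample, "DELAY", lt)
        d_cost[i] = ssa.cost - delay.cost
        d_qaly[i] = ssa.qaly - delay.qaly
    return PSAResult(n_iterations=n_iterations, seed=seed,
                     delta_cost=d_cost, delta_qaly=d_qaly)


def ceac(psa: PSAResult, wtp_grid) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    return [CEACPoint(wtp=float(w), prob_cost_effective=psa.prob_cost_effective(w))
            for w in grid]
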