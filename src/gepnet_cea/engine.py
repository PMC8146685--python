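"""Generic time-inhomogeneous Markov cohort machinery.

The engine is agnostic of the clinical content: it takes named states with
per-cycle exit probabilities (possibly varying by cycle, e.g. through
age-indexed background mortality), combines simultaneous exits as
competing risks, propagates a cohort trace, and accumulates discounted
costs and half-cycle-corrected QALYs. A per-individual microsimulation of
the identical model is provided as an independent validation oracle.

Conventions
-----------
* Cycle length is one month (1/12 year); discounting uses the factor
  ``(1 + r)**(-t/12)`` at cycle index ``t``.
* Half-cycle correction is trapezoidal averaging of the state-occupancy
  trace, applied to QALYs and life-years but not to costs (drug costs
  accrue per dispensed month at the start of the cycle).
* Within a cycle, simultaneous exits are combined by converting each
  probability to a constant rate, summing the rates, and apportioning the
  total exit probability proportionally to the rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StateSpec",
    "MarkovModel",
    "CohortTrace",
    "RewardTotals",
    "combine_competing_risks",
    "build_model",
    "run_cohort",
    "discount_factor",
    "accumulate_rewards",
    "microsim_oracle",
]

_ROW_TOL = 1e-10
CYCLES_PER_YEAR = 12


def combine_competing_risks(event_probs: Mapping[str, float]) -> dict[str, float]:
    """Adjust simultaneous per-cycle exit probabilities as competing risks.

    Each marginal probability ``p_i`` is converted to a constant rate
    ``r_i = -ln(1 - p_i)``; the total exit probability over the cycle is
    ``P = 1 - exp(-sum r_i)`` and is apportioned to event ``i`` as
    ``P * r_i / sum r_j``. The adjusted probabilities always sum to <= 1.

    An event with ``p = 1`` alongside any other positive-probability event
    is rejected (two simultaneous certain events are undefined).
    """
    if not event_probs:
        return {}
    probs = {k: float(p) for k, p in event_probs.items()}
    for k, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"event {k!r} probability {p} outside [0, 1]")
    certain = [k for k, p in probs.items() if p == 1.0]
    if certain:
        others = [k for k, p in probs.items() if p > 0.0 and k not in certain]
        if others or len(certain) > 1:
            raise ValueError("a certain event cannot compete with another event")
        return {k: (1.0 if k in certain else 0.0) for k in probs}
    rates = {k: -math.log1p(-p) for k, p in probs.items()}
    total_rate = sum(rates.values())
    if total_rate == 0.0:
        return {k: 0.0 for k in probs}
    p_total = -math.expm1(-total_rate)
    return {k: p_total * r / total_rate for k, r in rates.items()}


def _combine_competing_risks_vec(p: np.ndarray) -> np.ndarray:
    """Vectorised competing-risk adjustment.

    ``p`` has shape (n_events, n_cycles); returns the adjusted array of
    the same shape. Probabilities must lie in [0, 1).
    """
    if np.any((p < 0.0) | (p >= 1.0)):
        raise ValueError("vectorised competing risks requires probabilities in [0, 1)")
    rates = -np.log1p(-p)
    total = rates.sum(axis=0)
    p_total = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0.0, p_total * rates / np.where(total > 0, total, 1.0), 0.0)
    return out


@dataclass
class StateSpec:
    """One health state: rewards plus per-cycle exit probabilities.

    ``exits`` maps destination-state names to marginal per-cycle
    probabilities (scalar, or an array over cycles); they are combined as
    competing risks when the model is assembled. Mass not leaving through
    an exit goes to ``residual`` — the state itself by default, or the
    next state of a tunnel chain.
    """

    name: str
    cost_per_cycle: float = 0.0
    utility: float = 0.0
    exits: dict[str, float | np.ndarray] = field(default_factory=dict)
    residual: str | None = None


@dataclass(frozen=True)
class MarkovModel:
    """Assembled cohort model: a per-cycle transition tensor plus rewards."""

    states: tuple[str, ...]
    transition: np.ndarray      # (n_cycles, S, S), row-stochastic
    cost_per_cycle: np.ndarray  # (S,) dollars per cycle of occupancy
    utility: np.ndarray         # (S,) utility weight per year of occupancy
    absorbing: frozenset
    initial_state: str
    n_cycles: int

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def absorbing_mask(self) -> np.ndarray:
        return np.array([s in self.absorbing for s in self.states])


def build_model(states: Sequence[StateSpec], initial_state: str,
                absorbing: Sequence[str], n_cycles: int) -> MarkovModel:
    """Assemble a :class:`MarkovModel` from per-state exit specifications.

    Exit probabilities of each state are passed through the competing-risk
    adjustment cycle by cycle; absorbing states must declare no exits and
    carry zero rewards.
    """
    names = [s.name for s in states]
    if len(set(names)) != len(names):
        raise ValueError("duplicate state names")
    if initial_state not in names:
        raise ValueError(f"initial state {initial_state!r} not among states")
    absorbing = frozenset(absorbing)
    for a in absorbing:
        if a not in names:
            raise ValueError(f"absorbing state {a!r} not among states")
    idx = {n: i for i, n in enumerate(names)}
    S = len(names)
    P = np.zeros((n_cycles, S, S))
    costs = np.zeros(S)
    utils = np.zeros(S)
    for spec in states:
        i = idx[spec.name]
        costs[i] = spec.cost_per_cycle
        utils[i] = spec.utility
        if spec.name in absorbing:
            if spec.exits or spec.residual is not None:
                raise ValueError(f"absorbing state {spec.name!r} cannot have exits")
            if spec.cost_per_cycle != 0.0 or spec.utility != 0.0:
                raise ValueError(f"absorbing state {spec.name!r} must have zero rewards")
            P[:, i, i] = 1.0
            continue
        if spec.exits:
            dests = list(spec.exits)
            raw = np.vstack([np.broadcast_to(np.asarray(spec.exits[d], dtype=float),
                                             (n_cycles,)) for d in dests])
            adj = _combine_competing_risks_vec(raw)
            for d, row in zip(dests, adj):
                if d not in idx:
                    raise ValueError(f"unknown destination {d!r} from {spec.name!r}")
                P[:, i, idx[d]] += row
        stay = 1.0 - P[:, i, :].sum(axis=1)
        if np.any(stay < -_ROW_TOL):
            raise ValueError(f"exit probabilities from {spec.name!r} exceed 1")
        res = idx[spec.residual] if spec.residual is not None else i
        P[:, i, res] += np.clip(stay, 0.0, None)
    row_sums = P.sum(axis=2)
    if not np.allclose(row_sums, 1.0, atol=_ROW_TOL):
        raise ValueError("transition rows do not sum to 1")
    return MarkovModel(states=tuple(names), transition=P, cost_per_cycle=costs,
                       utility=utils, absorbing=absorbing,
                       initial_state=initial_state, n_cycles=n_cycles)


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle; row 0 is the initial cohort."""

    states: tuple[str, ...]
    occupancy: np.ndarray  # (n_cycles + 1, S)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def column(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def final(self, state: str) -> float:
        return float(self.occupancy[-1, self.states.index(state)])


@dataclass(frozen=True)
class RewardTotals:
    """Accumulated outcomes for one strategy run."""

    total_cost: float   # discounted dollars
    total_qaly: float   # discounted, half-cycle-corrected QALYs
    total_ly: float     # undiscounted life-years


def run_cohort(model: MarkovModel, n_cycles: int | None = None) -> CohortTrace:
    """Propagate the cohort through the transition tensor.

    Deterministic: row ``t+1`` of the trace is row ``t`` multiplied by the
    cycle-``t`` transition matrix.
    """
    T = model.n_cycles if n_cycles is None else n_cycles
    if T > model.n_cycles:
        raise ValueError("n_cycles exceeds the model's transition horizon")
    S = len(model.states)
    occ = np.empty((T + 1, S))
    occ[0] = 0.0
    occ[0, model.index(model.initial_state)] = 1.0
    v = occ[0]
    for t in range(T):
        v = v @ model.transition[t]
        occ[t + 1] = v
    return CohortTrace(states=model.states, occupancy=occ)


def discount_factor(cycle_index, annual_rate: float,
                    cycles_per_year: int = CYCLES_PER_YEAR):
    """Discount factor ``(1 + r)**(-t / cycles_per_year)`` at cycle ``t``."""
    if annual_rate < 0:
        raise ValueError("annual discount rate must be non-negative")
    t = np.asarray(cycle_index, dtype=float)
    out = (1.0 + annual_rate) ** (-t / cycles_per_year)
    return float(out) if np.isscalar(cycle_index) else out


def accumulate_rewards(trace: CohortTrace, model: MarkovModel,
                       annual_rate: float,
                       half_cycle_correction: bool = True) -> RewardTotals:
    """Accumulate discounted costs and QALYs and undiscounted life-years.

    Costs accrue on start-of-cycle occupancy (no half-cycle correction:
    a month's drug is dispensed to those alive at the start of the month).
    QALYs and life-years use the trapezoid of consecutive occupancy rows,
    the standard correction for transitions occurring mid-cycle; disable
    via ``half_cycle_correction`` for convention comparisons.
    """
    if trace.states != model.states:
        raise ValueError("trace and model state spaces differ")
    occ = trace.occupancy
    T = trace.n_cycles
    df = discount_factor(np.arange(T), annual_rate)
    cost = float(df @ (occ[:-1] @ model.cost_per_cycle))
    occ_eff = 0.5 * (occ[:-1] + occ[1:]) if half_cycle_correction else occ[:-1]
    qaly = float(df @ (occ_eff @ (model.utility / CYCLES_PER_YEAR)))
    alive = 1.0 - occ[:, model.absorbing_mask].sum(axis=1)
    alive_eff = 0.5 * (alive[:-1] + alive[1:]) if half_cycle_correction else alive[:-1]
    ly = float(alive_eff.sum() / CYCLES_PER_YEAR)
    return RewardTotals(total_cost=cost, total_qaly=qaly, total_ly=ly)


def microsim_oracle(model: MarkovModel, n_individuals: int, seed: int,
                    annual_rate: float,
                    half_cycle_correction: bool = True):
    """Individual-level simulation of the same model: a validation oracle.

    Simulates ``n_individuals`` trajectories with categorical draws from
    the identical per-cycle transition probabilities and accumulates the
    same rewards as :func:`accumulate_rewards`. Returns
    ``(RewardTotals of means, dict of standard errors)``. The cohort trace
    is the exact expectation of this process, so the two must agree within
    Monte Carlo error.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    S = len(model.states)
    T = model.n_cycles
    df = discount_factor(np.arange(T), annual_rate)
    u_year = model.utility / CYCLES_PER_YEAR
    alive_w = (~model.absorbing_mask).astype(float)
    cum = np.cumsum(model.transition, axis=2)
    state = np.full(n_individuals, model.index(model.initial_state))
    cost = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)
    ly = np.zeros(n_individuals)
    for t in range(T):
        cost += df[t] * model.cost_per_cycle[state]
        draws = rng.random(n_individuals)
        nxt = (draws[:, None] > cum[t][state]).sum(axis=1)
        if half_cycle_correction:
            qaly += df[t] * 0.5 * (u_year[state] + u_year[nxt])
            ly += 0.5 * (alive_w[state] + alive_w[nxt]) / CYCLES_PER_YEAR
        else:
            qaly += df[t] * u_year[state]
            ly += alive_w[state] / CYCLES_PER_YEAR
        state = nxt
    totals = RewardTotals(total_cost=float(cost.mean()),
                          total_qaly=float(qaly.mean()),
                          total_ly=float(ly.mean()))
    n = n_individuals
    se = {"total_cost": float(cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
          "total_qaly": float(qaly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
          "total_ly": float(ly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0}
    return totals, se
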