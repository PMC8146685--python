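"""The two management strategies for metastatic GEP-NETs as Markov models.

Strategy **SSA** starts the somatostatin analogue at diagnosis; strategy
**DELAY** observes and starts the SSA only at first tumour progression.
In both arms a serious drug complication stops the SSA permanently, and
progression (on SSA, or off SSA after a complication) leads to peptide
receptor radionuclide therapy (PRRT), delivered as a four-month tunnel of
treatment cycles with the SSA continued alongside at the escalated
(60 mg) dose. After PRRT no further progression event is modelled; the
cohort remains in a post-PRRT state until NET-related or background
death. The model cycles monthly from the starting age until age 100.

State map (union over both arms; not every state is reachable in each):

``StableUntreated`` (DELAY start) -> progression starts SSA in the same
transition (``ProgressedOnSSA``); ``StableOnSSA`` (SSA start) ->
progression enters the PRRT tunnel, complication moves to
``OffSSAComplication`` (uncontrolled symptoms, no drug) whose progression
enters a parallel no-SSA PRRT tunnel. NET-related and background deaths
are separate absorbing states so the cause-of-death split is observable.
"""

from __future__ import annotations

import numpy as np

from .cea import StrategyOutcome
from .engine import (CohortTrace, MarkovModel, RewardTotals, StateSpec,
                     accumulate_rewards, build_model, run_cohort)
from .lifetable import LifeTable, annual_to_cycle_prob
from .parameters import ParameterSet, median_to_cycle_prob

__all__ = [
    "STRATEGY_LABELS", "STATES", "build_strategy", "net_death_fraction",
    "evaluate_strategy", "background_mortality",
]

STRATEGY_LABELS = ("SSA", "DELAY")

S_STABLE_UNTREATED = "StableUntreated"
S_STABLE_ON_SSA = "StableOnSSA"
S_OFF_SSA_COMPLICATION = "OffSSAComplication"
S_PROGRESSED_ON_SSA = "ProgressedOnSSA"
S_POST_PRRT = "PostPRRT"
S_POST_PRRT_NOSSA = "PostPRRTNoSSA"
S_DEAD_NET = "DeadNET"
S_DEAD_OTHER = "DeadOther"


def _prrt_states(n: int, no_ssa: bool) -> list[str]:
    suffix = "NoSSA" if no_ssa else ""
    return [f"PRRT{k}{suffix}" for k in range(1, n + 1)]


def background_mortality(params: ParameterSet, lt: LifeTable) -> np.ndarray:
    """Per-cycle background death probability for each model cycle.

    The age at cycle ``t`` is ``floor(start_age + t/12)``; the annual
    life-table probability at that age is converted to a monthly one.
    """
    cpy = params.cycles_per_year
    t = np.arange(params.n_cycles)
    ages = np.floor(params.start_age + t / cpy).astype(int)
    return np.array([annual_to_cycle_prob(lt.q_at(a), cpy) for a in ages])


def build_strategy(params: ParameterSet, label: str, lt: LifeTable) -> MarkovModel:
    """Assemble the Markov model for one management strategy.

    Both arms share the same state union and transition structure; only
    the initial state differs (``StableOnSSA`` for SSA, ``StableUntreated``
    for DELAY). All per-state exits — NET death, progression, complication
    and background death — are combined as competing risks within each
    monthly cycle.
    """
    if label not in STRATEGY_LABELS:
        raise ValueError(f"unknown strategy label {label!r}; "
                         f"expected one of {STRATEGY_LABELS}")
    p = params
    n_cycles = p.n_cycles
    p_bg = background_mortality(p, lt)

    p_death_untreated = median_to_cycle_prob(p.median_net_death_untreated)
    p_death_on_ssa = median_to_cycle_prob(p.median_net_death_on_ssa)
    p_death_on_prrt = median_to_cycle_prob(p.median_net_death_on_prrt)
    p_prog_off = median_to_cycle_prob(p.median_progression_off_ssa)
    p_prog_on = median_to_cycle_prob(p.median_progression_on_ssa)
    p_prog_delayed = median_to_cycle_prob(p.median_progression_delayed_ssa)
    p_comp = p.p_complication_cycle

    cost_ssa = p.cost_ssa_month
    cost_ssa_prrt = p.cost_ssa_month * p.ssa_prrt_dose_multiplier
    tunnel = _prrt_states(p.n_prrt_cycles, no_ssa=False)
    tunnel_nossa = _prrt_states(p.n_prrt_cycles, no_ssa=True)

    specs = [
        StateSpec(S_STABLE_UNTREATED, cost_per_cycle=0.0, utility=p.u_pre_ssa,
                  exits={S_DEAD_NET: p_death_untreated,
                         S_PROGRESSED_ON_SSA: p_prog_off,
                         S_DEAD_OTHER: p_bg}),
        StateSpec(S_STABLE_ON_SSA, cost_per_cycle=cost_ssa, utility=p.u_on_ssa,
                  exits={S_DEAD_NET: p_death_on_ssa,
                         tunnel[0]: p_prog_on,
                         S_OFF_SSA_COMPLICATION: p_comp,
                         S_DEAD_OTHER: p_bg}),
        # SSA stopped for toxicity, disease not yet progressed: uncontrolled
        # symptoms, untreated hazards, no drug cost; progression goes to the
        # no-SSA tunnel (the drug cannot be resumed).
        StateSpec(S_OFF_SSA_COMPLICATION, cost_per_cycle=0.0,
                  utility=p.u_uncontrolled,
                  exits={S_DEAD_NET: p_death_untreated,
                         tunnel_nossa[0]: p_prog_off,
                         S_DEAD_OTHER: p_bg}),
        # DELAY arm after first progression: SSA started in the same
        # transition, so hazards and costs are the on-SSA ones but the
        # utility reflects progressed disease.
        StateSpec(S_PROGRESSED_ON_SSA, cost_per_cycle=cost_ssa,
                  utility=p.u_progressed,
                  exits={S_DEAD_NET: p_death_on_ssa,
                         tunnel[0]: p_prog_delayed,
                         tunnel_nossa[0]: p_comp,
                         S_DEAD_OTHER: p_bg}),
    ]
    for chain, ssa_cost, post in ((tunnel, cost_ssa_prrt, S_POST_PRRT),
                                  (tunnel_nossa, 0.0, S_POST_PRRT_NOSSA)):
        for k, name in enumerate(chain):
            nxt = chain[k + 1] if k + 1 < len(chain) else post
            specs.append(StateSpec(name,
                                   cost_per_cycle=p.cost_prrt_cycle + ssa_cost,
                                   utility=p.u_progressed,
                                   exits={S_DEAD_NET: p_death_on_prrt,
                                          S_DEAD_OTHER: p_bg},
                                   residual=nxt))
    specs += [
        StateSpec(S_POST_PRRT, cost_per_cycle=cost_ssa_prrt,
                  utility=p.u_progressed,
                  exits={S_DEAD_NET: p_death_on_prrt, S_DEAD_OTHER: p_bg}),
        StateSpec(S_POST_PRRT_NOSSA, cost_per_cycle=0.0,
                  utility=p.u_progressed,
                  exits={S_DEAD_NET: p_death_on_prrt, S_DEAD_OTHER: p_bg}),
        StateSpec(S_DEAD_NET),
        StateSpec(S_DEAD_OTHER),
    ]
    initial = S_STABLE_ON_SSA if label == "SSA" else S_STABLE_UNTREATED
    return build_model(specs, initial_state=initial,
                       absorbing=(S_DEAD_NET, S_DEAD_OTHER),
                       n_cycles=n_cycles)


STATES = (S_STABLE_UNTREATED, S_STABLE_ON_SSA, S_OFF_SSA_COMPLICATION,
          S_PROGRESSED_ON_SSA, *_prrt_states(4, False), *_prrt_states(4, True),
          S_POST_PRRT, S_POST_PRRT_NOSSA, S_DEAD_NET, S_DEAD_OTHER)


def net_death_fraction(trace: CohortTrace) -> float:
    """Percent of horizon deaths attributable to the tumour.

    ``100 * DeadNET / (DeadNET + DeadOther)`` at the final cycle.
    """
    dn = trace.final(S_DEAD_NET)
    do = trace.final(S_DEAD_OTHER)
    if dn + do <= 0.0:
        raise ValueError("no deaths at the horizon; fraction undefined")
    return 100.0 * dn / (dn + do)


def evaluate_strategy(params: ParameterSet, label: str, lt: LifeTable,
                      half_cycle_correction: bool = True) -> StrategyOutcome:
    """Run one strategy end to end and collect its outcome totals."""
    model = build_strategy(params, label, lt)
    trace = run_cohort(model)
    totals: RewardTotals = accumulate_rewards(
        trace, model, params.discount_annual,
        half_cycle_correction=half_cycle_correction)
    return StrategyOutcome(label=label, cost=totals.total_cost,
                           ly=totals.total_ly, qaly=totals.total_qaly,
                           net_death_pct=net_death_fraction(trace))
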