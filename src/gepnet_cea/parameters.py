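"""Model parameters for the GEP-NET treatment-timing analysis.

:class:`ParameterSet` carries every base-case input of the decision model
— drug and PRRT costs, median times to tumour progression and to
NET-related death under each management state, the serious-complication
rate on somatostatin analogues (SSAs), health-state utilities, the
discount rate and the willingness-to-pay threshold — together with the
one-way sensitivity ranges used by the tornado and probabilistic
analyses.

All clinical event inputs are medians (months); under the model's
constant-hazard assumption they convert to per-monthly-cycle
probabilities via :func:`median_to_cycle_prob`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ParameterSet",
    "median_to_cycle_prob",
    "cycle_prob_to_median",
    "interval_prob_to_cycle_prob",
    "weeks_to_months",
    "load_parameters",
]

WEEKS_PER_YEAR = 52.0
MONTHS_PER_YEAR = 12.0


def weeks_to_months(weeks: float) -> float:
    """Convert weeks to months via the 12-month / 52-week year."""
    return weeks * MONTHS_PER_YEAR / WEEKS_PER_YEAR


def median_to_cycle_prob(median_months: float) -> float:
    """Per-monthly-cycle event probability from a median time-to-event.

    Under an exponential (constant-rate) time-to-event, the monthly
    probability satisfying a median of ``m`` months is
    ``1 - 0.5**(1/m)``.
    """
    if median_months <= 0:
        raise ValueError("median must be positive")
    return 1.0 - 0.5 ** (1.0 / median_months)


def cycle_prob_to_median(p_cycle: float) -> float:
    """Inverse of :func:`median_to_cycle_prob` (median in months)."""
    if not 0.0 < p_cycle < 1.0:
        raise ValueError("per-cycle probability must be in (0, 1)")
    import math
    return math.log(0.5) / math.log(1.0 - p_cycle)


def interval_prob_to_cycle_prob(p_interval: float, interval_months: float) -> float:
    """Per-monthly-cycle probability from a cumulative interval risk.

    E.g. a 1% complication risk over 96 weeks (96 * 12/52 months) becomes
    roughly 4.54e-4 per month.
    """
    if not 0.0 <= p_interval < 1.0:
        raise ValueError("interval probability must be in [0, 1)")
    if interval_months <= 0:
        raise ValueError("interval must be positive")
    return 1.0 - (1.0 - p_interval) ** (1.0 / interval_months)


def _default_sa_ranges() -> dict[str, tuple[float, float]]:
    """One-way sensitivity ranges: medians and the complication rate vary
    +/-25%, utilities +/-0.1 absolute, costs from half to double list price."""
    r = {
        "cost_ssa_month": (2060.0, 8242.0),
        "cost_prrt_cycle": (25650.0, 102600.0),
        "p_complication_interval": (0.0075, 0.0125),
        "median_net_death_untreated": (13.5, 22.5),
        "median_net_death_on_ssa": (29.25, 48.75),
        "median_net_death_on_prrt": (29.25, 48.75),
        "median_progression_off_ssa": (4.5, 7.5),
        "median_progression_on_ssa": (10.5, 17.5),
        "median_progression_delayed_ssa": (10.5, 17.5),
        "u_pre_ssa": (0.69, 0.89),
        "u_on_ssa": (0.69, 0.89),
        "u_progressed": (0.62, 0.82),
        "u_uncontrolled": (0.22, 0.42),
    }
    return r


@dataclass(frozen=True)
class ParameterSet:
    """Base-case inputs and sensitivity ranges of the decision model.

    Costs are 2020 US dollars. ``ssa_prrt_dose_multiplier`` scales the
    monthly SSA drug cost on the PRRT pathway: stable patients receive
    octreotide LAR 20 mg per 28 days, while patients on and after PRRT
    receive 60 mg — three times the dose and hence three times the
    monthly acquisition cost.
    """

    start_age: int = 60
    horizon_age: int = 100
    cycles_per_year: int = 12

    cost_ssa_month: float = 4121.0
    cost_prrt_cycle: float = 51300.0
    n_prrt_cycles: int = 4
    ssa_prrt_dose_multiplier: float = 3.0

    p_complication_interval: float = 0.01
    complication_interval_weeks: float = 96.0

    median_net_death_untreated: float = 18.0
    median_net_death_on_ssa: float = 39.0
    median_net_death_on_prrt: float = 39.0
    median_progression_off_ssa: float = 6.0
    median_progression_on_ssa: float = 14.0
    median_progression_delayed_ssa: float = 14.0

    u_pre_ssa: float = 0.79
    u_on_ssa: float = 0.79
    u_progressed: float = 0.72
    u_uncontrolled: float = 0.32

    discount_annual: float = 0.03
    wtp: float = 100_000.0

    sa_ranges: dict = field(default_factory=_default_sa_ranges)

    def __post_init__(self):
        for name in ("u_pre_ssa", "u_on_ssa", "u_progressed", "u_uncontrolled"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {name} must be in [0, 1], got {u}")
        for name in ("median_net_death_untreated", "median_net_death_on_ssa",
                     "median_net_death_on_prrt", "median_progression_off_ssa",
                     "median_progression_on_ssa", "median_progression_delayed_ssa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cost_ssa_month", "cost_prrt_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_complication_interval <= 1.0:
            raise ValueError("complication probability must be in [0, 1]")
        if self.start_age >= self.horizon_age:
            raise ValueError("start_age must be below horizon_age")
        if self.discount_annual < 0:
            raise ValueError("discount rate must be non-negative")
        object.__setattr__(self, "sa_ranges",
                           {k: tuple(float(x) for x in v)
                            for k, v in self.sa_ranges.items()})

    # -- derived quantities -------------------------------------------------

    @property
    def n_cycles(self) -> int:
        return (self.horizon_age - self.start_age) * self.cycles_per_year

    @property
    def complication_interval_months(self) -> float:
        return weeks_to_months(self.complication_interval_weeks)

    @property
    def p_complication_cycle(self) -> float:
        return interval_prob_to_cycle_prob(self.p_complication_interval,
                                           self.complication_interval_months)

    @property
    def cost_prrt_total(self) -> float:
        return self.cost_prrt_cycle * self.n_prrt_cycles

    # -- manipulation -------------------------------------------------------

    def with_value(self, name: str, value) -> "ParameterSet":
        """Copy with one field replaced (used by sensitivity analyses)."""
        if name not in {f.name for f in dataclasses.fields(self)}:
            raise KeyError(f"unknown parameter {name!r}")
        return dataclasses.replace(self, **{name: value})

    def check_sa_ranges(self) -> None:
        """Verify every sensitivity range brackets its base value."""
        for name, (lo, hi) in self.sa_ranges.items():
            base = getattr(self, name)
            if not lo <= base <= hi:
                raise ValueError(
                    f"sensitivity range ({lo}, {hi}) for {name!r} does not "
                    f"bracket base value {base}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sa_ranges"] = {k: list(v) for k, v in d["sa_ranges"].items()}
        return d


def load_parameters(source=None, overrides: dict | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML/JSON config and overrides.

    ``source`` may be None (all defaults), a path, or a mapping. Keys must
    be ParameterSet field names; omitted keys take the base-case values;
    unknown keys raise. ``overrides`` is applied on top (CLI flags beat
    the file).
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            data = (json.loads(text) if str(source).endswith(".json")
                    else yaml.safe_load(text)) or {}
        elif isinstance(source, dict):
            data = dict(source)
        else:
            raise TypeError("config source must be a path or mapping")
    if overrides:
        data.update(overrides)
    valid = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if "sa_ranges" in data:
        base = _default_sa_ranges()
        base.update({k: tuple(v) for k, v in data["sa_ranges"].items()})
        data["sa_ranges"] = base
    return ParameterSet(**data)
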