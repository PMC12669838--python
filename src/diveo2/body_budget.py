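"""Total-body O2 store budget by dive-duration class.

Assembles the five-compartment budget (arterial and venous blood,
respiratory system, chest muscle, leg muscle): initial store, net
depletion-rate contribution to diving metabolic rate (DMR), and O2
consumed over a representative dive duration.  Budget arithmetic runs
in exact rational arithmetic on the one-decimal printed inputs, so
column totals are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .params import load_params

__all__ = [
    "COMPARTMENTS",
    "BLOOD_COMPARTMENTS",
    "DurationClass",
    "SHORT",
    "LONG",
    "duration_class",
    "CompartmentBudget",
    "BudgetTable",
    "ChestMuscleRate",
    "chest_muscle_rate",
    "build_budget",
    "budget_from_params",
    "percent_remaining",
    "replenishment_rate",
]

COMPARTMENTS = ("arterial", "venous", "respiratory", "muscle_chest", "muscle_legs")
BLOOD_COMPARTMENTS = ("arterial", "venous")


@dataclass(frozen=True)
class DurationClass:
    label: str                      # "short" (5-6 min) or "long" (10-12 min)
    representative_duration: float  # min

    def __post_init__(self) -> None:
        if self.representative_duration <= 0:
            raise ValueError("duration must be positive")


SHORT = DurationClass("short", 6.0)
LONG = DurationClass("long", 10.0)


def duration_class(label: str) -> DurationClass:
    try:
        return {"short": SHORT, "long": LONG}[label]
    except KeyError:
        raise ValueError(f"unknown duration class {label!r}") from None


@dataclass(frozen=True)
class CompartmentBudget:
    name: str
    initial: float    # ml O2 kg-1
    dmr_rate: float   # ml O2 kg-1 min-1
    consumed: float   # ml O2 kg-1 over the representative duration


@dataclass(frozen=True)
class BudgetTable:
    cls: DurationClass
    rows: tuple[CompartmentBudget, ...]
    total_initial: float
    total_rate: float
    total_consumed: float

    def row(self, name: str) -> CompartmentBudget:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass(frozen=True)
class ChestMuscleRate:
    """Chest-muscle depletion rate with its derivation bookkeeping.

    ``derived_rate`` is store size x myoglobin desaturation rate;
    ``rate`` is the literature's stated value; ``calibration`` is their
    ratio, reported so any residual (muscle-mass or Mb-concentration
    terms folded into the stated value) stays visible.
    """

    rate: float
    derived_rate: float
    calibration: float


def chest_muscle_rate(
    cls: DurationClass, mb_params: Mapping | None = None
) -> ChestMuscleRate:
    """Chest-muscle O2 depletion rate (ml O2 kg-1 min-1) for a class."""
    mb = mb_params or load_params()["myoglobin"]
    if cls.label not in mb["desat_rate_pct_min"]:
        raise ValueError(f"unknown duration class {cls.label!r}")
    store = float(mb["chest_store_ml_kg"])
    derived = store * float(mb["desat_rate_pct_min"][cls.label]) / 100.0
    stated = float(mb["stated_chest_rate"][cls.label])
    return ChestMuscleRate(rate=stated, derived_rate=derived, calibration=stated / derived)


def _frac(x: float) -> Fraction:
    # printed inputs carry <= 1 decimal; rationalize to keep sums exact
    return Fraction(x).limit_denominator(10**6)


def build_budget(
    cls: DurationClass, compartments: Mapping[str, tuple[float, float]]
) -> BudgetTable:
    """Assemble the per-compartment budget and its column totals.

    ``compartments`` maps each of the five compartment names to
    ``(initial store, dmr_rate)``.  Consumed O2 per compartment is
    rate x representative duration; totals are column sums, computed
    exactly.  A compartment consuming more than its initial store is an
    inconsistency and raises, except for the chest muscle, where the
    myoglobin store need not fully deplete and overshoot is only warned
    about (never silently clamped).
    """
    missing = set(COMPARTMENTS) - set(compartments)
    if missing:
        raise ValueError(f"missing compartments: {sorted(missing)}")
    dur = _frac(cls.representative_duration)
    rows = []
    tot_init = tot_rate = tot_cons = Fraction(0)
    for name in COMPARTMENTS:
        initial, rate = (_frac(v) for v in compartments[name])
        consumed = rate * dur
        if consumed > initial:
            msg = (f"{name}: consumed {float(consumed):.2f} exceeds initial "
                   f"{float(initial):.2f} ml O2 kg-1")
            if name == "muscle_chest":
                warnings.warn(msg, UserWarning, stacklevel=2)
            else:
                raise ValueError(msg)
        rows.append(
            CompartmentBudget(name, float(initial), float(rate), float(consumed))
        )
        tot_init += initial
        tot_rate += rate
        tot_cons += consumed
    return BudgetTable(
        cls=cls,
        rows=tuple(rows),
        total_initial=float(tot_init),
        total_rate=float(tot_rate),
        total_consumed=float(tot_cons),
    )


def budget_from_params(cls: DurationClass, params: Mapping | None = None) -> BudgetTable:
    """Budget built from the printed per-compartment inputs on file."""
    p = params or load_params()
    entry = p["budget"][cls.label]
    comps = {
        name: (spec["initial"], spec["rate"])
        for name, spec in entry["compartments"].items()
    }
    return build_budget(cls, comps)


def percent_remaining(budget: BudgetTable, scope: str = "total") -> float:
    """Percentage of the scoped initial store left after the dive.

    ``scope`` is ``"total"`` (all five compartments) or ``"blood"``
    (arterial + venous only).
    """
    if scope == "total":
        names = COMPARTMENTS
    elif scope == "blood":
        names = BLOOD_COMPARTMENTS
    else:
        raise ValueError(f"unknown scope {scope!r}")
    initial = sum(_frac(budget.row(n).initial) for n in names)
    consumed = sum(_frac(budget.row(n).consumed) for n in names)
    if initial == 0:
        raise ZeroDivisionError("scoped initial store is zero")
    return float(100 * (initial - consumed) / initial)


def replenishment_rate(deficit: float, window: float) -> float:
    """Mean O2 uptake rate (ml O2 kg-1 min-1) to repay ``deficit`` in
    ``window`` minutes."""
    if window <= 0:
        raise ValueError("window must be positive")
    return deficit / window
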