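"""Blood O2 content, compartment stores, depletion rates and summaries.

Total O2 content of whole blood (ml O2 dl-1) is

    content = sat * o2_capacity * hb_conc + solubility * PO2,

i.e. Hb-bound plus dissolved O2.  Compartment stores scale content by
blood volume and the arterial/venous volume fractions; net depletion of
a store over a dive divided by dive duration gives that store's
contribution to the diving metabolic rate (DMR).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .oxy_dissociation import BohrModel, curve_at_ph, hb_saturation
from .params import load_params

__all__ = [
    "BloodConstants",
    "StoreResult",
    "o2_content",
    "compartment_store",
    "store_result",
    "summarize_stores",
    "percent_increase",
    "paired_comparison",
    "PairedComparison",
    "read_endpoints_csv",
]


@dataclass(frozen=True)
class BloodConstants:
    """Constants of the blood O2 content/store formulas.

    Defaults come from the package parameter file; the arterial and
    venous volume fractions must sum to 1.
    """

    hb_conc: float = 18.3            # g Hb per dl blood
    o2_capacity: float = 1.34        # ml O2 per g Hb
    solubility: float = 0.003        # ml O2 per dl per mmHg
    blood_volume: float = 100.0      # ml blood per kg body mass
    arterial_fraction: float = 0.33
    venous_fraction: float = 0.67

    def __post_init__(self) -> None:
        vals = (
            self.hb_conc,
            self.o2_capacity,
            self.solubility,
            self.blood_volume,
            self.arterial_fraction,
            self.venous_fraction,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all blood constants must be positive")
        if abs(self.arterial_fraction + self.venous_fraction - 1.0) > 1e-9:
            raise ValueError("arterial and venous fractions must sum to 1.00")

    @classmethod
    def from_params(cls) -> "BloodConstants":
        b = load_params()["blood"]
        return cls(
            hb_conc=b["hb_conc_g_dl"],
            o2_capacity=b["o2_capacity_ml_g"],
            solubility=b["solubility_ml_dl_mmhg"],
            blood_volume=b["blood_volume_ml_kg"],
            arterial_fraction=b["arterial_fraction"],
            venous_fraction=b["venous_fraction"],
        )


@dataclass(frozen=True)
class StoreResult:
    """Per-dive O2 store bookkeeping for one blood compartment.

    Negative net depletion (repletion) is preserved, never clamped.
    """

    dive_id: str
    site: str
    ph_final: float
    initial: float          # ml O2 kg-1
    final: float            # ml O2 kg-1
    net_depletion: float    # ml O2 kg-1
    pct_net_depletion: float
    dmr_contribution: float  # ml O2 kg-1 min-1
    duration_min: float


def o2_content(sat: float, po2: float, constants: BloodConstants | None = None) -> float:
    """Total blood O2 content (ml O2 dl-1) at the given saturation and PO2."""
    c = constants or BloodConstants()
    if not 0.0 <= sat <= 1.0:
        raise ValueError(f"sat must lie in [0, 1], got {sat}")
    if po2 < 0:
        raise ValueError("po2 must be non-negative")
    return sat * c.o2_capacity * c.hb_conc + c.solubility * po2


def compartment_store(
    content: float, site: str, constants: BloodConstants | None = None
) -> float:
    """Mass-specific store (ml O2 kg-1) of one blood compartment."""
    c = constants or BloodConstants()
    if content < 0:
        raise ValueError("content must be non-negative")
    if site == "arterial":
        frac = c.arterial_fraction
    elif site == "venous":
        frac = c.venous_fraction
    else:
        raise ValueError(f"unknown site {site!r}")
    return content * (c.blood_volume / 100.0) * frac


def store_result(
    initial_state: tuple[float, float],
    final_state: tuple[float, float],
    site: str,
    duration_min: float,
    bohr: BohrModel | None = None,
    constants: BloodConstants | None = None,
    hill_n: float | None = None,
    dive_id: str = "",
) -> StoreResult:
    """O2 store accounting for one dive from (PO2, pH) endpoint states.

    Saturation at each endpoint is evaluated on the dissociation curve
    for that endpoint's pH (initial conventionally at resting pH 7.5,
    final at the caller's end-of-dive pH); dissolved O2 uses the
    endpoint's own PO2.  ``dmr_contribution = net_depletion / duration``.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    c = constants or BloodConstants()
    stores = []
    for po2, ph in (initial_state, final_state):
        sat = hb_saturation(po2, curve_at_ph(ph, bohr, hill_n))
        stores.append(compartment_store(o2_content(sat, po2, c), site, c))
    initial, final = stores
    net = initial - final
    return StoreResult(
        dive_id=dive_id,
        site=site,
        ph_final=final_state[1],
        initial=initial,
        final=final,
        net_depletion=net,
        pct_net_depletion=100.0 * net / initial if initial > 0 else float("nan"),
        dmr_contribution=net / duration_min,
        duration_min=duration_min,
    )


_METRICS = ["initial", "final", "net_depletion", "pct_net_depletion", "dmr_contribution"]
_STATS = ["median", "max", "min", "q25", "q75"]


def summarize_stores(results: Sequence[StoreResult]) -> pd.DataFrame:
    """Distributional summary of store results, per site and final pH.

    Returns a long-format frame with columns ``site``, ``ph_final``,
    ``metric`` and one column per statistic (median, max, min, 25% and
    75% quartiles, linear interpolation between order statistics).
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame([r.__dict__ for r in results])
    rows = []
    for (site, ph), grp in df.groupby(["site", "ph_final"], sort=True):
        for metric in _METRICS:
            v = grp[metric].to_numpy()
            rows.append(
                {
                    "site": site,
                    "ph_final": ph,
                    "metric": metric,
                    "median": float(np.median(v)),
                    "max": float(np.max(v)),
                    "min": float(np.min(v)),
                    "q25": float(np.quantile(v, 0.25)),
                    "q75": float(np.quantile(v, 0.75)),
                }
            )
    return pd.DataFrame(rows)


def percent_increase(new: float, old: float) -> float:
    """100 * (new - old) / old."""
    if old == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (new - old) / old


@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    pvalue: float
    n: int
    undefined: bool = False


def paired_comparison(
    values_a: Sequence[float], values_b: Sequence[float]
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired values.

    If every paired difference is zero the test statistic is undefined
    and the result is flagged rather than raising.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(a == b):
        return PairedComparison(float("nan"), float("nan"), a.size, undefined=True)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return PairedComparison(float(res.statistic), float(res.pvalue), a.size)


def read_endpoints_csv(path: str | Path) -> pd.DataFrame:
    """Read a dive-endpoint CSV: dive_id, site, duration_min,
    po2_start_mmHg, po2_end_mmHg."""
    df = pd.read_csv(path)
    required = {"dive_id", "site", "duration_min", "po2_start_mmHg", "po2_end_mmHg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return df
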