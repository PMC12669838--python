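"""Blood-chemistry panels: pH vs PCO2/lactate regression and pH bounds.

Implements the sample-partitioning rules (lactate split at
1.5 mmol l-1, PCO2 filter for the lactate regression), random-intercept
regressions of pH on a single predictor with marginal/conditional r2, a
candidate-model AIC comparison, and the exclusion-then-floor rule that
selects the lower blood-pH bound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .params import load_params

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "Condition",
    "BloodSample",
    "PhModelFit",
    "NoBoundError",
    "partition_samples",
    "lactate_regression_subset",
    "fit_random_intercept",
    "fit_candidates",
    "select_simplest",
    "select_ph_lower_bound",
    "resting_ph_summary",
    "read_samples_csv",
    "write_samples_csv",
]


class Site(str, Enum):
    ARTERIAL = "arterial"
    VENOUS = "venous"


class Condition(str, Enum):
    REST = "rest"
    DIVE = "dive"
    ANESTHESIA = "anesthesia"
    RESTRAINT = "restraint"


@dataclass(frozen=True)
class BloodSample:
    """One blood-gas/lactate measurement."""

    penguin_id: str
    ph: float
    pco2: float
    po2: float
    lactate: float
    body_mass: float
    site: Site
    condition: Condition
    year: int | None = None

    def __post_init__(self) -> None:
        if not 6.5 < self.ph < 8.0:
            raise ValueError(f"ph {self.ph} outside plausible range (6.5, 8.0)")
        if not self.pco2 > 0:
            raise ValueError("pco2 must be positive")
        if self.lactate < 0:
            raise ValueError("lactate must be non-negative")
        object.__setattr__(self, "site", Site(self.site))
        object.__setattr__(self, "condition", Condition(self.condition))


@dataclass(frozen=True)
class PhModelFit:
    """Result of a (random-intercept) regression of pH on one predictor."""

    predictor: str
    slope: float
    intercept: float
    slope_se: float
    penguin_intercepts: dict[str, float]
    var_fixed: float
    var_random: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    aic: float
    n_obs: int
    n_groups: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if min(self.var_fixed, self.var_random, self.var_residual) < 0:
            raise ValueError("variance components must be non-negative")
        if not self.r2_marginal <= self.r2_conditional + 1e-12:
            raise ValueError("r2_marginal must not exceed r2_conditional")

    def confint(self, z: float = 1.96) -> tuple[float, float]:
        return self.slope - z * self.slope_se, self.slope + z * self.slope_se


class NoBoundError(ValueError):
    """Raised when the exclusion rules leave no sample to bound pH with."""


def _thresholds() -> dict:
    return load_params()["thresholds"]


def partition_samples(
    samples: Sequence[BloodSample],
) -> tuple[list[BloodSample], list[BloodSample]]:
    """Split samples at the resting lactate criterion (1.5 mmol l-1).

    Returns ``(dive_group, surface_group)``: the low-lactate group
    pertains to pH during dives, the high-lactate group to surface
    intervals.  Samples at exactly the threshold go to the dive group
    (logged; tie handling is a package choice).
    """
    split = _thresholds()["lactate_split_mmol_l"]
    dive_group, surface_group = [], []
    for s in samples:
        if s.lactate < split:
            dive_group.append(s)
        elif s.lactate == split:
            logger.info("sample %s lactate exactly %.1f -> dive group", s.penguin_id, split)
            dive_group.append(s)
        else:
            surface_group.append(s)
    return dive_group, surface_group


def lactate_regression_subset(surface_group: Iterable[BloodSample]) -> list[BloodSample]:
    """Surface-group samples eligible for the lactate regression.

    High-PCO2 samples are removed so that the lactate effect on pH is
    not confounded by respiratory acidosis (cutoff 70 mmHg).
    """
    cutoff = _thresholds()["lactate_reg_pco2_max_mmhg"]
    return [s for s in surface_group if s.pco2 < cutoff]


def _to_frame(samples: Sequence[BloodSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "penguin_id": [s.penguin_id for s in samples],
            "ph": [s.ph for s in samples],
            "pco2": [s.pco2 for s in samples],
            "po2": [s.po2 for s in samples],
            "lactate": [s.lactate for s in samples],
            "body_mass": [s.body_mass for s in samples],
            "site": [s.site.value for s in samples],
            "condition": [s.condition.value for s in samples],
        }
    )


def fit_random_intercept(
    samples: Sequence[BloodSample], predictor: str
) -> PhModelFit:
    """Fit ``ph = intercept + slope*predictor + penguin offset + noise``.

    ``predictor`` is ``"pco2"`` or ``"lactate"``.  Estimation is REML via
    a linear mixed model with a random intercept per penguin; marginal
    and conditional r2 follow the variance-partition definitions
    (fixed / total and fixed+random / total).  With a single penguin the
    random intercept is unidentifiable: the fit falls back to ordinary
    least squares with ``var_random = 0`` and a warning.
    """
    if predictor not in ("pco2", "lactate"):
        raise ValueError(f"unknown predictor {predictor!r}")
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    df = _to_frame(samples)
    x = df[predictor].to_numpy()
    y = df["ph"].to_numpy()
    groups = df["penguin_id"].to_numpy()
    n_groups = df["penguin_id"].nunique()

    # perfect linear fit (noise-free synthetic data): return it exactly,
    # mixed-model optimizers are ill-posed at zero residual variance
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    if np.max(np.abs(ols.resid)) < 1e-10:
        return _fit_from_ols(ols, x, predictor, groups, degenerate=False)

    if n_groups < 2:
        warnings.warn(
            "single penguin: random intercept unidentifiable, using OLS",
            UserWarning,
            stacklevel=2,
        )
        return _fit_from_ols(ols, x, predictor, groups, degenerate=True)

    res = _fit_mixed(sm.MixedLM(y, X, groups=groups), reml=True)
    fe = np.asarray(res.fe_params, dtype=float)
    slope = float(fe[1])
    intercept = float(fe[0])
    var_random = float(np.asarray(res.cov_re)[0, 0])
    var_residual = float(res.scale)
    var_fixed = float(np.var(intercept + slope * x, ddof=1))
    denom = var_fixed + var_random + var_residual
    ranef = {str(k): float(np.asarray(v).ravel()[0]) for k, v in res.random_effects.items()}
    return PhModelFit(
        predictor=predictor,
        slope=slope,
        intercept=intercept,
        slope_se=float(np.asarray(res.bse_fe, dtype=float)[1]),
        penguin_intercepts=ranef,
        var_fixed=var_fixed,
        var_random=var_random,
        var_residual=var_residual,
        r2_marginal=var_fixed / denom if denom > 0 else 1.0,
        r2_conditional=(var_fixed + var_random) / denom if denom > 0 else 1.0,
        aic=float(res.aic) if res.aic is not None else float("nan"),
        n_obs=len(samples),
        n_groups=n_groups,
    )


def _fit_from_ols(ols, x, predictor, groups, degenerate: bool) -> PhModelFit:
    slope = float(ols.params[1])
    intercept = float(ols.params[0])
    var_fixed = float(np.var(intercept + slope * x, ddof=1))
    var_residual = float(max(ols.scale, 0.0))
    denom = var_fixed + var_residual
    return PhModelFit(
        predictor=predictor,
        slope=slope,
        intercept=intercept,
        slope_se=float(ols.bse[1]),
        penguin_intercepts={str(g): 0.0 for g in np.unique(groups)},
        var_fixed=var_fixed,
        var_random=0.0,
        var_residual=var_residual,
        r2_marginal=var_fixed / denom if denom > 0 else 1.0,
        r2_conditional=var_fixed / denom if denom > 0 else 1.0,
        aic=float(ols.aic),
        n_obs=len(x),
        n_groups=len(np.unique(groups)),
        degenerate=degenerate,
    )


def _fit_mixed(model, reml: bool):
    """Fit a MixedLM, cycling optimizers: variance components near the
    boundary can give a singular Hessian under a single method."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg", "bfgs"):
            try:
                return model.fit(reml=reml, method=method)
            except np.linalg.LinAlgError:
                continue
    raise RuntimeError("mixed model failed to converge under all optimizers")


_FORMULA_TERMS = {
    "pco2": "pco2",
    "lactate": "lactate",
    "po2": "po2",
    "body_mass": "body_mass",
    "condition": "C(condition, Treatment('rest'))",
    "site": "C(site)",
}


def fit_candidates(
    samples: Sequence[BloodSample],
    candidate_sets: Sequence[tuple[str, ...]],
) -> list[tuple[tuple[str, ...], float]]:
    """Fit each candidate fixed-effect set by ML and return its AIC.

    Candidate terms are drawn from pco2, lactate, po2, body_mass,
    condition, site; condition uses rest as the reference level.  Fits
    use maximum likelihood so AIC values are comparable.
    """
    df = _to_frame(samples)
    out = []
    for terms in candidate_sets:
        rhs = " + ".join(_FORMULA_TERMS[t] for t in terms) if terms else "1"
        model = smf.mixedlm(f"ph ~ {rhs}", data=df, groups=df["penguin_id"])
        res = _fit_mixed(model, reml=False)
        out.append((tuple(terms), float(res.aic)))
    return out


def select_simplest(
    fits: Sequence[tuple[tuple[str, ...], float]], delta: float = 2.0
) -> tuple[str, ...]:
    """AIC selection rule: among models within ``delta`` of the minimum
    AIC, pick the one with the fewest terms (ties broken by lower AIC)."""
    if not fits:
        raise ValueError("no candidate fits")
    best_aic = min(aic for _, aic in fits)
    eligible = [(terms, aic) for terms, aic in fits if aic - best_aic < delta]
    return min(eligible, key=lambda ta: (len(ta[0]), ta[1]))[0]


def _round_half_down(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_DOWN))


def _retained(group: Iterable[BloodSample]) -> list[BloodSample]:
    th = _thresholds()
    keep = []
    for s in group:
        if s.pco2 >= th["pco2_exclude_mmhg"]:
            continue  # implausible in an awake or diving animal
        if s.condition is Condition.ANESTHESIA and s.pco2 > th["anesthesia_pco2_exclude_mmhg"]:
            continue
        keep.append(s)
    return keep


def select_ph_lower_bound(
    dive_group: Sequence[BloodSample], surface_group: Sequence[BloodSample]
) -> float:
    """Lower blood-pH bound from the two sample groups.

    Applies the exclusion rules (PCO2 >= 93 mmHg anywhere; anesthesia
    samples with PCO2 > 70 mmHg), takes the minimum retained pH in each
    group, rounds to the 0.1 grid (half rounds down) and returns the
    smaller of the two group bounds.
    """
    if not dive_group or not surface_group:
        raise ValueError("both groups must be non-empty")
    bounds = []
    for group in (dive_group, surface_group):
        kept = _retained(group)
        if kept:
            bounds.append(_round_half_down(min(s.ph for s in kept)))
    if not bounds:
        raise NoBoundError("exclusion rules removed every sample")
    return min(bounds)


def resting_ph_summary(samples: Sequence[BloodSample]) -> tuple[float, float]:
    """Mean and s.d. of pH over samples taken at rest."""
    resting = [s.ph for s in samples if s.condition is Condition.REST]
    if not resting:
        raise ValueError("no resting samples")
    mean = float(np.mean(resting))
    sd = float(np.std(resting, ddof=1)) if len(resting) > 1 else 0.0
    return mean, sd


_CSV_COLUMNS = [
    "penguin_id",
    "year",
    "mass_kg",
    "site",
    "condition",
    "ph",
    "pco2_mmHg",
    "po2_mmHg",
    "lactate_mmol_l",
]


def read_samples_csv(path: str | Path) -> list[BloodSample]:
    """Read a blood-sample panel CSV (one header row, empty = missing)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            BloodSample(
                penguin_id=str(row.penguin_id),
                ph=float(row.ph),
                pco2=float(row.pco2_mmHg),
                po2=float(row.po2_mmHg),
                lactate=float(row.lactate_mmol_l),
                body_mass=float(row.mass_kg),
                site=Site(row.site),
                condition=Condition(row.condition),
                year=int(row.year) if not pd.isna(row.year) else None,
            )
        )
    return out


def write_samples_csv(samples: Sequence[BloodSample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "penguin_id": [s.penguin_id for s in samples],
            "year": [s.year for s in samples],
            "mass_kg": [s.body_mass for s in samples],
            "site": [s.site.value for s in samples],
            "condition": [s.condition.value for s in samples],
            "ph": [s.ph for s in samples],
            "pco2_mmHg": [s.pco2 for s in samples],
            "po2_mmHg": [s.po2 for s in samples],
            "lactate_mmol_l": [s.lactate for s in samples],
        }
    )
    df.to_csv(path, index=False)
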