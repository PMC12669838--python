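"""O2–hemoglobin dissociation curves and the Bohr shift.

A :class:`DissociationCurve` is a Hill-form saturation model,

.. math::

    S(P) = \\frac{P^n}{P^n + P_{50}^n},

parameterised by the half-saturation pressure ``p50`` and the
cooperativity exponent ``hill_n``.  A :class:`BohrModel` maps blood pH to
``p50`` by log-linear interpolation through a set of (pH, P50) anchor
points, with extrapolation along the fitted Bohr slope
``d(log10 P50)/d(pH)``.

The low-affinity comparison curve of the giant fulmar is shipped as a
named built-in (:func:`fulmar_curve`); its constants come from a
published Hill-plot fit ``log10[S/(1-S)] = n*log10(P) - b`` so that
``P50 = 10**(b/n)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .params import load_params

logger = logging.getLogger(__name__)

__all__ = [
    "DissociationCurve",
    "BohrModel",
    "hb_saturation",
    "po2_at_saturation",
    "p50_at_ph",
    "curve_at_ph",
    "saturation_difference",
    "emperor_bohr_model",
    "default_hill_n",
    "fulmar_curve",
    "curve_from_config",
]


@dataclass(frozen=True)
class DissociationCurve:
    """Hill-form O2–Hb dissociation curve.

    Attributes
    ----------
    p50:
        PO2 (mmHg) at 50% Hb saturation.  Lower values mean higher
        O2 affinity.
    hill_n:
        Dimensionless cooperativity exponent (> 0).
    label:
        Free-text description, e.g. ``"emperor pH 7.3"``.
    """

    p50: float
    hill_n: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.p50 > 0:
            raise ValueError(f"p50 must be positive, got {self.p50}")
        if not self.hill_n > 0:
            raise ValueError(f"hill_n must be positive, got {self.hill_n}")


@dataclass(frozen=True)
class BohrModel:
    """pH -> P50 mapping built from anchor points.

    Anchors are stored sorted by increasing pH; P50 must strictly
    decrease as pH increases (affinity rises with alkalinity).  The Bohr
    slope ``d(log10 P50)/d(pH)`` is fitted to all anchors by ordinary
    least squares unless supplied explicitly.
    """

    anchors: tuple[tuple[float, float], ...]
    bohr_slope: float = field(default=math.nan)

    def __post_init__(self) -> None:
        anchors = tuple(sorted((float(ph), float(p50)) for ph, p50 in self.anchors))
        if len(anchors) < 2:
            raise ValueError("BohrModel requires at least 2 anchors")
        phs = np.array([a[0] for a in anchors])
        p50s = np.array([a[1] for a in anchors])
        if np.any(p50s <= 0):
            raise ValueError("anchor P50 values must be positive")
        if len(np.unique(phs)) != len(phs):
            raise ValueError("anchor pH values must be distinct")
        if not np.all(np.diff(p50s) < 0):
            raise ValueError("anchor P50 must strictly decrease with pH")
        object.__setattr__(self, "anchors", anchors)
        if math.isnan(self.bohr_slope):
            object.__setattr__(self, "bohr_slope", _ls_slope(phs, np.log10(p50s)))
        if not self.bohr_slope < 0:
            raise ValueError("bohr_slope must be negative")

    @property
    def ph_min(self) -> float:
        return self.anchors[0][0]

    @property
    def ph_max(self) -> float:
        return self.anchors[-1][0]


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    # closed-form least squares; independent of np.polyfit for testability
    xm = x - x.mean()
    return float((xm * (y - y.mean())).sum() / (xm * xm).sum())


def hb_saturation(po2, curve: DissociationCurve):
    """Hb saturation (fraction in [0, 1]) at partial pressure ``po2``.

    Accepts a scalar or array-like PO2 in mmHg; negative values raise
    ``ValueError``.  Strictly increasing in ``po2`` with
    ``S(p50) = 0.5`` exactly and ``S(0) = 0``.
    """
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("po2 must be non-negative")
    pn = p**curve.hill_n
    sat = pn / (pn + curve.p50**curve.hill_n)
    if np.ndim(po2) == 0:
        return float(sat)
    return sat


def po2_at_saturation(sat: float, curve: DissociationCurve) -> float:
    """Exact inverse of :func:`hb_saturation` for ``0 < sat < 1`` (mmHg)."""
    if not 0.0 < sat < 1.0:
        raise ValueError(f"sat must be in (0, 1), got {sat}")
    return curve.p50 * (sat / (1.0 - sat)) ** (1.0 / curve.hill_n)


def p50_at_ph(ph: float, model: BohrModel | None = None) -> float:
    """P50 (mmHg) at ``ph`` under a Bohr model.

    Inside the anchor range, log10(P50) is interpolated linearly in pH
    (anchor values are reproduced exactly); outside the range,
    extrapolation follows the fitted Bohr slope and is limited to 0.2 pH
    units beyond the anchors (logged, since it is outside the evidence).
    """
    model = emperor_bohr_model() if model is None else model
    lo, hi = model.ph_min - 0.2, model.ph_max + 0.2
    if not lo <= ph <= hi:
        raise ValueError(f"ph {ph} outside supported range [{lo:.2f}, {hi:.2f}]")
    phs = np.array([a[0] for a in model.anchors])
    logs = np.log10([a[1] for a in model.anchors])
    if ph < model.ph_min:
        logger.warning("extrapolating P50 below pH %.2f anchor (pH=%.2f)", model.ph_min, ph)
        return float(10 ** (logs[0] + model.bohr_slope * (ph - phs[0])))
    if ph > model.ph_max:
        logger.warning("extrapolating P50 above pH %.2f anchor (pH=%.2f)", model.ph_max, ph)
        return float(10 ** (logs[-1] + model.bohr_slope * (ph - phs[-1])))
    return float(10 ** np.interp(ph, phs, logs))


def curve_at_ph(
    ph: float,
    model: BohrModel | None = None,
    hill_n: float | None = None,
    label: str | None = None,
) -> DissociationCurve:
    """Dissociation curve at blood pH ``ph`` under a Bohr model."""
    if hill_n is None:
        hill_n = default_hill_n()
    return DissociationCurve(
        p50=p50_at_ph(ph, model),
        hill_n=hill_n,
        label=label if label is not None else f"pH {ph:g}",
    )


def saturation_difference(
    po2,
    ph_hi: float,
    ph_lo: float,
    model: BohrModel | None = None,
    hill_n: float | None = None,
):
    """Saturation gap (percentage points) between two pH curves at ``po2``.

    Returns ``100 * [S(po2; pH_hi) - S(po2; pH_lo)]``; non-negative for
    every PO2 because a lower pH shifts the curve rightward.
    """
    if not ph_hi > ph_lo:
        raise ValueError("ph_hi must exceed ph_lo")
    hi = hb_saturation(po2, curve_at_ph(ph_hi, model, hill_n))
    lo = hb_saturation(po2, curve_at_ph(ph_lo, model, hill_n))
    return 100.0 * (np.asarray(hi) - np.asarray(lo)) if np.ndim(po2) else 100.0 * (hi - lo)


def emperor_bohr_model() -> BohrModel:
    """Built-in Bohr model from the high-affinity anchor points."""
    anchors = load_params()["dissociation"]["emperor_anchors"]
    return BohrModel(anchors=tuple((ph, p50) for ph, p50 in anchors))


def default_hill_n() -> float:
    return float(load_params()["dissociation"]["default_hill_n"])


def fulmar_curve() -> DissociationCurve:
    """Built-in giant fulmar curve, from its published Hill-plot fit."""
    cfg = load_params()["dissociation"]["fulmar"]
    n = float(cfg["hill_n"])
    b = float(cfg["hill_intercept"])
    return DissociationCurve(p50=10 ** (b / n), hill_n=n, label="giant fulmar")


def curve_from_config(path: str | Path) -> tuple[BohrModel, float, str]:
    """Load a (BohrModel, hill_n, label) triple from a key-value file.

    Expected YAML keys: ``anchors`` (list of [pH, P50] pairs), ``hill_n``
    (optional, defaults to the package default) and ``label`` (optional).
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    model = BohrModel(anchors=tuple((ph, p50) for ph, p50 in cfg["anchors"]))
    hill_n = float(cfg.get("hill_n", default_hill_n()))
    return model, hill_n, str(cfg.get("label", ""))
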