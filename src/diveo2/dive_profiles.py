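"""Dive records: phase segmentation, saturation profiles, recovery times.

A :class:`DiveRecord` holds one dive's (time, depth, PO2) series plus
the tracked post-dive surface interval.  Converting the PO2 series
through a pH-specific dissociation curve yields a
:class:`SaturationProfile`; from that, post-surfacing recovery time to a
saturation baseline is extracted by linear interpolation between
samples.  Respiratory PO2 at depth follows an ambient-pressure model of
1 ATA at the surface plus 1 ATA per 10 m, minus water-vapor pressure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .oxy_dissociation import BohrModel, DissociationCurve, curve_at_ph, hb_saturation
from .params import load_params

logger = logging.getLogger(__name__)

__all__ = [
    "DiveRecord",
    "SaturationProfile",
    "PhaseSegmentation",
    "NOT_REACHED",
    "segment_phases",
    "profile_to_saturation",
    "respiratory_po2",
    "recovery_time",
    "read_profiles_csv",
    "write_saturation_csv",
]

#: Sentinel for a baseline never attained before the series ends; compares
#: after every finite recovery time.
NOT_REACHED = math.inf


@dataclass(frozen=True)
class DiveRecord:
    """Time/depth/PO2 series for one dive plus its surface interval."""

    dive_id: str
    site: str
    t: np.ndarray        # s, strictly increasing
    depth: np.ndarray    # m, >= 0
    po2: np.ndarray      # mmHg, >= 0
    surface_end: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        depth = np.asarray(self.depth, dtype=float)
        po2 = np.asarray(self.po2, dtype=float)
        if not (len(t) == len(depth) == len(po2)):
            raise ValueError("t, depth and po2 must have equal length")
        if len(t) == 0:
            raise ValueError("empty record")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(depth < 0):
            raise ValueError("depth must be non-negative")
        if np.any(po2 < 0):
            raise ValueError("po2 must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "po2", po2)

    def __len__(self) -> int:
        return len(self.t)

    def truncated(self, n: int) -> "DiveRecord":
        return DiveRecord(
            self.dive_id, self.site, self.t[:n], self.depth[:n], self.po2[:n],
            surface_end=self.surface_end,
        )


@dataclass(frozen=True)
class PhaseSegmentation:
    labels: np.ndarray       # per-sample phase: descent/bottom/ascent/surface
    duration_min: float      # submerged duration of the principal dive
    dive_start_t: float | None
    dive_end_t: float | None

    @property
    def has_dive(self) -> bool:
        return self.dive_start_t is not None


@dataclass(frozen=True)
class SaturationProfile:
    """Pointwise Hb-saturation series derived from a dive record."""

    dive_id: str
    ph: float | None
    t: np.ndarray
    saturation: np.ndarray
    phases: np.ndarray
    curve_label: str = ""

    def __post_init__(self) -> None:
        sat = np.asarray(self.saturation, dtype=float)
        if len(sat) != len(self.t):
            raise ValueError("saturation must match series length")
        if np.any((sat < 0) | (sat > 1)):
            raise ValueError("saturation must lie in [0, 1]")


def segment_phases(record: DiveRecord, dive_threshold: float = 1.0) -> PhaseSegmentation:
    """Label each sample descent/bottom/ascent/surface.

    Submerged means depth > ``dive_threshold`` (default 1 m, excluding
    surface splash).  The dive is the longest maximal submerged run;
    within it a sample is labelled by the sign of the depth change to
    the next in-dive sample (increasing -> descent, decreasing ->
    ascent, flat -> bottom).  Everything outside the run is surface.
    """
    depth = record.depth
    labels = np.full(len(record), "surface", dtype=object)
    submerged = depth > dive_threshold
    if not submerged.any():
        logger.warning("record %s never exceeds %.1f m: zero-duration dive",
                       record.dive_id, dive_threshold)
        return PhaseSegmentation(labels.astype(str), 0.0, None, None)

    # maximal runs of submersion; keep the longest (first on ties)
    idx = np.flatnonzero(submerged)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=lambda r: record.t[r[-1]] - record.t[r[0]])
    i0, i1 = run[0], run[-1]

    for i in range(i0, i1 + 1):
        dd = depth[i + 1] - depth[i] if i < i1 else depth[i1] - depth[i1 - 1]
        if dd > 0:
            labels[i] = "descent"
        elif dd < 0:
            labels[i] = "ascent"
        else:
            labels[i] = "bottom"
    duration_min = (record.t[i1] - record.t[i0]) / 60.0
    return PhaseSegmentation(
        labels.astype(str), float(duration_min), float(record.t[i0]), float(record.t[i1])
    )


def profile_to_saturation(
    record: DiveRecord,
    ph: float | None = None,
    bohr: BohrModel | None = None,
    hill_n: float | None = None,
    curve: DissociationCurve | None = None,
    dive_threshold: float = 1.0,
) -> SaturationProfile:
    """Convert a record's PO2 series to a saturation profile.

    Either ``ph`` (curve taken from the Bohr model) or an explicit
    ``curve`` (e.g. the fulmar built-in) must be given.  The operation
    is pointwise and deterministic.
    """
    if curve is None:
        if ph is None:
            raise ValueError("either ph or curve is required")
        curve = curve_at_ph(ph, bohr, hill_n)
    seg = segment_phases(record, dive_threshold)
    sat = hb_saturation(record.po2, curve)
    return SaturationProfile(
        dive_id=record.dive_id,
        ph=ph,
        t=record.t,
        saturation=np.asarray(sat, dtype=float),
        phases=seg.labels,
        curve_label=curve.label,
    )


def respiratory_po2(fo2: float, depth: float) -> float:
    """Respiratory-gas PO2 (mmHg) at depth for O2 fraction ``fo2``.

    Ambient pressure is 760 mmHg at the surface plus one atmosphere per
    10 m of seawater; water-vapor pressure (47 mmHg) is subtracted
    before applying the O2 fraction.
    """
    if not 0.0 <= fo2 <= 1.0:
        raise ValueError("fo2 must lie in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    p = load_params()["pressure"]
    ambient = p["surface_mmhg"] * (1.0 + p["ata_per_10m"] * depth / 10.0)
    return fo2 * (ambient - p["water_vapor_mmhg"])


def recovery_time(
    profile: SaturationProfile, baseline: float, surface_start: float
) -> float:
    """Minutes after ``surface_start`` until saturation regains ``baseline``.

    Returns 0.0 when saturation is already at or above the baseline at
    surfacing; interpolates linearly between the samples straddling the
    threshold crossing; returns :data:`NOT_REACHED` (infinity) if the
    baseline is never attained before the series ends.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must lie in (0, 1)")
    t, s = profile.t, profile.saturation
    if not t[0] <= surface_start <= t[-1]:
        raise ValueError("surface_start outside the series")
    start = int(np.searchsorted(t, surface_start, side="left"))
    if s[start] >= baseline:
        return 0.0
    for j in range(start + 1, len(t)):
        if s[j] >= baseline:
            frac = (baseline - s[j - 1]) / (s[j] - s[j - 1])
            t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
            return float((t_cross - surface_start) / 60.0)
    return NOT_REACHED


def read_profiles_csv(path: str | Path) -> list[DiveRecord]:
    """Read dive profiles (dive_id, site, t_s, depth_m, po2_mmHg)."""
    df = pd.read_csv(path)
    required = {"dive_id", "site", "t_s", "depth_m", "po2_mmHg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for dive_id, grp in df.groupby("dive_id", sort=False):
        grp = grp.sort_values("t_s")
        records.append(
            DiveRecord(
                dive_id=str(dive_id),
                site=str(grp["site"].iloc[0]),
                t=grp["t_s"].to_numpy(float),
                depth=grp["depth_m"].to_numpy(float),
                po2=grp["po2_mmHg"].to_numpy(float),
            )
        )
    return records


def write_saturation_csv(
    profiles: Sequence[SaturationProfile], path: str | Path
) -> None:
    """Write saturation profiles in long CSV form."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "dive_id": p.dive_id,
                    "ph": p.ph if p.ph is not None else "",
                    "curve": p.curve_label,
                    "t_s": p.t,
                    "saturation": p.saturation,
                    "phase": p.phases,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
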