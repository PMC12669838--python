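"""Seeded generators for blood-sample panels and dive PO2/depth records.

The panel generator draws samples from the same linear mixed-model
structure the regression module assumes (fixed PCO2 and lactate slopes,
Gaussian per-penguin intercepts, Gaussian residuals), so parameter
recovery can be tested end to end.  The dive generator produces
phenomenological depth and PO2 shape templates (trapezoidal depth;
arterial PO2 rising with compression then falling on ascent; venous PO2
declining; exponential post-surfacing relaxation toward the resting
value) — downstream operations consume only the resulting series.

A single integer seed drives every stochastic draw; generated artifacts
embed the spec they were produced from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blood_chem import BloodSample, Condition, Site
from .dive_profiles import DiveRecord

__all__ = [
    "PanelSpec",
    "DiveSpec",
    "gen_blood_panel",
    "gen_dive_record",
    "study_like_panel",
]


@dataclass(frozen=True)
class PanelSpec:
    """Generating parameters of a synthetic blood-sample panel."""

    n_penguins: int = 12
    samples_per_penguin: int = 3
    pco2_range: tuple[float, float] = (30.0, 90.0)
    lactate_range: tuple[float, float] = (0.2, 1.4)
    slope_pco2: float = -0.0034       # pH per mmHg
    slope_lactate: float = -0.009     # pH per mmol l-1
    intercept: float = 7.65           # pH at zero predictors
    penguin_sd: float = 0.015         # pH
    residual_sd: float = 0.01         # pH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penguin_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for lo, hi in (self.pco2_range, self.lactate_range):
            if not hi > lo:
                raise ValueError("ranges must be non-degenerate")
        if self.n_penguins < 1 or self.samples_per_penguin < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class DiveSpec:
    """Generating parameters of a synthetic dive record."""

    duration: float = 6.0            # min submerged
    max_depth: float = 50.0          # m
    surface_minutes: float = 4.0     # tracked post-dive interval
    po2_start: float = 90.0          # mmHg at submersion
    po2_end_target: float = 30.0     # mmHg at end of dive
    recovery_rate: float = 1.2       # per-min rate constant of PO2 relaxation
    sampling_dt: float = 5.0         # s
    site: str = "arterial"
    seed: int = 0
    po2_noise_sd: float = 0.0        # mmHg, additive Gaussian
    po2_rest: float | None = None    # default 90 arterial / 60 venous
    compression_gain: float = 0.8    # mmHg of arterial PO2 boost per m depth
    dive_id: str = "dive-0"

    def __post_init__(self) -> None:
        if min(self.duration, self.max_depth, self.sampling_dt) <= 0:
            raise ValueError("duration, max_depth and sampling_dt must be positive")
        if self.surface_minutes < 0 or self.po2_noise_sd < 0:
            raise ValueError("surface_minutes and po2_noise_sd must be non-negative")
        if self.site not in ("arterial", "venous"):
            raise ValueError(f"unknown site {self.site!r}")

    @property
    def resting_po2(self) -> float:
        if self.po2_rest is not None:
            return self.po2_rest
        return 90.0 if self.site == "arterial" else 60.0


def _condition_for(pco2: float, lactate: float, rng: np.random.Generator) -> Condition:
    if lactate < 1.5:
        return Condition.REST if pco2 < 45.0 else Condition.DIVE
    return Condition(rng.choice([Condition.RESTRAINT.value, Condition.ANESTHESIA.value]))


def gen_blood_panel(spec: PanelSpec) -> list[BloodSample]:
    """Draw a reproducible blood-sample panel from the panel spec.

    pH is generated as intercept + slope_pco2*PCO2 + slope_lactate*
    [lactate] + penguin offset + residual noise; condition labels are
    assigned so the partitioning and bound-selection rules downstream
    are exercised.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = rng.normal(0.0, spec.penguin_sd, spec.n_penguins)
    samples = []
    for i in range(spec.n_penguins):
        pid = f"EP{i + 1:02d}"
        mass = float(rng.uniform(22.0, 28.0))
        for _ in range(spec.samples_per_penguin):
            pco2 = float(rng.uniform(*spec.pco2_range))
            lactate = float(rng.uniform(*spec.lactate_range))
            ph = (
                spec.intercept
                + spec.slope_pco2 * pco2
                + spec.slope_lactate * lactate
                + offsets[i]
                + float(rng.normal(0.0, spec.residual_sd))
            )
            po2 = float(rng.uniform(30.0, 100.0))
            samples.append(
                BloodSample(
                    penguin_id=pid,
                    ph=float(np.clip(ph, 6.51, 7.99)),
                    pco2=pco2,
                    po2=po2,
                    lactate=lactate,
                    body_mass=mass,
                    site=Site(rng.choice([Site.ARTERIAL.value, Site.VENOUS.value])),
                    condition=_condition_for(pco2, lactate, rng),
                )
            )
    return samples


def gen_dive_record(spec: DiveSpec) -> DiveRecord:
    """Generate one dive plus surface-interval record from the dive spec.

    Depth is a descent/bottom/ascent trapezoid (deterministic — the same
    spec always gives identical depths); PO2 follows the site-specific
    shape template, hits ``po2_end_target`` at the end of the dive at
    zero noise, and relaxes exponentially toward the resting value at
    the surface.  Noise (seeded) applies to PO2 only.
    """
    rng = np.random.default_rng(spec.seed)
    dive_s = spec.duration * 60.0
    total_s = dive_s + spec.surface_minutes * 60.0
    t = np.arange(0.0, total_s + spec.sampling_dt / 2, spec.sampling_dt)

    # trapezoidal depth: 20% descent, 60% bottom, 20% ascent
    depth_knots_t = [0.0, 0.2 * dive_s, 0.8 * dive_s, dive_s, total_s]
    depth_knots_d = [0.0, spec.max_depth, spec.max_depth, 0.0, 0.0]
    depth = np.interp(t, depth_knots_t, depth_knots_d)

    if spec.site == "arterial":
        peak = spec.po2_start + spec.compression_gain * spec.max_depth
        po2_knots_t = [0.0, 0.2 * dive_s, 0.8 * dive_s, dive_s]
        po2_knots_p = [
            spec.po2_start,
            peak,
            0.5 * (peak + spec.po2_end_target),
            spec.po2_end_target,
        ]
    else:
        po2_knots_t = [0.0, dive_s]
        po2_knots_p = [spec.po2_start, spec.po2_end_target]
    po2 = np.interp(t, po2_knots_t, po2_knots_p)

    surface = t > dive_s
    gap = spec.resting_po2 - spec.po2_end_target
    po2[surface] = spec.resting_po2 - gap * np.exp(
        -spec.recovery_rate * (t[surface] - dive_s) / 60.0
    )

    if spec.po2_noise_sd > 0:
        po2 = po2 + rng.normal(0.0, spec.po2_noise_sd, po2.shape)
    po2 = np.clip(po2, 0.0, None)

    record = DiveRecord(
        dive_id=spec.dive_id,
        site=spec.site,
        t=t,
        depth=depth,
        po2=po2,
        surface_end=float(total_s),
    )
    object.__setattr__(record, "spec", spec)  # provenance
    return record


def study_like_panel(seed: int = 0) -> list[BloodSample]:
    """Panel reproducing the study's printed pH/PCO2/lactate extremes.

    Low-lactate group (32 samples, 12 penguins): twelve resting samples
    near pH 7.51, fifteen dive samples at pH >= 7.32, four implausible
    high-PCO2 samples below pH 7.30 (excluded by the PCO2 >= 93 rule)
    and one retained sample with minimum pH in [7.28, 7.295).
    High-lactate group (14 samples): pH >= 7.29 except two anesthetized
    samples (pH 7.23/7.25 at PCO2 72/85 mmHg, excluded by the
    anesthesia rule).  The selected lower bound is therefore 7.3.
    """
    rng = np.random.default_rng(seed)
    samples: list[BloodSample] = []
    pids = [f"EP{i + 1:02d}" for i in range(12)]
    masses = {p: float(rng.uniform(22.0, 28.0)) for p in pids}

    def add(pid, ph, pco2, lactate, condition, site=Site.VENOUS):
        samples.append(
            BloodSample(
                penguin_id=pid,
                ph=float(ph),
                pco2=float(pco2),
                po2=float(rng.uniform(30.0, 95.0)),
                lactate=float(lactate),
                body_mass=masses[pid],
                site=site,
                condition=condition,
            )
        )

    # 12 resting samples, pH ~ 7.51 +/- 0.03
    for i in range(12):
        ph = np.clip(rng.normal(7.51, 0.03), 7.40, 7.58)
        add(pids[i], ph, rng.uniform(35.0, 44.0), rng.uniform(0.2, 1.2),
            Condition.REST, Site(rng.choice(["arterial", "venous"])))
    # 15 dive samples, pH comfortably above 7.30
    for i in range(15):
        add(pids[i % 12], rng.uniform(7.33, 7.50), rng.uniform(45.0, 80.0),
            rng.uniform(0.2, 1.4), Condition.DIVE)
    # 4 implausible high-PCO2 samples (dropped by the exclusion rule)
    for i in range(4):
        add(pids[i], rng.uniform(7.18, 7.27), rng.uniform(93.0, 110.0),
            rng.uniform(0.2, 1.4), Condition.DIVE)
    # 1 retained low-pH dive sample: the group's bounding minimum
    add(pids[4], rng.uniform(7.28, 7.2949), 80.0, 0.9, Condition.DIVE)

    # high-lactate group: 12 restraint samples with pH >= 7.29
    lo_ph = [7.29, 7.31]  # the two highest-lactate samples
    lo_lact = [15.4, 17.0]
    for ph, lact in zip(lo_ph, lo_lact):
        add(pids[int(rng.integers(0, 12))], ph, rng.uniform(36.0, 39.0), lact,
            Condition.RESTRAINT)
    for i in range(10):
        add(pids[int(rng.integers(0, 12))], rng.uniform(7.30, 7.45),
            rng.uniform(35.0, 65.0), rng.uniform(2.0, 10.0), Condition.RESTRAINT)
    # 2 anesthetized samples excluded by the anesthesia/PCO2 rule
    add(pids[0], 7.23, 72.0, rng.uniform(2.0, 4.0), Condition.ANESTHESIA)
    add(pids[1], 7.25, 85.0, rng.uniform(2.0, 4.0), Condition.ANESTHESIA)
    return samples
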