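import math

import numpy as np
import pytest

from diveo2.dive_profiles import (
    NOT_REACHED,
    DiveRecord,
    SaturationProfile,
    profile_to_saturation,
    read_profiles_csv,
    recovery_time,
    respiratory_po2,
    segment_phases,
    write_saturation_csv,
)
from diveo2.oxy_dissociation import p50_at_ph
from diveo2.synthetic_data import DiveSpec, gen_dive_record


def square_wave_record(depth_m=50.0, dive_min=6.0, dt=5.0, po2=60.0):
    t = np.arange(0.0, dive_min * 60 + 120 + dt, dt)
    depth = np.where((t > 0) & (t <= dive_min * 60), depth_m, 0.0)
    return DiveRecord("sq", "arterial", t, depth, np.full_like(t, po2))


class TestDiveRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            DiveRecord("x", "arterial", [0, 0], [0, 0], [50, 50])  # t not increasing
        with pytest.raises(ValueError):
            DiveRecord("x", "arterial", [0, 1], [0, -1], [50, 50])
        with pytest.raises(ValueError):
            DiveRecord("x", "arterial", [0, 1], [0, 1], [50, -1])
        with pytest.raises(ValueError):
            DiveRecord("x", "arterial", [], [], [])


class TestSegmentPhases:
    def test_all_surface_no_dive(self):
        t = np.arange(0, 100, 5.0)
        rec = DiveRecord("flat", "arterial", t, np.zeros_like(t), np.full_like(t, 80.0))
        seg = segment_phases(rec)
        assert not seg.has_dive
        assert seg.duration_min == 0.0
        assert set(seg.labels) == {"surface"}

    def test_square_wave_duration(self):
        seg = segment_phases(square_wave_record(dive_min=6.0, dt=5.0))
        # submerged run spans the 6-min plateau (within one sample step)
        assert seg.duration_min == pytest.approx(6.0, abs=5.0 / 60)

    def test_triangular_ascent_where_depth_decreasing(self):
        t = np.arange(0.0, 400.0, 10.0)
        depth = np.interp(t, [0, 180, 360, 390], [0, 60, 0, 0])
        rec = DiveRecord("tri", "venous", t, depth, np.full_like(t, 50.0))
        seg = segment_phases(rec)
        in_dive = (depth > 1.0)
        # oracle: sign of forward depth difference
        for i in np.flatnonzero(in_dive):
            if i + 1 < len(t) and in_dive[i + 1]:
                expected = "descent" if depth[i + 1] > depth[i] else "ascent" if depth[i + 1] < depth[i] else "bottom"
                assert seg.labels[i] == expected

    def test_time_shift_invariance(self):
        rec = square_wave_record()
        shifted = DiveRecord("sq2", rec.site, rec.t + 1234.0, rec.depth, rec.po2)
        a, b = segment_phases(rec), segment_phases(shifted)
        assert np.array_equal(a.labels, b.labels)
        assert a.duration_min == b.duration_min
        assert b.dive_start_t == a.dive_start_t + 1234.0

    def test_depth_scaling_above_threshold_invariance(self):
        rec = square_wave_record(depth_m=50.0)
        scaled = DiveRecord("sq3", rec.site, rec.t, rec.depth * 2.0, rec.po2)
        a, b = segment_phases(rec), segment_phases(scaled)
        assert np.array_equal(a.labels, b.labels)
        assert a.duration_min == b.duration_min

    def test_longest_run_selected(self):
        t = np.arange(0.0, 300.0, 5.0)
        depth = np.zeros_like(t)
        depth[(t >= 20) & (t <= 40)] = 10.0   # short bounce
        depth[(t >= 100) & (t <= 250)] = 30.0  # main dive
        rec = DiveRecord("two", "arterial", t, depth, np.full_like(t, 50.0))
        seg = segment_phases(rec)
        assert seg.dive_start_t == 100.0
        assert seg.dive_end_t == 250.0


class TestProfileToSaturation:
    def test_constant_po2_at_p50_gives_flat_half(self, bohr):
        p50 = p50_at_ph(7.4, bohr)
        t = np.arange(0.0, 100.0, 10.0)
        rec = DiveRecord("c", "venous", t, np.full_like(t, 20.0), np.full_like(t, p50))
        prof = profile_to_saturation(rec, ph=7.4, bohr=bohr)
        assert np.allclose(prof.saturation, 0.5, atol=1e-12)

    def test_ph_ordering_pointwise(self, bohr):
        rec = gen_dive_record(DiveSpec(seed=3, po2_noise_sd=3.0))
        hi = profile_to_saturation(rec, ph=7.5, bohr=bohr)
        lo = profile_to_saturation(rec, ph=7.3, bohr=bohr)
        assert np.all(hi.saturation >= lo.saturation)

    def test_commutes_with_truncation(self, bohr):
        rec = gen_dive_record(DiveSpec(seed=4))
        full = profile_to_saturation(rec, ph=7.5, bohr=bohr)
        half = profile_to_saturation(rec.truncated(len(rec) // 2), ph=7.5, bohr=bohr)
        assert np.allclose(full.saturation[: len(rec) // 2], half.saturation)

    def test_requires_ph_or_curve(self):
        rec = gen_dive_record(DiveSpec(seed=0))
        with pytest.raises(ValueError):
            profile_to_saturation(rec)

    def test_explicit_curve(self, fulmar):
        rec = gen_dive_record(DiveSpec(seed=0))
        prof = profile_to_saturation(rec, curve=fulmar)
        assert prof.curve_label == "giant fulmar"
        assert prof.ph is None


class TestRespiratoryPo2:
    def test_surface_4pct(self):
        # 0.04 * (760 - 47), prints as ~29
        assert respiratory_po2(0.04, 0.0) == pytest.approx(28.52, abs=1e-9)
        assert round(respiratory_po2(0.04, 0.0)) == 29

    def test_30m_4pct(self):
        # 0.04 * (760*4 - 47) = 119.72, prints as 120
        assert respiratory_po2(0.04, 30.0) == pytest.approx(119.72, abs=1e-9)
        assert round(respiratory_po2(0.04, 30.0)) == 120

    def test_zero_fraction(self):
        assert respiratory_po2(0.0, 500.0) == 0.0

    @pytest.mark.parametrize("fo2,depth", [(-0.1, 0.0), (1.1, 0.0), (0.04, -5.0)])
    def test_domain_errors(self, fo2, depth):
        with pytest.raises(ValueError):
            respiratory_po2(fo2, depth)


def ramp_profile(start_sat, rate_per_min, minutes=6.0, dt_s=5.0):
    t = np.arange(0.0, minutes * 60 + dt_s, dt_s)
    sat = np.clip(start_sat + rate_per_min * t / 60.0, 0.0, 1.0)
    return SaturationProfile("r", 7.5, t, sat, np.full(len(t), "surface"))


class TestRecoveryTime:
    def test_already_at_baseline(self):
        prof = ramp_profile(0.95, 0.0)
        assert recovery_time(prof, 0.90, 0.0) == 0.0

    def test_linear_ramp_derived(self):
        # 40% rising 25 points/min to 90% -> (90-40)/25 = 2.0 min
        prof = ramp_profile(0.40, 0.25)
        assert recovery_time(prof, 0.90, 0.0) == pytest.approx(2.0, abs=1e-9)

    def test_interpolates_between_samples(self):
        t = np.array([0.0, 60.0, 120.0])
        sat = np.array([0.5, 0.8, 1.0])
        prof = SaturationProfile("i", 7.5, t, sat, np.full(3, "surface"))
        # crosses 0.9 halfway through the second minute
        assert recovery_time(prof, 0.90, 0.0) == pytest.approx(1.5, abs=1e-12)

    def test_not_reached(self):
        prof = ramp_profile(0.40, 0.01, minutes=3.0)
        assert recovery_time(prof, 0.90, 0.0) == NOT_REACHED
        assert math.isinf(NOT_REACHED)

    def test_baseline_domain_error(self):
        prof = ramp_profile(0.5, 0.1)
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                recovery_time(prof, bad, 0.0)

    def test_surface_start_outside_series(self):
        prof = ramp_profile(0.5, 0.1)
        with pytest.raises(ValueError):
            recovery_time(prof, 0.9, 1e6)

    def test_lower_ph_recovers_slower(self, bohr):
        rec = gen_dive_record(DiveSpec(seed=5, duration=6.0, po2_end_target=30.0))
        end = segment_phases(rec).dive_end_t
        times = {
            ph: recovery_time(profile_to_saturation(rec, ph=ph, bohr=bohr), 0.90, end)
            for ph in (7.5, 7.3)
        }
        assert times[7.3] > times[7.5] > 0.0

    def test_fulmar_not_faster_than_emperor(self, bohr, fulmar):
        rec = gen_dive_record(DiveSpec(seed=6, duration=6.0, po2_end_target=30.0))
        end = segment_phases(rec).dive_end_t
        t_emp = recovery_time(profile_to_saturation(rec, ph=7.3, bohr=bohr), 0.90, end)
        t_ful = recovery_time(profile_to_saturation(rec, curve=fulmar), 0.90, end)
        assert t_ful >= t_emp


def test_profiles_csv_round_trip(tmp_path):
    import pandas as pd

    recs = [gen_dive_record(DiveSpec(seed=s, dive_id=f"d{s}")) for s in (0, 1)]
    rows = []
    for r in recs:
        rows.append(
            pd.DataFrame(
                {"dive_id": r.dive_id, "site": r.site, "t_s": r.t, "depth_m": r.depth, "po2_mmHg": r.po2}
            )
        )
    path = tmp_path / "profiles.csv"
    pd.concat(rows).to_csv(path, index=False)
    back = read_profiles_csv(path)
    assert [r.dive_id for r in back] == ["d0", "d1"]
    assert np.allclose(back[0].po2, recs[0].po2)

    profs = [profile_to_saturation(r, ph=7.5) for r in back]
    out = tmp_path / "sat.csv"
    write_saturation_csv(profs, out)
    df = pd.read_csv(out)
    assert {"dive_id", "ph", "t_s", "saturation", "phase"} <= set(df.columns)
    assert len(df) == sum(len(r) for r in back)
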