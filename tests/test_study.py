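import numpy as np
import pandas as pd
import pytest

from plaquefem import (
    KPA_PER_MMHG,
    PlaqueGeometrySpec,
    PressureWaveform,
    RuptureCriteria,
    StudyError,
    SweepConfig,
    SweepResult,
    classify,
    find_threshold,
    pulsatile_envelope,
    run_sweep,
    solve_model,
    validate_homogeneous_vs_lipid,
)
from plaquefem.postprocess import StressSummary


def summary(sigma_cr, D_max=0.1, P=14.6):
    return StressSummary(
        sigma_cr=sigma_cr, D_max=D_max, sigma_over_P=sigma_cr / P,
        sigma_cr_location=(0, 0, 0), D_max_location=(0, 0, 0),
        sigma_max_global=sigma_cr, D_max_global=D_max, cap_region="cap", P=P,
    )


def fake_result(d_cg, sigma, D=None):
    D = D if D is not None else [0.1] * len(d_cg)
    table = pd.DataFrame(
        {"d_cg": d_cg, "sigma_cr": sigma, "D_max": D, "feasible": True}
    )
    return SweepResult(table, SweepConfig(model_set="C"), RuptureCriteria())


class TestClassify:
    def test_above_threshold_is_rupture_risk(self):
        v = classify(summary(331.0), PlaqueGeometrySpec(stenosis=0.7, d_fc=0.05))
        assert v.verdict == "rupture-risk"
        assert v.thin_cap  # 0.05 mm < 65 um threshold

    def test_below_threshold_is_stable(self):
        v = classify(summary(28.7), PlaqueGeometrySpec(stenosis=0.9, d_fc=0.48))
        assert v.verdict == "stable" and not v.thin_cap

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            RuptureCriteria(stress_threshold=-1.0)


class TestFindThreshold:
    def test_linear_interpolation_of_bracket(self):
        """A 282 -> 318 kPa bracket across 300 kPa interpolates halfway."""
        res = fake_result([0.02, 0.06], [282.0, 318.0], [0.1, 0.3])
        thr = find_threshold(res, axis="d_cg")
        assert thr.crossed
        assert thr.value == pytest.approx(0.04)
        assert thr.D_max_at_crossing == pytest.approx(0.2)

    def test_stable_over_range(self):
        thr = find_threshold(fake_result([0.1, 0.2], [100.0, 150.0]), axis="d_cg")
        assert not thr.crossed and "stable" in thr.note

    def test_exceeds_over_range(self):
        thr = find_threshold(fake_result([0.1, 0.2], [400.0, 500.0]), axis="d_cg")
        assert not thr.crossed and "exceeds" in thr.note

    def test_exact_grid_point(self):
        thr = find_threshold(fake_result([0.1, 0.2, 0.3], [250.0, 300.0, 350.0]))
        assert thr.crossed and thr.value == 0.2


class TestPressureWaveform:
    def test_peak_and_floor(self):
        w = PressureWaveform()
        t = np.linspace(0, 1, 2001)
        p = w.pressure_mmHg(t)
        assert p.max() == pytest.approx(107.0)
        assert p.min() == pytest.approx(70.0, abs=1e-6)
        assert w.pressure_mmHg(0.0) == pytest.approx(w.pressure_mmHg(1.0))

    def test_invalid_waveforms_rejected(self):
        with pytest.raises(ValueError):
            PressureWaveform(diastolic=-5.0)
        with pytest.raises(ValueError):
            PressureWaveform(period=0.0)

    def test_envelope_constant_waveform_is_flat(self):
        s = summary(100.0, 0.2)
        w = PressureWaveform(peak=s.P / KPA_PER_MMHG, diastolic=s.P / KPA_PER_MMHG)
        env = pulsatile_envelope(w, s)
        np.testing.assert_allclose(env.sigma_cr, 100.0, rtol=1e-12)

    def test_envelope_peak_scaling(self):
        """107 mmHg = 14.26 kPa scales a 14.6 kPa reference by 0.977."""
        s = summary(331.0)
        env = pulsatile_envelope(PressureWaveform(), s)
        scale = env.sigma_cr.max() / 331.0
        assert scale == pytest.approx(107.0 * KPA_PER_MMHG / 14.6, rel=1e-9)
        assert scale == pytest.approx(0.977, abs=2e-3)

    def test_zero_waveform(self):
        env = pulsatile_envelope(PressureWaveform(peak=0.0, diastolic=0.0), summary(50.0))
        assert np.all(env.sigma_cr == 0.0)


class TestSweeps:
    def test_single_point_matches_direct_solve(self):
        cfg = SweepConfig(
            model_set="B", d_fc=(0.05,), E_lp=(1.0,), mesh_level="coarse"
        )
        res = run_sweep(cfg)
        assert len(res.table) == 1
        direct = solve_model(
            PlaqueGeometrySpec(stenosis=res.table.stenosis[0], d_fc=0.05),
            level="coarse", E_lp=1.0,
        )
        assert res.table.sigma_cr[0] == pytest.approx(direct.summary.sigma_cr)
        assert bool(res.table.thin_cap[0])

    def test_deterministic(self):
        cfg = SweepConfig(model_set="A", stenosis=(0.7,), mesh_level="coarse")
        t1, t2 = run_sweep(cfg).table, run_sweep(cfg).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_infeasible_points_recorded_not_fatal(self):
        cfg = SweepConfig(
            model_set="B", d_fc=(0.05, 1.5), E_lp=(1.0,), mesh_level="coarse"
        )
        with pytest.warns(UserWarning, match="infeasible"):
            res = run_sweep(cfg)
        assert res.table.feasible.tolist() == [True, False]

    def test_bad_grids_rejected(self):
        with pytest.raises(StudyError):
            SweepConfig(d_fc=())
        with pytest.raises(StudyError):
            SweepConfig(d_fc=(0.3, 0.1))
        with pytest.raises(StudyError):
            SweepConfig(model_set="Z")

    def test_section_filters_and_sorts(self):
        res = fake_result([0.3, 0.1, 0.2], [3.0, 1.0, 2.0])
        sec = res.section("d_cg")
        assert sec.d_cg.tolist() == [0.1, 0.2, 0.3]


def test_with_lipid_raises_normalized_stress():
    """At matched stenosis the lipid-pool model concentrates more stress
    on the cap than the homogeneous one, and its normalized stress falls
    as stenosis grows (the cap thickens)."""
    df = validate_homogeneous_vs_lipid((0.70, 0.80), level="coarse")
    assert (df.sigma_over_P_lipid > df.sigma_over_P_homogeneous).all()
    assert df.sigma_over_P_lipid.iloc[1] < df.sigma_over_P_lipid.iloc[0]
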