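import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plaquefem import (
    InfeasibleGeometryError,
    InvalidParameterError,
    PlaqueGeometrySpec,
    build_cross_section,
    cap_thickness_for_stenosis,
    stenosis_for_cap_thickness,
    stenosis_to_lumen,
)


def spec(**kw):
    kw.setdefault("stenosis", 0.70)
    return PlaqueGeometrySpec(**kw)


class TestStenosisToLumen:
    @pytest.mark.parametrize(
        "s, expected", [(0.70, 1.08), (0.90, 0.36), (1e-9, 3.6)]
    )
    def test_diameter_convention_arithmetic(self, s, expected):
        sp = spec(stenosis=s, stenosis_convention="diameter", has_lipid=False)
        assert stenosis_to_lumen(sp) == pytest.approx(expected, rel=1e-6)

    def test_area_convention(self):
        sp = spec(stenosis=0.70)
        assert stenosis_to_lumen(sp) == pytest.approx(3.6 * math.sqrt(0.3), rel=1e-12)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.1, 1.2])
    def test_invalid_stenosis_rejected(self, s):
        with pytest.raises(InvalidParameterError):
            spec(stenosis=s)


class TestSpecValidation:
    def test_gap_cannot_consume_whole_lipid(self):
        with pytest.raises(InvalidParameterError):
            spec(d_cg=0.35)

    def test_cap_thickness_positive(self):
        with pytest.raises(InvalidParameterError):
            spec(d_fc=0.0)

    def test_calcified_requires_lipid(self):
        with pytest.raises(InvalidParameterError):
            spec(has_lipid=False, d_cg=0.1)

    def test_agglomerate_thickness_is_remaining_lipid(self):
        sp = spec(d_cg=0.1)
        assert sp.d_cag == pytest.approx(0.25)
        assert spec().d_cag is None


class TestCrossSection:
    def test_noncalcified_has_no_agglomerate(self):
        rs = build_cross_section(spec())
        assert "cag" not in rs.regions
        assert {"wall", "fibrous", "cap", "lipid"} <= set(rs.regions)

    def test_homogeneous_model_has_only_wall_and_fibrous(self):
        rs = build_cross_section(spec(has_lipid=False))
        assert set(rs.regions) == {"wall", "fibrous"}

    def test_zero_gap_agglomerate_touches_cap_backing(self):
        rs = build_cross_section(spec(d_cg=0.0))
        assert rs.profile.cag_inner == pytest.approx(rs.profile.lipid_inner)

    def test_infeasible_lipid_reaches_wall(self):
        with pytest.raises(InfeasibleGeometryError, match="wall"):
            build_cross_section(spec(stenosis=0.2, d_fc=0.4, lipid_thickness=1.0))

    @pytest.mark.parametrize(
        "kw",
        [
            {},
            {"d_cg": 0.02},
            {"d_cg": 0.33},
            {"has_lipid": False},
            {"scale": 2.775},
            {"stenosis": 0.90, "d_fc": 0.48},
        ],
    )
    def test_area_conservation(self, kw):
        """Solid region areas partition the half annulus minus half lumen."""
        rs = build_cross_section(spec(**kw))
        prof = rs.profile
        total = sum(v for k, v in rs.areas.items() if k != "lumen")
        expected = 0.5 * math.pi * (prof.r_external**2 - prof.r_lumen**2)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_analytic_areas_match_polygons(self):
        """Closed-form/quadrature areas agree with independently sampled
        shapely polygons for every region."""
        rs = build_cross_section(spec(d_cg=0.1), resolution=2048)
        for label, poly in rs.regions.items():
            assert poly.area == pytest.approx(rs.areas[label], rel=5e-3)

    def test_lipid_area_closed_form(self):
        """Crescent area equals the annular-sector closed form plus the
        exact taper-end term, within 0.5%."""
        rs = build_cross_section(spec(), resolution=2048)
        p = rs.profile
        body = p.half_arc * 0.5 * (p.lipid_outer**2 - p.lipid_inner**2)
        ends = 4.0 * p.mid_radius * p.cap_radius * p.taper_width / math.pi
        assert rs.regions["lipid"].area == pytest.approx(body + ends, rel=5e-3)

    def test_mirror_symmetry_tiles_full_section(self):
        rs = build_cross_section(spec())
        full = rs.mirrored_union()
        half = sum(v for k, v in rs.areas.items() if k != "lumen")
        assert full.is_valid
        assert full.area == pytest.approx(2 * half, rel=1e-3)

    def test_yaml_roundtrip(self, tmp_path):
        sp = spec(d_cg=0.05, scale=2.775)
        sp.to_yaml(tmp_path / "g.yaml")
        assert PlaqueGeometrySpec.from_yaml(tmp_path / "g.yaml") == sp

    def test_geojson_export(self, tmp_path):
        rs = build_cross_section(spec())
        rs.write_geojson(tmp_path / "r.json")
        import json

        feats = json.loads((tmp_path / "r.json").read_text())["features"]
        assert {f["properties"]["region"] for f in feats} >= {"wall", "lipid", "lumen"}


class TestModelBCoupling:
    def test_fixed_lipid_reproduces_printed_pairs(self):
        """Anchored at (70%, 0.05 mm), the fixed-position lipid leaves a
        ~0.48 mm cap at 90% stenosis and vice versa."""
        assert cap_thickness_for_stenosis(0.70) == pytest.approx(0.05, abs=1e-12)
        assert cap_thickness_for_stenosis(0.90) == pytest.approx(0.48, abs=0.015)
        assert stenosis_for_cap_thickness(0.48) == pytest.approx(0.90, abs=0.006)

    def test_cap_thickens_with_stenosis(self):
        s = np.linspace(0.68, 0.95, 15)
        d = [cap_thickness_for_stenosis(x) for x in s]
        assert np.all(np.diff(d) > 0)

    def test_lumen_outside_lipid_rejected(self):
        with pytest.raises(InfeasibleGeometryError):
            cap_thickness_for_stenosis(0.3)


@given(
    s=st.floats(0.55, 0.92),
    d_fc=st.floats(0.05, 0.4),
    d_cg=st.one_of(st.none(), st.floats(0.0, 0.3)),
)
def test_feasible_specs_partition_and_stay_positive(s, d_fc, d_cg):
    """Any feasible spec yields positive region areas that tile the solid."""
    try:
        rs = build_cross_section(spec(stenosis=s, d_fc=d_fc, d_cg=d_cg))
    except InfeasibleGeometryError:
        return
    assert all(a > 0 for a in rs.areas.values())
    total = sum(v for k, v in rs.areas.items() if k != "lumen")
    prof = rs.profile
    assert total == pytest.approx(
        0.5 * math.pi * (prof.r_external**2 - prof.r_lumen**2), rel=1e-8
    )
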