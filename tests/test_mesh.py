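import numpy as np
import pytest

from plaquefem import (
    InsufficientDataError,
    PlaqueGeometrySpec,
    annulus_mesh,
    build_cross_section,
    generate_mesh,
    grid_independence,
    mirror_mesh,
)

CONFIGS = {
    "thin_cap": dict(stenosis=0.70, d_fc=0.05),
    "thick_cap": dict(stenosis=0.90, d_fc=0.48),
    "small_gap": dict(stenosis=0.70, d_fc=0.05, d_cg=0.02),
    "wide_gap": dict(stenosis=0.70, d_fc=0.05, d_cg=0.33),
    "homogeneous": dict(stenosis=0.70, has_lipid=False),
}


@pytest.fixture(scope="module")
def meshes():
    out = {}
    for name, kw in CONFIGS.items():
        rs = build_cross_section(PlaqueGeometrySpec(**kw))
        for lvl in ("coarse", "medium"):
            out[name, lvl] = (rs, generate_mesh(rs, lvl))
    return out


class TestMeshGeometry:
    @pytest.mark.parametrize("name", list(CONFIGS))
    def test_region_areas_match_exact_geometry(self, meshes, name):
        """Triangle areas per region reproduce the analytic region areas."""
        rs, mesh = meshes[name, "medium"]
        for label, area in rs.areas.items():
            if label == "lumen":
                continue
            assert mesh.region_area(label) == pytest.approx(area, rel=5e-3)

    def test_every_region_is_represented(self, meshes):
        _, mesh = meshes["small_gap", "coarse"]
        assert set(mesh.labels) == {"wall", "fibrous", "cap", "lipid", "cag"}

    def test_refinement_is_monotone(self):
        rs = build_cross_section(PlaqueGeometrySpec(**CONFIGS["thin_cap"]))
        counts = [generate_mesh(rs, lvl).n_elements for lvl in ("coarse", "medium", "fine")]
        assert counts[0] < counts[1] < counts[2]

    def test_fine_count_same_order_as_reference(self):
        """The fine no-lipid mesh lands at the order of ~1e4 elements."""
        rs = build_cross_section(PlaqueGeometrySpec(**CONFIGS["homogeneous"]))
        n = generate_mesh(rs, "fine").n_elements
        assert 4e3 <= n <= 4e4

    def test_positive_areas(self, meshes):
        for (_, _), (_, mesh) in meshes.items():
            assert mesh.element_areas().min() > 0

    def test_determinism(self):
        rs = build_cross_section(PlaqueGeometrySpec(**CONFIGS["small_gap"]))
        m1, m2 = generate_mesh(rs, "medium"), generate_mesh(rs, "medium")
        np.testing.assert_array_equal(m1.tris, m2.tris)
        np.testing.assert_array_equal(m1.points, m2.points)


class TestMeshQuality:
    @pytest.mark.parametrize("name", list(CONFIGS))
    @pytest.mark.parametrize("level", ["coarse", "medium"])
    def test_min_angle_and_skewness(self, meshes, name, level):
        _, mesh = meshes[name, level]
        assert mesh.min_angle() >= 15.0
        assert mesh.max_skewness() <= 0.85

    def test_fine_level_quality(self):
        rs = build_cross_section(PlaqueGeometrySpec(**CONFIGS["small_gap"]))
        mesh = generate_mesh(rs, "fine")
        assert mesh.min_angle() >= 15.0

    @pytest.mark.parametrize("level", ["coarse", "medium"])
    def test_layers_through_cap_and_gap(self, meshes, level):
        """At least 3 element layers across the cap and the gap thickness."""
        rs, mesh = meshes["small_gap", level]
        prof = rs.profile
        on_axis = np.abs(mesh.points[:, 1]) < 1e-12
        corner = np.unique(mesh.tris[:, :3])
        r = np.hypot(prof.ecc - mesh.points[:, 0], mesh.points[:, 1])
        axis_r = np.sort(r[corner][on_axis[corner]])
        tol = 1e-9
        in_cap = (axis_r > prof.r_lumen + tol) & (axis_r < prof.lipid_inner - tol)
        in_gap = (axis_r > prof.lipid_inner + tol) & (axis_r < prof.cag_inner - tol)
        assert in_cap.sum() >= 2  # >= 3 intervals need >= 2 interior nodes
        assert in_gap.sum() >= 2


class TestBoundaryTags:
    def test_tags_partition_the_boundary(self, meshes):
        """Exterior edges are exactly the union of lumen, outer wall and
        symmetry tags, with no overlap and no hanging nodes."""
        _, mesh = meshes["thin_cap", "coarse"]
        edges = mesh.tris[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        assert counts.max() <= 2  # conforming: an edge joins at most 2 cells
        exterior = {tuple(e) for e in uniq[counts == 1]}
        tagged = []
        for tag in ("lumen", "outer_wall", "symmetry"):
            tagged += [tuple(sorted(e[:2])) for e in mesh.boundary[tag]]
        assert len(tagged) == len(set(tagged))  # no edge under two tags
        assert set(tagged) == exterior


class TestGridIndependence:
    class S:
        def __init__(self, sigma_cr, D_max):
            self.sigma_cr, self.D_max = sigma_cr, D_max

    def test_identical_summaries_pass(self):
        rep = grid_independence({"medium": self.S(300, 0.3), "fine": self.S(300, 0.3)})
        assert rep.passed and rep.fine_vs_medium["sigma_cr"] == 0.0

    def test_two_percent_boundary_passes(self):
        rep = grid_independence({"medium": self.S(300, 0.3), "fine": self.S(306, 0.3)})
        assert rep.fine_vs_medium["sigma_cr"] == pytest.approx(0.02)
        assert rep.passed

    def test_ten_percent_fails(self):
        rep = grid_independence({"medium": self.S(300, 0.3), "fine": self.S(330, 0.3)})
        assert rep.fine_vs_medium["sigma_cr"] == pytest.approx(0.10)
        assert not rep.passed

    def test_requires_two_levels(self):
        with pytest.raises(InsufficientDataError):
            grid_independence({"fine": self.S(300, 0.3)})


def test_mirror_mesh_doubles_the_half_model(meshes):
    _, mesh = meshes["thin_cap", "coarse"]
    full = mirror_mesh(mesh)
    assert full.n_elements == 2 * mesh.n_elements
    assert full.region_area("lipid") == pytest.approx(2 * mesh.region_area("lipid"))
    assert len(full.boundary["symmetry"]) == 0
    assert full.element_areas().min() > 0


def test_annulus_mesh_is_wall_only():
    mesh = annulus_mesh(1.8, 2.0, "coarse")
    assert set(mesh.labels) == {"wall"}
    r = np.hypot(*mesh.points.T)
    assert r.min() == pytest.approx(1.8, abs=1e-9)
    assert r.max() == pytest.approx(2.0, abs=1e-9)


def test_vtu_export(tmp_path, meshes):
    _, mesh = meshes["thin_cap", "coarse"]
    path = tmp_path / "m.vtu"
    from plaquefem import write_vtu

    write_vtu(mesh, path, point_data={"u": np.zeros((mesh.n_nodes, 2))})
    text = path.read_text()
    assert f'NumberOfCells="{mesh.n_elements}"' in text
    assert "UnstructuredGrid" in text and 'Name="region"' in text


def test_vtu_roundtrip_preserves_labels(tmp_path, meshes):
    from plaquefem import read_vtu, write_vtu

    _, mesh = meshes["small_gap", "coarse"]
    write_vtu(mesh, tmp_path / "rt.vtu")
    back = read_vtu(tmp_path / "rt.vtu")
    assert back.n_elements == mesh.n_elements
    np.testing.assert_allclose(back.points, mesh.points, atol=1e-9)
    assert (back.labels == mesh.labels).all()
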