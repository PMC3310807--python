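import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plaquefem import (
    LoadSpec,
    PlaqueGeometrySpec,
    annulus_mesh,
    build_cross_section,
    generate_mesh,
    isotropic,
    solve,
    solve_model,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# reference configurations used across the suite
THIN_CAP = dict(stenosis=0.70, d_fc=0.05)       # thin-cap constant-lipid model
THICK_CAP = dict(stenosis=0.90, d_fc=0.48)      # thick-cap constant-lipid model


@pytest.fixture(scope="session")
def thin_cap_results():
    """Thin-cap reference model solved at all three refinement levels."""
    return {
        lvl: solve_model(PlaqueGeometrySpec(**THIN_CAP), level=lvl, E_lp=1.0)
        for lvl in ("coarse", "medium", "fine")
    }


@pytest.fixture(scope="session")
def thick_cap_result():
    return solve_model(PlaqueGeometrySpec(**THICK_CAP), level="fine", E_lp=1.0)


@pytest.fixture(scope="session")
def lame_solutions():
    """Pressurised concentric annulus (a=1.8, b=2.0 mm) at three levels."""
    mat = {"wall": isotropic(1000.0, 0.3)}
    out = {}
    for lvl in ("coarse", "medium", "fine"):
        mesh = annulus_mesh(1.8, 2.0, lvl)
        out[lvl] = solve(mesh, mat, LoadSpec(14.6))
    return out


@pytest.fixture(scope="session")
def coarse_crescent():
    """A cheap solved crescent model for property checks."""
    spec = PlaqueGeometrySpec(**THIN_CAP)
    return solve_model(spec, level="coarse", E_lp=1.0)
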