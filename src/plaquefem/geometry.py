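"""Parameterized half cross-section of a stenosed, plaque-bearing artery.

The model is a half annulus cut along a symmetry line (the x-axis, upper
half kept).  The arterial wall is the annulus between the healthy internal
and external diameters, centred at the origin.  Fibrous plaque fills the
interior of the internal circle around an eccentric circular lumen whose
diameter encodes the degree of stenosis.  An optional lipid crescent of
fixed arc and thickness sits inside the plaque at distance ``d_fc`` (the
fibrous cap thickness) from the lumen, and an optional calcification
agglomerate crescent sits inside the lipid at depth ``d_cg`` (the
calcification gap) from the lipid's cap-side boundary.

Geometric conventions
---------------------
* The lumen centre is shifted by the eccentricity along the symmetry axis
  *away* from the plaque, so both crescents are bisected by the symmetry
  line and the half model is valid.
* All crescent interfaces are circles centred at the lumen centre.  In
  polar coordinates ``(r, phi)`` about the lumen centre -- with ``phi``
  measured from the plaque-apex direction -- every region is a radial
  interval that depends only on ``phi``.  This "radial profile" form is
  what the mesh generator consumes.
* The lipid crescent ends in rounded cosine-taper caps: the half
  thickness decays as ``cos`` over a taper arc, joining the annular body
  tangent-continuously (no artificial corner in the fibrous tissue) and
  closing at a blunt wedge tip with bounded boundary slope, which keeps
  the end exactly representable -- and well-shaped -- in the
  ray-structured mesh.  The agglomerate ends with flat radial cuts
  buried in lipid.
* Units: millimetres.  ``scale`` multiplies every length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from shapely.geometry import Polygon
from shapely.ops import unary_union
from scipy.integrate import quad

__all__ = [
    "PlaqueGeometrySpec",
    "PlanarRegionSet",
    "RadialProfile",
    "InvalidParameterError",
    "InfeasibleGeometryError",
    "stenosis_to_lumen",
    "build_cross_section",
    "annulus_profile",
    "cap_thickness_for_stenosis",
    "stenosis_for_cap_thickness",
]


class InvalidParameterError(ValueError):
    """A morphological parameter is outside its admissible range."""


class InfeasibleGeometryError(ValueError):
    """The requested regions cannot coexist without overlap."""


#: minimum clearance (mm, at scale 1) between the lipid crescent and the
#: internal wall circle, so a fibrous layer always separates them.
_MIN_CLEARANCE = 1e-3


@dataclass(frozen=True)
class PlaqueGeometrySpec:
    """All morphological parameters of one cross-section model.

    ``d_cg is None`` means a non-calcified model; ``d_cg = 0`` means the
    agglomerate touches the fibrous-cap backing.  ``has_lipid = False``
    gives the homogeneous-plaque model used for validation (model set A).
    """

    stenosis: float
    d_fc: float = 0.05
    d_cg: Optional[float] = None
    has_lipid: bool = True
    internal_diameter: float = 3.6
    external_diameter: float = 4.0
    lumen_eccentricity: float = 0.5
    lipid_arc: float = 140.0  # degrees
    lipid_thickness: float = 0.35
    scale: float = 1.0
    stenosis_convention: str = "area"

    def __post_init__(self) -> None:
        if not 0.0 < self.stenosis < 1.0:
            raise InvalidParameterError(
                f"stenosis must lie in (0, 1), got {self.stenosis}"
            )
        if self.stenosis_convention not in ("area", "diameter"):
            raise InvalidParameterError(
                "stenosis_convention must be 'area' or 'diameter'"
            )
        if self.scale <= 0.0:
            raise InvalidParameterError("scale must be positive")
        if not 0.0 < self.internal_diameter < self.external_diameter:
            raise InvalidParameterError(
                "need 0 < internal_diameter < external_diameter"
            )
        if self.has_lipid:
            if self.d_fc <= 0.0:
                raise InvalidParameterError("cap thickness d_fc must be > 0")
            if not 0.0 < self.lipid_arc < 360.0:
                raise InvalidParameterError("lipid_arc must lie in (0, 360) degrees")
            if self.lipid_thickness <= 0.0:
                raise InvalidParameterError("lipid_thickness must be > 0")
            if self.d_cg is not None:
                if self.d_cg < 0.0:
                    raise InvalidParameterError("calcification gap d_cg must be >= 0")
                if self.d_cg >= self.lipid_thickness:
                    raise InvalidParameterError(
                        f"d_cg = {self.d_cg} leaves no agglomerate thickness "
                        f"(lipid_thickness = {self.lipid_thickness})"
                    )
        elif self.d_cg is not None:
            raise InvalidParameterError("a calcified model requires has_lipid=True")

    # -- derived lengths (scaled) -------------------------------------
    @property
    def lumen_diameter(self) -> float:
        """Lumen diameter L from the degree of stenosis.

        Area convention (default): L = ID * sqrt(1 - s); this is the
        reading under which the constant-lipid model family's printed
        (stenosis, cap thickness) pairs are mutually consistent.
        Diameter convention: L = ID * (1 - s).
        """
        if self.stenosis_convention == "area":
            frac = math.sqrt(1.0 - self.stenosis)
        else:
            frac = 1.0 - self.stenosis
        return frac * self.internal_diameter * self.scale

    @property
    def lumen_radius(self) -> float:
        return 0.5 * self.lumen_diameter

    @property
    def calcified(self) -> bool:
        return self.has_lipid and self.d_cg is not None

    @property
    def d_cag(self) -> Optional[float]:
        """Agglomerate thickness: the lipid depth not taken by the gap."""
        if not self.calcified:
            return None
        return self.lipid_thickness - self.d_cg

    # -- config I/O ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "stenosis": self.stenosis,
            "d_fc": self.d_fc,
            "d_cg": self.d_cg,
            "has_lipid": self.has_lipid,
            "internal_diameter": self.internal_diameter,
            "external_diameter": self.external_diameter,
            "lumen_eccentricity": self.lumen_eccentricity,
            "lipid_arc": self.lipid_arc,
            "lipid_thickness": self.lipid_thickness,
            "scale": self.scale,
            "stenosis_convention": self.stenosis_convention,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlaqueGeometrySpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlaqueGeometrySpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stenosis_to_lumen(spec: PlaqueGeometrySpec) -> float:
    """Lumen diameter L (mm) for the spec's degree of stenosis, under the
    spec's stenosis convention (area by default; diameter gives
    L = (1 - s) * internal_diameter)."""
    return spec.lumen_diameter


def _lumen_radius(stenosis: float, internal_diameter: float, convention: str) -> float:
    frac = (
        math.sqrt(1.0 - stenosis) if convention == "area" else 1.0 - stenosis
    )
    return 0.5 * frac * internal_diameter


def cap_thickness_for_stenosis(
    stenosis: float,
    anchor_stenosis: float = 0.70,
    anchor_d_fc: float = 0.05,
    internal_diameter: float = 3.6,
    convention: str = "area",
) -> float:
    """Cap thickness when the lipid's inner boundary is fixed in space.

    With the lipid anchored where a reference model put it, shrinking the
    lumen (raising stenosis) widens the fibrous gap between lumen and
    lipid: the cap thickens with stenosis.  This is the constant-lipid
    model family's coupling; under the area convention it reproduces the
    printed anchor pairs (70% -> 0.05 mm, 90% -> 0.48 mm).
    """
    r_anchor = _lumen_radius(anchor_stenosis, internal_diameter, convention) + anchor_d_fc
    d_fc = r_anchor - _lumen_radius(stenosis, internal_diameter, convention)
    if d_fc <= 0.0:
        raise InfeasibleGeometryError(
            f"stenosis {stenosis} puts the lumen outside the anchored lipid"
        )
    return d_fc


def stenosis_for_cap_thickness(
    d_fc: float,
    anchor_stenosis: float = 0.70,
    anchor_d_fc: float = 0.05,
    internal_diameter: float = 3.6,
    convention: str = "area",
) -> float:
    """Inverse of :func:`cap_thickness_for_stenosis`: the degree of
    stenosis at which the fixed-position lipid leaves a cap ``d_fc``
    thick."""
    r_anchor = _lumen_radius(anchor_stenosis, internal_diameter, convention) + anchor_d_fc
    r_l = r_anchor - d_fc
    if r_l <= 0.0:
        raise InfeasibleGeometryError(
            f"cap thickness {d_fc} exceeds the anchored lipid's inner radius"
        )
    if convention == "area":
        s = 1.0 - (2.0 * r_l / internal_diameter) ** 2
    else:
        s = 1.0 - 2.0 * r_l / internal_diameter
    return float(np.clip(s, 0.05, 0.97))


# ---------------------------------------------------------------------
# radial profile
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class RadialProfile:
    """Analytic description of the cross-section in lumen-centred polar form.

    ``phi`` runs from 0 (plaque apex, the -x direction) to pi (thin-wall
    side).  A point is ``(x, y) = (ecc - r cos phi, r sin phi)`` with the
    artery centre at the origin.  Each solid region occupies a radial
    interval ``[lo(phi), hi(phi)]``.
    """

    r_lumen: float
    r_internal: float
    r_external: float
    ecc: float
    # lipid crescent (None fields when absent)
    lipid_inner: Optional[float] = None   # a = r_lumen + d_fc
    lipid_outer: Optional[float] = None   # b = a + lipid_thickness
    half_arc: Optional[float] = None      # theta_c, radians
    cag_inner: Optional[float] = None     # a + d_cg
    taper_width: Optional[float] = None   # angular extent of the end cap

    # -- coordinate helpers -------------------------------------------
    def point(self, phi, r):
        phi = np.asarray(phi, dtype=float)
        r = np.asarray(r, dtype=float)
        return np.stack([self.ecc - r * np.cos(phi), r * np.sin(phi)], axis=-1)

    def wall_inner_radius(self, phi):
        phi = np.asarray(phi, dtype=float)
        return self.ecc * np.cos(phi) + np.sqrt(
            self.r_internal**2 - (self.ecc * np.sin(phi)) ** 2
        )

    def wall_outer_radius(self, phi):
        phi = np.asarray(phi, dtype=float)
        return self.ecc * np.cos(phi) + np.sqrt(
            self.r_external**2 - (self.ecc * np.sin(phi)) ** 2
        )

    # -- crescent geometry --------------------------------------------
    @property
    def has_lipid(self) -> bool:
        return self.lipid_inner is not None

    @property
    def calcified(self) -> bool:
        return self.cag_inner is not None

    @property
    def cap_radius(self) -> Optional[float]:
        """Radius of the semicircular lipid end caps (half the thickness)."""
        if not self.has_lipid:
            return None
        return 0.5 * (self.lipid_outer - self.lipid_inner)

    @property
    def mid_radius(self) -> Optional[float]:
        if not self.has_lipid:
            return None
        return 0.5 * (self.lipid_outer + self.lipid_inner)

    @property
    def tip_angle(self) -> Optional[float]:
        """Angular extent of the crescent including the tapered end."""
        if not self.has_lipid:
            return None
        return self.half_arc + self.taper_width

    def cap_half_thickness(self, dphi):
        """Half thickness of the taper cap at angle dphi past the body."""
        dphi = np.asarray(dphi, dtype=float)
        g = self.cap_radius * np.cos(
            0.5 * math.pi * np.clip(dphi / self.taper_width, 0.0, 1.0)
        )
        return np.where(dphi >= self.taper_width - 1e-15, 0.0, g)

    def lipid_interval(self, phi):
        """(lo, hi, present) radial bounds of the lipid (incl. agglomerate)."""
        phi = np.asarray(phi, dtype=float)
        lo = np.full(phi.shape, np.nan)
        hi = np.full(phi.shape, np.nan)
        present = np.zeros(phi.shape, dtype=bool)
        if not self.has_lipid:
            return lo, hi, present
        a, b, rm = self.lipid_inner, self.lipid_outer, self.mid_radius
        body = phi <= self.half_arc
        lo[body], hi[body] = a, b
        capz = (phi > self.half_arc) & (phi <= self.tip_angle + 1e-12)
        if np.any(capz):
            g = self.cap_half_thickness(phi[capz] - self.half_arc)
            lo[capz], hi[capz] = rm - g, rm + g
        present[:] = body | capz
        return lo, hi, present

    def cag_interval(self, phi):
        phi = np.asarray(phi, dtype=float)
        lo = np.full(phi.shape, np.nan)
        hi = np.full(phi.shape, np.nan)
        present = np.zeros(phi.shape, dtype=bool)
        if self.calcified:
            body = phi <= self.half_arc
            lo[body], hi[body] = self.cag_inner, self.lipid_outer
            present[:] = body
        return lo, hi, present

    def region_at(self, r, phi) -> str:
        """Region label at a single lumen-centred polar point."""
        if r < self.r_lumen:
            return "lumen"
        if r > self.wall_outer_radius(phi):
            return "outside"
        if r >= self.wall_inner_radius(phi):
            return "wall"
        clo, chi, cpres = self.cag_interval(np.atleast_1d(phi))
        if cpres[0] and clo[0] <= r <= chi[0]:
            return "cag"
        llo, lhi, lpres = self.lipid_interval(np.atleast_1d(phi))
        if lpres[0] and llo[0] <= r <= lhi[0]:
            return "lipid"
        if lpres[0] and phi <= self.tip_angle and r < llo[0]:
            return "cap"
        return "fibrous"

    # -- areas (closed forms + quadrature, pre-meshing oracle) --------
    def region_areas(self) -> dict[str, float]:
        areas: dict[str, float] = {}
        areas["lumen"] = 0.5 * math.pi * self.r_lumen**2
        areas["wall"] = 0.5 * math.pi * (self.r_external**2 - self.r_internal**2)
        lipid_full = 0.0
        if self.has_lipid:
            a, b = self.lipid_inner, self.lipid_outer
            # annular body plus the exact cosine-taper end area
            lipid_full = (
                0.5 * self.half_arc * (b**2 - a**2)
                + 4.0 * self.mid_radius * self.cap_radius * self.taper_width / math.pi
            )
            if self.calcified:
                areas["cag"] = 0.5 * self.half_arc * (b**2 - self.cag_inner**2)
                areas["lipid"] = lipid_full - areas["cag"]
            else:
                areas["lipid"] = lipid_full

            def cap_band(phi):
                lo, _, _ = self.lipid_interval(np.atleast_1d(phi))
                return 0.5 * (lo[0] ** 2 - self.r_lumen**2)

            areas["cap"], _ = quad(cap_band, 0.0, self.tip_angle, limit=200)
        fibrous_total = (
            0.5 * math.pi * (self.r_internal**2 - self.r_lumen**2) - lipid_full
        )
        areas["fibrous"] = fibrous_total - areas.get("cap", 0.0)
        return areas


def _profile_from_spec(spec: PlaqueGeometrySpec) -> RadialProfile:
    s = spec.scale
    prof_kwargs = dict(
        r_lumen=spec.lumen_radius,
        r_internal=0.5 * spec.internal_diameter * s,
        r_external=0.5 * spec.external_diameter * s,
        ecc=spec.lumen_eccentricity * s,
    )
    if spec.has_lipid:
        a = spec.lumen_radius + spec.d_fc * s
        b = a + spec.lipid_thickness * s
        rho, rm = 0.5 * (b - a), 0.5 * (b + a)
        # taper arc chosen so the tip closes at a ~37 degree boundary
        # slope against the circumferential direction (blunt wedge)
        thc = math.radians(spec.lipid_arc) / 2.0
        taper = min(rho * math.pi / (1.5 * rm), 0.55, 0.9 * (math.pi - thc))
        prof_kwargs.update(
            lipid_inner=a,
            lipid_outer=b,
            half_arc=thc,
            taper_width=taper,
        )
        if spec.calcified:
            prof_kwargs.update(cag_inner=a + spec.d_cg * s)
    prof = RadialProfile(**prof_kwargs)
    _check_feasible(prof, spec)
    return prof


def _check_feasible(prof: RadialProfile, spec: PlaqueGeometrySpec) -> None:
    if prof.ecc + prof.r_lumen >= prof.r_internal:
        raise InfeasibleGeometryError(
            "lumen extends beyond the internal wall circle "
            f"(ecc + r_lumen = {prof.ecc + prof.r_lumen:.4f} >= "
            f"{prof.r_internal:.4f}); reduce eccentricity or stenosis"
        )
    if prof.has_lipid:
        phis = np.linspace(0.0, prof.tip_angle, 181)
        clearance = prof.wall_inner_radius(phis).min() - prof.lipid_outer
        if clearance < _MIN_CLEARANCE * spec.scale:
            raise InfeasibleGeometryError(
                "lipid crescent reaches the arterial wall (clearance "
                f"{clearance:.4f} mm); violated constraint: lipid_outer "
                "< internal wall radius over the crescent arc"
            )


def annulus_profile(a: float, b: float) -> RadialProfile:
    """Concentric homogeneous annulus (inner radius a, outer b): the
    thick-walled-cylinder benchmark geometry.  The whole solid is the
    'wall' region."""
    if not 0.0 < a < b:
        raise InvalidParameterError("need 0 < a < b")
    return RadialProfile(r_lumen=a, r_internal=a, r_external=b, ecc=0.0)


# ---------------------------------------------------------------------
# polygonal region set
# ---------------------------------------------------------------------


@dataclass
class PlanarRegionSet:
    """Closed planar boundaries per region, plus the analytic radial profile.

    ``regions`` maps label -> shapely Polygon for the solid regions among
    {wall, fibrous, cap, lipid, cag}; ``lumen`` is the (non-solid) half
    lumen.  The symmetry line is the x-axis.
    """

    profile: RadialProfile
    regions: dict[str, Polygon]
    lumen: Polygon
    spec: Optional[PlaqueGeometrySpec] = None
    areas: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    def symmetry_segments(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        p = self.profile
        left = ((-p.wall_outer_radius(np.pi * 0) + p.ecc, 0.0), (p.ecc - p.r_lumen, 0.0))
        right = ((p.ecc + p.r_lumen, 0.0), (p.ecc + p.wall_outer_radius(np.pi), 0.0))
        return [left, right]

    def mirrored_union(self) -> Polygon:
        """Full cross-section obtained by reflecting across the symmetry line."""
        half = unary_union(list(self.regions.values()))
        from shapely.affinity import scale as shp_scale

        return unary_union([half, shp_scale(half, xfact=1, yfact=-1, origin=(0, 0))])

    def to_geojson(self) -> dict:
        feats = []
        for label, poly in {**self.regions, "lumen": self.lumen}.items():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"region": label, "area": poly.area},
                    "geometry": poly.__geo_interface__,
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


def _arc_points(prof: RadialProfile, radius_fn, phi0: float, phi1: float, n: int):
    phis = np.linspace(phi0, phi1, n)
    return prof.point(phis, radius_fn(phis))


def build_cross_section(
    spec: PlaqueGeometrySpec, resolution: int = 720
) -> PlanarRegionSet:
    """Construct the labelled half cross-section.

    ``resolution`` is the number of boundary samples per half turn used for
    the exported polygons; areas in ``.areas`` come from closed forms and
    quadrature on the exact profile, not from the polygons.
    """
    prof = _profile_from_spec(spec)
    n = max(resolution, 64)

    def half_disk(radius_fn):
        pts = _arc_points(prof, radius_fn, 0.0, math.pi, n)
        return Polygon(pts)

    lumen = half_disk(lambda p: np.full_like(p, prof.r_lumen))
    disk_int = half_disk(prof.wall_inner_radius)
    disk_ext = half_disk(prof.wall_outer_radius)
    wall = disk_ext.difference(disk_int)

    regions: dict[str, Polygon] = {}
    if prof.has_lipid:
        tip = prof.tip_angle
        n_c = max(n // 2, 64)

        def lip_lo(p):
            lo, _, _ = prof.lipid_interval(p)
            return lo

        def lip_hi(p):
            _, hi, _ = prof.lipid_interval(p)
            return hi

        inner = _arc_points(prof, lip_lo, 0.0, tip, n_c)
        outer = _arc_points(prof, lip_hi, tip, 0.0, n_c)
        lipid_full = Polygon(np.vstack([inner, outer[1:]]))

        cap_in = _arc_points(prof, lambda p: np.full_like(p, prof.r_lumen), 0.0, tip, n_c)
        cap_out = _arc_points(prof, lip_lo, tip, 0.0, n_c)
        cap = Polygon(np.vstack([cap_in, cap_out]))
        regions["cap"] = cap

        if prof.calcified:
            sec_in = _arc_points(
                prof, lambda p: np.full_like(p, prof.cag_inner), 0.0, prof.half_arc, n_c
            )
            sec_out = _arc_points(
                prof, lambda p: np.full_like(p, prof.lipid_outer), prof.half_arc, 0.0, n_c
            )
            cag = Polygon(np.vstack([sec_in, sec_out]))
            regions["cag"] = cag
            regions["lipid"] = lipid_full.difference(cag)
        else:
            regions["lipid"] = lipid_full

        fibrous = disk_int.difference(lumen).difference(lipid_full).difference(cap)
    else:
        fibrous = disk_int.difference(lumen)

    regions["fibrous"] = fibrous
    regions["wall"] = wall

    return PlanarRegionSet(
        profile=prof,
        regions=regions,
        lumen=lumen,
        spec=spec,
        areas=prof.region_areas(),
    )
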