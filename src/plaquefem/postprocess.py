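"""Derived quantities: principal stress, critical cap stress, deformation.

The rupture-relevant scalar is the peak maximum principal stress over the
fibrous cap ("critical stress", sigma_cr); the deformation measure D_max
is the peak displacement magnitude over the cap.  Stresses are recovered
at element integration points and reported per element as the maximum
over those points -- no nodal smoothing, so the thin-cap stress
concentration is not smeared.  The out-of-plane principal stress is zero
under plane stress and participates in the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .mesh import LabeledMesh
from .solver import LoadSpec, SolutionField

__all__ = [
    "StressSummary",
    "SummaryError",
    "principal_stress",
    "hoop_stress",
    "summarize",
]


class SummaryError(ValueError):
    """The mesh lacks the region needed for a summary."""


def principal_stress(field: SolutionField) -> np.ndarray:
    """Per-element maximum principal stress (kPa).

    The in-plane eigenvalues are computed in closed form at each Gauss
    point; the element value is the maximum over its points and over the
    zero out-of-plane stress.
    """
    s = field.stress_gp  # (m, g, 3)
    centre = 0.5 * (s[..., 0] + s[..., 1])
    radius = np.sqrt((0.5 * (s[..., 0] - s[..., 1])) ** 2 + s[..., 2] ** 2)
    s1 = centre + radius
    return np.maximum(s1.max(axis=1), 0.0)


def hoop_stress(field: SolutionField) -> np.ndarray:
    """Per-element peak circumferential stress about the artery centre."""
    xy = field.gp_coords
    alpha = np.arctan2(xy[..., 1], xy[..., 0])  # radial direction angle
    c, sn = np.cos(alpha), np.sin(alpha)
    s = field.stress_gp
    # hoop direction is (-sin, cos)
    hoop = s[..., 0] * sn**2 - 2.0 * s[..., 2] * sn * c + s[..., 1] * c**2
    return hoop.max(axis=1)


@dataclass
class StressSummary:
    """Scalars the parametric study reports for one solved model."""

    sigma_cr: float            # kPa, cap-restricted peak max principal stress
    D_max: float               # mm, cap-restricted peak displacement magnitude
    sigma_over_P: float        # peak circumferential stress / luminal pressure
    sigma_cr_location: tuple   # (x, y, element id)
    D_max_location: tuple      # (x, y, node id)
    sigma_max_global: float    # kPa, unrestricted peak max principal stress
    D_max_global: float        # mm, unrestricted peak displacement
    cap_region: str            # which region backed the cap restriction
    P: float                   # kPa

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_cr_location"] = list(self.sigma_cr_location)
        d["D_max_location"] = list(self.D_max_location)
        return d


def summarize(
    field: SolutionField,
    mesh: Optional[LabeledMesh] = None,
    load: Optional[LoadSpec] = None,
) -> StressSummary:
    """Reduce a solution field to the study's reported quantities.

    The cap restriction uses the 'cap' region when the model has a lipid
    crescent; the homogeneous-plaque models (no cap) fall back to the
    whole fibrous region.
    """
    mesh = mesh or field.mesh
    load = load or field.load
    labels = mesh.labels
    if "cap" in labels:
        cap_lab = "cap"
    elif "fibrous" in labels:
        cap_lab = "fibrous"
    else:
        raise SummaryError("mesh has neither a cap nor a fibrous region")
    cap_el = labels == cap_lab

    s1 = principal_stress(field)
    sh = hoop_stress(field)
    umag = field.displacement_magnitude

    i_cr = int(np.argmax(np.where(cap_el, s1, -np.inf)))
    cen = mesh.element_centroids()
    sigma_cr = float(s1[i_cr])

    cap_nodes = np.unique(mesh.tris[cap_el])
    i_d = int(cap_nodes[np.argmax(umag[cap_nodes])])
    D_max = float(umag[i_d])

    plaque = cap_el | (labels == "fibrous")
    P = load.pressure
    sigma_over_P = float(sh[plaque].max() / P) if P > 0 else 0.0

    return StressSummary(
        sigma_cr=sigma_cr,
        D_max=D_max,
        sigma_over_P=sigma_over_P,
        sigma_cr_location=(float(cen[i_cr, 0]), float(cen[i_cr, 1]), i_cr),
        D_max_location=(float(mesh.points[i_d, 0]), float(mesh.points[i_d, 1]), i_d),
        sigma_max_global=float(s1.max()),
        D_max_global=float(umag.max()),
        cap_region=cap_lab,
        P=float(P),
    )
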