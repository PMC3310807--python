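"""Tissue elastic constants and the orthotropic plane-stress constitutive law.

The plaque constituents are modelled as linearly elastic and orthotropic in
local radial--circumferential (r, θ) axes: arterial wall tissue is much
stiffer along the fibre (circumferential) direction than radially.  The
calcification agglomerate is a homogenized composite of fibrous tissue,
lipid and micro-calcium obtained by a volume-fraction rule of mixtures
applied modulus by modulus.

Units are kPa for all moduli and millimetres elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TissueProperties",
    "MixtureFractions",
    "ConstitutiveMatrix",
    "MaterialError",
    "InvalidMixtureError",
    "default_tissue_table",
    "homogenize_agglomerate",
    "isotropic",
    "plane_stress_matrix",
    "rotated_stiffness",
    "read_tissue_table",
    "write_tissue_table",
]


class MaterialError(ValueError):
    """Inadmissible elastic constants (non-positive-definite compliance)."""


class InvalidMixtureError(ValueError):
    """Mixture fractions outside [0, 1] or not summing to one."""


@dataclass(frozen=True)
class TissueProperties:
    """Orthotropic in-plane elastic constants of one tissue.

    ``nu_rtheta`` is the minor Poisson ratio paired with ``E_r`` (so the
    reciprocal ratio is ``nu_thetar = nu_rtheta * E_theta / E_r``).
    ``nu_rz`` is stored for out-of-plane strain recovery only; it does not
    enter plane-stress equilibrium.
    """

    label: str
    E_r: float
    E_theta: float
    G_rtheta: float
    nu_rtheta: float = 0.01
    nu_rz: float = 0.27

    def __post_init__(self) -> None:
        for name in ("E_r", "E_theta", "G_rtheta"):
            if getattr(self, name) <= 0.0:
                raise MaterialError(f"{self.label}: {name} must be > 0")
        if not 0.0 <= self.nu_rtheta < 0.5:
            raise MaterialError(f"{self.label}: nu_rtheta must lie in [0, 0.5)")
        if 1.0 - self.nu_rtheta * self.nu_thetar <= 0.0:
            raise MaterialError(
                f"{self.label}: compliance is not positive definite "
                f"(1 - nu_rtheta*nu_thetar <= 0)"
            )

    @property
    def nu_thetar(self) -> float:
        return self.nu_rtheta * self.E_theta / self.E_r

    def with_modulus(self, E: float) -> "TissueProperties":
        """Return a copy with all three moduli set to ``E`` (sweep override)."""
        return replace(self, E_r=E, E_theta=E, G_rtheta=E)


@dataclass(frozen=True)
class MixtureFractions:
    """Volume fractions of fibrous tissue, lipid and calcium in the agglomerate."""

    alpha: float = 0.05
    beta: float = 0.20
    gamma: float = 0.75

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidMixtureError(f"{name} = {v} outside [0, 1]")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise InvalidMixtureError(
                f"fractions sum to {self.alpha + self.beta + self.gamma}, not 1"
            )


#: Printed constants for the four primitive constituents, kPa.
_TABLE = {
    "ndw": (10.0, 100.0, 50.0),       # non-diseased arterial wall
    "ft": (50.0, 1000.0, 500.0),      # fibrous plaque tissue
    "lp": (1.0, 1.0, 1.0),            # lipid pool
    "Ca": (12600.0, 12600.0, 12600.0),  # micro-calcium
}


def default_tissue_table(
    fractions: MixtureFractions | None = None,
) -> dict[str, TissueProperties]:
    """Constituent table including the homogenized calcification agglomerate.

    The ``cag`` row is always recomputed from the mixture rule rather than
    stored, so overriding ``fractions`` propagates consistently.
    """
    table = {
        label: TissueProperties(label, *moduli) for label, moduli in _TABLE.items()
    }
    table["cag"] = homogenize_agglomerate(table, fractions or MixtureFractions())
    return table


def homogenize_agglomerate(
    base: Mapping[str, TissueProperties], f: MixtureFractions
) -> TissueProperties:
    """Rule-of-mixtures moduli for the calcification agglomerate.

    Each modulus is the fraction-weighted linear combination of the fibrous
    (alpha), lipid (beta) and calcium (gamma) constituent moduli.  Poisson
    ratios are carried over unchanged; all constituents share them, and a
    heterogeneous-ν mixture is rejected rather than silently averaged.
    """
    try:
        ft, lp, ca = base["ft"], base["lp"], base["Ca"]
    except KeyError as exc:
        raise InvalidMixtureError(f"missing constituent {exc} in base table") from exc
    nus = {(t.nu_rtheta, t.nu_rz) for t in (ft, lp, ca)}
    if len(nus) != 1:
        raise InvalidMixtureError(
            "constituents have heterogeneous Poisson ratios; the carry-over "
            "homogenization of nu is only valid when they coincide"
        )

    def mix(attr: str) -> float:
        return (
            f.alpha * getattr(ft, attr)
            + f.beta * getattr(lp, attr)
            + f.gamma * getattr(ca, attr)
        )

    return TissueProperties(
        "cag",
        E_r=mix("E_r"),
        E_theta=mix("E_theta"),
        G_rtheta=mix("G_rtheta"),
        nu_rtheta=ft.nu_rtheta,
        nu_rz=ft.nu_rz,
    )


def isotropic(E: float, nu: float, label: str = "iso") -> TissueProperties:
    """Isotropic tissue with the consistent shear modulus E / (2(1+ν))."""
    return TissueProperties(label, E, E, E / (2.0 * (1.0 + nu)), nu, nu)


def effective_isotropic(t: TissueProperties) -> TissueProperties:
    """Isotropic surrogate with the circumferential (fibre-direction)
    modulus: E = E_theta, nu = nu_rtheta, G consistent.

    The study layer defaults to this reading: the printed reference
    deformations of the plaque models are reproducible with it but not
    with the radially soft orthotropic constants (see the methods note).
    """
    return isotropic(t.E_theta, t.nu_rtheta, t.label)


def _local_stiffness(t: TissueProperties, formulation: str = "plane_stress") -> np.ndarray:
    """3x3 stiffness in material axes (Voigt order rr, θθ, rθ; engineering shear)."""
    nu_rt, nu_tr = t.nu_rtheta, t.nu_thetar
    if formulation == "plane_stress":
        S = np.array(
            [
                [1.0 / t.E_r, -nu_tr / t.E_theta, 0.0],
                [-nu_rt / t.E_r, 1.0 / t.E_theta, 0.0],
                [0.0, 0.0, 1.0 / t.G_rtheta],
            ]
        )
    elif formulation == "plane_strain":
        # Diagnostic toggle only.  Out-of-plane constants are not fully
        # characterised for these tissues; the axial direction is taken to
        # behave like the circumferential one (E_z = E_theta, nu_iz = nu_rz).
        nu_z = t.nu_rz
        E_z = t.E_theta
        S3 = np.array(
            [
                [1.0 / t.E_r, -nu_tr / t.E_theta, -nu_z / E_z],
                [-nu_rt / t.E_r, 1.0 / t.E_theta, -nu_z / E_z],
                [-nu_z / E_z, -nu_z / E_z, 1.0 / E_z],
            ]
        )
        C3 = np.linalg.inv(S3)
        # Condense back to the in-plane 3x3 with the shear term appended.
        Q = np.zeros((3, 3))
        Q[:2, :2] = C3[:2, :2]
        Q[2, 2] = t.G_rtheta
        return Q
    else:
        raise ValueError(f"unknown formulation {formulation!r}")
    try:
        Q = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by ctor
        raise MaterialError(f"{t.label}: singular compliance") from exc
    if np.any(np.linalg.eigvalsh(0.5 * (Q + Q.T)) <= 0.0):
        raise MaterialError(f"{t.label}: stiffness not positive definite")
    return 0.5 * (Q + Q.T)


def rotated_stiffness(Q: np.ndarray, theta: np.ndarray | float) -> np.ndarray:
    """Rotate Voigt plane stiffness from material axes to global axes.

    ``theta`` is the angle of the local r-axis measured from global x;
    broadcasting over an array of angles returns a stacked (..., 3, 3) array.
    Classical transformed reduced-stiffness (lamina) formulas.
    """
    theta = np.asarray(theta, dtype=float)
    m, n = np.cos(theta), np.sin(theta)
    m2, n2, mn = m * m, n * n, m * n
    Q11, Q12, Q22, Q66 = Q[0, 0], Q[0, 1], Q[1, 1], Q[2, 2]
    Q16l, Q26l = Q[0, 2], Q[1, 2]
    if abs(Q16l) > 1e-12 * abs(Q11) or abs(Q26l) > 1e-12 * abs(Q11):
        raise MaterialError("local stiffness must be orthotropic (no shear coupling)")
    Qb = np.empty(theta.shape + (3, 3))
    Qb[..., 0, 0] = Q11 * m2**2 + 2 * (Q12 + 2 * Q66) * m2 * n2 + Q22 * n2**2
    Qb[..., 1, 1] = Q11 * n2**2 + 2 * (Q12 + 2 * Q66) * m2 * n2 + Q22 * m2**2
    Qb[..., 0, 1] = (Q11 + Q22 - 4 * Q66) * m2 * n2 + Q12 * (m2**2 + n2**2)
    Qb[..., 0, 2] = (Q11 - Q12 - 2 * Q66) * m * n * m2 + (Q12 - Q22 + 2 * Q66) * m * n * n2
    Qb[..., 1, 2] = (Q11 - Q12 - 2 * Q66) * m * n * n2 + (Q12 - Q22 + 2 * Q66) * m * n * m2
    Qb[..., 2, 2] = (Q11 + Q22 - 2 * Q12 - 2 * Q66) * m2 * n2 + Q66 * (m2**2 + n2**2)
    Qb[..., 1, 0] = Qb[..., 0, 1]
    Qb[..., 2, 0] = Qb[..., 0, 2]
    Qb[..., 2, 1] = Qb[..., 1, 2]
    return Qb


@dataclass(frozen=True)
class ConstitutiveMatrix:
    """Plane stiffness in global axes with the rotation that produced it."""

    matrix: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 3) or not np.allclose(M, M.T, rtol=0, atol=1e-8 * abs(M).max()):
            raise MaterialError("constitutive matrix must be symmetric 3x3")
        if np.any(np.linalg.eigvalsh(M) <= 0.0):
            raise MaterialError("constitutive matrix must be positive definite")

    def kelvin(self) -> np.ndarray:
        """Kelvin (Mandel) form, in which axis rotation is an orthogonal
        similarity and eigenvalues are frame invariants."""
        T = np.diag([1.0, 1.0, np.sqrt(2.0)])
        return T @ self.matrix @ T


def plane_stress_matrix(
    t: TissueProperties, theta_local: float, formulation: str = "plane_stress"
) -> ConstitutiveMatrix:
    """Global-axis constitutive matrix for a material whose r-axis points
    along ``theta_local`` (radians from global x)."""
    Q = _local_stiffness(t, formulation)
    return ConstitutiveMatrix(rotated_stiffness(Q, float(theta_local)), float(theta_local))


_COLUMNS = ["tissue", "E_r", "E_theta", "G_rtheta", "nu_rtheta", "nu_rz"]


def write_tissue_table(table: Mapping[str, TissueProperties], path) -> None:
    """Write constants as CSV (columns tissue, E_r, E_theta, G_rtheta, nu_rtheta, nu_rz)."""
    rows = [
        [t.label, t.E_r, t.E_theta, t.G_rtheta, t.nu_rtheta, t.nu_rz]
        for t in table.values()
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_tissue_table(path) -> dict[str, TissueProperties]:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tissue table missing columns {sorted(missing)}")
    return {
        row.tissue: TissueProperties(
            row.tissue, row.E_r, row.E_theta, row.G_rtheta, row.nu_rtheta, row.nu_rz
        )
        for row in df.itertuples()
    }
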