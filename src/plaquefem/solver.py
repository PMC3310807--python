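"""Linear elastostatic plane-stress equilibrium on the labelled mesh.

Quadratic (six-node) triangles with three-point Gauss integration; the
orthotropic constitutive matrix of each element is rotated into global
axes using the radial direction from the artery (outer-wall) centre at
the element centroid.  The luminal pressure is applied as a consistent
normal traction on the quadratic lumen edges; symmetry edges are
constrained in their normal direction and one outer-wall node on the
symmetry line is pinned along the symmetry axis to remove the remaining
rigid translation (its reaction vanishes by symmetry).  The sparse system
is solved by LU factorisation with one step of iterative refinement.

Kinematics are small-strain and the pressure acts on the undeformed lumen
(dead load), so the response is exactly linear in the applied pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import TissueProperties, _local_stiffness, rotated_stiffness
from .mesh import LabeledMesh

__all__ = ["LoadSpec", "SolutionField", "SolverError", "solve"]


class SolverError(RuntimeError):
    """Singular or ill-posed linear system."""


@dataclass(frozen=True)
class LoadSpec:
    """Luminal pressure load in kPa; ``scale`` multiplies the waveform."""

    P: float = 14.6
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.P < 0.0:
            raise ValueError("luminal pressure must be non-negative")

    @property
    def pressure(self) -> float:
        return self.P * self.scale


# three-point Gauss rule on the reference triangle (degree-2 exact)
_GP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_GW = np.array([1 / 6, 1 / 6, 1 / 6])


def _shape_derivs(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """TRI6 shape functions and (xi, eta) derivatives at one point."""
    l1, l2, l3 = 1.0 - xi - eta, xi, eta
    N = np.array(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ]
    )
    d1, d2, d3 = np.array([-1.0, -1.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0])
    dN = np.vstack(
        [
            (4 * l1 - 1) * d1,
            (4 * l2 - 1) * d2,
            (4 * l3 - 1) * d3,
            4 * (l2 * d1 + l1 * d2),
            4 * (l3 * d2 + l2 * d3),
            4 * (l1 * d3 + l3 * d1),
        ]
    )
    return N, dN


@dataclass
class SolutionField:
    """Nodal displacements (mm) and Gauss-point stresses/strains (kPa)."""

    mesh: LabeledMesh
    displacement: np.ndarray           # (n_nodes, 2)
    stress_gp: np.ndarray              # (m, 3 gp, 3) Voigt xx, yy, xy
    strain_gp: np.ndarray              # (m, 3 gp, 3) engineering shear
    gp_coords: np.ndarray              # (m, 3 gp, 2)
    load: LoadSpec
    reactions: np.ndarray = field(default=None, repr=False)  # (n_nodes, 2)

    @property
    def displacement_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=1)

    def scaled(self, factor: float) -> "SolutionField":
        """Linearity: the field under ``factor`` times the pressure."""
        return SolutionField(
            self.mesh,
            self.displacement * factor,
            self.stress_gp * factor,
            self.strain_gp * factor,
            self.gp_coords,
            LoadSpec(self.load.P, self.load.scale * factor),
            None if self.reactions is None else self.reactions * factor,
        )


def _element_stiffness_and_fields(mesh, D):
    """Assemble K (csr) and keep per-gp B matrices for stress recovery."""
    coords = mesh.points[mesh.tris]  # (m, 6, 2)
    m = len(coords)
    Ke = np.zeros((m, 12, 12))
    B_all = np.zeros((3, m, 3, 12))
    detJ_all = np.zeros((3, m))
    gp_xy = np.zeros((m, 3, 2))
    for g, ((xi, eta), w) in enumerate(zip(_GP, _GW)):
        N, dN = _shape_derivs(xi, eta)
        J = np.einsum("ia,eib->eab", dN, coords)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            bad = int(np.argmin(detJ))
            raise SolverError(f"non-positive Jacobian in element {bad}")
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1] / detJ
        invJ[:, 0, 1] = -J[:, 0, 1] / detJ
        invJ[:, 1, 0] = -J[:, 1, 0] / detJ
        invJ[:, 1, 1] = J[:, 0, 0] / detJ
        dNdx = np.einsum("ia,eba->eib", dN, invJ)
        B = np.zeros((m, 3, 12))
        B[:, 0, 0::2] = dNdx[:, :, 0]
        B[:, 1, 1::2] = dNdx[:, :, 1]
        B[:, 2, 0::2] = dNdx[:, :, 1]
        B[:, 2, 1::2] = dNdx[:, :, 0]
        Ke += (w * detJ)[:, None, None] * np.einsum("eki,ekl,elj->eij", B, D, B)
        B_all[g], detJ_all[g] = B, detJ
        gp_xy[:, g, :] = np.einsum("i,eib->eb", N, coords)
    edof = np.empty((m, 12), dtype=np.int64)
    edof[:, 0::2] = 2 * mesh.tris
    edof[:, 1::2] = 2 * mesh.tris + 1
    rows = np.repeat(edof[:, :, None], 12, axis=2)
    cols = np.repeat(edof[:, None, :], 12, axis=1)
    K = sp.coo_matrix(
        (Ke.ravel(), (rows.ravel(), cols.ravel())),
        shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes),
    ).tocsr()
    return K, B_all, edof, gp_xy


def _pressure_load(mesh: LabeledMesh, pressure: float) -> np.ndarray:
    f = np.zeros(2 * mesh.n_nodes)
    edges = mesh.boundary.get("lumen")
    if edges is None or len(edges) == 0 or pressure == 0.0:
        return f
    centre = np.array([mesh.profile.ecc, 0.0]) if mesh.profile is not None else np.zeros(2)
    gl_x = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)])
    gl_w = np.array([5 / 9, 8 / 9, 5 / 9])
    xi_g = 0.5 * (1.0 + gl_x)
    w_g = 0.5 * gl_w
    pts = mesh.points[edges]  # (k, 3, 2) [end0, end1, mid]
    for xi, w in zip(xi_g, w_g):
        N = np.array([(1 - xi) * (1 - 2 * xi), xi * (2 * xi - 1), 4 * xi * (1 - xi)])
        dN = np.array([4 * xi - 3, 4 * xi - 1, 4 - 8 * xi])
        x_gp = np.einsum("i,kib->kb", N, pts)
        tau = np.einsum("i,kib->kb", dN, pts)
        n_raw = np.stack([tau[:, 1], -tau[:, 0]], axis=1)
        outward = x_gp - centre
        sign = np.sign(np.einsum("kb,kb->k", n_raw, outward))
        sign[sign == 0] = 1.0
        traction = pressure * sign[:, None] * n_raw  # |n_raw| = ds/dxi folded in
        for i in range(3):
            np.add.at(f, 2 * edges[:, i], w * N[i] * traction[:, 0])
            np.add.at(f, 2 * edges[:, i] + 1, w * N[i] * traction[:, 1])
    return f


def _constraint_transform(
    n_nodes: int,
    constrained: Mapping[int, list],
) -> sp.csr_matrix:
    """Map reduced dofs to full dofs, eliminating u.d = 0 constraints."""
    rows, cols, vals = [], [], []
    col = 0
    for node in range(n_nodes):
        dirs = constrained.get(node)
        if not dirs:
            rows += [2 * node, 2 * node + 1]
            cols += [col, col + 1]
            vals += [1.0, 1.0]
            col += 2
            continue
        basis = []
        for d in dirs:
            d = np.asarray(d, float)
            d = d / np.linalg.norm(d)
            if not any(abs(abs(d @ b) - 1.0) < 1e-9 for b in basis):
                basis.append(d)
        if len(basis) >= 2:
            continue  # fully fixed
        d = basis[0]
        t = np.array([-d[1], d[0]])
        rows += [2 * node, 2 * node + 1]
        cols += [col, col]
        vals += [t[0], t[1]]
        col += 1
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(2 * n_nodes, col)
    ).tocsr()


def solve(
    mesh: LabeledMesh,
    materials: Mapping[str, TissueProperties],
    load: LoadSpec = LoadSpec(),
    formulation: str = "plane_stress",
    symmetry_normal: Tuple[float, float] = (0.0, 1.0),
    extra_constraints: Sequence[tuple[int, Tuple[float, float]]] = (),
    pin_rigid: bool = True,
    residual_tol: float = 1e-8,
) -> SolutionField:
    """Solve equilibrium under luminal pressure with symmetry conditions.

    ``materials`` maps every region label present in the mesh to its
    tissue; missing labels raise.  ``extra_constraints`` are additional
    (node, direction) pairs enforcing zero displacement along direction.
    """
    labels = np.unique(mesh.labels)
    missing = [lab for lab in labels if lab not in materials]
    if missing:
        raise SolverError(f"no material assigned to region(s) {missing}")

    cen = mesh.element_centroids()
    theta = np.arctan2(cen[:, 1], cen[:, 0])  # radial axis from artery centre
    D = np.empty((mesh.n_elements, 3, 3))
    for lab in labels:
        sel = mesh.labels == lab
        Q = _local_stiffness(materials[lab], formulation)
        D[sel] = rotated_stiffness(Q, theta[sel])

    K, B_all, edof, gp_xy = _element_stiffness_and_fields(mesh, D)
    f = _pressure_load(mesh, load.pressure)

    constrained: dict[int, list] = {}
    sym = mesh.boundary.get("symmetry")
    n_hat = np.asarray(symmetry_normal, float)
    if sym is not None and len(sym):
        for node in np.unique(sym[:, :3]):
            constrained.setdefault(int(node), []).append(n_hat)
        if pin_rigid:
            axis = np.array([-n_hat[1], n_hat[0]])
            sym_nodes = np.unique(sym[:, :3])
            outer = mesh.boundary.get("outer_wall")
            outer_nodes = set(np.unique(outer[:, :3])) if outer is not None else set()
            cands = [n for n in sym_nodes if int(n) in outer_nodes]
            if not cands:
                cands = list(sym_nodes)
            pin = int(
                min(cands, key=lambda n: tuple(np.round(mesh.points[int(n)], 12)))
            )
            constrained.setdefault(pin, []).append(axis)
    for node, vec in extra_constraints:
        constrained.setdefault(int(node), []).append(np.asarray(vec, float))
    if not constrained:
        raise SolverError("no constraints: rigid modes make the system singular")

    T = _constraint_transform(mesh.n_nodes, constrained)
    Khat = (T.T @ K @ T).tocsc()
    fhat = T.T @ f
    try:
        lu = spla.splu(Khat)
    except RuntimeError as exc:
        raise SolverError(f"singular system: {exc}") from exc
    uhat = lu.solve(fhat)
    uhat += lu.solve(fhat - Khat @ uhat)  # one refinement step
    fnorm = np.linalg.norm(fhat)
    if fnorm > 0:
        rel = np.linalg.norm(fhat - Khat @ uhat) / fnorm
        if not np.isfinite(rel) or rel > residual_tol:
            raise SolverError(f"linear solve residual {rel:.2e} exceeds tolerance")
    u = (T @ uhat).reshape(-1, 2)

    ue = (T @ uhat)[edof]  # (m, 12)
    strain = np.einsum("gekj,ej->egk", B_all, ue)  # (m, 3gp, 3)
    stress = np.einsum("ekl,egl->egk", D, strain)
    reactions = (K @ u.ravel() - f).reshape(-1, 2)
    return SolutionField(mesh, u, stress, strain, gp_xy, load, reactions)
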