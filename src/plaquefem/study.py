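"""Parametric experiments: sweeps, rupture thresholds, vulnerability.

This module drives the pipeline end to end: build a cross-section, mesh
it, assign tissues, solve, summarize -- over grids of cap thickness,
calcification gap and composite elasticity -- then detects where the
critical cap stress crosses the rupture threshold (300 kPa) and flags
thin caps (65 um).  A quasi-static pulsatile envelope rescales a
reference solution along a pressure waveform, exact under linearity.

Model sets
----------
A: homogeneous plaque, no lipid (validation against the lipid-free
   configuration);
B: constant lipid crescent, cap thickness coupled to stenosis;
C: calcified plaque, sweeping the calcification gap and/or agglomerate
   modulus at fixed cap thickness.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    InfeasibleGeometryError,
    InvalidParameterError,
    PlaqueGeometrySpec,
    build_cross_section,
    stenosis_for_cap_thickness,
)
from .geometry import cap_thickness_for_stenosis
from .materials import (
    MixtureFractions,
    TissueProperties,
    default_tissue_table,
    effective_isotropic,
)
from .mesh import LabeledMesh, generate_mesh
from .postprocess import StressSummary, summarize
from .solver import LoadSpec, SolutionField, solve

__all__ = [
    "SweepConfig",
    "RuptureCriteria",
    "SweepResult",
    "ThresholdResult",
    "Verdict",
    "PressureWaveform",
    "StudyError",
    "KPA_PER_MMHG",
    "model_b_cap_thickness",
    "solve_model",
    "run_sweep",
    "validate_homogeneous_vs_lipid",
    "find_threshold",
    "classify",
    "pulsatile_envelope",
]

KPA_PER_MMHG = 101.325 / 760.0


class StudyError(RuntimeError):
    """No feasible grid point / malformed study configuration."""


@dataclass(frozen=True)
class RuptureCriteria:
    """Rupture thresholds: 300 kPa critical stress, 65 um cap thickness."""

    stress_threshold: float = 300.0     # kPa
    cap_thickness_threshold: float = 0.065  # mm

    def __post_init__(self) -> None:
        if self.stress_threshold <= 0 or self.cap_thickness_threshold <= 0:
            raise ValueError("rupture thresholds must be positive")


@dataclass
class SweepConfig:
    """Grids for one parametric sweep.

    For model set B (and the d_fc axis of set C) the degree of stenosis is
    coupled to the cap thickness through the constant-lipid relation
    unless ``couple_stenosis`` is disabled, in which case the first entry
    of ``stenosis`` is used throughout.
    """

    model_set: str = "B"
    stenosis: Sequence[float] = (0.70, 0.75, 0.80, 0.90)
    d_fc: Sequence[float] = (0.05, 0.1575, 0.265, 0.48)
    d_cg: Sequence[float] = tuple(np.round(np.arange(0.02, 0.331, 0.01), 4))
    E_lp: Sequence[float] = (1.0,)
    E_cag: Optional[Sequence[float]] = None   # None: Table-1 homogenized value
    P: float = 14.6
    mesh_level: str = "fine"
    couple_stenosis: bool = True
    material_model: str = "effective_isotropic"
    fractions: MixtureFractions = dc_field(default_factory=MixtureFractions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_set not in ("A", "B", "C"):
            raise StudyError(f"unknown model set {self.model_set!r}")
        for name in ("stenosis", "d_fc", "d_cg", "E_lp"):
            g = np.asarray(getattr(self, name), float)
            if g.size == 0:
                raise StudyError(f"empty grid {name}")
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise StudyError(f"grid {name} must be strictly increasing")


def model_b_cap_thickness(stenosis: float) -> float:
    """Cap thickness paired with a degree of stenosis in the
    constant-lipid model family (fixed lipid position, anchored at 70%
    stenosis with a 0.05 mm cap; reproduces the printed 90% -> 0.48 mm
    pair)."""
    return cap_thickness_for_stenosis(stenosis)


@dataclass
class ModelResult:
    spec: PlaqueGeometrySpec
    mesh: LabeledMesh
    field: SolutionField
    summary: StressSummary


def _tissue_map(
    mesh_labels: Iterable[str],
    table: Mapping[str, TissueProperties],
    E_lp: Optional[float],
    E_cag: Optional[float],
    material_model: str = "effective_isotropic",
) -> dict[str, TissueProperties]:
    lp = table["lp"] if E_lp is None else table["lp"].with_modulus(E_lp)
    cag = table["cag"] if E_cag is None else table["cag"].with_modulus(E_cag)
    full = {"wall": table["ndw"], "fibrous": table["ft"], "cap": table["ft"],
            "lipid": lp, "cag": cag}
    if material_model == "effective_isotropic":
        full = {k: effective_isotropic(v) for k, v in full.items()}
    elif material_model != "orthotropic":
        raise StudyError(f"unknown material model {material_model!r}")
    return {lab: full[lab] for lab in set(mesh_labels)}


def solve_model(
    spec: PlaqueGeometrySpec,
    level: str = "fine",
    E_lp: Optional[float] = None,
    E_cag: Optional[float] = None,
    P: float = 14.6,
    fractions: Optional[MixtureFractions] = None,
    mesh: Optional[LabeledMesh] = None,
    material_model: str = "effective_isotropic",
) -> ModelResult:
    """Build, mesh and solve one cross-section model; returns everything.

    ``material_model`` selects between the effective isotropic reading of
    the tissue table (default; each tissue at its circumferential
    modulus) and the fully orthotropic one.
    """
    regions = build_cross_section(spec, resolution=256)
    if mesh is None:
        mesh = generate_mesh(regions, level)
    table = default_tissue_table(fractions)
    mats = _tissue_map(mesh.labels, table, E_lp, E_cag, material_model)
    load = LoadSpec(P)
    fld = solve(mesh, mats, load)
    return ModelResult(spec, mesh, fld, summarize(fld, mesh, load))


@dataclass
class SweepResult:
    """Grid of summaries plus detected thresholds and per-model flags."""

    table: pd.DataFrame
    config: SweepConfig
    criteria: RuptureCriteria
    monotonicity: dict = dc_field(default_factory=dict)
    thresholds: dict = dc_field(default_factory=dict)

    def section(self, axis: str, **fixed) -> pd.DataFrame:
        df = self.table[self.table.feasible]
        for k, v in fixed.items():
            df = df[np.isclose(df[k], v)]
        return df.sort_values(axis).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _coupled_stenosis(cfg: SweepConfig, d_fc: float) -> float:
    if not cfg.couple_stenosis:
        return cfg.stenosis[0]
    try:
        return stenosis_for_cap_thickness(d_fc)
    except InfeasibleGeometryError:
        return np.nan  # recorded as an infeasible grid point downstream


def _grid_points(cfg: SweepConfig):
    if cfg.model_set == "A":
        for s in cfg.stenosis:
            yield dict(stenosis=s, d_fc=np.nan, d_cg=np.nan, E_lp=np.nan, E_cag=np.nan)
    elif cfg.model_set == "B":
        for d_fc, e_lp in itertools.product(cfg.d_fc, cfg.E_lp):
            s = _coupled_stenosis(cfg, d_fc)
            yield dict(stenosis=s, d_fc=d_fc, d_cg=np.nan, E_lp=e_lp, E_cag=np.nan)
    else:  # C
        e_cags = cfg.E_cag if cfg.E_cag is not None else (None,)
        for d_fc, d_cg, e_cag in itertools.product(cfg.d_fc, cfg.d_cg, e_cags):
            s = _coupled_stenosis(cfg, d_fc)
            yield dict(
                stenosis=s, d_fc=d_fc, d_cg=d_cg, E_lp=cfg.E_lp[0],
                E_cag=np.nan if e_cag is None else e_cag,
            )


def run_sweep(cfg: SweepConfig, criteria: RuptureCriteria = RuptureCriteria()) -> SweepResult:
    """Solve every feasible grid point and tabulate the summaries.

    Infeasible geometries are recorded (feasible=False) and skipped with a
    warning; an entirely infeasible grid raises.
    """
    rows = []
    for pt in _grid_points(cfg):
        row = dict(model_set=cfg.model_set, **pt, P=cfg.P, level=cfg.mesh_level)
        try:
            spec = PlaqueGeometrySpec(
                stenosis=pt["stenosis"],
                d_fc=pt["d_fc"] if np.isfinite(pt["d_fc"]) else 0.05,
                d_cg=pt["d_cg"] if np.isfinite(pt["d_cg"]) else None,
                has_lipid=cfg.model_set != "A",
            )
            res = solve_model(
                spec,
                level=cfg.mesh_level,
                E_lp=None if not np.isfinite(pt["E_lp"]) else pt["E_lp"],
                E_cag=None if not np.isfinite(pt["E_cag"]) else pt["E_cag"],
                P=cfg.P,
                fractions=cfg.fractions,
                material_model=cfg.material_model,
            )
        except (InfeasibleGeometryError, InvalidParameterError) as exc:
            warnings.warn(f"skipping infeasible grid point {pt}: {exc}")
            row.update(feasible=False, sigma_cr=np.nan, D_max=np.nan,
                       sigma_over_P=np.nan, n_elements=0,
                       rupture=False, thin_cap=False)
            rows.append(row)
            continue
        s = res.summary
        row.update(
            feasible=True,
            sigma_cr=s.sigma_cr,
            D_max=s.D_max,
            sigma_over_P=s.sigma_over_P,
            sigma_max_global=s.sigma_max_global,
            D_max_global=s.D_max_global,
            n_elements=res.mesh.n_elements,
            rupture=s.sigma_cr > criteria.stress_threshold,
            thin_cap=bool(
                np.isfinite(pt["d_fc"])
                and pt["d_fc"] <= criteria.cap_thickness_threshold
            ),
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.feasible.any():
        raise StudyError("no feasible grid point in the sweep")
    result = SweepResult(table, cfg, criteria)
    result.monotonicity = _monotonicity(table)
    return result


def _monotonicity(table: pd.DataFrame) -> dict:
    """Directional diagnostics along each 1D section of the grid."""
    out: dict[str, bool] = {}
    ok = table[table.feasible]

    def check(axis: str, others: list[str], name: str, direction: int):
        if axis not in ok or ok[axis].nunique() < 2:
            return
        verdicts = []
        group_cols = [c for c in others if c in ok and ok[c].nunique() > 1]
        groups = ok.groupby(group_cols) if group_cols else [(None, ok)]
        for _, g in groups:
            g = g.sort_values(axis)
            d = np.diff(g.sigma_cr.to_numpy())
            tol = 1e-9 * max(abs(g.sigma_cr).max(), 1.0)
            verdicts.append(bool(np.all(direction * d >= -tol)))
        if verdicts:
            out[name] = all(verdicts)

    check("d_fc", ["E_lp", "E_cag", "d_cg"], "sigma_cr_decreasing_in_d_fc", -1)
    check("d_cg", ["E_lp", "E_cag", "d_fc"], "sigma_cr_increasing_in_d_cg", +1)
    return out


@dataclass
class ThresholdResult:
    """Where a 1D sweep crosses the rupture stress threshold."""

    axis: str
    crossed: bool
    value: Optional[float] = None          # interpolated axis value at crossing
    bracket: Optional[tuple] = None        # (x_lo, x_hi)
    sigma_bracket: Optional[tuple] = None  # (sigma_lo, sigma_hi)
    D_max_at_crossing: Optional[float] = None
    note: str = ""


def find_threshold(
    result: SweepResult,
    criteria: RuptureCriteria = RuptureCriteria(),
    axis: str = "d_cg",
    **fixed,
) -> ThresholdResult:
    """Linear interpolation of the sigma_cr = threshold crossing along one axis.

    Also reports D_max at the crossing: the deformation threshold paired
    with the stress threshold.
    """
    df = result.section(axis, **fixed)
    if len(df) < 1:
        raise StudyError(f"no feasible points along axis {axis}")
    x = df[axis].to_numpy(float)
    y = df.sigma_cr.to_numpy(float)
    d = df.D_max.to_numpy(float)
    thr = criteria.stress_threshold
    exact = np.isclose(y, thr, rtol=0, atol=1e-9 * thr)
    if exact.any():
        i = int(np.argmax(exact))
        return ThresholdResult(axis, True, float(x[i]), (float(x[i]), float(x[i])),
                               (float(y[i]), float(y[i])), float(d[i]),
                               "threshold met exactly at a grid point")
    sign = y > thr
    crossings = np.nonzero(sign[1:] != sign[:-1])[0]
    if len(crossings) == 0:
        note = (
            "stable over range" if not sign.any() else
            "exceeds threshold over entire range"
        )
        return ThresholdResult(axis, False, note=note)
    i = int(crossings[0])
    t = (thr - y[i]) / (y[i + 1] - y[i])
    x_star = x[i] + t * (x[i + 1] - x[i])
    d_star = d[i] + t * (d[i + 1] - d[i])
    return ThresholdResult(
        axis, True, float(x_star), (float(x[i]), float(x[i + 1])),
        (float(y[i]), float(y[i + 1])), float(d_star),
    )


@dataclass(frozen=True)
class Verdict:
    verdict: str          # "rupture-risk" | "stable"
    thin_cap: bool
    sigma_cr: float
    criteria: RuptureCriteria


def classify(
    summary: StressSummary,
    spec: Optional[PlaqueGeometrySpec] = None,
    criteria: RuptureCriteria = RuptureCriteria(),
) -> Verdict:
    """Vulnerability verdict from the stress criterion, with an independent
    thin-cap flag from the 65 um histological threshold."""
    verdict = (
        "rupture-risk" if summary.sigma_cr > criteria.stress_threshold else "stable"
    )
    thin = bool(
        spec is not None
        and spec.has_lipid
        and spec.d_fc * spec.scale <= criteria.cap_thickness_threshold
    )
    return Verdict(verdict, thin, summary.sigma_cr, criteria)


@dataclass(frozen=True)
class PressureWaveform:
    """Two-harmonic systolic pulse: p(t) = dia + (peak - dia) * w(t),
    w = c0 + c1 cos(2 pi t / T) + c2 cos(4 pi t / T), normalized to
    w(0) = 1, min w = 0."""

    period: float = 1.0        # s
    peak: float = 107.0        # mmHg
    diastolic: float = 70.0    # mmHg
    c: tuple = (0.375, 0.5, 0.125)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 <= self.diastolic <= self.peak:
            raise ValueError("need 0 <= diastolic <= peak")

    def pressure_mmHg(self, t: np.ndarray) -> np.ndarray:
        th = 2.0 * np.pi * np.asarray(t, float) / self.period
        w = self.c[0] + self.c[1] * np.cos(th) + self.c[2] * np.cos(2 * th)
        return self.diastolic + (self.peak - self.diastolic) * w

    def pressure_kpa(self, t: np.ndarray) -> np.ndarray:
        return KPA_PER_MMHG * self.pressure_mmHg(t)


def pulsatile_envelope(
    waveform: PressureWaveform,
    summary: StressSummary,
    n_samples: int = 200,
) -> pd.DataFrame:
    """Quasi-static time series sigma_cr(t), D_max(t) by linear rescaling
    of a reference solution: sigma_cr(t) = sigma_cr(P_ref) p(t) / P_ref.

    Exact under the linear kinematics; the series peak equals a direct
    solve at the waveform's peak pressure.
    """
    t = np.linspace(0.0, waveform.period, n_samples, endpoint=False)
    p = waveform.pressure_kpa(t)
    if np.any(p < 0):
        raise ValueError("waveform produced negative pressure")
    if summary.P <= 0:
        raise StudyError("reference summary must come from a positive pressure")
    scale = p / summary.P
    return pd.DataFrame(
        {
            "t": t,
            "pressure_kpa": p,
            "sigma_cr": summary.sigma_cr * scale,
            "D_max": summary.D_max * scale,
        }
    )


def validate_homogeneous_vs_lipid(
    stenoses: Sequence[float] = (0.70, 0.75, 0.80, 0.90),
    level: str = "medium",
    P: float = 14.6,
    E_lp: float = 1.0,
) -> pd.DataFrame:
    """Normalized peak circumferential stress vs stenosis, with and
    without a lipid pool (the validation-style comparison)."""
    rows = []
    for s in stenoses:
        res_a = solve_model(PlaqueGeometrySpec(stenosis=s, has_lipid=False), level, P=P)
        d_fc = model_b_cap_thickness(s)
        res_b = solve_model(
            PlaqueGeometrySpec(stenosis=s, d_fc=d_fc), level, E_lp=E_lp, P=P
        )
        rows.append(
            dict(
                stenosis=s,
                d_fc_lipid_model=d_fc,
                sigma_over_P_homogeneous=res_a.summary.sigma_over_P,
                sigma_over_P_lipid=res_b.summary.sigma_over_P,
            )
        )
    return pd.DataFrame(rows)
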