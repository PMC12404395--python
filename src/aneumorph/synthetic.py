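"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* :func:`make_mesh` — labeled sac/vessel surfaces with analytic oracles
  (icospheres, ellipsoids, lobulated sacs, a hemispherical sac with a
  parent tube), standing in for segmented angiography geometries.
* :func:`make_field_series` — one cardiac cycle (1 s, 100 increments by
  default) of per-vertex traction/pressure/displacement/stress with a
  high-resolution quadrature oracle for the oscillatory shear index.
* :func:`make_cohort` — three-group cohort tables (ruptured n=58,
  unruptured n=52, stable n=15 by default) with lognormal marginals
  coupled through a Gaussian copula, plus an independent ruptured-only
  validation table (n=25).  Default group means and the default
  correlation structure emulate reported cohort-level statistics for
  ruptured / unruptured / stable anterior-communicating-artery aneurysms;
  dispersions are not published for such cohorts, so the coefficient of
  variation is a free knob (default 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
import trimesh
from scipy.special import sph_harm_y

from .fields import SurfaceFieldSeries
from .mesh import NECK, PARENT, SAC, OstiumDefinition, TriSurfaceMesh
from .workflow import PARAMETERS

__all__ = [
    "ShapeSpec",
    "CohortSpec",
    "DEFAULT_GROUP_MEANS",
    "OBSERVED_CORRELATIONS",
    "default_correlation",
    "make_mesh",
    "make_field_series",
    "make_cohort",
    "ellipsoid_gln_quadrature",
]

SHAPE_KINDS = ("icosphere", "ellipsoid", "lobulated-sac", "hemisphere-on-cylinder")


@dataclass
class ShapeSpec:
    """Recipe for a synthetic sac geometry (dimensions in mm)."""

    kind: str = "icosphere"
    radius: float = 2.0
    semiaxes: tuple[float, float, float] = (2.0, 1.0, 1.0)
    amplitude: float = 0.3          # lobulation amplitude, fraction of radius
    subdivisions: int = 4
    parent_radius: float = 1.5      # hemisphere-on-cylinder only
    parent_length: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.subdivisions < 1:
            raise ValueError("subdivisions must be >= 1")
        if self.radius <= 0 or min(self.semiaxes) <= 0 or self.parent_radius <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1) (fraction of radius)")


def _icosphere(radius: float, subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, dtype=np.float64), np.asarray(m.faces, dtype=np.int64)


def _lobulation_field(dirs: np.ndarray, seed: int) -> np.ndarray:
    """Smooth random radial modulation in [-1, 1] from degree-3 harmonics."""
    rng = np.random.default_rng(seed)
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    f = np.zeros(len(dirs))
    for m in range(-3, 4):
        c = rng.normal()
        f += c * np.real(sph_harm_y(3, m, theta, phi))
    amax = np.abs(f).max()
    return f / amax if amax > 0 else f


def _uv_hemisphere(radius: float, n_rings: int, n_seg: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper hemisphere with its equator ring exactly at z = 0.

    Returns (vertices, faces, equator_loop); outward winding.
    """
    verts = [np.array([0.0, 0.0, radius])]
    for j in range(1, n_rings + 1):
        th = j * (np.pi / 2) / n_rings
        for k in range(n_seg):
            ph = 2 * np.pi * k / n_seg
            verts.append(radius * np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            ))
    verts = np.asarray(verts)
    faces = []
    ring = lambda j, k: 1 + (j - 1) * n_seg + (k % n_seg)
    for k in range(n_seg):  # pole cap
        faces.append([0, ring(1, k), ring(1, k + 1)])
    for j in range(1, n_rings):
        for k in range(n_seg):
            a, b = ring(j, k), ring(j, k + 1)
            c, d = ring(j + 1, k), ring(j + 1, k + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    equator = np.array([ring(n_rings, k) for k in range(n_seg)], dtype=np.int64)
    return verts, np.asarray(faces, dtype=np.int64), equator


def _tube(radius: float, length: float, n_rings: int, n_seg: int,
          offset: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Open cylinder along z, outward winding, translated by ``offset``."""
    verts = []
    for j in range(n_rings):
        z = length * j / (n_rings - 1)
        for k in range(n_seg):
            ph = 2 * np.pi * k / n_seg
            verts.append([radius * np.cos(ph), radius * np.sin(ph), z])
    verts = np.asarray(verts) + offset
    faces = []
    ring = lambda j, k: j * n_seg + (k % n_seg)
    for j in range(n_rings - 1):
        for k in range(n_seg):
            a, b = ring(j, k), ring(j, k + 1)
            c, d = ring(j + 1, k), ring(j + 1, k + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    return verts, np.asarray(faces, dtype=np.int64)


def make_mesh(spec: ShapeSpec) -> tuple[TriSurfaceMesh, OstiumDefinition | None, dict]:
    """Build a labeled surface mesh plus closed-form oracle values.

    The oracle dict carries whatever the shape admits analytically:
    ``area``, ``volume``, ``K`` (constant Gaussian curvature), ``gln``,
    ``S``, ``AR``, ``VOR``, ``neck_width``, ``parent_diameter``.
    Deterministic per (spec, seed).
    """
    if spec.kind == "icosphere":
        r = spec.radius
        v, f = _icosphere(r, spec.subdivisions)
        mesh = TriSurfaceMesh(v, f, np.full(len(v), SAC))
        oracle = {"area": 4 * np.pi * r**2, "volume": 4 * np.pi * r**3 / 3,
                  "K": 1 / r**2, "gln": 1.0, "S": 2 * r}
        return mesh, None, oracle

    if spec.kind == "ellipsoid":
        a, b, c = spec.semiaxes
        v, f = _icosphere(1.0, spec.subdivisions)
        v = v * np.array([a, b, c])
        mesh = TriSurfaceMesh(v, f, np.full(len(v), SAC))
        A, gln_val = ellipsoid_gln_quadrature(a, b, c)
        oracle = {"area": A, "volume": 4 * np.pi * a * b * c / 3, "gln": gln_val}
        return mesh, None, oracle

    if spec.kind == "lobulated-sac":
        r = spec.radius
        v, f = _icosphere(r, spec.subdivisions)
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        v = v * (1.0 + spec.amplitude * _lobulation_field(dirs, spec.seed))[:, None]
        mesh = TriSurfaceMesh(v, f, np.full(len(v), SAC))
        oracle = {"base_radius": r, "base_gln": 1.0}
        return mesh, None, oracle

    # hemisphere-on-cylinder: hemispherical sac + disjoint parent tube
    r = spec.radius
    n = max(8, 4 * spec.subdivisions)
    hv, hf, equator = _uv_hemisphere(r, n_rings=n, n_seg=2 * n)
    offset = np.array([3 * r + 2 * spec.parent_radius, 0.0, 0.0])
    tv, tf = _tube(spec.parent_radius, spec.parent_length, n_rings=max(4, n // 2),
                   n_seg=2 * n, offset=offset)
    verts = np.vstack([hv, tv])
    faces = np.vstack([hf, tf + len(hv)])
    labels = np.concatenate([
        np.full(len(hv), SAC), np.full(len(tv), PARENT),
    ])
    labels[equator] = NECK
    mesh = TriSurfaceMesh(verts, faces, labels)
    ostium = OstiumDefinition(
        boundary_loop=equator,
        plane_point=np.zeros(3),
        plane_unit_normal=np.array([0.0, 0.0, 1.0]),
    )
    oracle = {
        "volume": 2 * np.pi * r**3 / 3,
        "S": 2 * r,
        "AR": 0.5,
        "VOR": 2 * r / 3,
        "neck_width": 2 * r,
        "parent_diameter": 2 * spec.parent_radius,
        "height": r,
    }
    return mesh, ostium, oracle


def ellipsoid_gln_quadrature(a: float, b: float, c: float,
                             n_theta: int = 400, n_phi: int = 800) -> tuple[float, float]:
    """(area, GLN) of an analytic ellipsoid by tensor-grid quadrature.

    Gaussian curvature of the ellipsoid is
    ``K = 1 / (a^2 b^2 c^2 (x^2/a^4 + y^2/b^4 + z^2/c^4)^2)``; the surface
    element comes from the spherical parameterisation.  Independent of any
    mesh discretisation.
    """
    th = np.linspace(0, np.pi, n_theta)
    ph = np.linspace(0, 2 * np.pi, n_phi)
    T, P = np.meshgrid(th, ph, indexing="ij")
    x = a * np.sin(T) * np.cos(P)
    y = b * np.sin(T) * np.sin(P)
    z = c * np.cos(T)
    # surface element |r_theta x r_phi|
    rt = np.stack([a * np.cos(T) * np.cos(P), b * np.cos(T) * np.sin(P),
                   -c * np.sin(T)], axis=-1)
    rp = np.stack([-a * np.sin(T) * np.sin(P), b * np.sin(T) * np.cos(P),
                   np.zeros_like(T)], axis=-1)
    dA = np.linalg.norm(np.cross(rt, rp), axis=-1)
    h = x**2 / a**4 + y**2 / b**4 + z**2 / c**4
    with np.errstate(divide="ignore", invalid="ignore"):
        K = 1.0 / (a**2 * b**2 * c**2 * h**2)
    K = np.nan_to_num(K, nan=0.0, posinf=0.0)
    integ2 = np.trapezoid(np.trapezoid(K**2 * dA, ph, axis=1), th)
    area = np.trapezoid(np.trapezoid(dA, ph, axis=1), th)
    return float(area), float(np.sqrt(area * integ2) / (4 * np.pi))


# ---------------------------------------------------------------------------
# surface-field series
# ---------------------------------------------------------------------------

WAVEFORMS = ("steady", "reversing", "non-reversing", "pulsatile")


def _field_model(mesh: TriSurfaceMesh, waveform: str, seed: int, period: float):
    """Analytic per-vertex field definitions, samplable on any time grid."""
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    sac = mesh.label_mask(SAC, NECK)
    # unit tangent-ish directions and magnitudes; sac wall is loaded harder
    d1 = rng.normal(size=(n, 3))
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    d2 = rng.normal(size=(n, 3))
    d2 -= (np.einsum("ij,ij->i", d2, d1))[:, None] * d1
    d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
    mag = rng.uniform(0.5, 1.5, size=n) * np.where(sac, 4.0, 2.0)      # Pa
    mix = rng.uniform(0.0, 1.0, size=n)
    disp0 = rng.uniform(0.5, 1.0, size=n) * np.where(sac, 0.25, 0.1)   # mm
    s_base = rng.normal(scale=80.0, size=(n, 6)) + np.array(            # kPa
        [120.0, 120.0, 120.0, 30.0, 30.0, 30.0]
    )
    s_base *= np.where(sac, 1.5, 1.0)[:, None]
    p0, dp = 8000.0, 4000.0                                             # Pa

    w = 2 * np.pi / period

    def a_t(t):
        if waveform == "steady":
            return np.ones_like(t)
        if waveform == "reversing":
            return np.sin(w * t)
        if waveform == "non-reversing":
            return 1.0 + 0.5 * np.cos(w * t)
        return 1.0 + 0.7 * np.cos(w * t) + 0.3 * np.sin(2 * w * t)      # pulsatile

    def b_t(t):
        if waveform == "pulsatile":
            return 0.8 * np.sin(w * t)
        return np.zeros_like(t)

    def traction(times):
        a, b = a_t(times), b_t(times)
        return (mag[None, :, None]
                * (d1[None] * a[:, None, None]
                   + (mix[:, None] * d2)[None] * b[:, None, None]))

    def pressure(times):
        wave = 0.55 + 0.45 * np.sin(w * times - 0.3)
        spatial = 1.0 + 0.05 * np.tanh(mesh.vertices[:, 2] / 10.0)
        return p0 * spatial[None, :] + dp * wave[:, None]

    def displacement(times):
        wave = 0.6 + 0.4 * np.sin(w * times - 0.2)
        return disp0[None, :] * wave[:, None]

    def stress(times):
        wave = 0.7 + 0.3 * np.sin(w * times - 0.2)
        return s_base[None, :, :] * wave[:, None, None]

    return traction, pressure, displacement, stress


def make_field_series(
    mesh: TriSurfaceMesh,
    waveform: str = "pulsatile",
    seed: int = 0,
    n_steps: int = 100,
    period: float = 1.0,
) -> tuple[SurfaceFieldSeries, dict]:
    """One cardiac cycle of synthetic surface fields plus an OSI oracle.

    The defaults mimic a 1 s cycle (60 bpm) discretised into 100 temporal
    increments.  The oracle OSI is evaluated on a 20001-point grid of the
    same analytic field — a quadrature refinement of the defining
    integrals, independent of the pipeline's reduction code.
    """
    if waveform not in WAVEFORMS:
        raise ValueError(f"unknown waveform {waveform!r}")
    if n_steps < 3:
        raise ValueError("need at least 3 time samples")
    traction, pressure, displacement, stress = _field_model(mesh, waveform, seed, period)
    times = np.linspace(0.0, period, n_steps)
    series = SurfaceFieldSeries(
        times=times,
        traction=traction(times),
        pressure=pressure(times),
        displacement=displacement(times),
        stress=stress(times),
    )
    dense = np.linspace(0.0, period, 20001)
    tau = traction(dense)
    num = np.linalg.norm(np.trapezoid(tau, x=dense, axis=0), axis=1)
    den = np.trapezoid(np.linalg.norm(tau, axis=2), x=dense, axis=0)
    osi = np.zeros(mesh.n_vertices)
    nz = den > 0
    osi[nz] = 0.5 * (1 - num[nz] / den[nz])
    return series, {"osi": np.clip(osi, 0.0, 0.5)}


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: calibration means per risk stratum (units as in the cohort CSV:
#: Pa for WSS, kPa for pressure and stress, mm/mm^3 for S and V)
DEFAULT_GROUP_MEANS: dict[str, dict[str, float]] = {
    "ruptured": {
        "WSS_rel_max": 0.514, "WSS_max": 6.127, "WSS_av": 0.244,
        "OSI_max": 0.370, "OSI_av": 0.062, "OSI_min": 1.536e-3,
        "P_max": 11.115, "P_av": 5.784, "P_min": 3.712,
        "D_rel_max": 2.421, "MISES_max": 250.3, "MISES_av": 75.27,
        "S": 6.929, "AR": 1.092, "SR": 3.711, "VOR": 4.738,
        "V": 75.29, "GLN": 2.164,
    },
    "unruptured": {
        "WSS_rel_max": 0.363, "WSS_max": 4.231, "WSS_av": 0.223,
        "OSI_max": 0.349, "OSI_av": 0.056, "OSI_min": 2.974e-3,
        "P_max": 9.236, "P_av": 5.621, "P_min": 3.944,
        "D_rel_max": 2.037, "MISES_max": 218.7, "MISES_av": 70.53,
        "S": 6.833, "AR": 0.957, "SR": 3.295, "VOR": 4.516,
        "V": 96.44, "GLN": 1.651,
    },
    "stable": {
        "WSS_rel_max": 0.260, "WSS_max": 2.590, "WSS_av": 0.260,
        "OSI_max": 0.289, "OSI_av": 0.062, "OSI_min": 7.011e-3,
        "P_max": 9.169, "P_av": 5.530, "P_min": 3.969,
        "D_rel_max": 1.445, "MISES_max": 174.1, "MISES_av": 60.67,
        "S": 4.448, "AR": 0.655, "SR": 2.157, "VOR": 1.474,
        "V": 18.63, "GLN": 0.927,
    },
}

#: pairwise Pearson correlations observed in AComA cohorts (within the
#: hemodynamic, structural and morphological parameter blocks); pairs not
#: listed default to a moderate background correlation.
OBSERVED_CORRELATIONS: dict[tuple[str, str], float] = {
    ("WSS_rel_max", "WSS_max"): 0.989,
    ("WSS_rel_max", "OSI_min"): -0.016,
    ("WSS_max", "OSI_min"): -0.016,
    ("D_rel_max", "MISES_max"): 0.234,
    ("S", "AR"): 0.502, ("S", "SR"): 0.799, ("S", "VOR"): 0.735,
    ("S", "V"): 0.823, ("S", "GLN"): 0.683,
    ("AR", "SR"): 0.448, ("AR", "VOR"): 0.767, ("AR", "V"): 0.387,
    ("AR", "GLN"): 0.448,
    ("SR", "VOR"): 0.491, ("SR", "V"): 0.661, ("SR", "GLN"): 0.580,
    ("VOR", "V"): 0.793, ("VOR", "GLN"): 0.451,
    ("V", "GLN"): 0.445,
}


def default_correlation(background: float = 0.3) -> pd.DataFrame:
    """Default Gaussian-copula correlation matrix over all 18 parameters."""
    n = len(PARAMETERS)
    R = np.full((n, n), background)
    np.fill_diagonal(R, 1.0)
    idx = {p: i for i, p in enumerate(PARAMETERS)}
    for (a, b), r in OBSERVED_CORRELATIONS.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return pd.DataFrame(R, index=PARAMETERS, columns=PARAMETERS)


@dataclass
class CohortSpec:
    """Recipe for a synthetic three-group cohort."""

    group_sizes: dict[str, int] = dfield(
        default_factory=lambda: {"ruptured": 58, "unruptured": 52, "stable": 15}
    )
    means: dict[str, dict[str, float]] = dfield(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_GROUP_MEANS.items()}
    )
    cv: float = 0.4
    correlation: pd.DataFrame | None = None
    n_validation: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("coefficient of variation must be non-negative")
        for g, m in self.means.items():
            if any(v <= 0 for v in m.values()):
                raise ValueError(f"group {g} has a non-positive mean")


def _lognormal_copula_draw(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    cv: float,
    chol: np.ndarray,
) -> np.ndarray:
    """n draws of lognormal marginals (given means and common CV) coupled
    through a Gaussian copula with Cholesky factor ``chol``."""
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    mu = np.log(means) - sigma2 / 2.0
    z = rng.standard_normal((n, len(means))) @ chol.T
    return np.exp(mu[None, :] + sigma * z)


def make_cohort(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, validation) tables, deterministic per seed.

    The cohort has columns ``id``, ``group`` and the 18 parameters; the
    validation table is drawn from the ruptured generative distribution
    (no group column).  In the CV -> 0 limit every draw equals its group
    mean.
    """
    spec = spec or CohortSpec()
    corr = spec.correlation if spec.correlation is not None else default_correlation()
    R = corr.loc[PARAMETERS, PARAMETERS].to_numpy(dtype=np.float64)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("copula correlation matrix is not positive definite") from e
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group in ("ruptured", "unruptured", "stable"):
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        means = np.array([spec.means[group][p] for p in PARAMETERS])
        X = _lognormal_copula_draw(rng, n, means, spec.cv, chol)
        df = pd.DataFrame(X, columns=PARAMETERS)
        df.insert(0, "group", group)
        df.insert(0, "id", [f"{group[0]}{i:03d}" for i in range(n)])
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    means_r = np.array([spec.means["ruptured"][p] for p in PARAMETERS])
    Xv = _lognormal_copula_draw(rng, spec.n_validation, means_r, spec.cv, chol)
    validation = pd.DataFrame(Xv, columns=PARAMETERS)
    validation.insert(0, "id", [f"v{i:03d}" for i in range(spec.n_validation)])
    return cohort, validation
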