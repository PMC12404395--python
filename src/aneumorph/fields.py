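"""Reduction of time-resolved surface fields to hemodynamic and structural
wall parameters.

A :class:`SurfaceFieldSeries` holds one cardiac cycle of per-vertex wall
traction (Pa), relative pressure (Pa), displacement magnitude (mm) and
Cauchy stress (kPa, Voigt order xx, yy, zz, xy, yz, zx).  The summaries
follow the conventions of fluid-structure post-processing:

* WSS (wall shear stress) is the traction magnitude; maxima are taken over
  the cycle then over the sac, averages are trapezoidal time-means then
  spatial means.
* OSI (oscillatory shear index) measures directional reversal of the
  traction over the cycle, ``0.5 * (1 - ||int tau dt|| / int ||tau|| dt)``,
  bounded in [0, 0.5].
* Relative quantities divide a sac value by the corresponding
  parent-vessel value (``x_rel = x_sac / x_parent``).
* Pressures are shifted so the minimum over the whole surface and cycle is
  zero, and reported in kPa.
* Wall stress is summarised by the von Mises equivalent stress.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .mesh import TriSurfaceMesh, PARENT, SAC

__all__ = [
    "SurfaceFieldSeries",
    "HemoStructSummary",
    "FieldError",
    "osi_field",
    "wss_summaries",
    "pressure_summaries",
    "relative_ratio",
    "von_mises",
    "summarize",
]


class FieldError(ValueError):
    """Raised when a surface-field series is malformed."""


@dataclass
class SurfaceFieldSeries:
    """One cardiac cycle of per-vertex surface fields.

    Attributes
    ----------
    times : (T,) array, seconds, strictly increasing
    traction : (T, N, 3) array, Pa
    pressure : (T, N) array, Pa (relative)
    displacement : (T, N) array, mm (magnitude)
    stress : (T, N, 6) array, kPa, Voigt (xx, yy, zz, xy, yz, zx)
    """

    times: np.ndarray
    traction: np.ndarray
    pressure: np.ndarray
    displacement: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.traction = np.asarray(self.traction, dtype=np.float64)
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.stress = np.asarray(self.stress, dtype=np.float64)

    @property
    def n_vertices(self) -> int:
        return self.traction.shape[1]

    def validate(self) -> None:
        T = len(self.times)
        if T < 3:
            raise FieldError("need at least 3 time samples")
        if (np.diff(self.times) <= 0).any():
            raise FieldError("times must be strictly increasing")
        for name, arr, shape in (
            ("traction", self.traction, (T, None, 3)),
            ("pressure", self.pressure, (T, None)),
            ("displacement", self.displacement, (T, None)),
            ("stress", self.stress, (T, None, 6)),
        ):
            if arr is None:
                raise FieldError(f"missing field: {name}")
            if arr.ndim != len(shape) or arr.shape[0] != T:
                raise FieldError(f"field {name} has shape {arr.shape}, expected {shape}")
            if len(shape) == 3 and arr.shape[2] != shape[2]:
                raise FieldError(f"field {name} has shape {arr.shape}, expected {shape}")
            if np.isnan(arr).any():
                raise FieldError(f"field {name} contains NaNs")
        ns = {self.traction.shape[1], self.pressure.shape[1],
              self.displacement.shape[1], self.stress.shape[1]}
        if len(ns) != 1:
            raise FieldError(f"fields disagree on vertex count: {sorted(ns)}")


@dataclass
class HemoStructSummary:
    """Scalar hemodynamic and structural summaries of one aneurysm."""

    WSS_max: float       # Pa, peak over cycle then sac
    WSS_av: float        # Pa, cycle-average then sac mean
    WSS_rel_max: float   # sac/parent peak ratio, dimensionless
    OSI_max: float
    OSI_av: float
    OSI_min: float
    P_max: float         # kPa, after relative shift
    P_av: float          # kPa
    P_min: float         # kPa
    D_rel_max: float     # sac/parent peak displacement ratio
    MISES_max: float     # kPa
    MISES_av: float      # kPa

    def as_dict(self) -> dict:
        return asdict(self)


def osi_field(series: SurfaceFieldSeries) -> np.ndarray:
    """Per-vertex oscillatory shear index.

    ``OSI_i = 0.5 * (1 - ||int_0^T tau_i dt|| / int_0^T ||tau_i|| dt)``
    with trapezoidal integration on the (possibly non-uniform) time grid.
    Vertices where the traction vanishes identically get OSI = 0.
    """
    if len(series.times) < 3:
        raise FieldError("need at least 3 time samples for OSI")
    t = series.times
    mean_vec = np.trapezoid(series.traction, x=t, axis=0)       # (N, 3)
    mag_int = np.trapezoid(
        np.linalg.norm(series.traction, axis=2), x=t, axis=0
    )                                                           # (N,)
    osi = np.zeros(series.n_vertices)
    nz = mag_int > 0
    osi[nz] = 0.5 * (1.0 - np.linalg.norm(mean_vec[nz], axis=1) / mag_int[nz])
    # guard tiny negative round-off
    return np.clip(osi, 0.0, 0.5)


def _check_region(mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FieldError(f"empty {what} region")
    return mask


def wss_summaries(series: SurfaceFieldSeries, sac_mask: np.ndarray) -> tuple[float, float]:
    """(WSS_max, WSS_av) over the sac, Pa.

    WSS_max: peak traction magnitude over the cycle, maximised over sac
    vertices.  WSS_av: trapezoidal time-average of the magnitude, averaged
    over sac vertices.
    """
    sac = _check_region(sac_mask, "sac")
    mag = np.linalg.norm(series.traction[:, sac, :], axis=2)    # (T, n_sac)
    T = series.times[-1] - series.times[0]
    w_max = float(mag.max())
    w_av = float(np.trapezoid(mag, x=series.times, axis=0).mean() / T)
    return w_max, w_av


def pressure_summaries(
    series: SurfaceFieldSeries, sac_mask: np.ndarray
) -> tuple[float, float, float]:
    """(P_max, P_av, P_min) in kPa over the sac.

    The pressure field is first shifted so its global minimum (all
    vertices, all times) is zero, then extrema and the trapezoidal
    time-mean/spatial-mean are taken over the sac.
    """
    sac = _check_region(sac_mask, "sac")
    p = series.pressure - series.pressure.min()
    psac = p[:, sac]
    T = series.times[-1] - series.times[0]
    p_av = float(np.trapezoid(psac, x=series.times, axis=0).mean() / T)
    return float(psac.max()) / 1e3, p_av / 1e3, float(psac.min()) / 1e3


def relative_ratio(sac_value: float, parent_value: float) -> float:
    """Sac-to-parent ratio ``x_sac / x_parent`` (dimensionless)."""
    if parent_value <= 0:
        raise FieldError(f"parent reference value must be positive, got {parent_value}")
    return sac_value / parent_value


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of Voigt tensors (..., 6), same units.

    ``sqrt(0.5*((sxx-syy)^2 + (syy-szz)^2 + (szz-sxx)^2) + 3*(sxy^2+syz^2+szx^2))``
    """
    s = np.asarray(stress, dtype=np.float64)
    sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


def summarize(
    series: SurfaceFieldSeries,
    mesh: TriSurfaceMesh,
) -> HemoStructSummary:
    """Assemble the full hemodynamic/structural summary for one aneurysm.

    Sac summaries use sac-labeled vertices; relative ratios use the
    parent-labeled vertices as reference.
    """
    series.validate()
    if series.n_vertices != mesh.n_vertices:
        raise FieldError(
            f"field series has {series.n_vertices} vertices, mesh has {mesh.n_vertices}"
        )
    sac = _check_region(mesh.label_mask(SAC), "sac")
    parent = _check_region(mesh.label_mask(PARENT), "parent")

    wss_max, wss_av = wss_summaries(series, sac)
    parent_wss_max = float(np.linalg.norm(series.traction[:, parent, :], axis=2).max())
    p_max, p_av, p_min = pressure_summaries(series, sac)

    osi = osi_field(series)[sac]
    d_sac = float(series.displacement[:, sac].max())
    d_parent = float(series.displacement[:, parent].max())

    vm = von_mises(series.stress[:, sac, :])                    # (T, n_sac)
    T = series.times[-1] - series.times[0]
    vm_av = float(np.trapezoid(vm, x=series.times, axis=0).mean() / T)

    return HemoStructSummary(
        WSS_max=wss_max,
        WSS_av=wss_av,
        WSS_rel_max=relative_ratio(wss_max, parent_wss_max),
        OSI_max=float(osi.max()),
        OSI_av=float(osi.mean()),
        OSI_min=float(osi.min()),
        P_max=p_max,
        P_av=p_av,
        P_min=p_min,
        D_rel_max=relative_ratio(d_sac, d_parent),
        MISES_max=float(vm.max()),
        MISES_av=vm_av,
    )
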