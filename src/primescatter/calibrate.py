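"""Diameter calibration against measured dose and agreement metrics.

The effective block diameter for a device/energy pair is obtained by
least-squares fitting the forward model to the measured dose matrix inside
the modulated region (within +/- 3.5 cm of central axis, 0.5 cm depth to
slightly beyond R90).  Agreement is reported as the RMS dose difference and
the 2%/2 mm pass rate (dose difference in percent of given dose, global
normalization, or distance-to-agreement with linear interpolation of the
calculated distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import maximum_filter, minimum_filter
from scipy.optimize import minimize_scalar

from .device import PrimeDevice
from .fluence import BeamSpec, DoseGrid, ForwardModel

__all__ = [
    "RegionSpec",
    "AgreementReport",
    "region_for_energy",
    "rms_percent",
    "pass_rate_2pct_2mm",
    "optimize_dmod",
]


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular evaluation region in the (y, z) dose plane, cm."""

    y_half_width: float = 3.5
    z_min: float = 0.5
    z_max: float = 2.0

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError("region requires z_min < z_max")
        if not self.y_half_width > 0:
            raise ValueError("region requires positive y half-width")

    def mask(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Boolean (len(z), len(y)) mask of in-region grid points."""
        tol = 1e-9
        my = np.abs(np.asarray(y, float)) <= self.y_half_width + tol
        mz = (np.asarray(z, float) >= self.z_min - tol) & (
            np.asarray(z, float) <= self.z_max + tol
        )
        return np.outer(mz, my)


def region_for_energy(e_p0: float) -> RegionSpec:
    """Modulated evaluation region for a commissioned beam energy."""
    from .reference import MODULATED_REGION_ZMAX

    best = min(MODULATED_REGION_ZMAX, key=lambda e: abs(e - e_p0))
    if abs(best - e_p0) > 0.5:
        raise KeyError(f"no modulated region defined near E_p0 = {e_p0} MeV")
    return RegionSpec(z_max=MODULATED_REGION_ZMAX[best])


@dataclass
class AgreementReport:
    """Agreement between a calculated and a measured dose plane."""

    rms_percent: float
    pass_rate: float
    n_points: int
    fail_mask: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "rms_percent": self.rms_percent,
            "pass_rate": self.pass_rate,
            "n_points": self.n_points,
        }


def _align(calc: DoseGrid, meas: DoseGrid) -> np.ndarray:
    """Calculated dose sampled on the measured grid (resampled if needed)."""
    if (
        calc.y.size == meas.y.size
        and calc.z.size == meas.z.size
        and np.allclose(calc.y, meas.y, atol=1e-9)
        and np.allclose(calc.z, meas.z, atol=1e-9)
    ):
        return calc.values
    interp = RegularGridInterpolator(
        (calc.z, calc.y), calc.values, method="linear", bounds_error=True
    )
    zz, yy = np.meshgrid(meas.z, meas.y, indexing="ij")
    return interp(np.column_stack([zz.ravel(), yy.ravel()])).reshape(zz.shape)


def rms_percent(calc: DoseGrid, meas: DoseGrid, region: RegionSpec) -> float:
    """Root-mean-square calculated-minus-measured dose over the region.

    Both grids are in percent of given dose; the calculated grid is
    resampled onto the measured grid if their coordinates differ.
    """
    cv = _align(calc, meas)
    m = region.mask(meas.y, meas.z)
    if not m.any():
        raise ValueError("evaluation region contains no grid points")
    diff = cv[m] - meas.values[m]
    return float(np.sqrt(np.mean(diff**2)))


def pass_rate_2pct_2mm(
    calc: DoseGrid,
    meas: DoseGrid,
    region: RegionSpec,
    dose_tol: float = 2.0,
    dta_tol: float = 0.2,
    *,
    fine_spacing: float = 0.02,
) -> AgreementReport:
    """Dose-difference-or-DTA pass rate with the measured grid as reference.

    A measured point passes if the calculated dose at that point agrees
    within ``dose_tol`` percent of given dose (global normalization), or if
    the calculated distribution attains the measured value somewhere within
    Euclidean distance ``dta_tol`` cm in the (y, z) plane.  Attainment is
    decided on a linearly interpolated calculated grid: since the
    interpolant is continuous and the search disc connected, the value is
    attained iff it lies between the local minimum and maximum over the
    disc.
    """
    dy, dz = meas.spacing()
    if max(dy, dz) > dta_tol / 2 + 1e-12:
        raise ValueError(
            f"grid spacing ({dy}, {dz}) cm too coarse for a {dta_tol} cm DTA search; "
            "need spacing <= dta_tol / 2"
        )
    cv = _align(calc, meas)
    m = region.mask(meas.y, meas.z)
    if not m.any():
        raise ValueError("evaluation region contains no grid points")

    dose_pass = np.abs(cv - meas.values) <= dose_tol + 1e-12

    # upsample the calculated plane so the DTA disc is finely sampled
    ky = max(1, int(round(dy / fine_spacing)))
    kz = max(1, int(round(dz / fine_spacing)))
    yf = np.linspace(meas.y[0], meas.y[-1], (meas.y.size - 1) * ky + 1)
    zf = np.linspace(meas.z[0], meas.z[-1], (meas.z.size - 1) * kz + 1)
    interp = RegularGridInterpolator((meas.z, meas.y), cv, method="linear")
    zz, yy = np.meshgrid(zf, yf, indexing="ij")
    fine = interp(np.column_stack([zz.ravel(), yy.ravel()])).reshape(zz.shape)

    # circular footprint of radius dta_tol in fine-grid units
    fy, fz = dy / ky, dz / kz
    ry, rz = int(math.floor(dta_tol / fy + 1e-9)), int(math.floor(dta_tol / fz + 1e-9))
    oy, oz = np.meshgrid(np.arange(-ry, ry + 1) * fy, np.arange(-rz, rz + 1) * fz, indexing="xy")
    footprint = (oy**2 + oz**2) <= dta_tol**2 + 1e-12
    lo = minimum_filter(fine, footprint=footprint, mode="nearest")
    hi = maximum_filter(fine, footprint=footprint, mode="nearest")
    lo = lo[::kz, ::ky]
    hi = hi[::kz, ::ky]
    dta_pass = (lo <= meas.values + 1e-12) & (meas.values <= hi + 1e-12)

    passed = dose_pass | dta_pass
    n = int(m.sum())
    rate = 100.0 * float(passed[m].sum()) / n
    fail = ~passed & m
    return AgreementReport(
        rms_percent=rms_percent(calc, meas, region),
        pass_rate=rate,
        n_points=n,
        fail_mask=fail,
    )


def optimize_dmod(
    meas: DoseGrid,
    device: PrimeDevice,
    beam: BeamSpec,
    region: RegionSpec,
    bounds: tuple[float, float],
    *,
    pdd: Callable | None = None,
    sigma_device: float | None = None,
    model: ForwardModel | None = None,
    coarse_step: float = 0.005,
    xtol: float = 1e-4,
) -> float:
    """Least-squares effective block diameter against a measured dose plane.

    Minimizes the sum of squared dose differences over the region for a
    single diameter shared by all blocks, with a coarse pre-scan
    (``coarse_step`` cm) to locate the basin followed by bounded scalar
    minimization to ``xtol`` cm.  ``bounds`` are insert-plane diameters in
    cm and must lie inside (0, r).
    """
    lo, hi = bounds
    if not 0 < lo < hi < device.r:
        raise ValueError(f"bounds must satisfy 0 < lo < hi < r={device.r}, got {bounds}")
    if model is None:
        if pdd is None:
            from .synthetic import gen_pdd

            pdd = gen_pdd(beam)
        if sigma_device is None:
            from .reference import calibrated_sigma_x

            sigma_device = calibrated_sigma_x(beam.e_p0)
        model = ForwardModel(device=device, beam=beam, pdd=pdd, sigma_device=sigma_device)

    mask = region.mask(meas.y, meas.z)
    if not mask.any():
        raise ValueError("evaluation region contains no grid points")
    zi = mask.any(axis=1)
    yi = mask.any(axis=0)
    y_r, z_r = meas.y[yi], meas.z[zi]
    target = meas.values[np.ix_(zi, yi)]

    def sse(d: float) -> float:
        calc = model.oar(d, y_r, z_r) * np.asarray(model.pdd(z_r), float)[:, None]
        v = float(np.sum((calc - target) ** 2))
        if not math.isfinite(v):
            raise RuntimeError(f"non-finite objective at d = {d}")
        return v

    # coarse scan guards against non-unimodality before the bounded search
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    vals = [sse(d) for d in grid]
    i = int(np.argmin(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, grid.size - 1)]
    if blo == bhi:
        return float(grid[i])
    res = minimize_scalar(sse, bounds=(blo, bhi), method="bounded", options={"xatol": xtol})
    if not res.success:
        raise RuntimeError(f"diameter optimization failed: {res.message}")
    return float(res.x)
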