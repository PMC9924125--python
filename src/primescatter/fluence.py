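"""Forward fluence and dose model under a PRIME device.

Each island block is represented by a small square pencil beam of side equal
to its equivalent square side; its Gaussian-blurred planar fluence is
subtracted from the open-field fluence.  A dose plane (in-plane position x
depth) is composed as PDD(z) x OAR(y, z), with 100% the foam-only
central-axis maximum.

This is a single-redefinition Gaussian pencil transport: the lateral spread
at depth z in water is modeled as sigma(z)^2 = sigma_device^2 +
sigma_water(z)^2 with a configurable power law for the in-water term.  It is
not the clinical pencil-beam-redefinition engine, which redefines pencils at
stepped planes; it captures the block-deficit physics that the diameter
calibration exercises.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.special import erf

from .device import PrimeDevice, project_between_planes
from .scatter import DmodCoefficients, d_modified, equivalent_square_side, inscatter_fraction

__all__ = [
    "BeamSpec",
    "FluenceMap",
    "DoseGrid",
    "TabulatedPDD",
    "blurred_step",
    "device_fluence",
    "fluence_profile",
    "compose_dose",
    "sigma_water",
    "ForwardModel",
    "periodic_mean_transmission",
]

_SQRT2 = math.sqrt(2.0)

DiameterMode = Literal["nominal", "in_scatter", "modified"]


@dataclass(frozen=True)
class BeamSpec:
    """Electron beam description.

    ``e_p0`` is the most probable energy at the surface (MeV); ``r100``,
    ``r90`` and ``rp`` are the central-axis depth of maximum dose, depth of
    the distal 90% and practical range (cm); ``x_ray_background`` is the
    bremsstrahlung tail level in percent of given dose.
    """

    e_p0: float
    ssd: float = 100.0
    r100: float = 2.0
    r90: float = 3.0
    rp: float = 5.0
    x_ray_background: float = 1.0

    def __post_init__(self) -> None:
        if self.e_p0 <= 0:
            raise ValueError("beam energy must be positive")
        if not 0 < self.r100 < self.r90 < self.rp:
            raise ValueError(
                f"depth-dose landmarks must satisfy 0 < r100 < r90 < rp, got "
                f"({self.r100}, {self.r90}, {self.rp})"
            )


@dataclass
class FluenceMap:
    """Relative planar fluence on a rectangular (x, y) grid; open field = 1."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # shape (len(y), len(x))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.y.size, self.x.size):
            raise ValueError("fluence values must have shape (len(y), len(x))")


@dataclass
class DoseGrid:
    """Percent-dose matrix on a (y, z) grid; 100 = foam-only CAX maximum."""

    y: np.ndarray
    z: np.ndarray
    values: np.ndarray  # shape (len(z), len(y))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.z = np.asarray(self.z, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.z.size, self.y.size):
            raise ValueError("dose values must have shape (len(z), len(y))")

    def spacing(self) -> tuple[float, float]:
        """(dy, dz) grid spacing, cm; requires uniform grids."""
        dy = np.diff(self.y)
        dz = np.diff(self.z)
        if dy.size and not np.allclose(dy, dy[0], rtol=0, atol=1e-9):
            raise ValueError("y grid is not uniform")
        if dz.size and not np.allclose(dz, dz[0], rtol=0, atol=1e-9):
            raise ValueError("z grid is not uniform")
        return (float(dy[0]) if dy.size else 0.0, float(dz[0]) if dz.size else 0.0)


class TabulatedPDD:
    """Percent depth dose from tabulated (depth, percent) samples.

    Linear interpolation; evaluation outside the tabulated domain raises.
    """

    def __init__(self, depths, percents) -> None:
        self.depths = np.asarray(depths, float)
        self.percents = np.asarray(percents, float)
        if self.depths.ndim != 1 or self.depths.size < 2:
            raise ValueError("need at least two depth samples")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    def __call__(self, z):
        z = np.asarray(z, float)
        if np.any(z < self.depths[0] - 1e-12) or np.any(z > self.depths[-1] + 1e-12):
            raise ValueError(
                f"depth outside tabulated PDD domain "
                f"[{self.depths[0]}, {self.depths[-1]}] cm"
            )
        return np.interp(z, self.depths, self.percents)


def blurred_step(u, half_width, sigma: float):
    """1-D Gaussian-convolved top-hat (unit height, half-width ``half_width``).

    H(u) = 1/2 [erf((u + a) / (sqrt(2) sigma)) - erf((u - a) / (sqrt(2) sigma))]

    ``sigma = 0`` returns the sharp indicator of ``|u| <= half_width``.  The
    integral over u equals ``2 * half_width`` for any sigma (convolution
    conserves area).  ``u`` and ``half_width`` broadcast.
    """
    u = np.asarray(u, float)
    hw = np.asarray(half_width, float)
    if np.any(hw <= 0):
        raise ValueError("half_width must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        # sharp indicator; edge value 1/2 is the sigma -> 0+ limit of the erf form
        au = np.abs(u)
        return np.where(au < hw, 1.0, np.where(au == hw, 0.5, 0.0))
    a = _SQRT2 * sigma
    return 0.5 * (erf((u + hw) / a) - erf((u - hw) / a))


def _resolve_diameters(
    device: PrimeDevice,
    mode: DiameterMode,
    *,
    e_p0: float | None = None,
    sigma_x: float | None = None,
    coeffs: DmodCoefficients | None = None,
) -> np.ndarray:
    """Per-block effective diameter (insert plane) for a diameter mode."""
    d = device.diameters()
    if mode == "nominal":
        return d
    if mode == "in_scatter":
        if sigma_x is None:
            if e_p0 is None:
                raise ValueError("in_scatter mode needs sigma_x or e_p0")
            from .reference import calibrated_sigma_x

            sigma_x = calibrated_sigma_x(e_p0)
        f = np.array([inscatter_fraction(equivalent_square_side(di), sigma_x) for di in d])
        return d * np.sqrt(1.0 + f)
    if mode == "modified":
        if e_p0 is None:
            raise ValueError("modified mode needs e_p0")
        return np.array([d_modified(di, e_p0, coeffs) for di in d])
    raise ValueError(f"unknown diameter mode {mode!r}")


def _projected_blocks(
    device: PrimeDevice, diameters: np.ndarray, plane: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block centers and diameters scaled to the requested plane."""
    pos = device.positions()
    if plane == "insert" or device.n_blocks == 0:
        return pos[:, 0], pos[:, 1], diameters
    if plane != "isocenter":
        raise ValueError(f"unknown plane {plane!r}")
    scale = device.source_to_isocenter / device.insert_distance
    return pos[:, 0] * scale, pos[:, 1] * scale, diameters * scale


def _deficit_profile(
    y: np.ndarray, sigma: float, xs: np.ndarray, ys: np.ndarray, half_sides: np.ndarray, x0: float
) -> np.ndarray:
    """Summed square-pencil fluence deficit along a y line at fixed x."""
    if xs.size == 0:
        return np.zeros_like(y)
    wx = blurred_step(x0 - xs, half_sides, sigma)  # (nb,)
    hy = blurred_step(y[None, :] - ys[:, None], half_sides[:, None], sigma)  # (nb, ny)
    return wx @ hy


def open_field(x, y, half_size: float, sigma_edge: float) -> np.ndarray:
    """Open-field fluence: unit inside the field, erf-blurred penumbra."""
    fx = blurred_step(np.asarray(x, float), half_size, sigma_edge)
    fy = blurred_step(np.asarray(y, float), half_size, sigma_edge)
    return np.multiply.outer(fy, fx)


def device_fluence(
    device: PrimeDevice,
    sigma: float,
    x,
    y,
    diameter_mode: DiameterMode = "nominal",
    *,
    e_p0: float | None = None,
    sigma_x: float | None = None,
    coeffs: DmodCoefficients | None = None,
    field_half_size: float = 10.5,
    sigma_edge: float = 0.1,
    plane: str = "isocenter",
) -> FluenceMap:
    """Relative planar fluence under a device on an (x, y) grid.

    phi(x, y) = phi_open(x, y) - sum_i H(x - x_i; s_i/2, sigma) H(y - y_i; s_i/2, sigma)

    where ``s_i`` is the equivalent square side of the mode-selected diameter
    of block ``i`` and ``phi_open`` is unit fluence with an erf-blurred field
    edge of width ``sigma_edge``.  Positions and diameters are projected to
    ``plane`` ('isocenter' by default, 'insert' for unprojected geometry).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d_eff = _resolve_diameters(device, diameter_mode, e_p0=e_p0, sigma_x=sigma_x, coeffs=coeffs)
    xs, ys, ds = _projected_blocks(device, d_eff, plane)
    sides = np.array([equivalent_square_side(d) for d in ds])
    if sigma == 0 and xs.size >= 2:
        # sharp square footprints may overlap -> local deficit can exceed 1
        from scipy.spatial import cKDTree

        tree = cKDTree(np.column_stack([xs, ys]))
        pairs = tree.query_pairs(float(sides.max() * _SQRT2))
        for i, j in pairs:
            if (
                abs(xs[i] - xs[j]) < (sides[i] + sides[j]) / 2
                and abs(ys[i] - ys[j]) < (sides[i] + sides[j]) / 2
            ):
                warnings.warn(
                    "square pencil footprints overlap at sigma=0; fluence deficit "
                    "may exceed 1 locally",
                    stacklevel=2,
                )
                break
    values = open_field(x, y, field_half_size, sigma_edge)
    if xs.size:
        hx = blurred_step(x[None, :] - xs[:, None], sides[:, None] / 2.0, sigma)  # (nb, nx)
        hy = blurred_step(y[None, :] - ys[:, None], sides[:, None] / 2.0, sigma)  # (nb, ny)
        values = values - hy.T @ hx
    return FluenceMap(x=x, y=y, values=values)


def fluence_profile(
    device: PrimeDevice,
    sigma: float,
    y,
    *,
    x0: float = 0.0,
    diameters: np.ndarray | None = None,
    field_half_size: float = 10.5,
    sigma_edge: float = 0.1,
    plane: str = "isocenter",
) -> np.ndarray:
    """1-D fluence along y at fixed cross-plane position ``x0``.

    Fast path used by the forward dose model; ``diameters`` (insert plane)
    default to the nominal block diameters.
    """
    y = np.asarray(y, float)
    if diameters is None:
        diameters = device.diameters()
    xs, ys, ds = _projected_blocks(device, np.asarray(diameters, float), plane)
    sides = np.array([equivalent_square_side(d) for d in ds])
    base = blurred_step(x0, field_half_size, sigma_edge) * blurred_step(
        y, field_half_size, sigma_edge
    )
    return base - _deficit_profile(y, sigma, xs, ys, sides / 2.0, x0)


def compose_dose(pdd: Callable, oar: np.ndarray, y, z, meta: dict | None = None) -> DoseGrid:
    """Dose plane as the product of depth dose and off-axis ratio.

    D(y, z) = PDD(z) x OAR(y, z), with ``oar`` shaped (len(z), len(y)).
    The x-ray background is part of the PDD tail, not added here.
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    oar = np.asarray(oar, float)
    if oar.shape != (z.size, y.size):
        raise ValueError("oar must have shape (len(z), len(y))")
    pddz = np.asarray(pdd(z), float)
    return DoseGrid(y=y, z=z, values=pddz[:, None] * oar, meta=dict(meta or {}))


def sigma_water(z, e_p0: float, k: float = 0.1):
    """In-water lateral spread power law, cm.

    sigma_water(z) = k * z**1.5 / sqrt(E_p0); ``k`` has units
    cm^(-1/2) MeV^(1/2).  A documented stand-in for the full pencil-beam
    redefinition transport, adequate for the smooth depth scaling the
    diameter calibration needs.
    """
    z = np.asarray(z, float)
    return k * np.clip(z, 0.0, None) ** 1.5 / math.sqrt(e_p0)


@dataclass
class ForwardModel:
    """Dose forward model for a device/beam pair.

    ``pdd`` is a callable z -> percent dose (100 = foam-only CAX maximum).
    ``sigma_device`` is the lateral spread accumulated upstream of the
    patient (air + foam), cm at the patient plane; the in-water spread is
    added in quadrature via :func:`sigma_water`.
    """

    device: PrimeDevice
    beam: BeamSpec
    pdd: Callable
    sigma_device: float
    k_water: float = 0.1
    sigma_edge: float = 0.15
    field_half_size: float = 10.5
    x0: float = 0.0

    def oar(self, diameter: float, y, z) -> np.ndarray:
        """Off-axis ratio matrix (len(z), len(y)) for a shared block diameter.

        ``diameter`` is the effective diameter at the insert plane, applied
        to every block.
        """
        y = np.asarray(y, float)
        z = np.atleast_1d(np.asarray(z, float))
        n = self.device.n_blocks
        diameters = np.full(n, float(diameter)) if n else np.zeros(0)
        out = np.empty((z.size, y.size))
        for i, zi in enumerate(z):
            sig = math.hypot(self.sigma_device, float(sigma_water(zi, self.beam.e_p0, self.k_water)))
            out[i] = fluence_profile(
                self.device,
                sig,
                y,
                x0=self.x0,
                diameters=diameters,
                field_half_size=self.field_half_size,
                sigma_edge=self.sigma_edge,
            )
        return out

    def dose(self, diameter: float, y, z) -> DoseGrid:
        """Dose plane D(y, z) = PDD(z) x OAR(y, z) at a shared diameter."""
        oar = self.oar(diameter, y, z)
        return compose_dose(self.pdd, oar, y, np.atleast_1d(z), meta={"diameter": float(diameter)})


def periodic_mean_transmission(
    d: float, r: float, sigma: float, *, cell_resolution: float = 0.005, pad_sigmas: float = 6.0
) -> float:
    """Mean fluence over the unit cell of an infinite hexagonal lattice.

    Tiles the lattice far enough that neighbour-image tails are negligible
    and averages ``1 - sum of square-pencil deficits`` over the central
    ``r x sqrt(3) r`` rectangular cell (which contains exactly two sites).
    By flux conservation this equals the nominal IRF for any blur ``sigma``.
    """
    s = equivalent_square_side(d)
    lx, ly = r, math.sqrt(3.0) * r
    pad = pad_sigmas * max(sigma, 1e-6) + s
    ni = math.ceil((lx / 2 + pad) / lx) + 1
    nj = math.ceil((ly / 2 + pad) / (ly / 2)) + 1
    xs, ys = [], []
    for j in range(-nj, nj + 1):
        yj = j * ly / 2.0
        off = 0.0 if j % 2 == 0 else 0.5
        for i in range(-ni, ni + 1):
            xs.append((i + off) * lx)
            ys.append(yj)
    xs = np.array(xs)
    ys = np.array(ys)
    keep = (np.abs(xs) <= lx / 2 + pad) & (np.abs(ys) <= ly / 2 + pad)
    xs, ys = xs[keep], ys[keep]
    gx = np.arange(-lx / 2, lx / 2, cell_resolution) + cell_resolution / 2
    gy = np.arange(-ly / 2, ly / 2, cell_resolution) + cell_resolution / 2
    hw = np.full(xs.size, s / 2.0)
    hx = blurred_step(gx[None, :] - xs[:, None], hw[:, None], sigma)
    hy = blurred_step(gy[None, :] - ys[:, None], hw[:, None], sigma)
    deficit = hy.T @ hx
    return float(1.0 - deficit.mean())
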