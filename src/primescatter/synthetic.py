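"""Synthetic "measured" water-phantom dose data.

Real commissioning data are central-axis PDDs and off-axis profiles combined
into a 2-D percent-dose matrix on a 0.1 cm grid.  This module emulates that
product: an analytic PDD built from the beam's depth-dose landmarks, the
forward fluence model evaluated at a ground-truth effective diameter, and
homoscedastic Gaussian noise in percent of given dose.  It exists so the full
diameter-calibration loop (forward model -> least squares -> agreement
metrics) can run and be tested without water-tank scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .device import PrimeDevice, build_hex_device
from .fluence import BeamSpec, DoseGrid, ForwardModel

__all__ = ["SyntheticConfig", "AnalyticPDD", "gen_pdd", "gen_measured_grid", "gen_test_device_files"]


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic measured dose grid.

    ``d_true`` is the ground-truth effective block diameter (cm, insert
    plane) fed to the forward model; ``noise_sd`` is the measurement noise
    standard deviation in percent of given dose.
    """

    beam: BeamSpec
    device: PrimeDevice
    d_true: float
    noise_sd: float = 0.5
    seed: int = 0
    spacing: float = 0.1
    y_half_width: float = 6.0
    z_max: float | None = None
    sigma_device: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.d_true < self.device.r:
            raise ValueError(f"d_true must lie in (0, r={self.device.r}), got {self.d_true}")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")


class AnalyticPDD:
    """Piecewise-smooth analytic percent-depth-dose curve.

    Cosine-ramp build-up from the surface value to 100 at ``r100``, a cosine
    segment through exactly 90 at ``r90``, a cosine falloff reaching the
    x-ray background at ``rp``, and a constant background beyond.  The shape
    is a stand-in for a measured electron PDD, exact at the landmarks by
    construction; it makes no claim about real depth-dose shapes between
    them.
    """

    def __init__(self, beam: BeamSpec, surface_dose: float = 85.0) -> None:
        if not 0 < surface_dose < 100:
            raise ValueError("surface dose must lie in (0, 100) percent")
        self.beam = beam
        self.surface_dose = surface_dose

    def __call__(self, z):
        z = np.asarray(z, float)
        if np.any(z < -1e-12):
            raise ValueError("depth must be nonnegative")
        b = self.beam
        out = np.empty(z.shape)
        # build-up: surface -> 100 at r100
        m = z <= b.r100
        u = np.clip(z[m] / b.r100, 0.0, 1.0)
        out[m] = self.surface_dose + (100.0 - self.surface_dose) * 0.5 * (1 - np.cos(math.pi * u))
        # shoulder: 100 -> 90 at r90
        m = (z > b.r100) & (z <= b.r90)
        u = (z[m] - b.r100) / (b.r90 - b.r100)
        out[m] = 100.0 - 10.0 * 0.5 * (1 - np.cos(math.pi * u))
        # falloff: 90 -> background at rp
        m = (z > b.r90) & (z <= b.rp)
        u = (z[m] - b.r90) / (b.rp - b.r90)
        out[m] = b.x_ray_background + (90.0 - b.x_ray_background) * 0.5 * (1 + np.cos(math.pi * u))
        # bremsstrahlung tail
        out[z > b.rp] = b.x_ray_background
        return out if out.ndim else float(out)


def gen_pdd(beam: BeamSpec, surface_dose: float = 85.0) -> AnalyticPDD:
    """Analytic PDD for a beam; PDD(r100) = 100 and PDD(r90) = 90 exactly."""
    return AnalyticPDD(beam, surface_dose)


def _default_sigma_device(e_p0: float) -> float:
    from .reference import calibrated_sigma_x

    return calibrated_sigma_x(e_p0)


def forward_model_for(cfg_or_beam, device=None, sigma_device=None, pdd=None, **kwargs) -> ForwardModel:
    """Build the forward model a synthetic grid (or its calibration) uses."""
    if isinstance(cfg_or_beam, SyntheticConfig):
        cfg = cfg_or_beam
        beam, device = cfg.beam, cfg.device
        sigma_device = cfg.sigma_device
    else:
        beam = cfg_or_beam
    if sigma_device is None:
        sigma_device = _default_sigma_device(beam.e_p0)
    if pdd is None:
        pdd = gen_pdd(beam)
    return ForwardModel(device=device, beam=beam, pdd=pdd, sigma_device=sigma_device, **kwargs)


def gen_measured_grid(cfg: SyntheticConfig) -> DoseGrid:
    """Synthetic measured dose matrix on the regular grid.

    The forward model is evaluated at ``cfg.d_true`` on a grid of
    ``cfg.spacing`` (0.1 cm default), and independent Gaussian noise of SD
    ``cfg.noise_sd`` percent is added with a seeded generator.  Metadata
    records the ground truth and seed for downstream recovery checks.
    """
    z_max = cfg.z_max if cfg.z_max is not None else cfg.beam.rp
    n_y = int(round(cfg.y_half_width / cfg.spacing))
    y = np.arange(-n_y, n_y + 1) * cfg.spacing
    z = np.arange(0, int(round(z_max / cfg.spacing)) + 1) * cfg.spacing
    model = forward_model_for(cfg)
    grid = model.dose(cfg.d_true, y, z)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        grid.values = grid.values + rng.normal(0.0, cfg.noise_sd, grid.values.shape)
    grid.meta.update(
        {"d_true": cfg.d_true, "seed": cfg.seed, "noise_sd": cfg.noise_sd, **cfg.meta}
    )
    return grid


def gen_test_device_files(outdir) -> list[Path]:
    """Write the four study device files (foam-only plus three diameters).

    Files use the device text dialect (isocenter-projected values); each
    block-bearing device is the 247-block hexagonal matrix.
    """
    from .io import write_device_file
    from .reference import FIELD_EXTENT, GRID_RADIUS, NOMINAL_DIAMETERS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    foam = PrimeDevice(blocks=[], r=GRID_RADIUS)
    p = outdir / "prime_foam_only.txt"
    write_device_file(p, foam)
    paths.append(p)
    for d in NOMINAL_DIAMETERS:
        dev = build_hex_device(*FIELD_EXTENT, r=GRID_RADIUS, d_nom=d)
        p = outdir / f"prime_d{d:.3f}.txt"
        write_device_file(p, dev)
        paths.append(p)
    return paths
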