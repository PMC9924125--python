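"""Pencil-beam in-scatter theory and the empirical modified-diameter surface.

Electrons laterally scattered into a block's side are absorbed, which makes
the block act larger than its physical diameter; electrons out-scattered from
the block's side act in the opposite direction.  In-scatter admits a closed
pencil-beam treatment: model the cylindrical block as a square parallelepiped
of equal cross-section (side ``s = d sqrt(pi)/2``) and ask what fraction of a
uniform beam launched over that square, after Gaussian lateral blurring of
RMS ``sigma_x``, leaves the square footprint.  The one-dimensional
containment probability is

    P(w) = erf(w) + (exp(-w^2) - 1) / (w sqrt(pi)),   w = s / (sqrt(2) sigma_x)

and the side-impinging (in-scatter) fraction is ``f = 1 - P(w)**2``.

Out-scatter has no such closed form; it is absorbed empirically into a
modified block diameter ``d_mod(d_nom, E_p0)``, parameterized as a quadratic
surface in diameter and beam energy fitted by least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .device import irf_nominal

__all__ = [
    "ScatterParams",
    "InScatterResult",
    "DmodCoefficients",
    "equivalent_square_side",
    "sigma_x_foam",
    "inscatter_fraction",
    "calibrate_sigma_x",
    "d_in_scatter",
    "irf_in_scatter",
    "in_scatter_result",
    "d_modified",
    "fit_dmod_surface",
]

_SQRT_PI = math.sqrt(math.pi)
_SQRT2 = math.sqrt(2.0)

#: Energy range (MeV) over which the modified-diameter surface was fitted.
DMOD_ENERGY_RANGE = (7.0, 20.5)


@dataclass(frozen=True)
class ScatterParams:
    """Inputs to the foam lateral-spread model.

    Parameters
    ----------
    sigma_theta_x : float
        Projected angular spread of the incident beam (multiple Coulomb
        scattering in the scattering foils and air), radians.  May already
        include the 50% foam increase.
    mass_scattering_power : float
        Mass angular scattering power of the machinable foam at the beam
        energy, radian^2 cm^2 / g.
    foam_density : float
        g / cm^3.
    foam_thickness : float
        Slab thickness traversed, cm.
    """

    sigma_theta_x: float
    mass_scattering_power: float
    foam_density: float = 0.096
    foam_thickness: float = 1.27

    def __post_init__(self) -> None:
        if self.sigma_theta_x < 0 or self.mass_scattering_power < 0 or self.foam_density < 0:
            raise ValueError("scatter parameters must be nonnegative")
        if not self.foam_thickness > 0:
            raise ValueError("foam thickness must be positive")


@dataclass(frozen=True)
class InScatterResult:
    """In-scatter-adjusted quantities for one block diameter and energy."""

    f: float
    d_is: float
    irf_is: float


@dataclass(frozen=True)
class DmodCoefficients:
    """Coefficients of the quadratic modified-diameter surface.

    d_mod = a0 + a1*d + a2*E + a3*d^2 + a4*d*E + a5*E^2

    with ``d`` in cm and ``E`` in MeV.  Units: a0 cm, a1 dimensionless,
    a2 cm/MeV, a3 1/cm, a4 1/MeV, a5 cm/MeV^2.  The defaults are the
    commissioned values for the study beams.
    """

    a0: float = 1.61e-2
    a1: float = 1.09
    a2: float = -2.51e-3
    a3: float = -1.45e-1
    a4: float = -1.40e-3
    a5: float = 6.42e-5

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not math.isfinite(v):
                raise ValueError(f"coefficient {name} is not finite: {v}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "DmodCoefficients":
        return cls(**{k: float(d[k]) for k in ("a0", "a1", "a2", "a3", "a4", "a5")})

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3, self.a4, self.a5])


def equivalent_square_side(d_nom: float) -> float:
    """Side of the square with the same area as a disc of diameter ``d_nom``.

    ``s = d sqrt(pi) / 2``, so that ``s**2 = pi d**2 / 4``.
    """
    if d_nom < 0:
        raise ValueError(f"diameter must be nonnegative, got {d_nom}")
    return d_nom * _SQRT_PI / 2.0


def sigma_x_foam(params: ScatterParams) -> float:
    """RMS lateral spread of a pencil beam after traversing the foam slab.

    sigma_x = t * sqrt(sigma_theta_x^2 + (1/6) (T/rho) rho t)

    where the first term is the incident angular spread carried over the slab
    thickness and the second is the spread accumulated by multiple Coulomb
    scattering inside the foam itself.
    """
    t = params.foam_thickness
    var = params.sigma_theta_x**2 + params.mass_scattering_power * params.foam_density * t / 6.0
    return t * math.sqrt(var)


def _containment_1d(w: float) -> float:
    """1-D probability that a uniform launch over a slit of half-width
    ``w = s / (sqrt(2) sigma)`` (in blur units) stays inside after blurring."""
    if w < 1e-6:
        # erf(w) ~ 2w/sqrt(pi) - 2w^3/(3 sqrt(pi)); (e^{-w^2}-1)/(w sqrt(pi))
        # ~ -w/sqrt(pi) + w^3/(2 sqrt(pi)) -> P ~ w/sqrt(pi)
        return w / _SQRT_PI
    return float(erf(w)) + (math.exp(-w * w) - 1.0) / (w * _SQRT_PI)


def inscatter_fraction(s: float, sigma_x: float) -> float:
    """Fraction of electrons impinging a block's sides relative to its face.

    A uniform square beam of side ``s`` is blurred by an independent zero-mean
    Gaussian of RMS ``sigma_x`` in each lateral axis; ``f`` is the complement
    of the two-dimensional containment probability, ``f = 1 - P(w)**2`` with
    ``w = s / (sqrt(2) sigma_x)``.  ``sigma_x = 0`` returns exactly 0.
    """
    if s <= 0:
        raise ValueError(f"equivalent square side must be positive, got {s}")
    if sigma_x < 0:
        raise ValueError(f"sigma_x must be nonnegative, got {sigma_x}")
    if sigma_x == 0:
        return 0.0
    w = s / (_SQRT2 * sigma_x)
    p = _containment_1d(w)
    return max(0.0, 1.0 - p * p)


def calibrate_sigma_x(s: float, f_target: float) -> float:
    """Invert :func:`inscatter_fraction` for the lateral spread ``sigma_x``.

    ``f`` is strictly increasing in ``sigma_x`` for fixed ``s``, so a
    bracketing root find is exact.  Used to calibrate one spread per beam
    energy from a tabulated in-scatter fraction.
    """
    if not 0.0 < f_target < 1.0:
        raise ValueError(f"f_target must lie in (0, 1), got {f_target}")
    if s <= 0:
        raise ValueError(f"equivalent square side must be positive, got {s}")

    def g(sigma: float) -> float:
        return inscatter_fraction(s, sigma) - f_target

    lo, hi = 1e-9 * s, 10.0 * s
    while g(hi) < 0:  # push bracket toward f -> 1 for extreme targets
        hi *= 4.0
        if hi > 1e6 * s:
            raise RuntimeError("failed to bracket sigma_x")
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16))


def d_in_scatter(d_nom: float, f: float) -> float:
    """Effective diameter once side in-scatter is folded into the block.

    ``d_IS = d_nom * sqrt(1 + f)``: the block absorbs the face-incident
    electrons plus the side-impinging fraction ``f`` of them, equivalent to a
    disc of area ``(1 + f)`` times larger.
    """
    if d_nom < 0:
        raise ValueError(f"diameter must be nonnegative, got {d_nom}")
    if not 0.0 <= f < 1.0:
        raise ValueError(f"in-scatter fraction must lie in [0, 1), got {f}")
    return d_nom * math.sqrt(1.0 + f)


def irf_in_scatter(irf_nom: float, f: float) -> float:
    """Intensity reduction factor adjusted for side in-scatter.

    ``IRF_IS = IRF_nom - f * (1 - IRF_nom)``: the blocked area fraction
    ``(1 - IRF_nom)`` grows by the in-scattered fraction ``f``.
    """
    if not 0.0 < irf_nom <= 1.0:
        raise ValueError(f"IRF_nom must lie in (0, 1], got {irf_nom}")
    if not 0.0 <= f < 1.0:
        raise ValueError(f"in-scatter fraction must lie in [0, 1), got {f}")
    return irf_nom - f * (1.0 - irf_nom)


def in_scatter_result(d_nom: float, r: float, sigma_x: float) -> InScatterResult:
    """Convenience: f, d_IS and IRF_IS for one block diameter and spread."""
    f = inscatter_fraction(equivalent_square_side(d_nom), sigma_x)
    return InScatterResult(
        f=f,
        d_is=d_in_scatter(d_nom, f),
        irf_is=irf_in_scatter(irf_nominal(d_nom, r), f),
    )


def d_modified(
    d_nom: float, e_p0: float, coeffs: DmodCoefficients | None = None
) -> float:
    """Empirical modified block diameter absorbing in- and out-scatter.

    Evaluates the quadratic surface ``d_mod(d_nom, E_p0)``.  Energies outside
    the commissioned range emit a warning (the surface is an extrapolation
    there).
    """
    if d_nom <= 0:
        raise ValueError(f"diameter must be positive, got {d_nom}")
    if coeffs is None:
        coeffs = DmodCoefficients()
    lo, hi = DMOD_ENERGY_RANGE
    if not lo <= e_p0 <= hi:
        warnings.warn(
            f"E_p0 = {e_p0} MeV is outside the commissioned range [{lo}, {hi}] MeV; "
            "the modified-diameter surface is extrapolating",
            stacklevel=2,
        )
    c = coeffs
    return c.a0 + c.a1 * d_nom + c.a2 * e_p0 + c.a3 * d_nom**2 + c.a4 * d_nom * e_p0 + c.a5 * e_p0**2


def _dmod_basis(d: np.ndarray, e: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(d), d, e, d**2, d * e, e**2])


def fit_dmod_surface(points) -> DmodCoefficients:
    """Ordinary least squares fit of the six-term quadratic surface.

    ``points`` is an iterable of ``(d_nom, e_p0, d_mod)`` triplets; at least
    six points spanning at least two distinct diameters and two distinct
    energies are required for the basis to have full rank.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (d_nom, e_p0, d_mod) triplets")
    if pts.shape[0] < 6:
        raise ValueError(f"need >= 6 points to fit 6 coefficients, got {pts.shape[0]}")
    d, e, dm = pts.T
    if np.unique(d).size < 2 or np.unique(e).size < 2:
        raise ValueError("points must span >= 2 distinct diameters and energies")
    basis = _dmod_basis(d, e)
    coef, _, rank, _ = np.linalg.lstsq(basis, dm, rcond=None)
    if rank < 6:
        raise ValueError(f"rank-deficient quadratic basis (rank {rank} < 6)")
    return DmodCoefficients(*coef)
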