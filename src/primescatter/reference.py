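"""Commissioned reference data for the three study beams.

These constants describe the measurement campaign the scatter model was
commissioned against: three test modulators (247 blocks each, 0.6 cm
hexagonal grid over an 8.4 x 8.4 cm^2 extent at the insert plane) at nominal
diameters of 0.158, 0.273 and 0.352 cm, scanned with 7, 13 and 20 MeV beams
(E_p0 = 7.14, 13.12, 20.47 MeV) at 100 cm SSD.

The in-scatter fraction table feeds the per-energy lateral-spread
calibration; the modified-diameter table anchors the quadratic surface fit.
Depth-dose landmarks for the synthetic beams are rule-of-thumb stand-ins
(see docs/methods.md), chosen so each beam's R90 sits just below the stated
modulated-region depth limit.
"""

from __future__ import annotations

from functools import lru_cache

from .fluence import BeamSpec
from .scatter import calibrate_sigma_x, equivalent_square_side

__all__ = [
    "GRID_RADIUS",
    "FIELD_EXTENT",
    "NOMINAL_DIAMETERS",
    "BEAM_ENERGIES",
    "STUDY_BEAMS",
    "INSCATTER_FRACTIONS",
    "DMOD_TABLE",
    "MODULATED_REGION_ZMAX",
    "calibrated_sigma_x",
    "dmod_fit_points",
]

#: Hexagonal packing radius at the insert plane, cm.
GRID_RADIUS = 0.6

#: Block-matrix extent at the insert plane, cm.
FIELD_EXTENT = (8.4, 8.4)

#: Nominal island-block diameters of the three test devices, cm.
NOMINAL_DIAMETERS = (0.158, 0.273, 0.352)

#: Most probable surface energy per beam label, MeV.
BEAM_ENERGIES = {"7MeV": 7.14, "13MeV": 13.12, "20MeV": 20.47}

#: Synthetic beam models: landmarks (r100, r90, rp in cm) and x-ray
#: background (percent of given dose) are stand-ins for the measured PDDs.
STUDY_BEAMS = {
    "7MeV": BeamSpec(e_p0=7.14, ssd=100.0, r100=1.4, r90=1.9, rp=3.5, x_ray_background=0.7),
    "13MeV": BeamSpec(e_p0=13.12, ssd=100.0, r100=2.6, r90=4.3, rp=6.6, x_ray_background=1.5),
    "20MeV": BeamSpec(e_p0=20.47, ssd=100.0, r100=2.8, r90=6.3, rp=10.2, x_ray_background=3.0),
}

#: Tabulated side in-scatter fractions f(E_p0, d_nom) for the study devices.
INSCATTER_FRACTIONS = {
    7.14: {0.158: 0.420, 0.273: 0.257, 0.352: 0.202},
    13.12: {0.158: 0.268, 0.273: 0.160, 0.352: 0.125},
    20.47: {0.158: 0.172, 0.273: 0.101, 0.352: 0.079},
}

#: Commissioned modified diameters d_mod(E_p0, d_nom), cm at the insert plane.
DMOD_TABLE = {
    7.14: {0.158: 0.167, 0.273: 0.283, 0.352: 0.361},
    13.12: {0.158: 0.159, 0.273: 0.274, 0.352: 0.352},
    20.47: {0.158: 0.155, 0.273: 0.269, 0.352: 0.345},
}

#: Distal depth limit of the modulated evaluation region per energy, cm
#: (0.5 cm to slightly beyond R90).
MODULATED_REGION_ZMAX = {7.14: 2.0, 13.12: 4.5, 20.47: 6.5}

#: Diameter whose tabulated f anchors the per-energy sigma_x calibration.
SIGMA_X_REFERENCE_DIAMETER = 0.158


def _nearest_energy(e_p0: float, table: dict) -> float:
    best = min(table, key=lambda e: abs(e - e_p0))
    if abs(best - e_p0) > 1e-6:
        raise KeyError(
            f"no tabulated entry at E_p0 = {e_p0} MeV (have {sorted(table)}); "
            "supply sigma_x explicitly for other energies"
        )
    return best


@lru_cache(maxsize=None)
def calibrated_sigma_x(e_p0: float, d_ref: float = SIGMA_X_REFERENCE_DIAMETER) -> float:
    """Lateral spread (cm) calibrated to the tabulated in-scatter fraction.

    Inverts the in-scatter formula at the reference diameter's tabulated f
    for the requested beam energy.  One spread per energy then predicts the
    remaining tabulated fractions at that energy.
    """
    e = _nearest_energy(e_p0, INSCATTER_FRACTIONS)
    f_ref = INSCATTER_FRACTIONS[e][d_ref]
    return calibrate_sigma_x(equivalent_square_side(d_ref), f_ref)


def dmod_fit_points() -> list[tuple[float, float, float]]:
    """The nine (d_nom, E_p0, d_mod) commissioning triplets."""
    return [
        (d, e, dm) for e, row in DMOD_TABLE.items() for d, dm in row.items()
    ]
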