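"""Geometry of passive electron intensity modulators (PRIME devices).

A PRIME device is a lattice of short cylindrical tungsten rods ("island
blocks") embedded in a low-density machinable foam slab inside the beam's
collimating insert.  Electrons hitting a block's upstream face are absorbed;
downstream scatter in air and foam restores local fluence uniformity at a
reduced level.  The unblocked area fraction of the hexagonal unit cell is the
nominal intensity reduction factor (IRF).

Coordinate convention: x = cross-plane, y = in-plane (scan direction),
z = depth in water, all in cm.  Block positions and diameters are stored at
the insert plane (``source_to_isocenter - insert_to_isocenter`` cm from the
source); device files store isocenter-projected values and are converted on
read (see :mod:`primescatter.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IslandBlock",
    "PrimeDevice",
    "irf_nominal",
    "build_hex_device",
    "project_between_planes",
]

#: Area ratio of a disc of diameter r to the hexagonal unit cell of packing
#: radius r: pi / (2 sqrt(3)).
HEX_CELL_FACTOR = math.pi / (2.0 * math.sqrt(3.0))

#: Position tolerance (cm) for boundary inclusion and lattice invariants.
GEOM_TOL = 1e-9


@dataclass(frozen=True)
class IslandBlock:
    """One cylindrical tungsten island block, specified at the insert plane.

    Parameters
    ----------
    x, y : float
        Cross-plane and in-plane center position, cm.
    d_nom : float
        Physical (nominal) diameter, cm.
    length : float
        Cylinder length along the beam axis, cm.  Carried as metadata; the
        block is treated as a total absorber regardless of length.
    """

    x: float
    y: float
    d_nom: float
    length: float = 0.6

    def __post_init__(self) -> None:
        if not self.d_nom > 0:
            raise ValueError(f"island block diameter must be positive, got {self.d_nom}")
        if not self.length > 0:
            raise ValueError(f"island block length must be positive, got {self.length}")


@dataclass
class PrimeDevice:
    """A lattice of island blocks embedded in a foam slab.

    ``r`` is the hexagonal packing radius (nearest-neighbour spacing) in cm.
    ``extent`` optionally records the declared field extent ``(ex, ey)`` in
    cm at the insert plane; when present, all blocks must lie inside it.
    """

    blocks: list[IslandBlock] = field(default_factory=list)
    r: float = 0.6
    foam_thickness: float = 1.27
    foam_density: float = 0.096
    insert_to_isocenter: float = 5.0
    source_to_isocenter: float = 100.0
    extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("packing radius r must be positive")
        if not self.foam_thickness > 0:
            raise ValueError("foam thickness must be positive")
        if self.insert_to_isocenter >= self.source_to_isocenter:
            raise ValueError("insert plane must lie between source and isocenter")
        self.validate()

    # -- derived geometry ------------------------------------------------

    @property
    def insert_distance(self) -> float:
        """Source-to-insert-plane distance, cm."""
        return self.source_to_isocenter - self.insert_to_isocenter

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def positions(self) -> np.ndarray:
        """(N, 2) array of block centers (x, y) at the insert plane, cm."""
        return np.array([[b.x, b.y] for b in self.blocks], dtype=float).reshape(-1, 2)

    def diameters(self) -> np.ndarray:
        """(N,) array of nominal diameters at the insert plane, cm."""
        return np.array([b.d_nom for b in self.blocks], dtype=float)

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check packing invariants; raise ``ValueError`` on violation."""
        for b in self.blocks:
            if b.d_nom >= self.r:
                raise ValueError(
                    f"block diameter {b.d_nom} >= packing radius {self.r}: blocks would overlap"
                )
        if self.extent is not None:
            ex, ey = self.extent
            for b in self.blocks:
                if abs(b.x) > ex / 2 + GEOM_TOL or abs(b.y) > ey / 2 + GEOM_TOL:
                    raise ValueError(
                        f"block at ({b.x}, {b.y}) lies outside declared extent {self.extent}"
                    )
        if self.n_blocks >= 2:
            dmin = self.min_pair_distance()
            if dmin < self.r - GEOM_TOL:
                raise ValueError(
                    f"minimum block spacing {dmin:.6g} cm violates packing radius {self.r} cm"
                )

    def min_pair_distance(self) -> float:
        """Minimum pairwise center-to-center distance, cm."""
        if self.n_blocks < 2:
            return math.inf
        from scipy.spatial import cKDTree

        pos = self.positions()
        tree = cKDTree(pos)
        dist, _ = tree.query(pos, k=2)
        return float(dist[:, 1].min())

    def irf_nominal(self) -> np.ndarray:
        """Per-block nominal IRF for this device's packing radius."""
        return np.array([irf_nominal(b.d_nom, self.r) for b in self.blocks])


def irf_nominal(d_nom: float, r: float) -> float:
    """Nominal intensity reduction factor of a hexagonal island-block lattice.

    The unblocked area fraction of a hexagonal unit cell of packing radius
    ``r`` containing one block of diameter ``d_nom``::

        IRF_nom = 1 - (pi / (2 sqrt(3))) * (d_nom / r)**2

    Parameters are in cm; the result is a dimensionless fraction in (0, 1].
    """
    if r <= 0:
        raise ValueError(f"packing radius must be positive, got {r}")
    if d_nom < 0 or d_nom >= r:
        raise ValueError(
            f"diameter must satisfy 0 <= d_nom < r (got d_nom={d_nom}, r={r}); "
            "blocks would overlap otherwise"
        )
    return 1.0 - HEX_CELL_FACTOR * (d_nom / r) ** 2


def build_hex_device(
    extent_x: float,
    extent_y: float,
    r: float = 0.6,
    d_nom: float = 0.273,
    **device_kwargs,
) -> PrimeDevice:
    """Build a centered hexagonal lattice of identical island blocks.

    The lattice is centered on the origin with a block at (0, 0): rows at
    ``y = k * (sqrt(3)/2) * r`` for integer ``k``; even-``k`` rows have sites
    at ``x = m * r``, odd-``k`` rows at ``x = (m + 1/2) * r``.  Sites with
    ``|x| <= extent_x/2`` and ``|y| <= extent_y/2`` are kept, boundaries
    inclusive within 1e-9 cm (so an 8.4 cm extent includes sites at exactly
    +/-4.2 cm).  Degenerate extents yield the single center block.
    """
    if extent_x <= 0 or extent_y <= 0 or r <= 0 or d_nom <= 0:
        raise ValueError("extents, packing radius and diameter must be positive")
    row_h = math.sqrt(3.0) / 2.0 * r
    half_x = extent_x / 2.0 + GEOM_TOL
    half_y = extent_y / 2.0 + GEOM_TOL
    k_max = math.floor(half_y / row_h)
    blocks: list[IslandBlock] = []
    for k in range(-k_max, k_max + 1):
        y = k * row_h
        offset = 0.0 if k % 2 == 0 else 0.5
        m_min = math.ceil(-half_x / r - offset)
        m_max = math.floor(half_x / r - offset)
        for m in range(m_min, m_max + 1):
            blocks.append(IslandBlock(x=(m + offset) * r, y=y, d_nom=d_nom))
    return PrimeDevice(blocks=blocks, r=r, extent=(extent_x, extent_y), **device_kwargs)


def project_between_planes(value: float, from_distance: float, to_distance: float) -> float:
    """Divergent-beam scaling of a length between planes.

    Scales positions and diameters between two planes at ``from_distance``
    and ``to_distance`` cm from the source: ``value * to / from``.
    """
    if from_distance <= 0 or to_distance <= 0:
        raise ValueError("plane distances from source must be positive")
    return value * (to_distance / from_distance)
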