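"""File formats: device text files, dose-grid CSV, and run configuration.

Device files are UTF-8 text in the treatment-planning dialect: ``#`` comment
header lines carrying ``key: value`` metadata, then the integer block count,
then one whitespace-separated ``x y d`` row per block (cm, projected to
isocenter).  Devices are converted to insert-plane canonical coordinates on
read and projected back on write.

Dose grids and fluence maps are CSV with one header line carrying the depth
(or cross-plane) coordinates; values are written at 9 significant digits so a
write/read round trip is value-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibrate import RegionSpec
from .device import IslandBlock, PrimeDevice, project_between_planes
from .fluence import BeamSpec, DoseGrid, FluenceMap
from .scatter import DmodCoefficients

__all__ = [
    "read_device_file",
    "write_device_file",
    "read_dose_csv",
    "write_dose_csv",
    "read_fluence_csv",
    "write_fluence_csv",
    "RunConfig",
]

_HEADER_KEYS = {
    "grid_spacing_cm": ("r", float),
    "foam_thickness_cm": ("foam_thickness", float),
    "foam_density_g_cm3": ("foam_density", float),
    "insert_to_isocenter_cm": ("insert_to_isocenter", float),
    "source_to_isocenter_cm": ("source_to_isocenter", float),
}


class DeviceFileError(ValueError):
    """Malformed device file; message names the offending line."""


def read_device_file(path) -> PrimeDevice:
    """Parse a device text file into insert-plane canonical coordinates.

    Positions and diameters in the file are projected to isocenter; they are
    scaled back to the insert plane here.  The declared block count must
    match the number of rows.
    """
    path = Path(path)
    meta: dict = {}
    count: int | None = None
    rows: list[tuple[float, float, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if count is None:
                try:
                    count = int(line)
                except ValueError:
                    raise DeviceFileError(
                        f"{path}:{lineno}: expected integer block count, got {line!r}"
                    ) from None
                if count < 0:
                    raise DeviceFileError(f"{path}:{lineno}: block count must be nonnegative")
                continue
            parts = line.split()
            if len(parts) != 3:
                raise DeviceFileError(
                    f"{path}:{lineno}: expected 'x y d' row with 3 fields, got {len(parts)}"
                )
            try:
                x, y, d = (float(p) for p in parts)
            except ValueError:
                raise DeviceFileError(f"{path}:{lineno}: malformed number in row {line!r}") from None
            if d <= 0:
                raise DeviceFileError(f"{path}:{lineno}: nonpositive diameter {d}")
            rows.append((x, y, d))
    if count is None:
        raise DeviceFileError(f"{path}: missing block count line")
    if len(rows) != count:
        raise DeviceFileError(
            f"{path}: header declares {count} blocks but file has {len(rows)} rows"
        )
    kwargs = {}
    for key, (attr, conv) in _HEADER_KEYS.items():
        if key in meta:
            kwargs[attr] = conv(meta[key])
    dev = PrimeDevice(blocks=[], **kwargs)
    scale_from = dev.source_to_isocenter
    scale_to = dev.insert_distance
    blocks = [
        IslandBlock(
            x=project_between_planes(x, scale_from, scale_to),
            y=project_between_planes(y, scale_from, scale_to),
            d_nom=project_between_planes(d, scale_from, scale_to),
        )
        for x, y, d in rows
    ]
    device = PrimeDevice(blocks=blocks, **kwargs)
    # keep the parsed isocenter rows so an unmodified device writes back
    # bit-identically (projection to the insert plane and back is not exact
    # in floating point)
    device._iso_rows = rows
    return device


def _rows_match(device: PrimeDevice, iso_rows) -> bool:
    """True if the device's blocks are exactly the projection of iso_rows."""
    if len(iso_rows) != device.n_blocks:
        return False
    f, t = device.source_to_isocenter, device.insert_distance
    return all(
        b.x == project_between_planes(x, f, t)
        and b.y == project_between_planes(y, f, t)
        and b.d_nom == project_between_planes(d, f, t)
        for b, (x, y, d) in zip(device.blocks, iso_rows)
    )


def write_device_file(path, device: PrimeDevice) -> None:
    """Write a device file, projecting insert-plane values to isocenter."""
    path = Path(path)
    s_from = device.insert_distance
    s_to = device.source_to_isocenter
    lines = [
        "# PRIME device",
        f"# grid_spacing_cm: {device.r:.9g}",
        f"# foam_thickness_cm: {device.foam_thickness:.9g}",
        f"# foam_density_g_cm3: {device.foam_density:.9g}",
        f"# insert_to_isocenter_cm: {device.insert_to_isocenter:.9g}",
        f"# source_to_isocenter_cm: {device.source_to_isocenter:.9g}",
        "# plane: isocenter",
        str(device.n_blocks),
    ]
    iso_rows = getattr(device, "_iso_rows", None)
    if iso_rows is not None and _rows_match(device, iso_rows):
        for x, y, d in iso_rows:
            lines.append(f"{x!r} {y!r} {d!r}")
    else:
        # shortest round-trippable floats so geometry invariants survive re-read
        for b in device.blocks:
            x = project_between_planes(b.x, s_from, s_to)
            y = project_between_planes(b.y, s_from, s_to)
            d = project_between_planes(b.d_nom, s_from, s_to)
            lines.append(f"{x!r} {y!r} {d!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_dose_csv(path, grid: DoseGrid) -> None:
    """Dose grid as CSV: header row of depths, one row per y position."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("y_cm\\z_cm," + ",".join(f"{z:.9g}" for z in grid.z) + "\n")
        for j, yv in enumerate(grid.y):
            fh.write(f"{yv:.9g}," + ",".join(f"{v:.9g}" for v in grid.values[:, j]) + "\n")


def read_dose_csv(path) -> DoseGrid:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        z = np.array([float(v) for v in header[1:]])
        ys, vals = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.strip().split(",")
            ys.append(float(parts[0]))
            vals.append([float(v) for v in parts[1:]])
    values = np.array(vals).T  # (nz, ny)
    return DoseGrid(y=np.array(ys), z=z, values=values)


def write_fluence_csv(path, fmap: FluenceMap) -> None:
    """Fluence map as CSV: header row of x coords, one row per y position."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("y_cm\\x_cm," + ",".join(f"{x:.9g}" for x in fmap.x) + "\n")
        for j, yv in enumerate(fmap.y):
            fh.write(f"{yv:.9g}," + ",".join(f"{v:.9g}" for v in fmap.values[j]) + "\n")


def read_fluence_csv(path) -> FluenceMap:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        x = np.array([float(v) for v in header[1:]])
        ys, vals = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.strip().split(",")
            ys.append(float(parts[0]))
            vals.append([float(v) for v in parts[1:]])
    return FluenceMap(x=x, y=np.array(ys), values=np.array(vals))


@dataclass
class RunConfig:
    """Run configuration: beams, calibrated spreads, coefficients, regions.

    Units are explicit in YAML key names (cm, MeV, percent of given dose).
    Foam adjustment flags mirror commissioning practice: the angular-spread
    increase for the foam slab is on by default; the R90 shift and energy
    reduction are off (appropriate when the input PDD was measured with the
    foam in place).
    """

    beams: dict[str, BeamSpec] = field(default_factory=dict)
    sigma_x_cm: dict[str, float] = field(default_factory=dict)
    dmod_coefficients: DmodCoefficients = field(default_factory=DmodCoefficients)
    regions: dict[str, RegionSpec] = field(default_factory=dict)
    foam_sigma_theta_factor: float = 1.5
    foam_shift_r90: bool = False
    foam_reduce_e_p0: bool = False

    @classmethod
    def default(cls) -> "RunConfig":
        from .reference import BEAM_ENERGIES, MODULATED_REGION_ZMAX, STUDY_BEAMS, calibrated_sigma_x

        return cls(
            beams=dict(STUDY_BEAMS),
            sigma_x_cm={label: calibrated_sigma_x(e) for label, e in BEAM_ENERGIES.items()},
            regions={
                label: RegionSpec(z_max=MODULATED_REGION_ZMAX[e])
                for label, e in BEAM_ENERGIES.items()
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls.default()
        for label, b in (raw.get("beams") or {}).items():
            cfg.beams[label] = BeamSpec(
                e_p0=float(b["e_p0_mev"]),
                ssd=float(b.get("ssd_cm", 100.0)),
                r100=float(b["r100_cm"]),
                r90=float(b["r90_cm"]),
                rp=float(b["rp_cm"]),
                x_ray_background=float(b.get("x_ray_background_pct", 1.0)),
            )
        for label, v in (raw.get("sigma_x_cm") or {}).items():
            cfg.sigma_x_cm[label] = float(v)
        if "dmod_coefficients" in raw:
            cfg.dmod_coefficients = DmodCoefficients.from_dict(raw["dmod_coefficients"])
        for label, r in (raw.get("regions") or {}).items():
            cfg.regions[label] = RegionSpec(
                y_half_width=float(r.get("y_half_width_cm", 3.5)),
                z_min=float(r.get("z_min_cm", 0.5)),
                z_max=float(r["z_max_cm"]),
            )
        flags = raw.get("foam_adjustments") or {}
        cfg.foam_sigma_theta_factor = float(flags.get("sigma_theta_factor", 1.5))
        cfg.foam_shift_r90 = bool(flags.get("shift_r90", False))
        cfg.foam_reduce_e_p0 = bool(flags.get("reduce_e_p0", False))
        return cfg

    def to_yaml(self, path) -> None:
        raw = {
            "beams": {
                label: {
                    "e_p0_mev": b.e_p0,
                    "ssd_cm": b.ssd,
                    "r100_cm": b.r100,
                    "r90_cm": b.r90,
                    "rp_cm": b.rp,
                    "x_ray_background_pct": b.x_ray_background,
                }
                for label, b in self.beams.items()
            },
            "sigma_x_cm": dict(self.sigma_x_cm),
            "dmod_coefficients": self.dmod_coefficients.as_dict(),
            "regions": {
                label: {
                    "y_half_width_cm": r.y_half_width,
                    "z_min_cm": r.z_min,
                    "z_max_cm": r.z_max,
                }
                for label, r in self.regions.items()
            },
            "foam_adjustments": {
                "sigma_theta_factor": self.foam_sigma_theta_factor,
                "shift_r90": self.foam_shift_r90,
                "reduce_e_p0": self.foam_reduce_e_p0,
            },
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


def write_report_json(path, report, **extra) -> None:
    """AgreementReport (or any mapping) as JSON."""
    data = report.as_dict() if hasattr(report, "as_dict") else dict(report)
    data.update(extra)
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
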