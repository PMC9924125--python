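# primescatter

Island-block scatter modeling for passive electron intensity modulators
(PRIME devices) used in intensity-modulated bolus electron conformal therapy
(IM-BECT).

A PRIME device is a lattice of short cylindrical tungsten rods ("island
blocks") embedded in low-density machinable foam inside the electron beam's
collimating insert. Blocks absorb the electrons hitting their upstream face;
downstream scatter restores a locally uniform but reduced fluence. For blocks
of diameter *d*<sub>nom</sub> on a hexagonal grid of packing radius *r*, the
nominal intensity reduction factor is

> IRF<sub>nom</sub> = 1 − (π / 2√3) (*d*<sub>nom</sub> / *r*)²

Treating blocks as perfect collimators is not quite right: electrons
scattered **into** a block's side are lost (the block acts larger), and
electrons scattered **out** of its side return to the beam (it acts
smaller). This package implements both corrections:

* **In-scatter (pencil-beam theory).** Model the block as a square
  parallelepiped of equal cross-section (side *s* = *d*√π/2). With lateral
  Gaussian blur of RMS σ<sub>x</sub>, the side-impinging fraction is
  *f* = 1 − P(w)², where P(w) = erf(w) + (e^(−w²) − 1)/(w√π) and
  w = *s*/(√2 σ<sub>x</sub>). This yields an effective diameter
  *d*<sub>IS</sub> = *d*<sub>nom</sub>√(1 + *f*) and
  IRF<sub>IS</sub> = IRF<sub>nom</sub> − *f*(1 − IRF<sub>nom</sub>).
* **Out-scatter (empirical).** No closed form exists; both effects are
  absorbed into a modified diameter parameterized as a quadratic surface
  *d*<sub>mod</sub>(*d*<sub>nom</sub>, *E*<sub>p,0</sub>) =
  A₀ + A₁d + A₂E + A₃d² + A₄dE + A₅E², with coefficients fitted by least
  squares to the diameters that best matched measured dose planes for three
  test devices at 7, 13 and 20 MeV.

Around this core the package provides the device geometry (hexagonal lattice
builder, text device files projected to isocenter), a Gaussian pencil-beam
fluence/dose forward model (square-pencil deficits subtracted from the open
field, dose = PDD × off-axis ratio on a 0.1 cm grid), the least-squares
diameter calibration against a measured dose plane, RMS and 2%/2 mm
(dose-difference or distance-to-agreement) metrics, and a synthetic
water-phantom data generator so the whole calibration loop runs without
measurements.

It is intended for medical physicists and algorithm developers working on
electron intensity modulation who need the scatter-corrected block diameters,
or a reproducible sandbox for the diameter-calibration workflow.

## Worked example

```python
from primescatter import (
    build_hex_device, irf_nominal, in_scatter_result, d_modified,
    SyntheticConfig, gen_measured_grid, optimize_dmod,
    region_for_energy, pass_rate_2pct_2mm,
)
from primescatter.reference import STUDY_BEAMS, FIELD_EXTENT, GRID_RADIUS, calibrated_sigma_x
from primescatter.synthetic import forward_model_for

beam = STUDY_BEAMS["20MeV"]                     # E_p0 = 20.47 MeV
device = build_hex_device(*FIELD_EXTENT, r=GRID_RADIUS, d_nom=0.273)
print(f"device: {device.n_blocks} blocks, IRF_nom = {irf_nominal(0.273, GRID_RADIUS):.3f}")

res = in_scatter_result(0.273, GRID_RADIUS, calibrated_sigma_x(beam.e_p0))
print(f"in-scatter at {beam.e_p0} MeV: f = {res.f:.3f}, d_IS = {res.d_is:.3f} cm, IRF_IS = {res.irf_is:.3f}")
d_mod = d_modified(0.273, beam.e_p0)
print(f"modified diameter d_mod = {d_mod:.3f} cm")

# synthetic "measured" grid at the modified diameter, then recover it
meas = gen_measured_grid(SyntheticConfig(
    beam=beam, device=device, d_true=d_mod, noise_sd=0.5, seed=42))
region = region_for_energy(beam.e_p0)
d_hat = optimize_dmod(meas, device, beam, region, (0.15, 0.45))
print(f"recovered effective diameter: {d_hat:.4f} cm (truth {d_mod:.4f})")

calc = forward_model_for(beam, device).dose(d_hat, meas.y, meas.z)
rep = pass_rate_2pct_2mm(calc, meas, region)
print(f"agreement: RMS = {rep.rms_percent:.3f}%, 2%/2mm pass rate = {rep.pass_rate:.1f}% over {rep.n_points} points")
```

which prints

```
device: 247 blocks, IRF_nom = 0.812
in-scatter at 20.47 MeV: f = 0.102, d_IS = 0.287 cm, IRF_IS = 0.793
modified diameter d_mod = 0.271 cm
recovered effective diameter: 0.2705 cm (truth 0.2706)
agreement: RMS = 0.500%, 2%/2mm pass rate = 100.0% over 4331 points
```

Reading: the 0.273 cm blocks nominally transmit 81.2% of the fluence; at
20 MeV side in-scatter alone would lower that to 79.3%, but out-scatter
wins at high energy and the net modified diameter (0.271 cm) is slightly
*smaller* than physical. The least-squares calibration recovers the
generating diameter to 0.0001 cm from a noisy synthetic scan, the residual
RMS equals the injected 0.5% noise, and every point in the modulated region
(|y| ≤ 3.5 cm, 0.5 ≤ z ≤ 6.5 cm) passes 2%/2 mm.

A `prime` console script exposes the same operations
(`irf`, `inscatter`, `dmod`, `fluence`, `dose`, `optimize`, `compare`,
`simulate`, `make-fixtures`); try `prime --help`.

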