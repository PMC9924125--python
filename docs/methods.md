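# Methods

## Device geometry

A modulator is a list of island blocks (cylindrical tungsten rods, 0.6 cm
long by default) at positions (x, y) with nominal diameters d_nom, embedded
in a machinable foam slab (1.27 cm, 0.096 g/cm³ by default). The canonical
internal plane is the insert plane, 95 cm from the source (5 cm upstream of
isocenter); device text files store isocenter-projected positions and
diameters and are converted on read by divergent-beam scaling from the
source. Coordinates: x = cross-plane, y = in-plane (scan direction),
z = depth in water, all cm; dose planes are (y, z) at fixed x.

The hexagonal builder centers the lattice on the origin with a block at
(0, 0): rows at y = k(√3/2)r, even rows at x = mr, odd rows at x = (m+½)r.
Boundary sites are included within 1e-9 cm, so an 8.4 × 8.4 cm² extent at
r = 0.6 cm keeps the sites at exactly ±4.2 cm and yields the 247-block test
matrix. The lattice phase (block at the center) is a convention adopted here;
it is the one that reproduces the 247 count.

Blocks are treated as total absorbers: attenuation and scatter inside the
tungsten are not transported, which is exactly what the effective-diameter
corrections below compensate for. Packing invariants are enforced on
construction (pairwise spacing ≥ r, d_nom < r, blocks inside a declared
extent).

## In-scatter theory

The block is modeled as a right square parallelepiped of equal
cross-section, side s = d√π/2. An electron launched uniformly over the
square and displaced laterally by a zero-mean Gaussian of RMS σx (per axis,
independent) stays inside a slit of width s with probability

    P(w) = erf(w) + (exp(−w²) − 1)/(w √π),     w = s/(√2 σx),

so the fraction impinging the sides of the block is f = 1 − P(w)². For
w < 1e-6 the series limit P ≈ w/√π is used to avoid 0/0; σx = 0 returns
exactly f = 0, and f → 1 as σx → ∞. A ≥10⁶-sample Monte-Carlo simulation of
the same experiment cross-checks the closed form in the test suite.

Folding the side-impinging electrons into the absorber gives the effective
diameter d_IS = d_nom √(1+f) (equal-area argument) and the adjusted
intensity reduction factor IRF_IS = IRF_nom − f (1 − IRF_nom). Both express
removal of the same fractional fluence, and the package asserts their mutual
consistency (IRF_nom evaluated at d_IS equals IRF_IS) to 1e-12.

The lateral spread entering f can come from two routes:

* physically, σx = t √(σθx² + (1/6)(T/ρ)foam ρfoam t), given the projected
  angular spread σθx of the incident beam (optionally ×1.5 for the foam
  slab) and the foam's mass scattering power — for users who have those
  commissioning parameters;
* by calibration: one σx per beam energy, obtained by inverting f at the
  smallest study diameter (0.158 cm) against its tabulated fraction. This is
  the package default because the angular-spread and scattering-power values
  behind the tabulated fractions are not published. The inversion is a
  bracketed Brent root find (f is strictly increasing in σx) to machine
  tolerance. The calibrated spreads are ≈0.0419, 0.0253 and 0.0158 cm at
  7.14, 13.12 and 20.47 MeV, and a single spread per energy predicts the
  tabulated fractions at the other two diameters to ±0.001 — the validation
  that pins down the containment form of f above.

## Modified-diameter surface

Out-scattered electrons have broad energy and angular spectra and no closed
pencil-beam form, so the net effect of both scatter channels is absorbed
into a modified diameter fitted per device/energy pair and parameterized as

    d_mod(d, E) = A0 + A1 d + A2 E + A3 d² + A4 d E + A5 E².

Default coefficients (A0 = 1.61e-2 cm, A1 = 1.09, A2 = −2.51e-3 cm/MeV,
A3 = −1.45e-1 cm⁻¹, A4 = −1.40e-3 MeV⁻¹, A5 = 6.42e-5 cm/MeV²) are the
commissioned values for 0.158–0.352 cm blocks at 7.14–20.47 MeV; they
reproduce the nine commissioned d_mod values within 0.003 cm (the
coefficients are only quoted to three significant figures). Refitting the
surface to the nine triplets with the package's own least-squares fitter
leaves residuals ≤ 0.0004 cm. Evaluation outside the commissioned energy
range is allowed but warns. Note the commissioned IRF_mod values quoted
alongside rounded d_mod values were computed from unrounded diameters;
recomputing IRF from a 3-decimal d_mod can differ in the last digit. The
package always computes IRF from the unrounded diameter.

At 7 MeV d_mod exceeds d_nom (in-scatter dominates), at 13 MeV they roughly
cancel, and at 20 MeV d_mod < d_nom (out-scatter dominates); the forward
model's deficit ordering under the three diameter modes reflects this.

## Forward fluence/dose model

Each block contributes a separable square-pencil deficit
H(x−xi; s/2, σ) H(y−yi; s/2, σ), H being the 1-D Gaussian-convolved top-hat;
the open field is unit fluence with an erf-blurred penumbra of width
σ_edge (default 0.15 cm — the penumbra model is a free parameter here, not a
commissioned value, and is irrelevant inside the modulated region). The
deficit integrates exactly to s² for any σ (area conservation under
convolution), and the spatial average under a periodic lattice equals the
IRF, both asserted numerically.

Dose planes are composed as D(y, z) = PDD(z) × OAR(y, z) with the off-axis
ratio taken from the fluence profile at depth and 100% = the foam-only
central-axis maximum. The depth-dependent lateral spread is
σ(z)² = σ_device² + σ_water(z)², σ_water(z) = k z^{3/2} / √E_p0 with
k = 0.1 cm^{-1/2} MeV^{1/2} by default. This single-redefinition Gaussian
transport is a deliberate simplification of the clinical
pencil-beam-redefinition engine (which redefines pencils at stepped planes
and carries an energy-binned spectrum); energy bins are collapsed to one
effective bin, consistent with treating the scattered spectrum as the
primary spectrum. Divergence-tilted block axes, cutout edge scatter and
heterogeneities are out of scope.

## Synthetic measured data

The generator emulates the structure of water-phantom commissioning data:
a PDD × off-axis-ratio product re-gridded at 0.1 cm. The analytic PDD is a
piecewise-cosine curve exact at its landmarks (100% at R100, 90% at R90,
x-ray background at Rp and beyond, ~85% surface dose); the landmarks for the
7/13/20 MeV study beams (R100 = 1.4/2.6/2.8, R90 = 1.9/4.3/6.3,
Rp = 3.5/6.6/10.2 cm, background 0.7/1.5/3.0%) are rule-of-thumb electron
depth-dose values chosen once so each R90 sits just below the stated
modulated-region depth limit (2.0/4.5/6.5 cm). Noise is homoscedastic
Gaussian in percent of given dose (0.5% default), seeded and reproducible.

What this does *not* emulate: real build-up/falloff shapes, chamber volume
averaging, beam symmetry errors, or the out-of-field scatter tail observed
under real devices. Passing tests therefore demonstrate the correctness of
the geometry, scatter formulae, metrics and the calibration loop's
self-consistency — not clinical dose accuracy against water-tank scans,
which requires measured data.

## Diameter calibration and agreement metrics

`optimize_dmod` minimizes the sum of squared dose differences over the
modulated region (|y| ≤ 3.5 cm, 0.5 cm ≤ z ≤ 2.0/4.5/6.5 cm per energy) for
a single diameter shared by all blocks, using a 0.005 cm coarse pre-scan (to
guard against non-unimodality) followed by bounded scalar minimization to
1e-4 cm. On synthetic grids it recovers the generating diameter to well
under 0.002 cm noiseless and under 0.005 cm with 0.5% noise.

Dose differences are globally normalized (% of the foam-only maximum). The
2%/2 mm pass rate takes the measured grid as reference: a point passes on
|ΔD| ≤ 2% or if the calculated distribution attains the measured value
within 2 mm. Attainment is evaluated on a linearly interpolated calculated
grid (upsampled to 0.02 cm): because the interpolant is continuous and the
search disc connected, the value is attained iff it lies between the local
minimum and maximum over the disc, computed with circular-footprint rank
filters. This interpolating convention is a choice — nearest-grid-point DTA
would be slightly stricter — and is exposed via `fine_spacing`. The grid
spacing must be ≤ half the DTA tolerance.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 247-block device on 0.1 cm
grids (the study geometry); recovery replicates use the 7 MeV beam's region
(~1.1k points per evaluation). Root finds use Brent with 1e-14 x-tolerance;
the surface fit is ordinary least squares on the 6-term basis with a rank
check; quadrature checks use trapezoid rules at ≤ σ/4 spacing. Degenerate
inputs (zero blocks, σ = 0, empty regions, out-of-domain depths) raise or
return exact limits as documented on each function.
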