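import numpy as np
import pytest
from scipy.stats import spearmanr

from primescatter.calibrate import (
    RegionSpec,
    optimize_dmod,
    pass_rate_2pct_2mm,
    region_for_energy,
    rms_percent,
)
from primescatter.fluence import DoseGrid
from primescatter.reference import STUDY_BEAMS
from primescatter.synthetic import SyntheticConfig, gen_measured_grid


def flat_grid(value=50.0, spacing=0.1, ny=41, nz=31):
    y = (np.arange(ny) - ny // 2) * spacing
    z = np.arange(nz) * spacing
    return DoseGrid(y=y, z=z, values=np.full((nz, ny), float(value)))


SMALL_REGION = RegionSpec(y_half_width=1.5, z_min=0.3, z_max=2.5)


@pytest.fixture(scope="module")
def synthetic_pair():
    """Noiseless measured grid and a perturbed calculated grid (7 MeV)."""
    from primescatter.device import build_hex_device

    beam = STUDY_BEAMS["7MeV"]
    device = build_hex_device(8.4, 8.4, 0.6, 0.273)
    meas = gen_measured_grid(SyntheticConfig(beam=beam, device=device, d_true=0.30, noise_sd=0.0))
    return beam, device, meas


class TestRegionSpec:
    def test_invalid_regions_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec(z_min=2.0, z_max=1.0)
        with pytest.raises(ValueError):
            RegionSpec(y_half_width=0.0)

    def test_region_for_commissioned_energy(self):
        assert region_for_energy(7.14).z_max == 2.0
        assert region_for_energy(20.47).z_max == 6.5
        with pytest.raises(KeyError):
            region_for_energy(45.0)


class TestRms:
    def test_identical_grids(self):
        g = flat_grid()
        assert rms_percent(g, g, SMALL_REGION) == 0.0

    def test_uniform_offset(self):
        g = flat_grid()
        g2 = flat_grid(51.0)
        assert rms_percent(g2, g, SMALL_REGION) == pytest.approx(1.0)

    def test_matches_brute_force_loop(self, rng):
        g = flat_grid()
        calc = flat_grid()
        calc.values = calc.values + rng.normal(0, 2, calc.values.shape)
        expected_sq, n = 0.0, 0
        for i, z in enumerate(g.z):
            for j, y in enumerate(g.y):
                if abs(y) <= SMALL_REGION.y_half_width + 1e-9 and (
                    SMALL_REGION.z_min - 1e-9 <= z <= SMALL_REGION.z_max + 1e-9
                ):
                    expected_sq += (calc.values[i, j] - g.values[i, j]) ** 2
                    n += 1
        assert rms_percent(calc, g, SMALL_REGION) == pytest.approx(np.sqrt(expected_sq / n))

    def test_empty_region_rejected(self):
        g = flat_grid()
        with pytest.raises(ValueError, match="region"):
            rms_percent(g, g, RegionSpec(z_min=50.0, z_max=60.0))


class TestPassRate:
    def test_identical_grids_pass_everywhere(self):
        g = flat_grid()
        rep = pass_rate_2pct_2mm(g, g, SMALL_REGION)
        assert rep.pass_rate == 100.0
        assert rep.n_points > 0
        assert not rep.fail_mask.any()

    def test_flat_field_offset_beyond_tolerance_fails_everywhere(self):
        # on a constant-dose field the DTA search cannot rescue a 2.1% offset
        meas = flat_grid()
        calc = flat_grid(52.1)
        rep = pass_rate_2pct_2mm(calc, meas, SMALL_REGION)
        assert rep.pass_rate == 0.0

    def test_offset_within_dose_tolerance_passes_everywhere(self):
        meas = flat_grid()
        calc = flat_grid(51.9)
        assert pass_rate_2pct_2mm(calc, meas, SMALL_REGION).pass_rate == 100.0

    def test_coarse_grid_rejected(self):
        y = np.arange(-2, 2.1, 0.3)
        z = np.arange(0, 3.1, 0.3)
        g = DoseGrid(y=y, z=z, values=np.full((z.size, y.size), 50.0))
        with pytest.raises(ValueError, match="coarse"):
            pass_rate_2pct_2mm(g, g, SMALL_REGION)

    def test_monotone_in_tolerances(self, synthetic_pair):
        beam, device, meas = synthetic_pair
        region = region_for_energy(beam.e_p0)
        calc = DoseGrid(y=meas.y, z=meas.z, values=meas.values + 2.5)
        base = pass_rate_2pct_2mm(calc, meas, region).pass_rate
        looser_dose = pass_rate_2pct_2mm(calc, meas, region, dose_tol=3.0).pass_rate
        looser_dta = pass_rate_2pct_2mm(calc, meas, region, dta_tol=0.3).pass_rate
        assert looser_dose >= base
        assert looser_dta >= base

    def test_dta_rescues_shifted_gradient(self):
        # a 1 mm depth shift of a steep gradient fails on dose but passes DTA
        y = (np.arange(21) - 10) * 0.1
        z = np.arange(41) * 0.1
        slope = 30.0  # %/cm
        vals = 100.0 - slope * z[:, None] + 0.0 * y[None, :]
        meas = DoseGrid(y=y, z=z, values=np.broadcast_to(vals, (41, 21)).copy())
        calc = DoseGrid(y=y, z=z, values=meas.values - slope * 0.1)  # 3% offset, 1 mm shift
        region = RegionSpec(y_half_width=1.0, z_min=0.5, z_max=3.5)
        rep = pass_rate_2pct_2mm(calc, meas, region)
        assert rep.pass_rate == 100.0

    def test_pass_rate_anticorrelates_with_rms(self, synthetic_pair):
        beam, device, meas = synthetic_pair
        region = region_for_energy(beam.e_p0)
        rmss, rates = [], []
        for c in (0.5, 1.5, 2.5, 3.0, 4.0, 5.0):
            calc = DoseGrid(y=meas.y, z=meas.z, values=meas.values + c)
            rep = pass_rate_2pct_2mm(calc, meas, region)
            rmss.append(rep.rms_percent)
            rates.append(rep.pass_rate)
        rho = spearmanr(rmss, rates).statistic
        assert rho < 0


class TestOptimizeDmod:
    def test_noiseless_self_consistency(self, synthetic_pair):
        beam, device, meas = synthetic_pair
        region = region_for_energy(beam.e_p0)
        d = optimize_dmod(meas, device, beam, region, (0.2, 0.4))
        assert d == pytest.approx(0.30, abs=0.002)

    def test_rms_improves_over_nominal(self, synthetic_pair):
        beam, device, meas = synthetic_pair  # generated at d_true = 0.30
        region = region_for_energy(beam.e_p0)
        d_hat = optimize_dmod(meas, device, beam, region, (0.2, 0.4))
        nominal = gen_measured_grid(
            SyntheticConfig(beam=beam, device=device, d_true=0.273, noise_sd=0.0)
        )
        fitted = gen_measured_grid(
            SyntheticConfig(beam=beam, device=device, d_true=d_hat, noise_sd=0.0)
        )
        assert rms_percent(fitted, meas, region) <= rms_percent(nominal, meas, region)

    def test_degenerate_bounds_rejected(self, synthetic_pair):
        beam, device, meas = synthetic_pair
        region = region_for_energy(beam.e_p0)
        with pytest.raises(ValueError, match="bounds"):
            optimize_dmod(meas, device, beam, region, (0.4, 0.2))
        with pytest.raises(ValueError, match="bounds"):
            optimize_dmod(meas, device, beam, region, (0.2, 0.9))
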