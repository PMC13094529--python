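"""Spherical-crown light-penetration model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optocord import optics


class TestScalarOps:
    @pytest.mark.parametrize(
        "duty,power",
        [(0.25, 1.1725), (0.5, 2.345), (0.75, 3.5175), (1.0, 4.69), (0.0, 0.0)],
    )
    def test_duty_scaled_power(self, source, duty, power):
        assert optics.duty_scaled_power(
            source, optics.PWMSetting(duty)
        ) == pytest.approx(power)

    def test_surface_density_crown_area(self, source):
        # crown lateral area 2 pi rho H = 0.4788 mm^2 with device constants
        assert source.crown_area_mm2 == pytest.approx(0.47878, rel=1e-4)
        assert optics.surface_power_density(source, 0.0) == 0.0
        assert optics.surface_power_density(source, 4.69) == pytest.approx(
            9.796, rel=1e-3
        )
        assert optics.surface_power_density(source, 3.5175) == pytest.approx(
            7.347, rel=1e-3
        )

    def test_attenuation_geometric_values(self, source):
        rho = source.crown_radius_rho
        assert optics.attenuation_geometric(0.0, source) == 1.0
        assert optics.attenuation_geometric(rho, source) == pytest.approx(0.25)
        # hand arithmetic: 0.508^2 / 0.608^2
        assert optics.attenuation_geometric(0.1, source) == pytest.approx(
            0.6981, abs=1e-4
        )
        with pytest.raises(ValueError):
            optics.attenuation_geometric(-0.1, source)

    def test_attenuation_full_values(self, source, tissue):
        assert optics.attenuation_full(0.0, source, tissue) == 1.0
        # hand oracle: geometric 0.6981 x 1/(10.3*0.1 + 1)
        assert optics.attenuation_full(0.1, source, tissue) == pytest.approx(
            0.3439, abs=1e-4
        )
        no_scatter = optics.TissueOptics(scattering_S=0.0)
        z = np.linspace(0, 2, 50)
        np.testing.assert_allclose(
            optics.attenuation_full(z, source, no_scatter),
            optics.attenuation_geometric(z, source),
        )

    def test_power_density_at_depth(self, source, tissue):
        # printed check: 75% duty falls to the 1 mW/mm2 threshold at 236 um
        assert optics.power_density_at_depth(
            0.236, source, tissue, 3.5175
        ) == pytest.approx(1.0, rel=2e-3)
        assert optics.power_density_at_depth(
            0.0, source, tissue, 4.69
        ) == pytest.approx(9.796, rel=1e-3)
        assert optics.power_density_at_depth(50.0, source, tissue, 4.69) < 1e-4


class TestEffectiveDepth:
    @pytest.mark.parametrize(
        "duty,depth_um",
        [(0.25, 80), (0.5, 170), (0.75, 236), (1.0, 289)],
    )
    def test_printed_depths(self, source, tissue, duty, depth_um):
        z, ok = optics.effective_depth(source, tissue, duty * 4.69)
        assert ok
        assert z * 1000 == pytest.approx(depth_um, abs=1.0)

    def test_subthreshold_flagged(self, source, tissue):
        z, ok = optics.effective_depth(source, tissue, 0.4)
        assert (z, ok) == (0.0, False)

    def test_roundtrip_threshold(self, source, tissue):
        for p in (1.1725, 2.345, 4.69):
            z, _ = optics.effective_depth(source, tissue, p)
            i = optics.power_density_at_depth(z, source, tissue, p)
            assert i == pytest.approx(tissue.opsin_threshold, rel=1e-6)

    def test_against_grid_scan_oracle(self, tissue):
        """Root agrees with a dense-grid scan for random parameter draws."""
        rng = np.random.default_rng(42)
        z_grid = np.arange(0.0, 1.5, 1e-5)
        for _ in range(100):
            src = optics.LEDSource(
                crown_radius_rho=rng.uniform(0.3, 0.8),
                crown_height_H=rng.uniform(0.05, 0.3),
            )
            opt = optics.TissueOptics(scattering_S=rng.uniform(5.0, 20.0))
            p = rng.uniform(1.0, 6.0)
            z_root, ok = optics.effective_depth(src, opt, p)
            dens = optics.power_density_at_depth(z_grid, src, opt, p)
            if not ok:
                assert dens[0] <= opt.opsin_threshold
                continue
            z_scan = z_grid[np.searchsorted(-dens, -opt.opsin_threshold)]
            assert abs(z_root - z_scan) < 1e-4

    def test_monotone_in_power(self, source, tissue):
        depths = [
            optics.effective_depth(source, tissue, p)[0] for p in (1.0, 2.0, 4.0)
        ]
        assert depths == sorted(depths)


class TestAreaAndTable:
    def test_effective_area_closed_form(self, source):
        assert optics.effective_area(0.0, source) == pytest.approx(0.811, abs=1e-3)
        assert optics.effective_area(0.289, source) == pytest.approx(1.995, abs=1e-2)
        assert optics.effective_area(0.080, source) == pytest.approx(1.086, abs=1e-2)
        with pytest.raises(ValueError):
            optics.effective_area(-1.0, source)

    def test_custom_area_model(self, source, tissue):
        df = optics.pwm_summary_table(
            source, tissue, (1.0,), area_model=lambda z, s: 99.0
        )
        assert df["effective_area_mm2"].iloc[0] == 99.0

    def test_table_matches_scalar_ops(self, source, tissue):
        df = optics.pwm_summary_table(source, tissue, (0.25, 0.5, 0.75, 1.0))
        np.testing.assert_allclose(
            df["surface_density_mW_mm2"], [2.449, 4.898, 7.347, 9.796], rtol=1e-3
        )
        assert df["effective_depth_mm"].iloc[1] == pytest.approx(0.170, abs=1e-3)
        single = optics.pwm_summary_table(source, tissue, (1.0,))
        assert single["luminous_power_mW"].iloc[0] == pytest.approx(4.69)
        with pytest.raises(ValueError):
            optics.pwm_summary_table(source, tissue, ())


class TestProperties:
    @settings(derandomize=True, max_examples=50)
    @given(
        z1=st.floats(0.0, 5.0),
        z2=st.floats(1e-6, 1.0),
        p=st.floats(0.1, 50.0),
        s=st.floats(0.0, 30.0),
    )
    def test_decreasing_and_linear(self, z1, z2, p, s):
        src = optics.LEDSource()
        opt = optics.TissueOptics(scattering_S=s)
        i1 = optics.power_density_at_depth(z1, src, opt, p)
        i2 = optics.power_density_at_depth(z1 + z2, src, opt, p)
        assert i2 < i1
        # strict linearity in power
        assert optics.power_density_at_depth(z1, src, opt, 2 * p) == pytest.approx(
            2 * i1, rel=1e-12
        )
        # scattering only ever attenuates
        assert optics.attenuation_full(z1, src, opt) <= optics.attenuation_geometric(
            z1, src
        )

    def test_fit_scattering_recovers_truth(self, source):
        truth = optics.TissueOptics(scattering_S=10.3)
        z = np.linspace(0.0, 0.5, 60)
        profile = optics.power_density_at_depth(z, source, truth, 4.69)
        s_hat = optics.fit_scattering(z, profile, source, 4.69)
        assert s_hat == pytest.approx(10.3, rel=1e-3)


def test_invalid_domain_types():
    with pytest.raises(ValueError):
        optics.LEDSource(crown_radius_rho=-1.0)
    with pytest.raises(ValueError):
        optics.LEDSource(divergence_angle=200.0)
    with pytest.raises(ValueError):
        optics.TissueOptics(opsin_threshold=0.0)
    with pytest.raises(ValueError):
        optics.PWMSetting(1.3)
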