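"""Synthetic-data generators: determinism, schema conformance, planted truth."""

import numpy as np
import pytest

from scatterprint.colloid import cumulant_pdi, diffusion_coefficient
from scatterprint.curves import read_composition_table, write_composition_table
from scatterprint.smearing import SmearingGeometry
from scatterprint.synth import (
    DLS_TEMPERATURE_K,
    DLS_VISCOSITY,
    EmulsionModel,
    GaussianPeak,
    ModelValidationError,
    PorodSphere,
    PowerLaw,
    dls_rate_distribution,
    generate_dls_correlation,
    generate_emulsion_curve,
    generate_sample_set,
    scattering_vector,
    sphere_intensity,
)


class TestEmulsionCurve:
    def test_single_power_law_is_exact(self):
        model = EmulsionModel(power_laws=[PowerLaw(2.0, 2.5)],
                              q_range=(1e-3, 1.0), n_points=100)
        c = generate_emulsion_curve(model)
        np.testing.assert_allclose(c.intensity, 2.0 * c.q ** -2.5, rtol=1e-12)

    def test_seed_reproducibility(self):
        model = EmulsionModel(power_laws=[PowerLaw(1.0, 2.0)],
                              q_range=(1e-3, 1.0), noise=0.1, seed=42)
        a = generate_emulsion_curve(model)
        b = generate_emulsion_curve(model)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        other = EmulsionModel(power_laws=[PowerLaw(1.0, 2.0)],
                              q_range=(1e-3, 1.0), noise=0.1, seed=43)
        assert not np.array_equal(
            generate_emulsion_curve(other).intensity, a.intensity
        )

    def test_sphere_high_q_slope_is_porod(self, droplet_curve):
        sel = droplet_curve.q >= 0.002
        slope = np.polyfit(np.log(droplet_curve.q[sel]),
                           np.log(droplet_curve.intensity[sel]), 1)[0]
        assert slope == pytest.approx(-4.0, abs=0.1)

    def test_smear_option_records_geometry(self, droplet_model):
        c = generate_emulsion_curve(droplet_model,
                                    smear=SmearingGeometry(0.015))
        assert c.smeared and c.slit_length == 0.015

    def test_validation_lists_problems(self):
        model = EmulsionModel(power_laws=[PowerLaw(-1.0, 9.0)],
                              peaks=[GaussianPeak(5.0, -0.1, -1.0)])
        with pytest.raises(ModelValidationError) as err:
            generate_emulsion_curve(model)
        msg = str(err.value)
        assert "exponent" in msg and "amplitude" in msg and "width" in msg

    def test_zero_polydispersity_matches_single_sphere_form(self):
        sphere = PorodSphere(mean_radius_um=0.1, polydispersity=0.0,
                             volume_fraction=0.01)
        q = np.geomspace(1e-4, 1e-3, 50)
        i = sphere_intensity(q, sphere)
        r = 0.1 * 1e4
        x = q * r
        f = 3 * (np.sin(x) - x * np.cos(x)) / x ** 3
        v = 4 / 3 * np.pi * r ** 3
        expected = 0.01 / v * sphere.delta_rho ** 2 * v ** 2 * f ** 2 / 1e-8
        np.testing.assert_allclose(i, expected, rtol=1e-9)


class TestSampleSet:
    def test_determinism_and_schema(self, tmp_path):
        curves, records, truth = generate_sample_set(29, seed=3, n_points=200)
        curves2, records2, _ = generate_sample_set(29, seed=3, n_points=200)
        assert records == records2
        np.testing.assert_array_equal(curves[0].intensity, curves2[0].intensity)
        # table round-trips through the composition reader's validation
        path = tmp_path / "comp.csv"
        write_composition_table(records, path)
        back = read_composition_table(path)
        assert back == records
        assert {r.category for r in records} == {"milk", "yoghurt", "cream"}
        assert all(1.0 <= r.fat <= 36.0 for r in records)

    def test_curves_validate_downstream_preconditions(self):
        curves, _, _ = generate_sample_set(6, seed=0, n_points=200)
        for c in curves:
            assert np.all(np.diff(c.q) > 0) and np.all(c.q > 0)
            assert c.mask.all()

    def test_planted_fat_link_monotone_at_zero_noise(self):
        from scatterprint.correlations import intensity_at_q, spearman

        curves, records, _ = generate_sample_set(8, noise=0.0, seed=9,
                                                 n_points=300)
        rho, _ = spearman([r.fat for r in records],
                          [intensity_at_q(c, 0.0003) for c in curves])
        assert rho == pytest.approx(1.0)


class TestDLSGenerator:
    def test_monodisperse_pdi_zero(self):
        lag, g2, _ = generate_dls_correlation(1500.0, 0.0)
        fit = cumulant_pdi(lag, g2, baseline=1.0, coherence_factor=1.0)
        assert fit.pdi == pytest.approx(0.0, abs=1e-3)

    def test_mean_rate_matches_stokes_einstein(self):
        lag, g2, truth = generate_dls_correlation(1500.0, 0.0)
        fit = cumulant_pdi(lag, g2, baseline=1.0, coherence_factor=1.0)
        D = diffusion_coefficient(1500.0, DLS_TEMPERATURE_K, DLS_VISCOSITY)
        expected = D * scattering_vector() ** 2
        assert fit.a1 == pytest.approx(expected, rel=1e-3)
        assert truth["mean_rate"] == pytest.approx(expected, rel=1e-12)

    def test_spread_pdi_matches_integration_oracle(self):
        spread = 0.3
        lag, g2, truth = generate_dls_correlation(1500.0, spread)
        fit = cumulant_pdi(lag, g2, baseline=1.0, coherence_factor=1.0)
        # oracle: independent dense numeric integration of the planted
        # intensity-weighted decay-rate distribution
        rates, w = dls_rate_distribution(1500.0, spread, n_nodes=4001)
        mean = float((w * rates).sum())
        relvar = float((w * (rates - mean) ** 2).sum()) / mean ** 2
        assert truth["rate_relative_variance"] == pytest.approx(relvar, rel=1e-3)
        assert fit.pdi == pytest.approx(relvar, rel=0.10)

    def test_noise_is_seeded(self):
        a = generate_dls_correlation(1500.0, 0.1, noise=1e-3, seed=1)[1]
        b = generate_dls_correlation(1500.0, 0.1, noise=1e-3, seed=1)[1]
        c = generate_dls_correlation(1500.0, 0.1, noise=1e-3, seed=2)[1]
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_optics(self):
        with pytest.raises(ValueError):
            scattering_vector(wavelength_nm=-1.0)
        with pytest.raises(ValueError):
            generate_dls_correlation(-10.0, 0.1)
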