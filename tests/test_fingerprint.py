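"""Log-Q resampling, gradients, normalisation and fingerprint matrices."""

import numpy as np
import pytest

from scatterprint.curves import ScatteringCurve
from scatterprint.fingerprint import (
    build_fingerprint,
    classify_regime,
    loglog_gradient,
    normalize_intensity,
    resample_loglog,
)

from conftest import power_law_curve


def lamellar_curve(sample_id="s", amp=5.0):
    q = np.geomspace(1e-3, 1.0, 800)
    i = 1e-4 * q ** -2.0 + amp * np.exp(-0.5 * ((q - 0.15) / 0.012) ** 2) + 0.01
    return ScatteringCurve(q=q, intensity=i, sample_id=sample_id)


class TestResample:
    def test_power_law_is_exact(self):
        c = power_law_curve(amplitude=2.0, exponent=2.5, qlo=1e-3, qhi=1.0)
        qg, ig = resample_loglog(c, 100)
        np.testing.assert_allclose(ig, 2.0 * qg ** -2.5, rtol=1e-12)

    def test_grid_properties(self):
        c = power_law_curve(qlo=1e-3, qhi=1.0)
        qg, _ = resample_loglog(c, 100)
        assert len(qg) == 100
        assert qg[0] == c.q[0] and qg[-1] == c.q[-1]
        ratios = qg[1:] / qg[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_needs_a_decade(self):
        c = power_law_curve(qlo=1e-3, qhi=5e-3)
        with pytest.raises(ValueError):
            resample_loglog(c, 100)


class TestGradient:
    def test_power_law_gradient_exact(self):
        for p in (0.5, 2.0, 4.0):
            c = power_law_curve(amplitude=1.0, exponent=p, qlo=1e-3, qhi=1.0)
            qg, ig = resample_loglog(c, 100)
            _, g = loglog_gradient(qg, ig)
            assert np.max(np.abs(g + p)) < 1e-9

    def test_constant_gradient_zero(self):
        q = np.geomspace(1e-3, 1.0, 50)
        _, g = loglog_gradient(q, np.full_like(q, 2.0))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_gradient_sign_change_at_planted_peak(self):
        c = lamellar_curve()
        qg, ig = resample_loglog(c, 200)
        qm, g = loglog_gradient(qg, ig)
        # signed gradient crosses zero within one grid step of the apex
        crossings = qm[np.where(np.diff(np.sign(g)) < 0)[0]]
        step = qg[1] / qg[0]
        assert any(0.15 / step <= x <= 0.15 * step for x in crossings)
        # modulus shows a local maximum on each flank
        mod = np.abs(g)
        near = (qm > 0.1) & (qm < 0.15 / step)
        far = (qm > 0.15 * step) & (qm < 0.25)
        assert mod[near].max() > 1.0 and mod[far].max() > 1.0


class TestNormalize:
    def test_hits_zero_and_one(self):
        c = lamellar_curve()
        _, ig = resample_loglog(c, 100)
        out = normalize_intensity(ig)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_scalar_invariance(self):
        _, ig = resample_loglog(lamellar_curve(), 100)
        np.testing.assert_allclose(
            normalize_intensity(ig), normalize_intensity(17.3 * ig), atol=1e-12
        )

    def test_monotone_preserved_and_constant_rejected(self):
        q = np.geomspace(1e-3, 1.0, 50)
        out = normalize_intensity(q ** -1.0)
        assert np.all(np.diff(out) < 0)
        with pytest.raises(ValueError):
            normalize_intensity(np.full(50, 2.0))


class TestClassify:
    @pytest.mark.parametrize(
        "g, label",
        [
            (-4.0, "porod_surface"),
            (-3.2, "smeared_surface_or_steep"),
            (-2.0, "mass_fractal"),
            (0.0, "plateau"),
            (1.5, "rising_peak_flank"),
        ],
    )
    def test_labels(self, g, label):
        assert classify_regime(g) == label


class TestBuildFingerprint:
    def test_power_law_row_uniform(self):
        c = power_law_curve(amplitude=1.0, exponent=3.0, qlo=1e-3, qhi=1.0,
                            sample_id="pl")
        fm = build_fingerprint([c], 100)
        np.testing.assert_allclose(fm.gradient_modulus[0], 3.0, atol=1e-9)

    def test_identical_curves_identical_rows(self):
        a = lamellar_curve("a")
        b = lamellar_curve("b")
        fm = build_fingerprint([a, b], 100)
        np.testing.assert_array_equal(fm.gradient[0], fm.gradient[1])
        np.testing.assert_array_equal(
            fm.normalized_intensity[0], fm.normalized_intensity[1]
        )

    def test_scaling_invariance_of_both_layers(self):
        a = lamellar_curve("a")
        scaled = ScatteringCurve(q=a.q, intensity=100.0 * a.intensity,
                                 sample_id="a")
        fa = build_fingerprint([a], 100)
        fb = build_fingerprint([scaled], 100)
        np.testing.assert_allclose(fa.gradient, fb.gradient, atol=1e-9)
        np.testing.assert_allclose(
            fa.normalized_intensity, fb.normalized_intensity, atol=1e-9
        )

    def test_lamellar_band_distinguishes_cream_from_milk(self):
        cream = lamellar_curve("cream", amp=5.0)
        milk = ScatteringCurve(
            q=cream.q, intensity=1e-4 * cream.q ** -2.0 + 0.01, sample_id="milk"
        )
        fm = build_fingerprint([cream, milk], 150)
        band = (fm.q_mid > 0.12) & (fm.q_mid < 0.19)
        assert fm.gradient_modulus[0][band].max() > 4.0
        assert fm.gradient_modulus[1][band].max() < 2.5

    def test_mismatched_range_names_offender(self):
        a = lamellar_curve("full")
        short = ScatteringCurve(q=np.geomspace(1e-2, 1.0, 100),
                                intensity=np.geomspace(1e-2, 1.0, 100) ** -2.0,
                                sample_id="short")
        with pytest.raises(ValueError, match="short"):
            build_fingerprint([a, short], 100, q_range=(1e-3, 1.0))

    def test_halved_grid_tracks_fine_grid_on_smooth_input(self):
        # 10x resolution oracle on a smooth broad-peak curve
        q = np.geomspace(1e-3, 1.0, 2000)
        i = 1e-3 * q ** -2.0 + 0.5 * np.exp(-0.5 * ((np.log(q) + 2.0) / 0.8) ** 2)
        c = ScatteringCurve(q=q, intensity=i, sample_id="smooth")
        qg, ig = resample_loglog(c, 50)
        qm, g = loglog_gradient(qg, ig)
        qg10, ig10 = resample_loglog(c, 500)
        qm10, g10 = loglog_gradient(qg10, ig10)
        oracle = np.interp(np.log(qm), np.log(qm10), g10)
        assert np.max(np.abs(g - oracle)) < 0.08
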