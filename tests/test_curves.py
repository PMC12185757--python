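"""Curve container, file round-trips, merging, backgrounds, Q geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatterprint.curves import (
    CoverageError,
    CurveFormatError,
    MergeError,
    SampleRecord,
    ScatteringCurve,
    SchemaError,
    merge_curves,
    q_from_angle,
    read_composition_table,
    read_curve,
    subtract_background,
    write_composition_table,
    write_curve,
)

from conftest import power_law_curve


class TestScatteringCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScatteringCurve(q=[1.0], intensity=[1.0])
        with pytest.raises(ValueError):
            ScatteringCurve(q=[2.0, 1.0], intensity=[1.0, 1.0])
        with pytest.raises(ValueError):
            ScatteringCurve(q=[-1.0, 1.0], intensity=[1.0, 1.0])
        with pytest.raises(ValueError):
            ScatteringCurve(q=[0.1, 0.2], intensity=[1.0, 1.0], smeared=True)

    def test_nonpositive_intensity_masked_not_dropped(self):
        c = ScatteringCurve(q=[0.1, 0.2, 0.3], intensity=[1.0, -2.0, 3.0])
        assert len(c) == 3
        assert c.mask.tolist() == [True, False, True]


class TestReadWriteCurve:
    def test_roundtrip_identity(self, tmp_path):
        q = np.geomspace(1e-3, 1.0, 25)
        rng = np.random.default_rng(0)
        c = ScatteringCurve(q=q, intensity=q ** -2.0,
                            sigma=0.05 * q ** -2.0 * rng.uniform(0.5, 1.5, 25))
        path = tmp_path / "c.dat"
        write_curve(c, path)
        back = read_curve(path)
        np.testing.assert_allclose(back.q, c.q, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-9)
        np.testing.assert_allclose(back.sigma, c.sigma, rtol=1e-9)

    def test_comment_lines_and_csv_dialect(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("# a comment\n0.1, 5.0\n0.2, 4.0\n# tail\n0.3, 3.0\n")
        c = read_curve(path)
        assert len(c) == 3
        assert c.sigma is None
        np.testing.assert_allclose(c.intensity, [5.0, 4.0, 3.0])

    def test_descending_rows_sorted_consistently(self, tmp_path):
        # 5-row fixture sorted by an independent argsort oracle
        q = np.array([0.5, 0.1, 0.4, 0.2, 0.3])
        i = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
        order = np.argsort(q)
        path = tmp_path / "c.dat"
        np.savetxt(path, np.column_stack([q, i]))
        c = read_curve(path)
        np.testing.assert_allclose(c.q, q[order])
        np.testing.assert_allclose(c.intensity, i[order])

    def test_non_numeric_line_named_in_error(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.1 1.0\nfoo bar\n")
        with pytest.raises(CurveFormatError, match="line 2"):
            read_curve(path)

    def test_too_few_rows(self, tmp_path):
        path = tmp_path / "short.dat"
        path.write_text("0.1 1.0\n")
        with pytest.raises(CurveFormatError):
            read_curve(path)


class TestMergeCurves:
    def test_exact_factor_two(self):
        q = np.geomspace(1e-3, 1e-2, 400)
        high = ScatteringCurve(q=q, intensity=q ** -3.0, technique="SAXS")
        low = ScatteringCurve(q=q, intensity=0.5 * q ** -3.0, technique="USAXS")
        merged, scale = merge_curves(low, high, (0.0052, 0.0055))
        assert scale == pytest.approx(2.0, rel=1e-9)
        np.testing.assert_allclose(
            merged.interp_log(q[5:-5]), high.intensity[5:-5], rtol=1e-6
        )

    def test_noisy_power_law_scale_near_unity(self):
        # two noisy samplings of the same power law: true scale factor is 1
        rng = np.random.default_rng(42)
        sigma_rel = 0.05
        qa = np.geomspace(1e-3, 0.0056, 120)
        qb = np.geomspace(0.0050, 0.05, 120)
        low = ScatteringCurve(
            q=qa, intensity=qa ** -3.0 * np.exp(sigma_rel * rng.standard_normal(120)),
            technique="USAXS")
        high = ScatteringCurve(
            q=qb, intensity=qb ** -3.0 * np.exp(sigma_rel * rng.standard_normal(120)),
            technique="SAXS")
        merged, scale = merge_curves(low, high, (0.0052, 0.0055))
        n_overlap = np.sum((qa >= 0.0052) & (qa <= 0.0055))
        # two independent log-noise averages -> sd of ln(scale)
        sd = sigma_rel * np.sqrt(2.0 / n_overlap)
        assert abs(np.log(scale)) < 2 * sd + 1e-12

    def test_disjoint_ranges_error(self):
        low = power_law_curve(qlo=1e-4, qhi=1e-3)
        high = power_law_curve(qlo=1e-2, qhi=1e-1)
        with pytest.raises(MergeError):
            merge_curves(low, high, (0.0052, 0.0055))

    def test_idempotent_at_unit_scale(self):
        q = np.geomspace(1e-3, 1e-2, 80)
        c = ScatteringCurve(q=q, intensity=q ** -2.5)
        merged, scale = merge_curves(c, c, (0.004, 0.006))
        assert scale == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(
            merged.interp_log(q), c.intensity, rtol=1e-9
        )


class TestSubtractBackground:
    def test_self_subtraction_fully_masked(self):
        c = power_law_curve()
        out = subtract_background(c, c, factor=1.0)
        assert np.all(out.intensity == 0.0)
        assert not out.mask.any()

    def test_zero_factor_identity(self):
        c = power_law_curve()
        out = subtract_background(c, c, factor=0.0)
        np.testing.assert_allclose(out.intensity, c.intensity)
        assert out.mask.all()

    def test_constant_background_removed_from_power_law(self):
        q = np.geomspace(1e-2, 1.0, 200)
        const = 5.0
        sample = ScatteringCurve(q=q, intensity=1e-4 * q ** -3.0 + const)
        bg = ScatteringCurve(q=q, intensity=np.full_like(q, const))
        out = subtract_background(sample, bg, factor=1.0)
        np.testing.assert_allclose(out.intensity, 1e-4 * q ** -3.0, rtol=1e-6)

    def test_coverage_error(self):
        sample = power_law_curve(qlo=1e-4, qhi=1e-2)
        bg = power_law_curve(qlo=1e-3, qhi=1e-2)
        with pytest.raises(CoverageError):
            subtract_background(sample, bg)


class TestQFromAngle:
    def test_limits(self):
        assert q_from_angle(0.0, 1.54) == 0.0
        assert q_from_angle(180.0, 1.54) == pytest.approx(4 * np.pi / 1.54, rel=1e-12)

    def test_cu_kalpha_inverse(self):
        # theta giving Q = 2 1/A at lambda = 1.54 A, found by inverting Eq.
        theta = 2.0 * np.degrees(np.arcsin(2.0 * 1.54 / (4 * np.pi)))
        assert theta == pytest.approx(28.36, abs=0.05)
        assert q_from_angle(theta, 1.54) == pytest.approx(2.0, rel=1e-12)

    def test_invalid_wavelength(self):
        with pytest.raises(ValueError):
            q_from_angle(10.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 179.0), st.floats(0.01, 10.0), st.floats(1e-6, 1.0))
    def test_strictly_increasing_in_theta(self, theta, wavelength, dtheta):
        hi = min(theta + dtheta, 180.0)
        if hi > theta:
            assert q_from_angle(hi, wavelength) > q_from_angle(theta, wavelength)


class TestCompositionTable:
    def test_table_rows_parsed(self, tmp_path):
        path = tmp_path / "comp.csv"
        path.write_text(
            "number,sample,fat,carbohydrate,protein,category,material\n"
            "4,Almond milk,1.2,0.1,0.4,milk,almond\n"
            "23,Dairy cream,36,2.9,2.3,cream,casein\n"
        )
        recs = read_composition_table(path)
        assert recs[0].fat == 1.2 and recs[0].material == "almond"
        assert recs[1].fat == 36.0 and recs[1].category == "cream"

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "comp.csv"
        path.write_text("number,sample,fat\n1,x,2\n")
        with pytest.raises(SchemaError):
            read_composition_table(path)

    def test_empty_table_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "comp.csv"
        path.write_text("number,sample,fat,carbohydrate,protein,category,material\n")
        with caplog.at_level("WARNING"):
            assert read_composition_table(path) == []
        assert any("no rows" in m for m in caplog.messages)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SampleRecord(1, "x", "milk", "oat", fat=120.0, carbohydrate=0, protein=0)
        with pytest.raises(ValueError):
            SampleRecord(1, "x", "milk", "oat", fat=60.0, carbohydrate=50.0,
                         protein=0.1)

    def test_write_read_roundtrip(self, tmp_path):
        recs = [SampleRecord(1, "a", "milk", "oat", 1.0, 2.0, 3.0)]
        path = tmp_path / "c.csv"
        write_composition_table(recs, path)
        assert read_composition_table(path) == recs
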