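import numpy as np
import pytest

from femrel.response_surface import (
    PUBLISHED_MODEL,
    QuadraticResponseModel,
    classify_region,
    failure_boundary_bmd,
    fit,
    region_to_dataframe,
)

YIELD = 0.0085


class TestEvaluate:
    @pytest.mark.parametrize(
        "bmd, bw, expected",
        [
            (0.0, 0.0, 4.09e-3),  # intercept only
            (0.15, 2.5, 0.007599825),
            (0.3375, 2.38, 0.0044078034375),  # 50-64 / walking means
        ],
    )
    def test_published_model_values(self, bmd, bw, expected):
        assert PUBLISHED_MODEL.evaluate(bmd, bw) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            PUBLISHED_MODEL.evaluate(-0.1, 2.0)

    def test_warns_outside_training_envelope(self):
        with pytest.warns(UserWarning, match="training envelope"):
            PUBLISHED_MODEL.evaluate(0.5, 5.0, warn_extrapolation=True)

    def test_vectorized_evaluation_matches_scalar(self):
        b = np.array([0.1, 0.3, 0.5])
        w = np.array([1.0, 2.0, 3.0])
        vec = PUBLISHED_MODEL.evaluate(b, w)
        scl = [PUBLISHED_MODEL.evaluate(bi, wi) for bi, wi in zip(b, w)]
        np.testing.assert_allclose(vec, scl, rtol=1e-15)

    def test_loading_gradient_positive_over_domain(self):
        # dS/dBW > 0 across the physiological domain
        b, w = np.meshgrid(np.linspace(0, 0.9, 50), np.linspace(0, 3.5, 50))
        m = PUBLISHED_MODEL
        grad = m.scale * (m.a2 + m.a3 * b + 2 * m.a5 * w)
        assert (grad > 0).all()

    def test_density_gradient_negative_in_osteoporotic_range(self):
        b, w = np.meshgrid(np.linspace(0, 0.56, 50), np.linspace(1.5, 3.5, 50))
        m = PUBLISHED_MODEL
        grad = m.scale * (m.a1 + m.a3 * w + 2 * m.a4 * b)
        assert (grad < 0).all()


class TestFit:
    @staticmethod
    def _design(n, seed=0):
        rng = np.random.default_rng(seed)
        bmd = rng.uniform(0.1, 0.9, n)
        bw = rng.uniform(1.0, 3.0, n)
        return bmd, bw

    def test_recovers_own_noise_free_predictions(self):
        bmd, bw = self._design(100)
        strain = PUBLISHED_MODEL.evaluate(bmd, bw)
        model, stats = fit(np.column_stack([bmd, bw, strain]))
        np.testing.assert_allclose(
            model.coefficients, PUBLISHED_MODEL.coefficients, rtol=1e-10
        )
        assert stats.r_squared == pytest.approx(1.0, abs=1e-12)
        assert stats.sse == pytest.approx(0.0, abs=1e-20)

    def test_exact_interpolation_at_minimum_sample_count(self):
        bmd, bw = self._design(6, seed=4)
        strain = PUBLISHED_MODEL.evaluate(bmd, bw)
        model, stats = fit(np.column_stack([bmd, bw, strain]))
        assert stats.sse == pytest.approx(0.0, abs=1e-18)

    def test_constant_response_defines_r2_zero(self):
        bmd, bw = self._design(50)
        strain = np.full(50, 2e-3)
        with pytest.warns(UserWarning, match="constant response"):
            model, stats = fit(np.column_stack([bmd, bw, strain]))
        assert stats.r_squared == 0.0
        np.testing.assert_allclose(model.coefficients[1:], 0.0, atol=1e-8)

    def test_rank_deficient_design_names_regressors(self):
        bmd = np.full(20, 0.5)  # constant BMD collapses bmd, bmd^2, bmd*bw
        bw = np.linspace(1, 3, 20)
        strain = PUBLISHED_MODEL.evaluate(bmd, bw)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit(np.column_stack([bmd, bw, strain]))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit(np.zeros((5, 3)))

    def test_fit_statistics_definitions(self):
        rng = np.random.default_rng(7)
        bmd, bw = self._design(100, seed=7)
        strain = PUBLISHED_MODEL.evaluate(bmd, bw) + rng.normal(0, 5e-4, 100)
        _, stats = fit(np.column_stack([bmd, bw, strain]))
        assert stats.rmse == pytest.approx(np.sqrt(stats.sse / (100 - 6)), rel=1e-12)
        assert stats.adjusted_r_squared == pytest.approx(
            1 - (1 - stats.r_squared) * 99 / 94, rel=1e-12
        )
        assert 0.0 <= stats.r_squared <= 1.0


class TestFailureBoundary:
    def test_root_on_walking_overload_column(self):
        roots = failure_boundary_bmd(PUBLISHED_MODEL, YIELD, bw=2.5)
        assert roots[0] == pytest.approx(0.10396778085755151, rel=1e-10)
        for r in roots:
            assert PUBLISHED_MODEL.evaluate(r, 2.5) == pytest.approx(YIELD, abs=1e-10)

    def test_low_load_column_safe_over_trabecular_range(self):
        # S(0, 1.0) = 6.84e-3 < yield; the only contour crossing at bw = 1
        # sits far outside the trabecular density range (upward parabola in
        # BMD), so the physical range [0, 0.9] g/cm^3 is entirely safe
        roots = failure_boundary_bmd(PUBLISHED_MODEL, YIELD, bw=1.0)
        assert all(r > 0.9 for r in roots)
        assert PUBLISHED_MODEL.evaluate(0.0, 1.0) < YIELD
        b = np.linspace(0.0, 0.9, 200)
        assert (np.asarray(PUBLISHED_MODEL.evaluate(b, np.full_like(b, 1.0))) < YIELD).all()

    def test_no_crossing_gives_empty_list(self):
        # at bw = 3 the strain minimum over BMD exceeds a 0.002 yield, so
        # the whole axis fails and there is no contour crossing; bmd = 0
        # disambiguates which side of the criterion the axis sits on
        assert failure_boundary_bmd(PUBLISHED_MODEL, 0.002, bw=3.0) == []
        assert PUBLISHED_MODEL.evaluate(0.0, 3.0) > 0.002

    def test_linear_degenerate_model(self):
        linear = QuadraticResponseModel(a0=4.0, a1=-2.0, a2=1.0, a3=0.0, a4=0.0, a5=0.0)
        roots = failure_boundary_bmd(linear, 0.003, bw=1.0)
        # 1e-3 * (4 - 2 b + 1) = 0.003  =>  b = 1
        assert roots == pytest.approx([1.0])

    def test_rejects_nonpositive_yield(self):
        with pytest.raises(ValueError):
            failure_boundary_bmd(PUBLISHED_MODEL, 0.0, bw=2.0)


class TestClassifyRegion:
    def test_known_safe_and_failure_points(self):
        mask = classify_region(
            PUBLISHED_MODEL, YIELD, np.array([0.10, 0.5]), np.array([2.0, 3.0])
        )
        assert mask[0, 1]  # (0.10, 3.0): S ~ 9.73e-3, failure
        assert not mask[1, 0]  # (0.5, 2.0): S ~ 2.23e-3, safe

    def test_zero_yield_fails_wherever_strain_nonnegative(self):
        # the surrogate dips slightly below zero in the low-load /
        # mid-density corner, so a zero yield marks exactly the S >= 0 set
        bmd = np.linspace(0, 0.9, 10)
        bw = np.linspace(0.5, 3, 10)
        mask = classify_region(PUBLISHED_MODEL, 0.0, bmd, bw)
        B, W = np.meshgrid(bmd, bw, indexing="ij")
        np.testing.assert_array_equal(mask, np.asarray(PUBLISHED_MODEL.evaluate(B, W)) >= 0)
        assert mask.any() and not mask.all()

    def test_rejects_unsorted_grid(self):
        with pytest.raises(ValueError, match="sorted"):
            classify_region(PUBLISHED_MODEL, YIELD, np.array([0.5, 0.1]), np.array([1.0]))

    def test_mask_transitions_match_boundary_roots(self):
        bmd_grid = np.linspace(0.0, 0.9, 400)
        bw_grid = np.array([2.5, 3.0])
        mask = classify_region(PUBLISHED_MODEL, YIELD, bmd_grid, bw_grid)
        for j, bw in enumerate(bw_grid):
            roots = failure_boundary_bmd(PUBLISHED_MODEL, YIELD, bw)
            flips = np.flatnonzero(np.diff(mask[:, j].astype(int)))
            in_range = [r for r in roots if bmd_grid[0] <= r <= bmd_grid[-1]]
            assert len(flips) == len(in_range)
            for k, r in zip(flips, in_range):
                assert bmd_grid[k] <= r <= bmd_grid[k + 1]

    def test_long_format_export(self):
        df = region_to_dataframe(
            PUBLISHED_MODEL, YIELD, np.array([0.1, 0.5]), np.array([2.0])
        )
        assert list(df.columns) == ["bmd", "bw", "strain", "failure_flag"]
        assert len(df) == 2


def test_model_round_trips_through_yaml(tmp_path):
    path = tmp_path / "model.yaml"
    PUBLISHED_MODEL.to_yaml(path)
    loaded = QuadraticResponseModel.from_yaml(path)
    assert loaded == PUBLISHED_MODEL
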