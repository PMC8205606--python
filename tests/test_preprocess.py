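"""Pretreatment operators: SG filtering, SNV, MSC, normalization, PCA."""

import numpy as np
import pytest

import nirleaf as nl
from nirleaf.errors import DegenerateSpectrumError, ParameterError, PipelineError
from nirleaf.preprocess import PipelineStep, trim


class TestSavitzkyGolay:
    def test_first_derivative_of_constant_is_zero(self):
        X = np.full((2, 50), 3.7)
        out = nl.sg_filter(X, window=11, polyorder=2, deriv_order=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_first_derivative_exact_on_linear(self):
        # f(lam) = 2*lam has derivative 2 everywhere; SG is exact for
        # polynomials up to polyorder, and the step scaling carries nm units
        lam = 900 + 3.125 * np.arange(64)
        X = (2 * lam)[None, :]
        out = nl.sg_filter(X, window=11, polyorder=2, deriv_order=1,
                           mode="valid", step_nm=3.125)
        np.testing.assert_allclose(out, 2.0, atol=1e-8)

    def test_second_derivative_exact_on_quadratic(self):
        lam = np.linspace(0, 10, 80)
        step = lam[1] - lam[0]
        X = (lam**2)[None, :]
        out = nl.sg_filter(X, window=9, polyorder=3, deriv_order=2,
                           mode="valid", step_nm=step)
        np.testing.assert_allclose(out, 2.0, atol=1e-7)

    def test_identity_when_polyorder_saturates_window(self, rng):
        # polyorder = window-1 interpolates the window exactly, so interior
        # (valid) points pass through unchanged
        X = rng.normal(size=(3, 40))
        out = nl.sg_filter(X, window=5, polyorder=4, deriv_order=0, mode="valid")
        np.testing.assert_allclose(out, X[:, 2:-2], atol=1e-9)

    def test_valid_mode_shortens_by_window_minus_one(self, rng):
        X = rng.normal(size=(4, 512))
        out = nl.sg_filter(X, window=59, polyorder=2, deriv_order=1, mode="valid")
        assert out.shape == (4, 454)

    @pytest.mark.parametrize("kwargs", [
        {"window": 10}, {"window": 5, "polyorder": 5},
        {"window": 61}, {"window": 5, "mode": "weird"},
        {"window": 5, "polyorder": 3, "deriv_order": 4},
    ])
    def test_parameter_validation(self, rng, kwargs):
        with pytest.raises(ParameterError):
            nl.sg_filter(rng.normal(size=(2, 50)), **kwargs)


class TestSNV:
    def test_small_example(self):
        np.testing.assert_allclose(nl.snv([[1.0, 2.0, 3.0]]), [[-1, 0, 1]])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(5, 30))
        np.testing.assert_allclose(nl.snv(2.0 + 3.5 * x), nl.snv(x), atol=1e-10)

    def test_output_rows_standardized(self, rng):
        out = nl.snv(rng.normal(size=(6, 40)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_constant_row_names_offender(self, rng):
        X = rng.normal(size=(3, 10))
        X[1] = 4.0
        with pytest.raises(DegenerateSpectrumError, match="row 1"):
            nl.snv(X)


class TestMSC:
    def test_exact_affine_rows_collapse_to_reference(self, rng):
        ref = rng.normal(size=25)
        alphas, betas = rng.normal(size=5), rng.uniform(0.5, 2.0, size=5)
        X = alphas[:, None] + betas[:, None] * ref
        fitted = nl.msc_fit(X)
        corrected = nl.msc_apply(X, nl.MSCReference(ref))
        np.testing.assert_allclose(corrected, np.tile(ref, (5, 1)), atol=1e-9)
        # fitting on the affine family gives a reference in the same family
        assert fitted.reference_spectrum.shape == ref.shape

    def test_reference_maps_to_itself(self, rng):
        ref = rng.normal(size=30)
        out = nl.msc_apply(ref[None, :], nl.MSCReference(ref))
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # independent per-row OLS of x on [1, ref] via explicit normal equations
        X = rng.normal(size=(5, 20))
        ref = X.mean(axis=0)
        A = np.column_stack([np.ones_like(ref), ref])
        expected = np.empty_like(X)
        for i, x in enumerate(X):
            a, b = np.linalg.solve(A.T @ A, A.T @ x)
            expected[i] = (x - a) / b
        out = nl.msc_apply(X, nl.msc_fit(X))
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_requires_two_training_rows(self, rng):
        with pytest.raises(ParameterError):
            nl.msc_fit(rng.normal(size=(1, 10)))


class TestNormalization:
    def test_minmax_example(self):
        np.testing.assert_allclose(nl.minmax_norm([[2.0, 4.0, 6.0]]), [[0, 0.5, 1]])

    def test_minmax_idempotent_and_bounded(self, rng):
        X = rng.normal(size=(4, 30))
        out = nl.minmax_norm(X)
        np.testing.assert_allclose(nl.minmax_norm(out), out, atol=1e-12)
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            nl.minmax_norm(np.ones((2, 5)))

    def test_unit_norm_rows(self, rng):
        out = nl.unit_norm(rng.normal(size=(3, 15)))
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_trim(self, rng):
        X = rng.normal(size=(2, 10))
        np.testing.assert_array_equal(trim(X, 2, 3), X[:, 2:7])
        with pytest.raises(ParameterError):
            trim(X, 6, 4)


class TestPipeline:
    def test_empty_pipeline_is_identity(self, rng):
        X = rng.normal(size=(3, 20))
        np.testing.assert_array_equal(nl.PreprocessPipeline([]).fit_transform(X), X)

    def test_default_pipeline_maps_512_to_454(self, rng):
        X = rng.normal(size=(5, 512))
        out = nl.default_pipeline(step_nm=3.125).fit_transform(X)
        assert out.shape == (5, 454)
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-12)

    def test_snv_then_minmax_bounded(self, rng):
        pipe = nl.PreprocessPipeline([PipelineStep("snv"), PipelineStep("minmax_norm")])
        out = pipe.fit_transform(rng.normal(size=(4, 25)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_msc_requires_fit_before_transform(self, rng):
        pipe = nl.PreprocessPipeline([PipelineStep("msc")])
        with pytest.raises(PipelineError, match="fit"):
            pipe.transform(rng.normal(size=(3, 10)))

    def test_msc_reference_frozen_for_test_rows(self, rng):
        # test rows are corrected against the training reference, so the
        # same row maps identically whether or not it was in training
        Xtr = rng.normal(size=(6, 15))
        pipe = nl.PreprocessPipeline([PipelineStep("msc")])
        out_tr = pipe.fit_transform(Xtr)
        out_again = pipe.transform(Xtr)
        np.testing.assert_allclose(out_tr, out_again, atol=1e-12)

    def test_step_error_carries_index(self, rng):
        pipe = nl.PreprocessPipeline(
            [PipelineStep("snv"), PipelineStep("sg_smooth", {"window": 10})])
        with pytest.raises(PipelineError, match="step 1"):
            pipe.fit_transform(rng.normal(size=(2, 30)))

    def test_unknown_step_rejected(self):
        with pytest.raises(ParameterError, match="wavelet"):
            nl.PreprocessPipeline([PipelineStep("wavelet")])

    def test_config_round_trip(self):
        pipe = nl.default_pipeline(step_nm=3.125)
        cfg = pipe.to_config()
        back = nl.PreprocessPipeline.from_config(cfg, step_nm=3.125)
        assert [s.name for s in back.steps] == [s.name for s in pipe.steps]
        X = np.random.default_rng(0).normal(size=(3, 512))
        np.testing.assert_allclose(back.fit_transform(X), pipe.fit_transform(X))

    def test_operators_are_row_independent(self, rng):
        X = rng.normal(size=(6, 40))
        perm = rng.permutation(6)
        for op in (nl.snv, nl.minmax_norm,
                   lambda M: nl.sg_filter(M, window=7, polyorder=2, deriv_order=1)):
            np.testing.assert_allclose(op(X)[perm], op(X[perm]), atol=1e-12)


class TestPCA:
    def test_rank_one_data_has_unit_first_ratio(self, rng):
        v = rng.normal(size=12)
        X = rng.normal(size=(20, 1)) * v
        _, ratios = nl.pca_scores(X, 3)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_splits_variance_evenly(self, rng):
        X = rng.normal(size=(4000, 2))
        _, ratios = nl.pca_scores(X, 2)
        np.testing.assert_allclose(ratios, [0.5, 0.5], atol=0.03)

    def test_full_decomposition_is_lossless(self, rng):
        # with all components the scores are an orthogonal rotation of the
        # centered data: total variance and row norms are preserved
        X = rng.normal(size=(15, 6))
        scores, ratios = nl.pca_scores(X, 6)
        Xc = X - X.mean(axis=0)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            np.linalg.norm(scores, axis=1), np.linalg.norm(Xc, axis=1), atol=1e-8)

    def test_component_budget_enforced(self, rng):
        with pytest.raises(ParameterError):
            nl.pca_scores(rng.normal(size=(5, 10)), 5)
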