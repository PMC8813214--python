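"""PLS extraction, projection, back-projection and the composite fits."""

import numpy as np
import pytest

from plspline.cox import fit_cox
from plspline.data import SurvivalData
from plspline.pls import (
    back_project,
    extract_components,
    fit_pls_cox,
    fit_pls_spline,
    project,
)
from plspline.rp import fit_rp
from plspline.scales import HAZARD
from plspline.simulate import SimulationSpec, simulate_dataset


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


@pytest.fixture
def survival_dataset():
    spec = SimulationSpec(n=120, p=6, corr_max=0.5, seed=5,
                          true_beta=np.r_[0.4, 0.4, np.zeros(4)])
    return simulate_dataset(spec)


class TestExtraction:
    def test_single_covariate_score_is_standardized_column(self, rng):
        X = rng.normal(size=(40, 1)) * 3 + 2
        y = rng.normal(size=40)
        dec = extract_components(X, y, 1)
        xs = _standardize(X)[:, 0]
        sign = np.sign(dec.scores[:, 0] @ xs)
        np.testing.assert_allclose(dec.scores[:, 0], sign * xs, atol=1e-10)

    def test_full_rank_pls_equals_ols_on_orthogonal_design(self, rng):
        n, p = 64, 4
        # exactly orthogonal columns via QR
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n - 1)
        y = rng.normal(size=n)
        dec = extract_components(X, y, p)
        b_pls = dec.rotations @ dec.y_loadings
        ys = (y - y.mean()) / y.std(ddof=1)
        b_ols = np.linalg.lstsq(_standardize(X), ys, rcond=None)[0]
        np.testing.assert_allclose(b_pls, b_ols, atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        """Weights, scores and held-out projections agree with scikit-learn's
        NIPALS PLS regression on random problems (up to component signs)."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for trial in range(5):
            X = rng.normal(size=(50, 10)) @ rng.normal(size=(10, 10))
            y = rng.normal(size=50)
            dec = extract_components(X, y, 3)
            ref = sklearn.PLSRegression(n_components=3, scale=True).fit(X, y)
            for c in range(3):
                sign = np.sign(dec.weights[:, c] @ ref.x_weights_[:, c])
                np.testing.assert_allclose(
                    dec.weights[:, c], sign * ref.x_weights_[:, c], atol=1e-8
                )
                np.testing.assert_allclose(
                    dec.scores[:, c], sign * ref.x_scores_[:, c], atol=1e-8
                )
            X_new = rng.normal(size=(7, 10))
            np.testing.assert_allclose(
                np.abs(project(dec, X_new)), np.abs(ref.transform(X_new)), atol=1e-8
            )

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(60, 15)) @ rng.normal(size=(15, 15))
        dec = extract_components(X, rng.normal(size=60), 5)
        corr = np.corrcoef(dec.scores, rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_zero_variance_column_named_in_error(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            extract_components(X, rng.normal(size=30), 2)

    def test_component_count_beyond_rank_rejected(self, rng):
        base = rng.normal(size=(30, 2))
        X = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        with pytest.raises(ValueError, match="rank"):
            extract_components(X, rng.normal(size=30), 4)

    def test_component_count_bounds_checked(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="C must satisfy"):
            extract_components(X, rng.normal(size=10), 4)


class TestProjection:
    def test_training_round_trip(self, rng):
        X = rng.normal(size=(40, 8))
        dec = extract_components(X, rng.normal(size=40), 3)
        np.testing.assert_allclose(project(dec, X), dec.scores, atol=1e-8)

    def test_training_mean_row_scores_zero(self, rng):
        X = rng.normal(size=(40, 8))
        dec = extract_components(X, rng.normal(size=40), 3)
        np.testing.assert_allclose(
            project(dec, X.mean(axis=0)[None, :]), 0.0, atol=1e-10
        )

    def test_column_mismatch_rejected(self, rng):
        X = rng.normal(size=(40, 8))
        dec = extract_components(X, rng.normal(size=40), 2)
        with pytest.raises(ValueError, match="columns"):
            project(dec, rng.normal(size=(3, 5)))


class TestBackProjection:
    def test_scores_times_coefficients_equals_xstd_times_backprojection(self, rng):
        X = rng.normal(size=(50, 12)) @ rng.normal(size=(12, 12))
        dec = extract_components(X, rng.normal(size=50), 4)
        b_comp = rng.normal(size=4)
        b_cov = back_project(dec, b_comp)
        np.testing.assert_allclose(
            dec.scores @ b_comp, _standardize(X) @ b_cov, atol=1e-8
        )


class TestCompositeFits:
    def test_full_rank_equivalence_with_direct_fit(self, rng):
        """With uncorrelated covariates and C = p, fitting on the scores is a
        reparameterization of fitting on the standardized covariates."""
        spec = SimulationSpec(n=150, p=4, corr_max=0.0, seed=9,
                              true_beta=np.array([0.5, -0.3, 0.0, 0.2]))
        d = simulate_dataset(spec)
        composite = fit_pls_spline(d, C=4, scale=HAZARD, n_internal_knots=0)
        d_std = SurvivalData(d.time, d.status, _standardize(d.covariates))
        direct = fit_rp(d_std, HAZARD, 0, compute_se=False)
        assert composite.survival_stage.log_likelihood == pytest.approx(
            direct.log_likelihood, abs=1e-4
        )
        np.testing.assert_allclose(
            composite.covariate_coefficients, direct.beta, atol=1e-3
        )

    def test_permuting_covariates_permutes_coefficients(self, survival_dataset):
        d = survival_dataset
        perm = np.array([3, 0, 5, 1, 4, 2])
        d_perm = SurvivalData(
            d.time, d.status, d.covariates[:, perm],
            covariate_names=[d.covariate_names[j] for j in perm],
        )
        f = fit_pls_spline(d, C=2, scale=HAZARD, n_internal_knots=0)
        f_perm = fit_pls_spline(d_perm, C=2, scale=HAZARD, n_internal_knots=0)
        assert f_perm.survival_stage.log_likelihood == pytest.approx(
            f.survival_stage.log_likelihood, abs=1e-6
        )
        np.testing.assert_allclose(
            f_perm.covariate_coefficients, f.covariate_coefficients[perm], atol=1e-6
        )

    def test_spline_and_cox_share_identical_decomposition(self, survival_dataset):
        fs = fit_pls_spline(survival_dataset, C=2, scale=HAZARD, n_internal_knots=0)
        fc = fit_pls_cox(survival_dataset, C=2)
        np.testing.assert_array_equal(fs.decomposition.weights, fc.decomposition.weights)
        np.testing.assert_array_equal(fs.decomposition.scores, fc.decomposition.scores)

    def test_pls_cox_single_covariate_reduces_to_plain_cox(self, rng):
        spec = SimulationSpec(n=100, p=1, corr_max=0.0, seed=13,
                              true_beta=np.array([0.6]))
        d = simulate_dataset(spec)
        composite = fit_pls_cox(d, C=1)
        d_std = SurvivalData(d.time, d.status, _standardize(d.covariates))
        direct = fit_cox(d_std)
        assert abs(composite.survival_stage.beta[0]) == pytest.approx(
            abs(direct.beta[0]), abs=1e-6
        )

    def test_cox_stage_matches_external_fit_on_exported_scores(self, survival_dataset):
        """Feeding the exported score matrix to lifelines directly reproduces
        the composite's Cox coefficients."""
        import pandas as pd
        from lifelines import CoxPHFitter

        composite = fit_pls_cox(survival_dataset, C=2)
        df = pd.DataFrame(composite.decomposition.scores, columns=["c1", "c2"])
        df["time"] = survival_dataset.time
        df["status"] = survival_dataset.status
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="status")
        np.testing.assert_allclose(
            composite.survival_stage.beta, cph.params_.to_numpy(), atol=1e-6
        )

    def test_collinear_high_dimensional_fits_succeed(self):
        """p=200 >> n after reduction: every C in 1..5 yields finite fits even
        though a direct 200-covariate fit is refused."""
        d = simulate_dataset(SimulationSpec(seed=3))  # n=100, p=200, corr to 0.9
        for C in range(1, 6):
            comp = fit_pls_spline(d, C=C, scale=HAZARD, n_internal_knots=0)
            assert np.all(np.isfinite(comp.covariate_coefficients))
            assert np.isfinite(comp.survival_stage.aic)
        with pytest.raises(ValueError, match="p=200 >= n=100"):
            fit_rp(d, HAZARD, 0)

    def test_stage_errors_are_labelled(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 0.0
        d = SurvivalData(np.abs(rng.normal(size=30)) + 0.1, np.ones(30), X)
        with pytest.raises(ValueError, match="PLS stage"):
            fit_pls_spline(d, C=2, scale=HAZARD, n_internal_knots=0)
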