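"""Discrepancy functions, optimizer behaviour and standard errors."""

import numpy as np
import pytest

from structparafac import (
    FitOptions,
    ModelSpec,
    ThreeWayLayout,
    align_solutions,
    fit,
    implied_covariance,
    ml_discrepancy,
    quadratic_discrepancy,
    standard_errors,
)
from structparafac.estimation import _Objective, _Parameterization
from structparafac.exceptions import DefinitenessError, DimensionError
from structparafac.synthetic import draw_identifiable_params


def _random_pd(rng, n, ridge=0.5):
    A = rng.normal(size=(n, n))
    return A @ A.T + ridge * n * np.eye(n)


class TestQuadraticDiscrepancy:
    def test_zero_at_equality(self, rng):
        S = _random_pd(rng, 4)
        W = _random_pd(rng, 4)
        assert quadratic_discrepancy(S, S, W) == pytest.approx(0.0, abs=1e-14)

    def test_scalar_case(self):
        assert quadratic_discrepancy([[2.0]], [[1.0]], [[1.0]]) == pytest.approx(0.5)

    def test_matches_explicit_trace_oracle(self, rng):
        S, Sigma, W = (_random_pd(rng, 4) for _ in range(3))
        A = (S - Sigma) @ np.linalg.inv(W)
        oracle = sum((A @ A)[i, i] for i in range(4)) / 2.0
        assert quadratic_discrepancy(S, Sigma, W) == pytest.approx(oracle, rel=1e-10)

    def test_singular_weight_rejected(self, rng):
        S = _random_pd(rng, 3)
        with pytest.raises(DefinitenessError):
            quadratic_discrepancy(S, S, np.zeros((3, 3)))


class TestMLDiscrepancy:
    def test_zero_at_equality(self, rng):
        S = _random_pd(rng, 5)
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        # ln 2 + 1/2 - 1
        expected = np.log(2.0) - 0.5
        assert ml_discrepancy([[1.0]], [[2.0]]) == pytest.approx(expected)

    def test_second_order_agreement_with_gls(self, rng):
        # near Sigma = S, F_ML ~ quadratic discrepancy with W = S
        S = _random_pd(rng, 4)
        E = rng.normal(size=(4, 4))
        E = (E + E.T) / 2
        ratios = []
        for eps in (1e-2, 1e-3, 1e-4):
            Sigma = S + eps * E
            ratios.append(
                ml_discrepancy(S, Sigma) / quadratic_discrepancy(S, Sigma, S)
            )
        assert abs(ratios[-1] - 1.0) < 1e-3
        assert abs(ratios[-1] - 1.0) < abs(ratios[0] - 1.0)

    def test_non_pd_rejected(self, rng):
        S = _random_pd(rng, 3)
        with pytest.raises(DefinitenessError):
            ml_discrepancy(S, -np.eye(3))


class TestObjectiveGradient:
    @pytest.mark.parametrize("method,phi", [("ml", "orthogonal"),
                                            ("quad", "oblique")])
    def test_gradient_matches_fd_of_value(self, rng, layout43, method, phi):
        spec = ModelSpec(2, phi, "banded_within_variable", "variant_b",
                         "first_row_unit")
        par = _Parameterization(spec, layout43)
        S = _random_pd(rng, 12, ridge=0.2)
        if method == "ml":
            obj = _Objective(par, S, "ml")
        else:
            obj = _Objective(par, S, "quad", W=np.eye(12))
        theta = rng.normal(0, 0.4, par.n_free)
        _, g = obj.value_and_grad(theta)
        for i in rng.choice(par.n_free, size=6, replace=False):
            h = 1e-6
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            fd = (obj.value(tp) - obj.value(tm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestParameterizationRoundTrip:
    @pytest.mark.parametrize("phi,psi,invariance,ident", [
        ("orthogonal", "diagonal", "variant_b", "first_row_unit"),
        ("oblique", "banded_within_variable", "variant_b", "first_row_unit"),
        ("oblique", "block_within_occasion", "none", "unit_column_norm"),
    ])
    def test_from_params_inverts_to_params(self, layout43, phi, psi,
                                           invariance, ident):
        spec = ModelSpec(2, phi, psi, invariance, ident)
        truth = draw_identifiable_params(spec, layout43, seed=17)
        par = _Parameterization(spec, layout43)
        theta = par.from_params(truth)
        back = par.to_params(theta)
        np.testing.assert_allclose(back.B, truth.B, atol=1e-10)
        np.testing.assert_allclose(back.C, truth.C, atol=1e-10)
        np.testing.assert_allclose(back.Phi, truth.Phi, atol=1e-10)
        np.testing.assert_allclose(back.Psi, truth.Psi, atol=1e-10)
        np.testing.assert_allclose(back.D, truth.D, atol=1e-10)


class TestFit:
    def test_population_input_recovers_truth(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        truth = draw_identifiable_params(spec, layout43, seed=23)
        Sigma = implied_covariance(truth, spec, layout43)
        res = fit(Sigma, 1000, spec, layout43,
                  FitOptions(n_starts=4, seed=1))
        assert res.F_hat <= 1e-8
        aligned, _ = align_solutions(res.params, truth, spec)
        err = max(
            np.abs(aligned.B - truth.B).max(),
            np.abs(aligned.C - truth.C).max(),
            np.abs(aligned.Phi - truth.Phi).max(),
        )
        assert err <= 1e-4

    def test_seeded_determinism(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        truth = draw_identifiable_params(spec, layout43, seed=23)
        Sigma = implied_covariance(truth, spec, layout43)
        opts = FitOptions(n_starts=3, seed=99)
        r1 = fit(Sigma, 500, spec, layout43, opts)
        r2 = fit(Sigma, 500, spec, layout43, opts)
        assert r1.F_hat == r2.F_hat
        np.testing.assert_array_equal(r1.params.B, r2.params.B)
        np.testing.assert_array_equal(r1.start_discrepancies,
                                      r2.start_discrepancies)

    def test_warns_when_sample_smaller_than_parameter_count(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        truth = draw_identifiable_params(spec, layout43, seed=23)
        Sigma = implied_covariance(truth, spec, layout43)
        with pytest.warns(UserWarning, match="sample size"):
            fit(Sigma, 20, spec, layout43, FitOptions(n_starts=1, seed=0))

    def test_asymmetric_input_rejected(self, layout43):
        spec = ModelSpec(2, identification="first_row_unit",
                         invariance="variant_b")
        M = np.eye(12)
        M[0, 1] = 0.5
        with pytest.raises(DimensionError):
            fit(M, 100, spec, layout43)


class TestStandardErrors:
    def test_just_identified_factor_model_vs_wishart_delta_oracle(self):
        # one-factor model for three variables at a single occasion is
        # just identified: theta has a closed form in the covariances, so
        # the asymptotic covariance A Cov(vech S) A' (Wishart fourth
        # moments + numerical Jacobian of the closed form) is an oracle
        # entirely independent of the package's Hessian machinery.
        layout = ThreeWayLayout(3, 1)
        spec = ModelSpec(1, "orthogonal", "diagonal", "none", "first_row_unit")
        b2, b3, phi = 0.8, 1.2, 0.9
        psi = np.array([0.5, 0.6, 0.7])
        lam = np.array([1.0, b2, b3])
        S = phi * np.outer(lam, lam) + np.diag(psi)
        n_obs = 100
        res = fit(S, n_obs, spec, layout, FitOptions(n_starts=3, seed=5))
        assert res.F_hat < 1e-10
        se = standard_errors(res)

        def theta_of(s):
            S_ = s.reshape(3, 3)
            phi_ = S_[0, 1] * S_[0, 2] / S_[1, 2]
            b2_ = S_[1, 2] / S_[0, 2]
            b3_ = S_[1, 2] / S_[0, 1]
            lam_ = np.array([1.0, b2_, b3_])
            psi_ = np.diag(S_) - phi_ * lam_**2
            return np.array([b2_, b3_, phi_, *psi_])

        # Wishart covariance of the sample covariance entries
        n = n_obs - 1
        cov_s = np.empty((9, 9))
        for a in range(9):
            i, j = divmod(a, 3)
            for b in range(9):
                k, l = divmod(b, 3)
                cov_s[a, b] = (S[i, k] * S[j, l] + S[i, l] * S[j, k]) / n
        h = 1e-6
        s0 = S.ravel()
        A = np.empty((6, 9))
        for a in range(9):
            sp_ = s0.copy(); sp_[a] += h
            sm_ = s0.copy(); sm_[a] -= h
            A[:, a] = (theta_of(sp_) - theta_of(sm_)) / (2 * h)
        oracle = np.sqrt(np.diag(A @ cov_s @ A.T))

        got = np.array([
            se["B[V2,F1]"], se["B[V3,F1]"], se["Phi[F1,F1]"],
            se["Psi[V1@O1,V1@O1]"], se["Psi[V2@O1,V2@O1]"],
            se["Psi[V3@O1,V3@O1]"],
        ])
        np.testing.assert_allclose(got, oracle, rtol=5e-3)

    def test_repeat_fits_same_optimum_give_identical_ses(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        truth = draw_identifiable_params(spec, layout43, seed=31)
        Sigma = implied_covariance(truth, spec, layout43)
        r1 = fit(Sigma, 300, spec, layout43, FitOptions(n_starts=2, seed=1))
        r2 = fit(Sigma, 300, spec, layout43, FitOptions(n_starts=2, seed=8))
        se1, se2 = standard_errors(r1), standard_errors(r2)
        assert se1.keys() == se2.keys()
        for k in se1:
            assert se1[k] == pytest.approx(se2[k], rel=1e-3, abs=1e-6)
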