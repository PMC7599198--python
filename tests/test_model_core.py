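"""Implied covariance, Psi supports, parameter counting and rescaling."""

import numpy as np
import pytest

from structparafac import (
    ModelSpec,
    ParafacParams,
    ThreeWayLayout,
    count_parameters,
    implied_covariance,
    psi_support,
    rescale,
)
from structparafac.exceptions import UnsupportedModelError
from structparafac.synthetic import draw_identifiable_params


def _elementwise_sigma(params):
    """Brute-force oracle: entry-by-entry double sum over factors."""
    J, K, S = params.n_variables, params.n_occasions, params.n_factors
    jk = J * K
    Sigma = np.empty((jk, jk))
    for k in range(K):
        for j in range(J):
            for k2 in range(K):
                for j2 in range(J):
                    a, b = k * J + j, k2 * J + j2
                    common = sum(
                        params.B[j, s] * params.C[k, s] * params.Phi[s, t]
                        * params.B[j2, t] * params.C[k2, t]
                        for s in range(S)
                        for t in range(S)
                    )
                    Sigma[a, b] = params.D[a] * params.D[b] * (
                        common + params.Psi[a, b]
                    )
    return Sigma


class TestImpliedCovariance:
    def test_rank_one_all_ones(self):
        p = ParafacParams(
            B=np.ones((4, 1)), C=np.ones((3, 1)), Phi=[[1.0]], Psi=np.eye(12)
        )
        np.testing.assert_allclose(
            implied_covariance(p), np.ones((12, 12)) + np.eye(12)
        )

    def test_scalar_d_scaling(self, rng):
        B = rng.normal(size=(4, 2))
        C = rng.normal(size=(3, 2))
        base = ParafacParams(B=B, C=C, Phi=np.eye(2), Psi=np.eye(12))
        scaled = ParafacParams(
            B=B, C=C, Phi=np.eye(2), Psi=np.eye(12), D=2.0 * np.ones(12)
        )
        np.testing.assert_allclose(
            implied_covariance(scaled), 4.0 * implied_covariance(base)
        )

    def test_matches_elementwise_oracle(self, rng):
        B = rng.normal(size=(4, 2))
        C = rng.normal(size=(3, 2))
        A = rng.normal(size=(2, 2))
        Phi = A @ A.T + 0.5 * np.eye(2)
        Psi = np.diag(rng.uniform(0.2, 1.0, 12))
        D = rng.uniform(0.5, 1.5, 12)
        p = ParafacParams(B=B, C=C, Phi=Phi, Psi=Psi, D=D)
        np.testing.assert_allclose(
            implied_covariance(p), _elementwise_sigma(p), atol=1e-12
        )

    def test_symmetric_and_positive_definite(self, rng, layout43):
        spec = ModelSpec(2, "oblique", "block_within_occasion", "variant_b",
                         "first_row_unit")
        p = draw_identifiable_params(spec, layout43, seed=5)
        Sigma = implied_covariance(p, spec, layout43)
        np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-14)
        np.linalg.cholesky(Sigma)  # raises if not PD

    def test_off_support_psi_rejected(self, layout43):
        spec = ModelSpec(1, psi_structure="diagonal",
                         identification="first_row_unit", invariance="variant_b")
        Psi = np.eye(12)
        Psi[0, 1] = Psi[1, 0] = 0.3
        p = ParafacParams(B=np.ones((4, 1)), C=np.ones((3, 1)), Phi=[[1.0]],
                          Psi=Psi)
        with pytest.raises(ValueError):
            implied_covariance(p, spec, layout43)


class TestPsiSupport:
    def test_counts(self, layout43):
        diag = psi_support("diagonal", layout43)
        assert len(diag) == 12
        block = psi_support("block_within_occasion", layout43)
        # 12 diagonal + K * J(J-1) ordered off-diagonal pairs
        assert len(block) == 12 + 3 * 4 * 3
        assert sum(1 for a, b in block if a < b) == 18
        banded = psi_support("banded_within_variable", layout43)
        assert len(banded) == 12 + 4 * 3 * 2
        assert sum(1 for a, b in banded if a < b) == 12

    def test_symmetric_and_block_membership(self, layout43):
        block = psi_support("block_within_occasion", layout43)
        assert all((b, a) in block for a, b in block)
        # same occasion, different variables
        assert (0, 1) in block and (0, 4) not in block
        banded = psi_support("banded_within_variable", layout43)
        # same variable, different occasions
        assert (0, 4) in banded and (0, 1) not in banded

    def test_unknown_structure(self, layout43):
        with pytest.raises(ValueError):
            psi_support("bogus", layout43)


# full "number of parameters" column of the 12-model comparison grid
TABLE2_COUNTS = [
    (2, "orthogonal", "diagonal", 24),
    (2, "oblique", "diagonal", 25),
    (2, "orthogonal", "banded_within_variable", 36),
    (2, "oblique", "banded_within_variable", 37),
    (2, "orthogonal", "block_within_occasion", 42),
    (2, "oblique", "block_within_occasion", 43),
    (3, "orthogonal", "diagonal", 30),
    (3, "oblique", "diagonal", 33),
    (3, "orthogonal", "banded_within_variable", 42),
    (3, "oblique", "banded_within_variable", 45),
    (3, "orthogonal", "block_within_occasion", 48),
    (3, "oblique", "block_within_occasion", 51),
]


class TestCountParameters:
    @pytest.mark.parametrize("S,phi,psi,expected", TABLE2_COUNTS)
    def test_scale_invariant_mtmm_grid(self, layout43, S, phi, psi, expected):
        spec = ModelSpec(S, phi, psi, "variant_b", "first_row_unit")
        assert count_parameters(spec, layout43) == expected

    def test_unit_column_norm_plain(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "none", "unit_column_norm")
        # (J-1)S + (K-1)S + S + JK = 6 + 4 + 2 + 12
        assert count_parameters(spec, layout43) == 24

    def test_unsupported_combination_raises(self, layout43):
        spec = ModelSpec(2, invariance="variant_a",
                         identification="first_row_unit")
        with pytest.raises(UnsupportedModelError):
            count_parameters(spec, layout43)


class TestRescale:
    def test_identity_scaling_is_noop(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        p = draw_identifiable_params(spec, layout43, seed=2)
        out = rescale(p, np.ones(4), np.ones(3), spec)
        np.testing.assert_array_equal(out.D, p.D)
        np.testing.assert_array_equal(out.B, p.B)

    def test_variant_b_scaling_goes_into_d(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        p = draw_identifiable_params(spec, layout43, seed=2)
        out = rescale(p, np.array([2.0, 1, 1, 1]), np.ones(3), spec)
        np.testing.assert_array_equal(out.B, p.B)
        # only entries of variable 0 doubled
        mask = np.array([r % 4 == 0 for r in range(12)])
        np.testing.assert_allclose(out.D[mask], 2 * p.D[mask])
        np.testing.assert_allclose(out.D[~mask], p.D[~mask])

    @pytest.mark.parametrize("invariance,identification", [
        ("none", "unit_column_norm"),
        ("variant_b", "first_row_unit"),
    ])
    def test_implied_covariance_congruence(self, rng, layout43, invariance,
                                           identification):
        # Sigma(rescaled params) == L Sigma L computed independently
        spec = ModelSpec(2, "oblique", "banded_within_variable", invariance,
                         identification)
        p = draw_identifiable_params(spec, layout43, seed=9)
        l_v = rng.uniform(0.5, 2.0, 4)
        l_o = rng.uniform(0.5, 2.0, 3)
        L = np.kron(l_o, l_v)
        lhs = implied_covariance(rescale(p, l_v, l_o, spec))
        rhs = L[:, None] * implied_covariance(p) * L[None, :]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_nonpositive_scale_rejected(self, layout43):
        spec = ModelSpec(2, "orthogonal", "diagonal", "variant_b",
                         "first_row_unit")
        p = draw_identifiable_params(spec, layout43, seed=2)
        with pytest.raises(ValueError):
            rescale(p, np.array([1.0, -1, 1, 1]), np.ones(3), spec)
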