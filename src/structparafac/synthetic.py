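"""Synthetic identifiable truths, normal sampling, alignment, and the
packaged multitrait-multimethod fixture.

The generator draws parameter sets that provably satisfy the uniqueness
conditions relevant to their specific-factor structure (checked, not
assumed: generic draws satisfy the conditions almost surely and rejection
sampling makes it certain), then simulates zero-mean multivariate normal
observations with the model-implied covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .exceptions import DimensionError, GenerationError
from .identifiability import (
    k_rank,
    occasion_rank_condition,
    row_deletion_condition,
)
from .model import ModelSpec, ParafacParams, implied_covariance
from .tensorops import ThreeWayLayout, khatri_rao

__all__ = [
    "SyntheticStudy",
    "draw_identifiable_params",
    "sample_covariance",
    "draw_study",
    "align_solutions",
    "bentler_mcclain_fixture",
    "MTMMFixture",
]


# ---------------------------------------------------------------------------
# packaged fixture: 12 x 12 MTMM correlation matrix (I = 68), 4 personality
# traits (Extraversion, Test anxiety, Impulsivity, Academic achievement
# motivation) rated by Peer report, Teacher rating and Self-rating.
# Lower triangle in composite (method-slowest) order.
# ---------------------------------------------------------------------------

_BENTLER_MCCLAIN_LOWER = """
1
-0.38  1
 0.42 -0.21  1
-0.25  0.54 -0.54  1
 0.64 -0.15  0.26 -0.05  1
-0.29  0.66 -0.19  0.44 -0.25  1
 0.38 -0.09  0.56 -0.19  0.59 -0.14  1
-0.22  0.51 -0.33  0.66  0.06  0.62 -0.05  1
 0.45 -0.05  0.12  0.10  0.50 -0.05  0.36  0.17  1
 0.04  0.38 -0.03  0.14  0.08  0.30  0.09  0.16  0.02  1
 0.33 -0.13  0.35 -0.18  0.41 -0.14  0.45 -0.13  0.43  0.16  1
-0.21  0.37 -0.44  0.58 -0.01  0.41 -0.10  0.62  0.06  0.04 -0.37  1
"""


@dataclass(frozen=True)
class MTMMFixture:
    matrix: np.ndarray
    layout: ThreeWayLayout
    n_obs: int


def bentler_mcclain_fixture() -> MTMMFixture:
    """The packaged 12 x 12 MTMM correlation matrix with its layout.

    Returns the correlation matrix (symmetric, unit diagonal, positive
    definite) of J = 4 traits (E, A, I, M) measured by K = 3 methods
    (P, T, S) on I = 68 children, rows in composite order (traits within
    methods).
    """
    rows = [
        [float(x) for x in line.split()]
        for line in _BENTLER_MCCLAIN_LOWER.strip().splitlines()
    ]
    n = len(rows)
    R = np.zeros((n, n))
    for i, vals in enumerate(rows):
        R[i, : len(vals)] = vals
    R = R + R.T - np.diag(np.diag(R))
    layout = ThreeWayLayout(
        n_variables=4,
        n_occasions=3,
        variable_labels=("E", "A", "I", "M"),
        occasion_labels=("P", "T", "S"),
    )
    return MTMMFixture(matrix=R, layout=layout, n_obs=68)


# ---------------------------------------------------------------------------
# identifiable truths
# ---------------------------------------------------------------------------

def _random_correlation(rng, m):
    A = rng.normal(size=(m, m))
    V = A @ A.T + 0.5 * m * np.eye(m)
    s = 1.0 / np.sqrt(np.diag(V))
    return s[:, None] * V * s[None, :]


def _conditions_hold(params: ParafacParams, spec: ModelSpec) -> bool:
    S = spec.n_factors
    if k_rank(params.B) + k_rank(params.C) < S + 2:
        return False
    if spec.psi_structure == "diagonal":
        return row_deletion_condition(khatri_rao(params.C, params.B))
    if spec.psi_structure == "block_within_occasion":
        return occasion_rank_condition(params.B, params.C)[1]
    # banded_within_variable: the symmetric counterpart, blocks over variables
    return occasion_rank_condition(params.C, params.B)[1]


def draw_identifiable_params(
    spec: ModelSpec,
    layout: ThreeWayLayout,
    seed=None,
    max_retries: int = 100,
) -> ParafacParams:
    """Draw a random truth satisfying the uniqueness conditions.

    Loading entries are uniform on [-1, 1] (then the identification
    convention is applied), Phi is a random correlation-type PD matrix
    (diagonal under orthogonal factors), Psi respects the declared
    support, and D is uniform on [0.5, 1.5] for the scale-invariant
    variants.  Draws are rejected until the Kruskal-type condition and
    the structure-appropriate rank condition hold; exhausting the retry
    budget raises :class:`GenerationError` naming the failed condition.
    """
    rng = np.random.default_rng(seed)
    J, K, S = layout.n_variables, layout.n_occasions, spec.n_factors
    jk = J * K
    for _ in range(max_retries):
        B = rng.uniform(-1.0, 1.0, (J, S))
        C = rng.uniform(-1.0, 1.0, (K, S))
        if spec.identification == "first_row_unit":
            B[0] = 1.0
            C[0] = 1.0
        else:
            B /= np.linalg.norm(B, axis=0)
            C /= np.linalg.norm(C, axis=0)
        if spec.phi_structure == "orthogonal":
            Phi = np.diag(rng.uniform(0.5, 1.5, S))
        else:
            Phi = _random_correlation(rng, S)
        Psi = np.eye(jk)
        if spec.invariance != "variant_b":
            np.fill_diagonal(Psi, rng.uniform(0.3, 1.0, jk))
        if spec.psi_structure == "block_within_occasion":
            blocks = [np.arange(k * J, (k + 1) * J) for k in range(K)]
        elif spec.psi_structure == "banded_within_variable":
            blocks = [np.array([k * J + j for k in range(K)]) for j in range(J)]
        else:
            blocks = []
        for idx in blocks:
            R = _random_correlation(rng, idx.size)
            s = np.sqrt(np.diag(Psi)[idx])
            Psi[np.ix_(idx, idx)] = s[:, None] * R * s[None, :]
        if spec.invariance == "none":
            D = np.ones(jk)
        elif spec.invariance == "variant_a":
            # D is determined by the unit-diagonal core constraint
            Lam = khatri_rao(C, B)
            M = Lam @ Phi @ Lam.T + Psi
            D = 1.0 / np.sqrt(np.diag(M))
        else:
            D = rng.uniform(0.5, 1.5, jk)
        params = ParafacParams(B=B, C=C, Phi=Phi, Psi=Psi, D=D)
        if _conditions_hold(params, spec):
            return params
    raise GenerationError(
        "could not draw parameters satisfying the uniqueness conditions "
        f"(k-rank(B) + k-rank(C) >= S + 2 plus the {spec.psi_structure!r} "
        f"rank condition) in {max_retries} attempts for J={J}, K={K}, S={S}"
    )


def sample_covariance(
    true_params: ParafacParams,
    spec: ModelSpec,
    n_obs: int,
    seed=None,
) -> np.ndarray:
    """Sample covariance (divisor I - 1) of I zero-mean normal draws with
    the model-implied population covariance.

    For I - 1 < JK the result is singular; it is still returned (with a
    warning) since some discrepancy functions remain usable.
    """
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    rng = np.random.default_rng(seed)
    Sigma = implied_covariance(true_params, spec)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((n_obs, Sigma.shape[0])) @ L.T
    S = np.cov(X, rowvar=False, ddof=1)
    if n_obs - 1 < Sigma.shape[0]:
        warnings.warn(
            f"sample covariance from {n_obs} observations of dimension "
            f"{Sigma.shape[0]} is singular",
            stacklevel=2,
        )
    return S


@dataclass
class SyntheticStudy:
    """A reproducible simulated data set: truth, seed and sample."""

    true_params: ParafacParams
    spec: ModelSpec
    layout: ThreeWayLayout
    sample_size: int
    seed: int
    sample_cov: np.ndarray

    @property
    def population_cov(self) -> np.ndarray:
        return implied_covariance(self.true_params, self.spec, self.layout)


def draw_study(
    spec: ModelSpec,
    layout: ThreeWayLayout,
    sample_size: int,
    seed=None,
) -> SyntheticStudy:
    """Draw an identifiable truth and a normal sample from it (seeded)."""
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, 2)
    params = draw_identifiable_params(spec, layout, seed=int(s1))
    S = sample_covariance(params, spec, sample_size, seed=int(s2))
    return SyntheticStudy(
        true_params=params,
        spec=spec,
        layout=layout,
        sample_size=sample_size,
        seed=seed,
        sample_cov=S,
    )


# ---------------------------------------------------------------------------
# alignment for recovery checks
# ---------------------------------------------------------------------------

def align_solutions(
    est: ParafacParams,
    truth: ParafacParams,
    spec: ModelSpec = None,
):
    """Align an estimate with a truth over the essential-uniqueness group.

    Exhaustively searches simultaneous column permutations of B and C --
    and, under the ``unit_column_norm`` identification, per-column sign
    flips of B and C with compensating sign changes in Phi -- minimizing
    the total squared deviation of (B, C) from the truth.  Phi is
    permuted as P' Phi P.  Returns ``(aligned_params, permutation)``.
    """
    S = est.n_factors
    if S != truth.n_factors or est.B.shape != truth.B.shape or est.C.shape != truth.C.shape:
        raise DimensionError("estimate and truth must share dimensions")
    if S > 8:
        raise DimensionError("exhaustive permutation search refused for S > 8")
    allow_flips = spec is not None and spec.identification == "unit_column_norm"
    best = None
    for perm in permutations(range(S)):
        perm = list(perm)
        Bp = est.B[:, perm].copy()
        Cp = est.C[:, perm].copy()
        Phip = est.Phi[np.ix_(perm, perm)].copy()
        if allow_flips:
            eb = np.where(np.sum(Bp * truth.B, axis=0) < 0, -1.0, 1.0)
            ec = np.where(np.sum(Cp * truth.C, axis=0) < 0, -1.0, 1.0)
            Bp *= eb
            Cp *= ec
            sign = eb * ec
            Phip = Phip * np.outer(sign, sign)
        dev = np.sum((Bp - truth.B) ** 2) + np.sum((Cp - truth.C) ** 2)
        if best is None or dev < best[0]:
            best = (dev, tuple(perm), Bp, Cp, Phip)
    _, perm, Bp, Cp, Phip = best
    aligned = ParafacParams(
        B=Bp, C=Cp, Phi=Phip, Psi=est.Psi.copy(), D=est.D.copy()
    )
    return aligned, perm
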