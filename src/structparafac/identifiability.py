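"""Runnable checkers for factor-uniqueness conditions.

The structural Parafac solution (B, C, Phi) is essentially unique -- i.e.
determined up to a simultaneous column permutation once a scaling
convention is fixed -- under verifiable rank conditions:

* Kruskal-type condition: ``k-rank(B) + k-rank(C) >= S + 2`` (with a
  full-rank Phi, equivalent to Kruskal's three-factor condition
  ``k-rank(Phi^{1/2}) + k-rank(B) + k-rank(C) >= 2S + 2``);
* with diagonal Psi, the Anderson-Rubin row-deletion condition on the
  loading matrix Lambda = C * B: deleting any single row leaves two
  disjoint row subsets each of rank S;
* with block-diagonal (within-occasion) Psi, Browne's multiple-battery
  condition: ``rank(B diag(c_k)) = S`` for at least three occasions.

Rank is numerical: singular values are compared against a relative
tolerance, surfaced as a parameter because the k-rank is discontinuous in
the matrix entries.  The subset searches are exhaustive (no heuristics),
with a size guard appropriate for the small problems this model targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import eigh

from .exceptions import DimensionError
from .model import ModelSpec, ParafacParams
from .tensorops import ThreeWayLayout, khatri_rao

__all__ = [
    "DEFAULT_RANK_TOL",
    "UniquenessReport",
    "k_rank",
    "kruskal_condition",
    "row_deletion_condition",
    "occasion_rank_condition",
    "check_uniqueness",
]

DEFAULT_RANK_TOL = 1e-8

_MAX_ROWS = 30
_MAX_COLS = 12


def _num_rank(M: np.ndarray, tol: float) -> int:
    """Numerical rank: count of singular values above tol * largest."""
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > tol * s[0]))


def k_rank(M: np.ndarray, tol: float = DEFAULT_RANK_TOL) -> int:
    """Kruskal rank: largest k such that EVERY k-column subset has rank k.

    Returns 0 when some single column is numerically zero.  All subsets
    are enumerated exhaustively; matrices beyond the size guard
    (30 rows / 12 columns) are refused.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise DimensionError("k_rank requires a nonempty 2-d matrix")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_rows, n_cols = M.shape
    if n_rows > _MAX_ROWS or n_cols > _MAX_COLS:
        raise DimensionError(
            f"k_rank size guard: at most {_MAX_ROWS} rows and {_MAX_COLS} "
            "columns (exhaustive enumeration)"
        )
    upper = min(n_rows, n_cols)
    for k in range(1, upper + 1):
        for cols in combinations(range(n_cols), k):
            if _num_rank(M[:, cols], tol) < k:
                return k - 1
    return upper


def kruskal_condition(k_a: int, k_b: int, k_c: int, n_factors: int) -> bool:
    """Kruskal's sufficient uniqueness condition kA + kB + kC >= 2S + 2."""
    if min(k_a, k_b, k_c) < 0 or n_factors < 1:
        raise ValueError("k-ranks must be nonnegative and n_factors >= 1")
    return k_a + k_b + k_c >= 2 * n_factors + 2


def row_deletion_condition(
    Lambda: np.ndarray, tol: float = DEFAULT_RANK_TOL
) -> bool:
    """Anderson-Rubin style condition on a loading matrix.

    True iff after deleting ANY single row of ``Lambda`` (n x S) the
    remaining rows can be partitioned into two disjoint subsets each of
    numerical rank S.  Returns False immediately when n < 2S + 1 (the
    condition cannot hold by counting).  The search enumerates S-row
    subsets of the survivors and accepts when the complement also has
    rank S.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    if Lambda.ndim != 2:
        raise DimensionError("Lambda must be 2-d")
    n, S = Lambda.shape
    if n > _MAX_ROWS or S > 6:
        raise DimensionError(
            "row_deletion_condition size guard: at most 30 rows, 6 factors"
        )
    if n < 2 * S + 1:
        return False  # cannot hold: too few rows for two disjoint rank-S sets
    all_rows = np.arange(n)
    for drop in range(n):
        rest = np.delete(all_rows, drop)
        ok = False
        for subset in combinations(range(rest.size), S):
            sel = np.zeros(rest.size, dtype=bool)
            sel[list(subset)] = True
            if _num_rank(Lambda[rest[sel]], tol) == S and _num_rank(
                Lambda[rest[~sel]], tol
            ) == S:
                ok = True
                break
        if not ok:
            return False
    return True


def occasion_rank_condition(
    B: np.ndarray, C: np.ndarray, tol: float = DEFAULT_RANK_TOL
):
    """Browne-type condition for block-diagonal (within-occasion) Psi.

    Counts the occasions k for which ``rank(B diag(c_k)) = S`` and flags
    whether at least three qualify.  Returns ``(count, flag)``.
    """
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if B.ndim != 2 or C.ndim != 2 or B.shape[1] != C.shape[1]:
        raise DimensionError("B and C must be 2-d with equal column counts")
    S = B.shape[1]
    count = sum(
        1 for k in range(C.shape[0]) if _num_rank(B * C[k][None, :], tol) == S
    )
    return count, count >= 3


@dataclass
class UniquenessReport:
    """Outcome of the uniqueness checks for one parameter set."""

    k_rank_B: int
    k_rank_C: int
    kruskal_lhs: int
    kruskal_satisfied: bool
    row_deletion_satisfied: bool
    occasion_rank_count: int
    result2_satisfied: bool

    def to_dict(self) -> dict:
        return {
            "k_rank_B": self.k_rank_B,
            "k_rank_C": self.k_rank_C,
            "kruskal_lhs": self.kruskal_lhs,
            "kruskal_satisfied": self.kruskal_satisfied,
            "row_deletion_satisfied": self.row_deletion_satisfied,
            "occasion_rank_count": self.occasion_rank_count,
            "result2_satisfied": self.result2_satisfied,
        }


def _phi_sqrt(Phi: np.ndarray) -> np.ndarray:
    w, V = eigh(np.asarray(Phi, dtype=float))
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w)) @ V.T


def check_uniqueness(
    params: ParafacParams,
    spec: ModelSpec = None,
    layout: ThreeWayLayout = None,
    tol: float = DEFAULT_RANK_TOL,
    scaled: bool = False,
) -> UniquenessReport:
    """Evaluate all uniqueness conditions for a parameter set.

    With ``scaled=False`` the row-deletion and per-occasion rank checks
    are run on Lambda = C * B; with ``scaled=True`` they are run on
    D (C * B) Phi^{1/2}, the loading matrix of the scale-invariant
    formulation (both have the same row space when Phi is full rank and
    D positive, but both entry points are surfaced).
    """
    J = params.n_variables
    S = params.n_factors
    kB = k_rank(params.B, tol)
    kC = k_rank(params.C, tol)
    lhs = kB + kC
    Lam = khatri_rao(params.C, params.B)
    if scaled:
        Lam = params.D[:, None] * (Lam @ _phi_sqrt(params.Phi))
    occ_count = sum(
        1
        for k in range(params.n_occasions)
        if _num_rank(Lam[k * J : (k + 1) * J], tol) == S
    )
    return UniquenessReport(
        k_rank_B=kB,
        k_rank_C=kC,
        kruskal_lhs=lhs,
        kruskal_satisfied=lhs >= S + 2,
        row_deletion_satisfied=row_deletion_condition(Lam, tol),
        occasion_rank_count=occ_count,
        result2_satisfied=occ_count >= 3,
    )
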