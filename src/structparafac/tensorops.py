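"""Structured-matrix primitives for three-way covariance models.

A three-way data set holds J manifest variables observed at K occasions
(in a multitrait-multimethod design: J traits rated by K methods).  After
vectorization, the JK variable-occasion combinations are ordered
*occasion-slowest*: the composite row index of variable ``j`` at occasion
``k`` is ``k * J + j`` (0-based).  This matches the row ordering of the
Kronecker product ``C (x) B`` and of the Khatri-Rao product ``C * B``, so
the per-occasion blocks of the implied covariance matrix are contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError

__all__ = ["ThreeWayLayout", "composite_index", "khatri_rao"]


@dataclass(frozen=True)
class ThreeWayLayout:
    """Dimensions and labels of a variables x occasions design.

    Parameters
    ----------
    n_variables
        Number of manifest variables J (>= 1).
    n_occasions
        Number of occasions K (>= 1).
    variable_labels, occasion_labels
        Optional label sequences; defaults are ``V1..VJ`` and ``O1..OK``.
        Labels must be unique within each mode.
    """

    n_variables: int
    n_occasions: int
    variable_labels: tuple = None
    occasion_labels: tuple = None

    def __post_init__(self):
        if self.n_variables < 1 or self.n_occasions < 1:
            raise DimensionError("n_variables and n_occasions must be >= 1")
        vlab = self.variable_labels
        olab = self.occasion_labels
        if vlab is None:
            vlab = tuple(f"V{j + 1}" for j in range(self.n_variables))
        if olab is None:
            olab = tuple(f"O{k + 1}" for k in range(self.n_occasions))
        vlab, olab = tuple(map(str, vlab)), tuple(map(str, olab))
        if len(vlab) != self.n_variables or len(set(vlab)) != self.n_variables:
            raise DimensionError("need n_variables unique variable labels")
        if len(olab) != self.n_occasions or len(set(olab)) != self.n_occasions:
            raise DimensionError("need n_occasions unique occasion labels")
        object.__setattr__(self, "variable_labels", vlab)
        object.__setattr__(self, "occasion_labels", olab)

    @property
    def size(self) -> int:
        """Order JK of the vectorized covariance matrix."""
        return self.n_variables * self.n_occasions

    def composite_labels(self) -> list:
        """Row labels ``variable@occasion`` in composite-index order."""
        return [
            f"{v}@{o}"
            for o in self.occasion_labels
            for v in self.variable_labels
        ]

    def variable_of(self, row: int) -> int:
        return row % self.n_variables

    def occasion_of(self, row: int) -> int:
        return row // self.n_variables


def composite_index(j: int, k: int, layout: ThreeWayLayout) -> int:
    """Row index of variable ``j`` at occasion ``k`` (0-based, occasion-slowest).

    Bijective from {0..J-1} x {0..K-1} onto {0..JK-1}.
    """
    if not (0 <= j < layout.n_variables):
        raise IndexError(f"variable index {j} out of range [0, {layout.n_variables})")
    if not (0 <= k < layout.n_occasions):
        raise IndexError(f"occasion index {k} out of range [0, {layout.n_occasions})")
    return k * layout.n_variables + j


def khatri_rao(C: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker (Khatri-Rao) product ``C * B``.

    Column ``s`` of the result is ``kron(C[:, s], B[:, s])``; with C of
    order (K x S) and B of order (J x S) the result has order (JK x S) and
    row ordering consistent with :func:`composite_index`.
    """
    C = np.asarray(C, dtype=float)
    B = np.asarray(B, dtype=float)
    if C.ndim != 2 or B.ndim != 2:
        raise DimensionError("khatri_rao expects two 2-d arrays")
    if C.shape[1] != B.shape[1]:
        raise DimensionError(
            f"column-count mismatch: C has {C.shape[1]} columns, B has {B.shape[1]}"
        )
    K, S = C.shape
    J = B.shape[0]
    return (C[:, None, :] * B[None, :, :]).reshape(K * J, S)
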