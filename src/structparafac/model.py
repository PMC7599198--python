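"""Structural Parafac model: parameters and implied covariance structure.

The model reparameterizes the JK x JK covariance matrix of J variables
observed at K occasions as

    Sigma = D [ (C * B) Phi (C * B)' + Psi ] D

where ``*`` is the Khatri-Rao product, B (J x S) holds variable loadings,
C (K x S) occasion loadings, Phi (S x S) the common-factor covariance,
Psi (JK x JK) the specific-factor covariance and D a positive diagonal
scaling matrix that makes the model scale invariant.  With D = I the
plain structural Parafac model is recovered.

Specific-factor structures
--------------------------
``diagonal``
    classical FA: specific factors uncorrelated.
``block_within_occasion``
    specific factors of different variables may correlate within the same
    occasion (block-diagonal Psi, one J x J block per occasion).
``banded_within_variable``
    specific factors of the same variable may correlate across occasions
    (one K x K block per variable, a "banded" pattern in composite order).

Scale-invariance variants
-------------------------
``none``
    D = I; the model is generally not scale invariant.
``variant_a``
    identifies D through the constraint that the core matrix
    (C*B) Phi (C*B)' + Psi has a unit diagonal; implemented as a
    reparameterization (D is computed, not estimated), so the implied
    Sigma is a correlation matrix.
``variant_b``
    identifies D through diag(Psi) = I with D free and positive; the
    configuration used for multitrait-multimethod correlation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError, UnsupportedModelError
from .tensorops import ThreeWayLayout, khatri_rao

__all__ = [
    "PHI_STRUCTURES",
    "PSI_STRUCTURES",
    "INVARIANCES",
    "IDENTIFICATIONS",
    "ModelSpec",
    "ParafacParams",
    "psi_support",
    "psi_support_mask",
    "implied_covariance",
    "count_parameters",
    "rescale",
]

PHI_STRUCTURES = ("orthogonal", "oblique")
PSI_STRUCTURES = ("diagonal", "block_within_occasion", "banded_within_variable")
INVARIANCES = ("none", "variant_a", "variant_b")
IDENTIFICATIONS = ("unit_column_norm", "first_row_unit")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of a structural Parafac model.

    Parameters
    ----------
    n_factors
        Number of common factors S (>= 1).
    phi_structure
        ``orthogonal`` (Phi diagonal) or ``oblique`` (Phi unstructured PD).
    psi_structure
        One of :data:`PSI_STRUCTURES`.
    invariance
        One of :data:`INVARIANCES`; see module docstring.
    identification
        ``unit_column_norm`` scales B and C to unit column norms;
        ``first_row_unit`` fixes the first rows of B and C to ones (the
        convention used when fitting correlation data with free D).
    """

    n_factors: int
    phi_structure: str = "orthogonal"
    psi_structure: str = "diagonal"
    invariance: str = "none"
    identification: str = "unit_column_norm"

    def __post_init__(self):
        if self.n_factors < 1:
            raise DimensionError("n_factors must be >= 1")
        for name, value, choices in [
            ("phi_structure", self.phi_structure, PHI_STRUCTURES),
            ("psi_structure", self.psi_structure, PSI_STRUCTURES),
            ("invariance", self.invariance, INVARIANCES),
            ("identification", self.identification, IDENTIFICATIONS),
        ]:
            if value not in choices:
                raise ValueError(f"unknown {name} {value!r}; choose from {choices}")

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "phi_structure": self.phi_structure,
            "psi_structure": self.psi_structure,
            "invariance": self.invariance,
            "identification": self.identification,
        }


@dataclass
class ParafacParams:
    """Parameter matrices of the structural Parafac model.

    ``D`` may be given as a length-JK vector of diagonal entries or a
    JK x JK diagonal matrix; ``None`` means the identity.
    """

    B: np.ndarray
    C: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    D: np.ndarray = None

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.Phi = np.atleast_2d(np.asarray(self.Phi, dtype=float))
        self.Psi = np.atleast_2d(np.asarray(self.Psi, dtype=float))
        if self.B.shape[1] != self.C.shape[1]:
            raise DimensionError("B and C must have the same number of columns")
        if self.Phi.shape != (self.n_factors, self.n_factors):
            raise DimensionError("Phi must be S x S")
        jk = self.B.shape[0] * self.C.shape[0]
        if self.Psi.shape != (jk, jk):
            raise DimensionError("Psi must be JK x JK")
        if self.D is None:
            self.D = np.ones(jk)
        else:
            D = np.asarray(self.D, dtype=float)
            if D.ndim == 2:
                D = np.diag(D)
            if D.shape != (jk,):
                raise DimensionError("D must have JK diagonal entries")
            self.D = D

    @property
    def n_variables(self) -> int:
        return self.B.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.C.shape[0]

    @property
    def n_factors(self) -> int:
        return self.B.shape[1]

    def loadings(self) -> np.ndarray:
        """Khatri-Rao structured loading matrix Lambda = C * B (JK x S)."""
        return khatri_rao(self.C, self.B)

    def copy(self) -> "ParafacParams":
        return ParafacParams(
            self.B.copy(), self.C.copy(), self.Phi.copy(), self.Psi.copy(),
            self.D.copy(),
        )


def psi_support(psi_structure: str, layout: ThreeWayLayout) -> set:
    """Set of (row, col) composite-index pairs allowed nonzero in Psi.

    The set is symmetric and always contains the diagonal.
    """
    J, K = layout.n_variables, layout.n_occasions
    jk = J * K
    support = {(a, a) for a in range(jk)}
    if psi_structure == "diagonal":
        pass
    elif psi_structure == "block_within_occasion":
        for k in range(K):
            for j in range(J):
                for j2 in range(J):
                    if j != j2:
                        support.add((k * J + j, k * J + j2))
    elif psi_structure == "banded_within_variable":
        for j in range(J):
            for k in range(K):
                for k2 in range(K):
                    if k != k2:
                        support.add((k * J + j, k2 * J + j))
    else:
        raise ValueError(f"unknown psi_structure {psi_structure!r}")
    return support


def psi_support_mask(psi_structure: str, layout: ThreeWayLayout) -> np.ndarray:
    """Boolean JK x JK mask of the Psi support."""
    jk = layout.size
    mask = np.zeros((jk, jk), dtype=bool)
    for a, b in psi_support(psi_structure, layout):
        mask[a, b] = True
    return mask


def implied_covariance(
    params: ParafacParams,
    spec: ModelSpec = None,
    layout: ThreeWayLayout = None,
) -> np.ndarray:
    """Model-implied covariance matrix Sigma = D[(C*B) Phi (C*B)' + Psi]D.

    ``spec`` and ``layout``, when given, are used for consistency checks
    (dimensions, Psi support, sign of D); the formula itself depends only
    on the parameter matrices.
    """
    if layout is not None:
        if (params.n_variables, params.n_occasions) != (
            layout.n_variables,
            layout.n_occasions,
        ):
            raise DimensionError("params do not match layout dimensions")
    if spec is not None:
        if params.n_factors != spec.n_factors:
            raise DimensionError("params do not match spec.n_factors")
        lay = layout or ThreeWayLayout(params.n_variables, params.n_occasions)
        off = ~psi_support_mask(spec.psi_structure, lay)
        if np.any(params.Psi[off] != 0.0):
            raise ValueError(
                "Psi has nonzero entries outside the declared "
                f"{spec.psi_structure!r} support"
            )
    d = params.D
    if np.any(d <= 0):
        raise ValueError("D must have strictly positive diagonal entries")
    Lam = params.loadings()
    M = Lam @ params.Phi @ Lam.T + params.Psi
    Sigma = d[:, None] * M * d[None, :]
    return (Sigma + Sigma.T) / 2.0


def count_parameters(spec: ModelSpec, layout: ThreeWayLayout) -> int:
    """Number of free (identified) parameters of the model.

    Defined for the two conventions whose counting rules are established:

    * ``first_row_unit`` with ``variant_b``:
      JK (D) + (J-1)S (B) + (K-1)S (C) + S or S(S+1)/2 (Phi) +
      off-diagonal Psi support (upper triangle);
    * ``unit_column_norm`` with ``none``:
      (J-1)S + (K-1)S + Phi + full Psi support (diagonal included).

    Any other combination raises :class:`UnsupportedModelError` rather
    than returning a possibly wrong number.
    """
    J, K, S = layout.n_variables, layout.n_occasions, spec.n_factors
    phi_count = S if spec.phi_structure == "orthogonal" else S * (S + 1) // 2
    if spec.psi_structure == "diagonal":
        psi_off = 0
    elif spec.psi_structure == "block_within_occasion":
        psi_off = K * J * (J - 1) // 2
    else:  # banded_within_variable
        psi_off = J * K * (K - 1) // 2
    if spec.identification == "first_row_unit" and spec.invariance == "variant_b":
        return J * K + (J - 1) * S + (K - 1) * S + phi_count + psi_off
    if spec.identification == "unit_column_norm" and spec.invariance == "none":
        return (J - 1) * S + (K - 1) * S + phi_count + psi_off + J * K
    raise UnsupportedModelError(
        "parameter counting is only defined for identification="
        "'first_row_unit' with invariance='variant_b' and for "
        "'unit_column_norm' with invariance='none'; got "
        f"{spec.identification!r} with {spec.invariance!r}"
    )


def rescale(
    params: ParafacParams,
    l_v: np.ndarray,
    l_o: np.ndarray,
    spec: ModelSpec,
) -> ParafacParams:
    """Apply the variable/occasion rescaling L = L_O (x) L_V to the parameters.

    For ``invariance='none'`` the scaling is absorbed by the Khatri-Rao
    structure: B <- L_V B, C <- L_O C, Psi <- L Psi L.  For the scale-
    invariant variants the scaling is absorbed entirely by D <- L D, with
    B, C, Phi, Psi unchanged.  In both cases the implied covariance of the
    result equals L Sigma L.
    """
    l_v = np.asarray(l_v, dtype=float).ravel()
    l_o = np.asarray(l_o, dtype=float).ravel()
    if l_v.shape != (params.n_variables,) or l_o.shape != (params.n_occasions,):
        raise DimensionError("scale vectors must have lengths J and K")
    if np.any(l_v <= 0) or np.any(l_o <= 0):
        raise ValueError("scale factors must be strictly positive")
    L = np.kron(l_o, l_v)  # composite (occasion-slowest) order
    out = params.copy()
    if spec.invariance == "none":
        out.B = l_v[:, None] * out.B
        out.C = l_o[:, None] * out.C
        out.Psi = L[:, None] * out.Psi * L[None, :]
    else:
        out.D = L * out.D
    return out
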