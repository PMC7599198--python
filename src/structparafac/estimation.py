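"""Discrepancy-function estimation of the structural Parafac model.

The free parameters are mapped to an unconstrained internal vector so
that Newton-type optimization needs no explicit constraints:

* loadings B, C: free entries (first rows fixed to 1 under the
  ``first_row_unit`` identification, in which case they are not part of
  the vector at all);
* Phi: log-variances (orthogonal) or a Cholesky factor with
  log-parameterized diagonal (oblique), guaranteeing positive
  definiteness;
* Psi: under ``variant_b`` each within-occasion or within-variable block
  is a correlation matrix built from a row-normalized Cholesky factor
  (unit diagonal by construction); otherwise blocks are log-Cholesky
  covariance blocks and the diagonal case uses log-variances;
* D: log-diagonal (``variant_b``); under ``variant_a`` D is eliminated
  analytically as diag(M)^{-1/2} of the core matrix M, and under
  ``none`` it is the identity.

Because every point of the internal space maps to a positive definite
Sigma, the discrepancy functions are finite everywhere (barring floating
overflow) and quasi-Newton iterations never leave the feasible set.

Multi-start protocol: each run starts from a random internal vector,
first minimizes the unweighted quadratic discrepancy (W = I, the OLS
solution) and then refines with the requested method -- the default
``ols_then_ml`` strategy.  The global optimum is bookkept by comparing
minimized discrepancies rounded to four decimals across starts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from .exceptions import (
    ConvergenceError,
    DefinitenessError,
    DimensionError,
    UnsupportedModelError,
)
from .model import ModelSpec, ParafacParams, count_parameters
from .tensorops import ThreeWayLayout

__all__ = [
    "FitOptions",
    "FitResult",
    "quadratic_discrepancy",
    "ml_discrepancy",
    "fit",
    "standard_errors",
]

_BIG = 1e12


# ---------------------------------------------------------------------------
# discrepancy functions
# ---------------------------------------------------------------------------

def _check_square(name, M, n=None):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError(f"{name} must be square")
    if n is not None and M.shape[0] != n:
        raise DimensionError(f"{name} must be {n} x {n}")
    return M


def quadratic_discrepancy(S_mat, Sigma, W) -> float:
    """Weighted quadratic discrepancy tr{[(S - Sigma) W^-1]^2} / 2.

    W = I gives the OLS discrepancy, W = S the (best) GLS discrepancy;
    zero iff S equals Sigma.
    """
    S_mat = _check_square("S", S_mat)
    n = S_mat.shape[0]
    Sigma = _check_square("Sigma", Sigma, n)
    W = _check_square("W", W, n)
    try:
        cW = cho_factor(W, lower=True)
    except LinAlgError as exc:
        raise DefinitenessError("weight matrix W is not positive definite") from exc
    X = cho_solve(cW, S_mat - Sigma)  # W^-1 (S - Sigma)
    return float(np.sum(X * X.T) / 2.0)


def ml_discrepancy(S_mat, Sigma) -> float:
    """Normal-theory ML discrepancy ln|Sigma| - ln|S| + tr(S Sigma^-1) - JK.

    Nonnegative, and zero iff S equals Sigma.  Asymptotically equivalent
    to the quadratic discrepancy with the iteratively reweighted choice
    W = Sigma(theta).
    """
    S_mat = _check_square("S", S_mat)
    n = S_mat.shape[0]
    Sigma = _check_square("Sigma", Sigma, n)
    try:
        cS = cho_factor(S_mat, lower=True)
        cSig = cho_factor(Sigma, lower=True)
    except LinAlgError as exc:
        raise DefinitenessError("S and Sigma must be positive definite") from exc
    logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
    logdet_Sig = 2.0 * np.sum(np.log(np.diag(cSig[0])))
    return float(logdet_Sig - logdet_S + np.trace(cho_solve(cSig, S_mat)) - n)


# ---------------------------------------------------------------------------
# internal parameterization
# ---------------------------------------------------------------------------

def _corr_chol_rows(z: np.ndarray, m: int) -> np.ndarray:
    """Row-normalized lower Cholesky factor of an m x m correlation matrix."""
    W = np.zeros((m, m))
    W[0, 0] = 1.0
    pos = 0
    for i in range(1, m):
        v = np.empty(i + 1)
        v[:i] = z[pos : pos + i]
        v[i] = 1.0
        W[i, : i + 1] = v / np.sqrt(v @ v)
        pos += i
    return W


def _corr_params_from_block(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_corr_chol_rows` for a PD unit-diagonal block."""
    m = R.shape[0]
    W = cholesky(R, lower=True)
    z = []
    for i in range(1, m):
        z.extend(W[i, :i] / W[i, i])
    return np.asarray(z)


def _chol_build(z: np.ndarray, m: int) -> np.ndarray:
    """Lower Cholesky factor with log-parameterized diagonal."""
    L = np.zeros((m, m))
    pos = 0
    for i in range(m):
        L[i, :i] = z[pos : pos + i]
        L[i, i] = math.exp(z[pos + i])
        pos += i + 1
    return L


def _chol_params_from_block(V: np.ndarray) -> np.ndarray:
    m = V.shape[0]
    L = cholesky(V, lower=True)
    z = []
    for i in range(m):
        z.extend(L[i, :i])
        z.append(math.log(L[i, i]))
    return np.asarray(z)


class _Parameterization:
    """Bijection between the internal vector and the parameter matrices."""

    def __init__(self, spec: ModelSpec, layout: ThreeWayLayout):
        self.spec = spec
        self.layout = layout
        J, K, S = layout.n_variables, layout.n_occasions, spec.n_factors
        self.J, self.K, self.S = J, K, S
        self.jk = J * K
        self.first_row_unit = spec.identification == "first_row_unit"

        self.n_b = (J - 1) * S if self.first_row_unit else J * S
        self.n_c = (K - 1) * S if self.first_row_unit else K * S
        self.orthogonal = spec.phi_structure == "orthogonal"
        self.n_phi = S if self.orthogonal else S * (S + 1) // 2

        # Psi block index sets in composite order
        if spec.psi_structure == "diagonal":
            self.psi_blocks = []
        elif spec.psi_structure == "block_within_occasion":
            self.psi_blocks = [
                np.array([k * J + j for j in range(J)]) for k in range(K)
            ]
        else:  # banded_within_variable
            self.psi_blocks = [
                np.array([k * J + j for k in range(K)]) for j in range(J)
            ]
        self.psi_corr = spec.invariance == "variant_b"
        if spec.psi_structure == "diagonal":
            self.n_psi = 0 if self.psi_corr else self.jk
        else:
            m = self.psi_blocks[0].size
            per = m * (m - 1) // 2 if self.psi_corr else m * (m + 1) // 2
            self.n_psi = per * len(self.psi_blocks)

        self.n_d = self.jk if spec.invariance == "variant_b" else 0
        self.n_free = self.n_b + self.n_c + self.n_phi + self.n_psi + self.n_d

        o = 0
        self.sl_b = slice(o, o + self.n_b); o += self.n_b
        self.sl_c = slice(o, o + self.n_c); o += self.n_c
        self.sl_phi = slice(o, o + self.n_phi); o += self.n_phi
        self.sl_psi = slice(o, o + self.n_psi); o += self.n_psi
        self.sl_d = slice(o, o + self.n_d)

        # Khatri-Rao row index maps: row r pairs variable jj[r], occasion kk[r]
        self.jj = np.tile(np.arange(J), K)
        self.kk = np.repeat(np.arange(K), J)

    # -- forward map -------------------------------------------------------

    def unpack(self, theta: np.ndarray):
        """Internal vector -> (B, C, Phi, Psi); D is resolved in sigma()."""
        J, K, S = self.J, self.K, self.S
        if self.first_row_unit:
            B = np.ones((J, S))
            B[1:] = theta[self.sl_b].reshape(J - 1, S)
            C = np.ones((K, S))
            C[1:] = theta[self.sl_c].reshape(K - 1, S)
        else:
            B = theta[self.sl_b].reshape(J, S).copy()
            C = theta[self.sl_c].reshape(K, S).copy()
        if self.orthogonal:
            Phi = np.diag(np.exp(theta[self.sl_phi]))
        else:
            L = _chol_build(theta[self.sl_phi], S)
            Phi = L @ L.T
        Psi = np.zeros((self.jk, self.jk))
        zpsi = theta[self.sl_psi]
        if self.spec.psi_structure == "diagonal":
            if self.psi_corr:
                np.fill_diagonal(Psi, 1.0)
            else:
                np.fill_diagonal(Psi, np.exp(zpsi))
        else:
            m = self.psi_blocks[0].size
            per = m * (m - 1) // 2 if self.psi_corr else m * (m + 1) // 2
            for b, idx in enumerate(self.psi_blocks):
                z = zpsi[b * per : (b + 1) * per]
                if self.psi_corr:
                    W = _corr_chol_rows(z, m)
                    block = W @ W.T
                else:
                    L = _chol_build(z, m)
                    block = L @ L.T
                Psi[np.ix_(idx, idx)] = block
        return B, C, Psi, Phi

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        """Implied covariance at an internal vector (always PD)."""
        B, C, Psi, Phi = self.unpack(theta)
        Lam = C[self.kk, :] * B[self.jj, :]
        if self.orthogonal:
            M = (Lam * np.diag(Phi)) @ Lam.T + Psi
        else:
            M = Lam @ Phi @ Lam.T + Psi
        inv = self.spec.invariance
        if inv == "variant_b":
            d = np.exp(theta[self.sl_d])
        elif inv == "variant_a":
            d = 1.0 / np.sqrt(np.diag(M))
        else:
            return (M + M.T) / 2.0
        Sig = d[:, None] * M * d[None, :]
        return (Sig + Sig.T) / 2.0

    def _resolve_d(self, theta, B, C, Psi, Phi):
        inv = self.spec.invariance
        if inv == "variant_b":
            return np.exp(theta[self.sl_d])
        if inv == "variant_a":
            Lam = C[self.kk, :] * B[self.jj, :]
            M = Lam @ Phi @ Lam.T + Psi
            return 1.0 / np.sqrt(np.diag(M))
        return np.ones(self.jk)

    def _identify(self, B, C, Phi):
        """Apply the output scaling convention (unit column norms)."""
        if self.first_row_unit:
            return B, C, Phi
        nb = np.linalg.norm(B, axis=0)
        nc = np.linalg.norm(C, axis=0)
        nb = np.where(nb > 0, nb, 1.0)
        nc = np.where(nc > 0, nc, 1.0)
        scale = nb * nc
        return B / nb, C / nc, Phi * np.outer(scale, scale)

    def to_params(self, theta: np.ndarray) -> ParafacParams:
        B, C, Psi, Phi = self.unpack(theta)
        d = self._resolve_d(theta, B, C, Psi, Phi)
        B, C, Phi = self._identify(B, C, Phi)
        return ParafacParams(B=B, C=C, Phi=Phi, Psi=Psi, D=d)

    # -- inverse map -------------------------------------------------------

    def from_params(self, params: ParafacParams) -> np.ndarray:
        """Internal vector reproducing a (valid, identified) parameter set."""
        if (params.n_variables, params.n_occasions, params.n_factors) != (
            self.J, self.K, self.S,
        ):
            raise DimensionError("params do not match this model's dimensions")
        theta = np.zeros(self.n_free)
        if self.first_row_unit:
            theta[self.sl_b] = params.B[1:].ravel()
            theta[self.sl_c] = params.C[1:].ravel()
        else:
            theta[self.sl_b] = params.B.ravel()
            theta[self.sl_c] = params.C.ravel()
        if self.orthogonal:
            theta[self.sl_phi] = np.log(np.diag(params.Phi))
        else:
            theta[self.sl_phi] = _chol_params_from_block(params.Phi)
        if self.spec.psi_structure == "diagonal":
            if not self.psi_corr:
                theta[self.sl_psi] = np.log(np.diag(params.Psi))
        else:
            chunks = []
            for idx in self.psi_blocks:
                block = params.Psi[np.ix_(idx, idx)]
                if self.psi_corr:
                    chunks.append(_corr_params_from_block(block))
                else:
                    chunks.append(_chol_params_from_block(block))
            theta[self.sl_psi] = np.concatenate(chunks)
        if self.spec.invariance == "variant_b":
            theta[self.sl_d] = np.log(params.D)
        return theta

    # -- natural-scale view (for standard errors) --------------------------

    def natural_names(self) -> list:
        vlab = self.layout.variable_labels
        olab = self.layout.occasion_labels
        clab = self.layout.composite_labels()
        names = []
        rows = range(1, self.J) if self.first_row_unit else range(self.J)
        for j in rows:
            for s in range(self.S):
                names.append(f"B[{vlab[j]},F{s + 1}]")
        rows = range(1, self.K) if self.first_row_unit else range(self.K)
        for k in rows:
            for s in range(self.S):
                names.append(f"C[{olab[k]},F{s + 1}]")
        if self.orthogonal:
            names += [f"Phi[F{s + 1},F{s + 1}]" for s in range(self.S)]
        else:
            for s in range(self.S):
                for t in range(s + 1):
                    names.append(f"Phi[F{s + 1},F{t + 1}]")
        for a, b in self._psi_natural_entries():
            names.append(f"Psi[{clab[a]},{clab[b]}]")
        if self.spec.invariance == "variant_b":
            names += [f"D[{lab}]" for lab in clab]
        return names

    def _psi_natural_entries(self):
        """Free Psi entries: (row, col) with row >= col, support order."""
        entries = []
        if self.spec.psi_structure == "diagonal":
            if not self.psi_corr:
                entries = [(a, a) for a in range(self.jk)]
        else:
            for idx in self.psi_blocks:
                for i in range(idx.size):
                    start = i + 1 if self.psi_corr else i
                    for i2 in range(start, idx.size):
                        a, b = idx[i2], idx[i]
                        entries.append((max(a, b), min(a, b)))
        return entries

    def natural_vector(self, theta: np.ndarray) -> np.ndarray:
        B, C, Psi, Phi = self.unpack(theta)
        d = self._resolve_d(theta, B, C, Psi, Phi)
        B, C, Phi = self._identify(B, C, Phi)
        out = []
        out.append((B[1:] if self.first_row_unit else B).ravel())
        out.append((C[1:] if self.first_row_unit else C).ravel())
        if self.orthogonal:
            out.append(np.diag(Phi))
        else:
            out.append(Phi[np.tril_indices(self.S)])
        ent = self._psi_natural_entries()
        if ent:
            rows, cols = zip(*ent)
            out.append(Psi[list(rows), list(cols)])
        if self.spec.invariance == "variant_b":
            out.append(d)
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# objective with gradient
# ---------------------------------------------------------------------------

class _Objective:
    """F(theta) with gradient via dF/dSigma chained through a central-
    difference Jacobian of the (cheap) parameter -> Sigma map."""

    def __init__(self, param: _Parameterization, S_mat: np.ndarray,
                 method: str, W: np.ndarray = None):
        self.param = param
        self.S = S_mat
        self.p = S_mat.shape[0]
        self.method = method
        if method == "ml":
            cS = cho_factor(S_mat, lower=True)
            self.logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
        else:
            self.Winv = np.linalg.inv(W)
        self._eye = np.eye(self.p)

    def _f_and_gmat(self, Sigma):
        """Discrepancy and its matrix derivative dF/dSigma."""
        if self.method == "ml":
            try:
                cSig = cho_factor(Sigma, lower=True)
            except LinAlgError:
                return _BIG, None
            logdet = 2.0 * np.sum(np.log(np.diag(cSig[0])))
            SigInv = cho_solve(cSig, self._eye)
            SigInvS = SigInv @ self.S
            f = logdet - self.logdet_S + np.trace(SigInvS) - self.p
            G = SigInv - SigInvS @ SigInv
        else:
            R = self.Winv @ (self.S - Sigma)
            f = np.sum(R * R.T) / 2.0
            G = -R @ self.Winv
        if not np.isfinite(f):
            return _BIG, None
        return float(f), (G + G.T) / 2.0

    def value(self, theta):
        with np.errstate(all="ignore"):
            try:
                Sigma = self.param.sigma(theta)
            except (FloatingPointError, ValueError):
                return _BIG
            if not np.all(np.isfinite(Sigma)):
                return _BIG
            return self._f_and_gmat(Sigma)[0]

    def value_and_grad(self, theta):
        n = theta.size
        with np.errstate(all="ignore"):
            try:
                Sigma = self.param.sigma(theta)
            except (FloatingPointError, ValueError):
                return _BIG, np.zeros(n)
            if not np.all(np.isfinite(Sigma)):
                return _BIG, np.zeros(n)
            f, G = self._f_and_gmat(Sigma)
            if G is None:
                return f, np.zeros(n)
            g = np.empty(n)
            sigma = self.param.sigma
            for i in range(n):
                h = 1e-6 * (1.0 + abs(theta[i]))
                tp = theta.copy(); tp[i] += h
                tm = theta.copy(); tm[i] -= h
                dS = sigma(tp)
                dS -= sigma(tm)
                g[i] = np.sum(G * dS) / (2.0 * h)
            if not np.all(np.isfinite(g)):
                g = np.where(np.isfinite(g), g, 0.0)
        return f, g

    def gradient(self, theta):
        return self.value_and_grad(theta)[1]


def _fd_hessian(obj: _Objective, theta: np.ndarray, rel_h: float = 1e-5):
    """Central-difference Hessian of the discrepancy (symmetrized)."""
    n = theta.size
    H = np.empty((n, n))
    for i in range(n):
        h = rel_h * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        H[:, i] = (obj.gradient(tp) - obj.gradient(tm)) / (2.0 * h)
    return (H + H.T) / 2.0


def _newton_polish(obj: _Objective, theta: np.ndarray, max_iter: int = 10):
    """A few damped Newton steps to sharpen the incumbent optimum."""
    f, g = obj.value_and_grad(theta)
    for _ in range(max_iter):
        if np.linalg.norm(g, np.inf) < 1e-11:
            break
        H = _fd_hessian(obj, theta)
        scale = max(np.abs(np.diag(H)).max(), 1.0)
        step = None
        for ridge in (0.0, 1e-10, 1e-8, 1e-6, 1e-4, 1e-2):
            try:
                cH = cho_factor(H + ridge * scale * np.eye(theta.size))
                step = cho_solve(cH, g)
                break
            except LinAlgError:
                continue
        if step is None:
            break
        t, improved = 1.0, False
        while t > 1e-6:
            cand = theta - t * step
            fc = obj.value(cand)
            if fc < f - 1e-14:
                theta, f = cand, fc
                improved = True
                break
            t /= 2.0
        if not improved:
            break
        f, g = obj.value_and_grad(theta)
    return theta, f


# ---------------------------------------------------------------------------
# fit driver
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Options controlling the multi-start minimization.

    ``start_strategy='ols_then_ml'`` first minimizes the W = I quadratic
    discrepancy from a random initialization, then refines with the
    requested method -- mirroring the protocol of starting every run at a
    randomly initialized OLS solution.  ``init`` optionally supplies a
    warm start used as the first start (the remaining starts are random).
    """

    method: str = "ml"
    n_starts: int = 100
    max_iter: int = 500
    gtol: float = 1e-8
    seed: int = None
    start_strategy: str = "ols_then_ml"
    start_scale: float = 0.5
    stage1_max_iter: int = 150
    init: ParafacParams = None
    polish: bool = True

    def __post_init__(self):
        if self.method not in ("ols", "gls", "ml"):
            raise ValueError("method must be 'ols', 'gls' or 'ml'")
        if self.start_strategy not in ("random", "ols_then_ml"):
            raise ValueError("start_strategy must be 'random' or 'ols_then_ml'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.gtol <= 0 or self.start_scale <= 0:
            raise ValueError("tolerances and scales must be positive")


@dataclass
class FitResult:
    """Outcome of :func:`fit`.

    ``chi_square = (I - 1) * F_hat`` with ``df = JK(JK+1)/2 - q`` free
    parameters ``q``; the information criteria are ``AIC = chi2 + 2q``
    and ``BIC = chi2 + q ln I``.  ``n_at_global`` counts converged starts
    whose minimized discrepancy matches the best one to four decimals.
    """

    params: ParafacParams
    F_hat: float
    chi_square: float
    df: int
    p_value: float
    aic: float
    bic: float
    n_parameters: int
    standard_errors: dict
    n_converged: int
    n_at_global: int
    spec: ModelSpec
    layout: ThreeWayLayout
    sample_size: int
    method: str
    n_starts: int
    start_discrepancies: np.ndarray
    start_converged: np.ndarray
    best_start: int
    sample_cov: np.ndarray = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)
    _parameterization: object = field(repr=False, default=None)


def _validate_sample_cov(S_mat, layout):
    S_mat = _check_square("sample covariance", S_mat, layout.size)
    if not np.allclose(S_mat, S_mat.T, atol=1e-10):
        raise DimensionError("sample covariance must be symmetric")
    try:
        cho_factor(S_mat, lower=True)
    except LinAlgError as exc:
        raise DefinitenessError(
            "sample covariance must be positive definite"
        ) from exc
    return (S_mat + S_mat.T) / 2.0


def fit(
    S_mat: np.ndarray,
    sample_size: int,
    spec: ModelSpec,
    layout: ThreeWayLayout,
    options: FitOptions = None,
) -> FitResult:
    """Fit the structural Parafac model to a sample covariance matrix.

    Parameters
    ----------
    S_mat
        JK x JK symmetric positive definite sample covariance (or
        correlation) matrix, rows in composite (occasion-slowest) order.
    sample_size
        Number of observations I behind ``S_mat``; used for the test
        statistic and information criteria.
    spec, layout
        Model configuration and data layout.
    options
        Multi-start and optimizer settings; see :class:`FitOptions`.

    Returns the best local minimum over all starts, with multi-start
    diagnostics.  Raises :class:`ConvergenceError` when no start
    converges.
    """
    options = options or FitOptions()
    S_mat = _validate_sample_cov(S_mat, layout)
    try:
        q = count_parameters(spec, layout)
    except UnsupportedModelError:
        q = None
    if q is not None and sample_size <= q:
        warnings.warn(
            f"sample size {sample_size} does not exceed the parameter "
            f"count {q}; test statistics are unreliable",
            stacklevel=2,
        )

    param = _Parameterization(spec, layout)
    rng = np.random.default_rng(options.seed)
    n = param.n_free

    if options.method == "ml":
        target = _Objective(param, S_mat, "ml")
    elif options.method == "gls":
        target = _Objective(param, S_mat, "quad", W=S_mat)
    else:
        target = _Objective(param, S_mat, "quad", W=np.eye(layout.size))
    stage1 = None
    if options.start_strategy == "ols_then_ml" and options.method != "ols":
        stage1 = _Objective(param, S_mat, "quad", W=np.eye(layout.size))

    thetas0 = [rng.normal(0.0, options.start_scale, n) for _ in range(options.n_starts)]
    if options.init is not None:
        thetas0[0] = param.from_params(options.init)

    f_by_start = np.full(options.n_starts, np.inf)
    conv_by_start = np.zeros(options.n_starts, dtype=bool)
    thetas = [None] * options.n_starts
    for i, theta0 in enumerate(thetas0):
        theta = theta0
        if stage1 is not None and not (i == 0 and options.init is not None):
            res1 = optimize.minimize(
                stage1.value_and_grad, theta, jac=True, method="BFGS",
                options={"maxiter": options.stage1_max_iter,
                         "gtol": options.gtol * 10},
            )
            theta = res1.x
        res = optimize.minimize(
            target.value_and_grad, theta, jac=True, method="BFGS",
            options={"maxiter": options.max_iter, "gtol": options.gtol},
        )
        f_by_start[i] = res.fun
        thetas[i] = res.x
        gnorm = np.linalg.norm(res.jac, np.inf)
        # BFGS frequently exits with a precision-loss status once the FD
        # gradient noise floor is reached; a near-zero gradient still
        # counts as converged.
        conv_by_start[i] = bool(res.success) or gnorm <= 1e-4 * (1.0 + abs(res.fun))

    if not np.any(f_by_start < _BIG):
        raise ConvergenceError(
            "no optimization start converged",
            diagnostics={"discrepancies": f_by_start, "converged": conv_by_start},
        )

    # the solution with the minimum loss value is the best-fitting one,
    # even when that start exhausted its iteration budget (the Newton
    # polish below finishes the job)
    best = int(np.argmin(f_by_start))
    f_best_raw = f_by_start[best]
    theta_hat = thetas[best]
    if options.polish:
        theta_hat, f_hat = _newton_polish(target, theta_hat)
    else:
        f_hat = f_best_raw
    if -1e-8 < f_hat < 0.0:
        f_hat = 0.0  # discrepancies are nonnegative; absorb rounding
    n_at_global = int(
        np.sum(np.round(f_by_start[conv_by_start], 4) == round(f_best_raw, 4))
    )

    jk = layout.size
    chi2 = df = p = aic = bic = None
    if q is not None:
        df = jk * (jk + 1) // 2 - q
        if df > 0 and sample_size >= 2:
            chi2 = (sample_size - 1) * f_hat
            p = float(stats.chi2.sf(chi2, df))
            aic = chi2 + 2 * q
            bic = chi2 + q * math.log(sample_size)

    return FitResult(
        params=param.to_params(theta_hat),
        F_hat=float(f_hat),
        chi_square=chi2,
        df=df,
        p_value=p,
        aic=aic,
        bic=bic,
        n_parameters=q,
        standard_errors=None,
        n_converged=int(conv_by_start.sum()),
        n_at_global=n_at_global,
        spec=spec,
        layout=layout,
        sample_size=sample_size,
        method=options.method,
        n_starts=options.n_starts,
        start_discrepancies=f_by_start,
        start_converged=conv_by_start,
        best_start=best,
        sample_cov=S_mat,
        _theta=theta_hat,
        _parameterization=param,
    )


def standard_errors(result: FitResult) -> dict:
    """Delta-method standard errors on the natural parameter scale.

    The covariance of the internal estimate is ``(2 / (I - 1)) H^-1``
    with H the numerically differentiated Hessian of the discrepancy at
    the optimum; it is propagated through the Jacobian of the internal ->
    natural map so the errors refer to loadings, covariances and scaling
    entries directly.  If the Hessian is not positive definite a warning
    is issued and ``None`` is returned (never a fabricated number).
    """
    param = result._parameterization
    theta = result._theta
    if param is None or theta is None:
        raise ValueError("result does not carry internal state")
    if result.method == "ml":
        obj = _Objective(param, result.sample_cov, "ml")
    elif result.method == "gls":
        obj = _Objective(param, result.sample_cov, "quad", W=result.sample_cov)
    else:
        obj = _Objective(param, result.sample_cov, "quad",
                         W=np.eye(result.layout.size))
    H = _fd_hessian(obj, theta)
    w = np.linalg.eigvalsh(H)
    if w[0] <= 1e-10 * max(w[-1], 1.0):
        warnings.warn(
            "Hessian at the optimum is not positive definite; "
            "standard errors are unavailable",
            stacklevel=2,
        )
        return None
    cov_theta = 2.0 / (result.sample_size - 1) * np.linalg.inv(H)
    # Jacobian of the natural-scale view
    nat0 = param.natural_vector(theta)
    Jc = np.empty((nat0.size, theta.size))
    for i in range(theta.size):
        h = 1e-6 * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        Jc[:, i] = (param.natural_vector(tp) - param.natural_vector(tm)) / (2 * h)
    cov_nat = Jc @ cov_theta @ Jc.T
    se = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
    out = dict(zip(param.natural_names(), se))
    result.standard_errors = out
    return out
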