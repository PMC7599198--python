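# Methods

## Model

The structural Parafac model represents the covariance matrix of J
variables observed at K occasions as

    Sigma(theta) = D [ (C • B) Phi (C • B)' + Psi ] D,

with B (J × S), C (K × S), Phi (S × S) positive definite, Psi (JK × JK)
positive definite with zeros off a declared support, and D positive
diagonal. Rows are vectorized occasion-slowest: variable j at occasion k
sits at composite index kJ + j, so each occasion's J × J block of Sigma
is contiguous and the loading matrix Lambda = C • B (the Khatri–Rao,
i.e. column-wise Kronecker, product) has row (j, k) equal to
c_k ⊙ b_j-row products. With D = I the plain structural model is
recovered; the observed vector is x = mu + D[(C • B) a + e] with
E(aa') = Phi, E(ee') = Psi, and the mean structure mu is not modelled
(all computations use central second moments only).

Three specific-factor supports are implemented:

* **diagonal** — classical FA errors;
* **block_within_occasion** — one J × J block per occasion: variables
  may share occasion-specific nuisance factors;
* **banded_within_variable** — one K × K block per variable: the same
  variable's specific factors correlate across occasions. "Banded"
  refers to the stripe pattern these blocks form in composite order.
  The within-variable reading (rather than literal band-limited
  correlation) is the one consistent with the parameter count
  J·K(K−1)/2 of the reference analysis this package reproduces.

Scale-invariance variants:

* **none** — D = I. A diagonal rescaling L = L_O ⊗ L_V (same variable
  scaling at every occasion, same occasion scaling for every variable)
  is still absorbed by the Khatri–Rao structure: B ← L_V B, C ← L_O C,
  Psi ← L Psi L.
* **variant_a** — unit diagonal of the core matrix
  M = (C • B) Phi (C • B)' + Psi. Implemented as a reparameterization:
  the diagonal of Psi is free and D is *computed* as diag(M)^{−1/2}, so
  the implied Sigma is a correlation matrix and no constrained
  optimization is needed. This is an analytical elimination of D, not a
  Lagrangian treatment of the constraint.
* **variant_b** — diag(Psi) = I with D free and positive; the
  configuration used when fitting correlation matrices, where D plays
  the role of (rescaled) communal standard deviations.

Identification of the loading scale: either unit column norms of B and C
(`unit_column_norm`, the component-analysis convention; column norms are
absorbed into Phi on output) or first rows of B and C fixed to ones
(`first_row_unit`, the convention of the packaged application; requires
the first variable and occasion to load on every factor).

Parameter counting is implemented only for the two conventions whose
counts are well established — `first_row_unit` + `variant_b`
(JK + (J−1)S + (K−1)S + |Phi| + off-diagonal Psi support) and
`unit_column_norm` + `none` — and raises for any other combination
rather than guessing. Degrees of freedom are
df = JK(JK+1)/2 − q.

## Uniqueness checkers

The k-rank of a matrix (largest k such that every k-column subset has
full rank) is computed by exhaustive subset enumeration with numerical
rank from singular values at a relative tolerance (default 1e-8 of the
largest singular value). The tolerance is surfaced because k-rank is
discontinuous in the entries. Size guards (≤ 30 rows, ≤ 12 columns for
k-rank; ≤ 30 rows, S ≤ 6 for the row-deletion search) keep the
enumeration exact at the model sizes this package targets; there is no
heuristic fallback.

Checked conditions:

* Kruskal-type: k-rank(B) + k-rank(C) ≥ S + 2 (with full-rank Phi this
  is the classical three-matrix condition with k-rank(Phi^{1/2}) = S);
* row-deletion (diagonal Psi): deleting any one row of Lambda leaves two
  disjoint row sets each of rank S — searched exhaustively over S-row
  subsets;
* per-occasion rank (block-diagonal Psi): rank(B diag(c_k)) = S for at
  least three occasions. For the banded (within-variable) structure the
  symmetric condition with the roles of B and C exchanged is used.

The checks can be run on Lambda = C • B or on D (C • B) Phi^{1/2} (the
scale-invariant formulation); for positive D and full-rank Phi the two
have equal row spaces, and both entry points are exposed.

## Estimation

Discrepancy functions between the sample covariance S and Sigma(theta):

* quadratic: F_W = tr{[(S − Sigma) W^{−1}]²}/2 with W = I (OLS) or
  W = S (best GLS);
* normal-theory ML: F_ML = ln|Sigma| − ln|S| + tr(S Sigma^{−1}) − JK.

F_ML is the maximum-likelihood discrepancy under i.i.d. multivariate
normal observations and is asymptotically equivalent to the quadratic
form with the iteratively reweighted choice W = Sigma(theta); the
normal-theory form is used because it reproduces the reference
chi-square/AIC/BIC analysis (the reweighted form was implemented and
checked during development and reproduces it worse; see the known
limitations below). Test statistics use chi² = (I − 1) F̂ — the
convention verified against the reference analysis arithmetic — with
AIC = chi² + 2q and BIC = chi² + q ln I.

### Parameterization

All constraints are absorbed into an unconstrained internal vector:

* B, C: free entries (first rows excluded under `first_row_unit`);
* Phi: log-variances (orthogonal) or Cholesky factor with
  log-parameterized diagonal (oblique);
* Psi: under `variant_b`, each support block is a correlation matrix
  built from a row-normalized Cholesky factor (each row's free entries
  are appended with a 1 and normalized to unit length), which
  parameterizes exactly the positive definite unit-diagonal matrices;
  otherwise blocks are log-Cholesky covariance blocks and the diagonal
  structure uses log-variances;
* D: log-diagonal (`variant_b`); computed (`variant_a`); identity
  otherwise.

Every internal point therefore maps to a positive definite Sigma, and
the objective is finite everywhere (floating overflow excepted, which is
trapped and returned as a large value).

### Optimization

Gradients are exact in Sigma: grad_i = <dF/dSigma, dSigma/dtheta_i>,
with dF/dSigma analytic (Sigma^{−1}(Sigma − S)Sigma^{−1} for ML,
W^{−1}(Sigma − S)W^{−1} for the quadratic family) and dSigma/dtheta_i
from central differences of the cheap parameter-to-Sigma map (step
1e-6·(1 + |theta_i|)). Each start runs BFGS (default gradient tolerance
1e-8, max 500 iterations); the default `ols_then_ml` strategy first
minimizes the W = I quadratic discrepancy from the random start and
then refines with the requested method. The best solution over starts
— by minimized value, even if that start exhausted its iteration budget
— is sharpened by up to ten damped Newton steps using a
finite-difference Hessian with ridge regularization and backtracking.
Random starts draw the internal vector i.i.d. normal with scale 0.5
from a seeded generator; an explicit warm start can be supplied and is
used by the model scan, which starts every correlated-Psi model from
its diagonal-Psi counterpart's solution (with a handful of extra random
starts and an enlarged iteration budget, since these runs track long,
flat valleys). "Number of starts at the global optimum" compares
minimized values rounded to four decimals.

A fit raises a convergence error only when no start produces a finite
minimum; starts whose final gradient norm exceeds 1e-4·(1 + |F|) are
recorded as non-converged in the diagnostics.

### Standard errors

The covariance of the internal estimate is (2/(I − 1)) H^{−1} with H
the finite-difference Hessian of the discrepancy at the optimum,
propagated to the natural scale (loadings, covariances, scaling
entries) through the numerically differentiated Jacobian of the
internal-to-natural map (delta method). For the just-identified
one-factor/three-variable model this reproduces the closed-form Wishart
delta-method covariance to the finite-difference accuracy (verified in
the test suite). If H is not positive definite — as happens under the
deliberately overparameterized `unit_column_norm` internal
parameterization — a warning is issued and no standard errors are
returned.

## Synthetic data

`draw_identifiable_params` draws loading entries uniform on [−1, 1]
(then applies the identification convention), Phi as a random
correlation-type PD matrix (or random variances when diagonal), Psi
blocks as random correlation matrices scaled by random variances, and D
uniform on [0.5, 1.5] — and rejects draws until the uniqueness
conditions relevant to the Psi structure hold (at most 100 retries;
generic draws pass almost surely, so rejection is a certificate, not a
crutch). `sample_covariance` draws I i.i.d. zero-mean multivariate
normal vectors with the implied covariance and returns the sample
covariance with divisor I − 1.

The generator emulates exactly the model's data-generating process:
multivariate normality, zero means, exact support zeros in Psi. It does
not emulate non-normal errors (the ADF regime), missing data, or
model misspecification, so passing recovery tests demonstrate
identification and optimizer correctness under the stated model, not
robustness on real data.

Recovery experiments fit the *population* Sigma(theta_true) and require
the aligned maximum absolute parameter error to be at most 1e-4, where
alignment searches all column permutations (and, under
`unit_column_norm`, per-column sign flips of B and C with compensating
sign changes in Phi) minimizing the squared deviation of (B, C).

## Numerical choices and problem sizes

* Rank/k-rank tolerance 1e-8 (relative); optimizer gradient tolerance
  1e-8 by default; the packaged analyses use 1e-6 per start with the
  Newton polish providing the final sharpening, which reaches gradient
  norms near 1e-11.
* Multi-start sizes used by the shipped analyses and tests: 24 random
  starts for diagonal-Psi models and warm starts plus 3–8 random starts
  for correlated-Psi models. These sizes were chosen from the observed
  basin-of-attraction frequencies (the global optimum is found from
  roughly half to four fifths of random starts, depending on the
  model), which makes the probability of missing the global optimum
  negligible at 24 starts.
* Discrepancies are clamped at zero when a perfect fit lands at −1e-12
  by rounding.
* Sample covariances from fewer observations than dimensions are
  flagged with a warning but returned.

## Known limitations

* **Flat likelihood valleys.** In the packaged MTMM application the
  selected model's likelihood is nearly flat in some loading
  directions; the corresponding standard errors are of the same order
  as the estimates. Fit statistics (F̂, chi², AIC, BIC) are stable to
  four decimals across optimizers, but individual loadings in these
  directions can differ substantially between software packages at
  essentially identical fit — comparisons of historical printed
  estimates should be made through the fit statistics and
  permutation-invariant, well-determined summaries, not through
  individual flat-direction loadings. The package reports the actual
  minimizer of the stated discrepancy, sharpened by Newton steps until
  the gradient vanishes.
* The sign of Phi^{1/2} columns is not identified; Phi itself is
  reported (positive definite by construction). Software that
  parameterizes a free square root may print negative diagonal root
  elements for the same Phi.
* Exhaustive uniqueness checks are exponential and guarded to small
  sizes; no certificates are produced beyond the boolean outcomes.
* ADF (fourth-moment weighted) and Bayesian estimation, Tucker3
  covariance structures (a core-matrix generalization of this model),
  and raw three-way data fitting are out of scope.
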