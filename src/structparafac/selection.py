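"""Fit statistics, information criteria and multi-model comparison.

The overall-fit test treats ``chi2 = (I - 1) * F_hat`` as asymptotically
chi-square with ``df = JK(JK+1)/2 - q`` degrees of freedom under the null
hypothesis that the population covariance has the Parafac structure.  The
information criteria are on the chi-square scale: ``AIC = chi2 + 2 q``
and ``BIC = chi2 + q ln I``, so ``BIC - AIC = q (ln I - 2)`` identically.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitOptions, FitResult, fit
from .exceptions import UnsupportedModelError
from .model import ModelSpec, count_parameters
from .tensorops import ThreeWayLayout

__all__ = [
    "chi_square_test",
    "information_criteria",
    "default_model_grid",
    "model_scan",
]


def chi_square_test(F_hat: float, sample_size: int, q: int, jk: int):
    """Overall goodness-of-fit test; returns ``(chi2, df, p)``."""
    if F_hat < 0:
        raise ValueError("F_hat must be nonnegative")
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    df = jk * (jk + 1) // 2 - q
    if df <= 0:
        raise UnsupportedModelError(
            f"model is saturated or over-parameterized (df = {df})"
        )
    chi2 = (sample_size - 1) * F_hat
    return chi2, df, float(stats.chi2.sf(chi2, df))


def information_criteria(chi2: float, q: int, sample_size: int):
    """AIC and BIC on the chi-square scale; returns ``(aic, bic)``."""
    if chi2 < 0 or q < 0 or sample_size < 1:
        raise ValueError("inputs must be nonnegative (sample_size >= 1)")
    return chi2 + 2 * q, chi2 + q * math.log(sample_size)


def default_model_grid(n_factors=(2, 3)) -> list:
    """The 12-model scale-invariant grid used for MTMM correlation data.

    For each number of factors: orthogonal/oblique common factors crossed
    with diagonal, banded (within-variable) and block-diagonal
    (within-occasion) specific-factor structures, all with free positive
    scaling D identified through a unit Psi diagonal and first rows of B
    and C fixed to one.
    """
    grid = []
    for S in n_factors:
        for psi in ("diagonal", "banded_within_variable", "block_within_occasion"):
            for phi in ("orthogonal", "oblique"):
                grid.append(
                    ModelSpec(
                        n_factors=S,
                        phi_structure=phi,
                        psi_structure=psi,
                        invariance="variant_b",
                        identification="first_row_unit",
                    )
                )
    return grid


_COLUMNS = [
    "n_factors", "phi_structure", "psi_structure", "F_hat", "chi_square",
    "df", "p_value", "aic", "bic", "n_parameters", "n_at_global",
    "not_rejected", "error",
]


def model_scan(
    S_mat: np.ndarray,
    sample_size: int,
    layout: ThreeWayLayout,
    specs,
    options: FitOptions = None,
    alpha: float = 0.05,
    warm_start: bool = True,
    warm_extra_starts: int = 5,
    return_fits: bool = False,
):
    """Fit every model of ``specs`` and tabulate the comparison.

    With ``warm_start=True`` (the estimation protocol for the correlated-
    specific-factor models), each model with non-diagonal Psi whose
    diagonal-Psi counterpart (same number of factors and Phi structure)
    appears earlier in the grid is started from that counterpart's best
    solution, plus ``warm_extra_starts`` random starts.  Rows whose fit
    raises are annotated in the ``error`` column rather than aborting the
    scan.

    Returns a :class:`pandas.DataFrame` in the order of ``specs`` (and,
    with ``return_fits=True``, also the list of per-row
    :class:`FitResult` objects, ``None`` for failed rows).
    """
    if not specs:
        raise ValueError("spec grid must be nonempty")
    base = options or FitOptions()
    diag_fits = {}
    rows, fits = [], []
    for spec in specs:
        opts = base
        if (
            warm_start
            and spec.psi_structure != "diagonal"
            and (spec.n_factors, spec.phi_structure) in diag_fits
        ):
            # warm-started runs are few but may track a long, flat valley:
            # give them a larger iteration budget than the random starts
            opts = replace(
                base,
                init=diag_fits[(spec.n_factors, spec.phi_structure)].params,
                n_starts=1 + warm_extra_starts,
                max_iter=max(base.max_iter, 1000),
            )
        row = {
            "n_factors": spec.n_factors,
            "phi_structure": spec.phi_structure,
            "psi_structure": spec.psi_structure,
        }
        try:
            res = fit(S_mat, sample_size, spec, layout, opts)
        except Exception as exc:  # annotated row, not a crash
            row.update({c: np.nan for c in _COLUMNS[3:-1]})
            row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            fits.append(None)
            continue
        if spec.psi_structure == "diagonal":
            diag_fits[(spec.n_factors, spec.phi_structure)] = res
        row.update(
            {
                "F_hat": res.F_hat,
                "chi_square": res.chi_square,
                "df": res.df,
                "p_value": res.p_value,
                "aic": res.aic,
                "bic": res.bic,
                "n_parameters": res.n_parameters,
                "n_at_global": res.n_at_global,
                "not_rejected": (
                    res.p_value is not None and res.p_value > alpha
                ),
                "error": None,
            }
        )
        rows.append(row)
        fits.append(res)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    if return_fits:
        return table, fits
    return table
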