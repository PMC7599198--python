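"""Reading and writing matrices, model configurations and fit reports.

Matrix files are plain CSV: a square block of numbers with an optional
header row of composite ``variable@occasion`` labels in composite-index
order (occasion-slowest).  Model configurations are flat YAML key/value
files; the parsed configuration is echoed bit-exactly into every report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DimensionError
from .model import ModelSpec
from .tensorops import ThreeWayLayout

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_model_config",
    "layout_to_dict",
    "fit_report_text",
    "file_sha256",
]


def write_matrix_csv(path, matrix: np.ndarray, layout: ThreeWayLayout = None):
    """Write a square matrix as CSV with composite labels as header."""
    matrix = np.asarray(matrix, dtype=float)
    cols = layout.composite_labels() if layout is not None else [
        f"x{i}" for i in range(matrix.shape[1])
    ]
    pd.DataFrame(matrix, columns=cols).to_csv(path, index=False, float_format="%.10g")


def read_matrix_csv(path):
    """Read a square matrix from CSV; returns ``(matrix, labels_or_None)``."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not np.issubdtype(first.dtypes.iloc[0], np.number)
    df = pd.read_csv(path, header=0 if has_header else None)
    matrix = df.to_numpy(dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DimensionError(
            f"matrix file {path} is not square: shape {matrix.shape}"
        )
    labels = list(df.columns) if has_header else None
    return matrix, labels


def read_model_config(path):
    """Parse a YAML model configuration.

    Recognized keys: ``n_factors``, ``phi_structure``, ``psi_structure``,
    ``invariance``, ``identification``, ``n_variables``, ``n_occasions``,
    ``variable_labels``, ``occasion_labels``, ``sample_size`` (optional).
    Returns ``(spec, layout, raw_dict)``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    spec = ModelSpec(
        n_factors=int(raw["n_factors"]),
        phi_structure=raw.get("phi_structure", "orthogonal"),
        psi_structure=raw.get("psi_structure", "diagonal"),
        invariance=raw.get("invariance", "none"),
        identification=raw.get("identification", "unit_column_norm"),
    )
    layout = ThreeWayLayout(
        n_variables=int(raw["n_variables"]),
        n_occasions=int(raw["n_occasions"]),
        variable_labels=tuple(raw["variable_labels"]) if "variable_labels" in raw else None,
        occasion_labels=tuple(raw["occasion_labels"]) if "occasion_labels" in raw else None,
    )
    return spec, layout, raw


def layout_to_dict(layout: ThreeWayLayout) -> dict:
    return {
        "n_variables": layout.n_variables,
        "n_occasions": layout.n_occasions,
        "variable_labels": list(layout.variable_labels),
        "occasion_labels": list(layout.occasion_labels),
    }


def file_sha256(path) -> str:
    """Content hash used to tie reports to their exact inputs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fmt(x, nd=4):
    if x is None:
        return "n/a"
    return f"{x:.{nd}f}"


def _matrix_block(name, M, row_labels, col_labels, se=None):
    lines = [name]
    width = 10
    lines.append(" " * 8 + "".join(f"{c:>{width}}" for c in col_labels))
    for i, rl in enumerate(row_labels):
        lines.append(
            f"{rl:>8}" + "".join(f"{M[i, j]:>{width}.4f}" for j in range(M.shape[1]))
        )
    return lines


def fit_report_text(result, uniqueness=None, extra=None) -> str:
    """Aligned plain-text report of a fit, stable across reruns."""
    spec, layout = result.spec, result.layout
    lines = ["structural Parafac fit report", "=" * 30, ""]
    lines.append("model configuration:")
    for k, v in spec.to_dict().items():
        lines.append(f"  {k}: {v}")
    for k, v in layout_to_dict(layout).items():
        lines.append(f"  {k}: {v}")
    if extra:
        for k, v in extra.items():
            lines.append(f"  {k}: {v}")
    lines += [
        "",
        "fit statistics:",
        f"  method: {result.method}",
        f"  sample size I: {result.sample_size}",
        f"  minimized discrepancy F: {_fmt(result.F_hat, 6)}",
        f"  chi-square: {_fmt(result.chi_square, 2)}",
        f"  df: {result.df if result.df is not None else 'n/a'}",
        f"  p-value: {_fmt(result.p_value, 4)}",
        f"  AIC: {_fmt(result.aic, 2)}",
        f"  BIC: {_fmt(result.bic, 2)}",
        f"  free parameters: {result.n_parameters}",
        "",
        "multi-start diagnostics:",
        f"  starts: {result.n_starts}",
        f"  converged: {result.n_converged}",
        f"  at global optimum (4 decimals): {result.n_at_global}",
        f"  best start index: {result.best_start}",
        "",
    ]
    p = result.params
    flab = [f"F{s + 1}" for s in range(p.n_factors)]
    lines += _matrix_block("variable loadings B:", p.B, layout.variable_labels, flab)
    lines += [""]
    lines += _matrix_block("occasion loadings C:", p.C, layout.occasion_labels, flab)
    lines += [""]
    lines += _matrix_block("factor covariance Phi:", p.Phi, flab, flab)
    lines += [""]
    clab = layout.composite_labels()
    lines.append("scaling D (diagonal):")
    for lab, d in zip(clab, p.D):
        lines.append(f"  {lab:>8}: {d:.4f}")
    lines += [""]
    lines += _matrix_block("specific-factor covariance Psi:", p.Psi, clab, clab)
    if result.standard_errors:
        lines += ["", "standard errors (natural scale):"]
        for name, se in result.standard_errors.items():
            lines.append(f"  {name}: {se:.4f}")
    if uniqueness is not None:
        lines += ["", "uniqueness conditions:"]
        for k, v in uniqueness.to_dict().items():
            lines.append(f"  {k}: {v}")
    lines.append("")
    return "\n".join(lines)
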