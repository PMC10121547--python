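"""CSV ingestion and report assembly for the command-line interface."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimator import FitResult
from .model import Dataset

__all__ = ["read_dataset", "coefficient_report", "trace_frame"]


def read_dataset(path, response_column: str, scale: bool = True) -> Dataset:
    """Read a header CSV into a :class:`Dataset`.

    The named response column becomes ``y``; every other column is a
    predictor, scaled to unit sample standard deviation (the divisors are
    recorded in ``scale_factors``).  Missing values, non-numeric columns and
    constant predictors are explicit errors.
    """
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise ValueError(
            f"response column {response_column!r} not found; available: {list(df.columns)}"
        )
    if df.isna().any().any():
        bad_rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows {bad_rows}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric column(s): {non_numeric}")
    y = df[response_column].to_numpy(dtype=float)
    pred = df.drop(columns=[response_column])
    sd = pred.to_numpy().std(axis=0, ddof=1) if pred.shape[1] else np.array([])
    const = [c for c, s in zip(pred.columns, sd) if s <= 0]
    if const:
        raise ValueError(f"constant predictor column(s): {const}")
    return Dataset.from_arrays(y, pred.to_numpy(dtype=float), scale=scale, names=list(pred.columns))


def coefficient_report(result: FitResult, data: Dataset, delta_bics: dict | None = None) -> pd.DataFrame:
    """Tidy coefficient table on both the scaled and original predictor scales.

    ``delta_bics`` optionally maps ``(component, index)`` to the BIC change
    from dropping that coefficient; reported only for active coefficients.
    """
    p1 = data.X.shape[1]
    se = result.se()
    unscale = np.concatenate([[1.0], data.scale_factors])
    rows = []
    for comp, coefs, offset, active in (
        ("location", result.params_sparse.beta, 0, set(result.active_beta.tolist())),
        ("dispersion", result.params_sparse.alpha, p1, set(result.active_alpha.tolist())),
    ):
        for j in range(p1):
            is_active = j in active
            est = coefs[j]
            s = se[offset + j] if is_active else np.nan
            row = {
                "name": data.names[j],
                "component": comp,
                "estimate_scaled": est,
                "estimate_original": est / unscale[j],
                "se_original": s / unscale[j] if is_active else np.nan,
                "ci_lower": (est - 1.96 * s) / unscale[j] if is_active else np.nan,
                "ci_upper": (est + 1.96 * s) / unscale[j] if is_active else np.nan,
                "active": is_active,
            }
            if delta_bics is not None:
                row["delta_bic"] = delta_bics.get((comp, j), np.nan) if (is_active and j > 0) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def trace_frame(result: FitResult, names: list[str]) -> pd.DataFrame:
    """Per-telescope-step trace: eps, iterations, objective and all coefficients."""
    rows = []
    for step in result.trace:
        row = {
            "eps": step.eps,
            "n_iter": step.n_iter,
            "converged": step.converged,
            "objective": step.objective,
            "n_active": int(np.sum(np.abs(step.beta[1:]) > result.zero_tol))
            + int(np.sum(np.abs(step.alpha[1:]) > result.zero_tol)),
        }
        for j, nm in enumerate(names):
            row[f"beta_{nm}"] = step.beta[j]
            row[f"alpha_{nm}"] = step.alpha[j]
        rows.append(row)
    return pd.DataFrame(rows)
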