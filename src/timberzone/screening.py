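"""Multicollinearity screening by iterative variance-inflation-factor removal.

VIF(x_j) = 1 / (1 - R^2) from the ordinary least-squares regression of x_j
on all other predictors plus an intercept.  The iterative screen removes the
worst offender one variable at a time until every survivor's VIF sits below
the threshold (default 10), mirroring standard practice for climate
predictor sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class DegenerateTableError(ValueError):
    """Predictor table unusable for VIF (too few rows/columns or rank defect)."""


def _validate(table: pd.DataFrame) -> None:
    if table.shape[1] < 2:
        raise DegenerateTableError("VIF needs at least 2 predictor columns")
    if table.shape[0] <= table.shape[1] + 1:
        raise DegenerateTableError(
            f"VIF needs more than p + 1 = {table.shape[1] + 1} rows, "
            f"got {table.shape[0]}")
    if table.isna().any().any():
        raise DegenerateTableError("predictor table contains missing values")


def compute_vif(table: pd.DataFrame, target: str) -> float:
    """VIF of ``target`` regressed on every other column plus intercept.

    Perfect collinearity (R^2 -> 1) is reported as ``inf``.
    """
    _validate(table)
    if target not in table.columns:
        raise KeyError(f"target column {target!r} not in table")
    y = table[target].to_numpy(dtype=float)
    X = table.drop(columns=[target]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return float("inf")  # constant target is perfectly 'explained'
    r2 = 1.0 - float((resid ** 2).sum()) / sst
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return max(1.0, 1.0 / (1.0 - r2))


def iterative_vif_screen(
    table: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[tuple[str, float]]]:
    """Remove the highest-VIF column until all VIFs fall below ``threshold``.

    Ties at the maximum go to the earliest column in input order; removed
    variables are never re-admitted.  Returns the retained column names and
    an ordered removal log of ``(column, VIF at removal)``.
    """
    if threshold <= 1.0:
        raise ValueError("VIF threshold must exceed 1")
    _validate(table)
    work = table.copy()
    removal_log: list[tuple[str, float]] = []
    while work.shape[1] >= 2:
        vifs = np.array([compute_vif(work, c) for c in work.columns])
        worst = int(np.argmax(vifs))  # argmax -> earliest column on ties
        if vifs[worst] < threshold:
            break
        removal_log.append((work.columns[worst], float(vifs[worst])))
        work = work.drop(columns=[work.columns[worst]])
    return list(work.columns), removal_log
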