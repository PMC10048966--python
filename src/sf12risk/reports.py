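"""Tabular report generators for the reducer comparison.

The cumulative columns of the per-component statistics table are always
computed from the per-component values handed in — they are never stored or
accepted independently — so the table is internally consistent by
construction even when the inputs come from an external source.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sf12risk.reducers import ReducerModel, variance_explained_k

__all__ = ["component_table", "method_comparison_table", "model_component_table"]


def component_table(
    eigenvalues: Sequence[float],
    pct_variance: Sequence[float] | None = None,
    *,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-component eigenvalue statistics with cumulative columns.

    Parameters
    ----------
    eigenvalues :
        Per-component eigenvalues (variance along each axis).
    pct_variance :
        Per-component percent of total variance.  When omitted it is derived
        from the eigenvalues (100·λᵢ/Σλ); passing it explicitly allows
        tabulating externally reported per-component percentages, with the
        cumulative column still computed here.
    """
    eig = np.asarray(list(eigenvalues), dtype=float)
    if eig.ndim != 1 or eig.size == 0:
        raise ValueError("eigenvalues must be a non-empty 1-D sequence")
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be non-negative")
    if pct_variance is None:
        total = eig.sum()
        if total <= 0:
            raise ValueError("total eigenvalue mass must be positive")
        pct = 100.0 * eig / total
    else:
        pct = np.asarray(list(pct_variance), dtype=float)
        if pct.shape != eig.shape:
            raise ValueError("pct_variance must match eigenvalues in length")
    df = pd.DataFrame(
        {
            "component": np.arange(1, eig.size + 1),
            "eigenvalue": np.round(eig, decimals),
            "pct_variance": np.round(pct, decimals),
            "cumulative_eigenvalue": np.round(np.cumsum(eig), decimals),
            "cumulative_pct": np.round(np.cumsum(pct), decimals),
        }
    )
    return df


def model_component_table(model: ReducerModel, *, decimals: int = 2) -> pd.DataFrame:
    """Component table of a fitted reducer (eigenvalue analogues + fractions)."""
    return component_table(
        model.axis_variances,
        100.0 * model.variance_explained,
        decimals=decimals,
    )


def method_comparison_table(
    models: Mapping[str, ReducerModel], k: int = 4, *, decimals: int = 2
) -> pd.DataFrame:
    """Method × percent-of-total-variance-explained comparison at fixed k."""
    rows = []
    for name, model in models.items():
        rows.append(
            {
                "method": name,
                "pct_variance_explained": round(variance_explained_k(model, k), decimals),
                "k": k,
            }
        )
    return pd.DataFrame(rows)
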