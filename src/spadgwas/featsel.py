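"""Vegetation-index feature selection for the SPAD inversion model.

Two rankings are combined per (env, treatment, stage) cell: impurity-based
random-forest importance of each index for SPAD, and the pairwise-complete
Pearson correlation of each index with SPAD. The selected feature set is the
union of the top-k indices by importance and the single index with the
largest |r| — making explicit the common practice of picking "top importance
plus strongest correlate".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .vegindex import INDEX_NAMES


@dataclass
class SelectionResult:
    """Ordered selected index names with provenance per name."""

    indices: list[str]
    provenance: dict[str, str]  # name -> "importance-rank" | "correlation-max"


def rf_importance(
    vi: pd.DataFrame,
    spad: np.ndarray | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    index_names=INDEX_NAMES,
) -> pd.Series:
    """Impurity-based random-forest importances, normalized to sum to 1.

    Rows with any missing feature or missing response are dropped; at least
    20 complete pairs are required. The response must vary.
    """
    y = np.asarray(spad, dtype=float)
    cols = [c for c in index_names if c in vi.columns]
    X = vi[cols].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    if len(y) < 20:
        raise ValueError(f"need >= 20 paired observations, got {len(y)}")
    if np.ptp(y) == 0:
        raise ValueError("constant SPAD vector: no variance to explain")
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X, y)
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=cols, name="importance")


def correlate_with_spad(
    vi: pd.DataFrame, spad: np.ndarray | pd.Series, index_names=INDEX_NAMES
) -> pd.Series:
    """Pairwise-complete Pearson r of each index with SPAD.

    Indices with fewer than 3 valid pairs, or zero variance in either
    member, are reported as NaN.
    """
    y = np.asarray(spad, dtype=float)
    out = {}
    for name in index_names:
        if name not in vi.columns:
            continue
        x = vi[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            out[name] = np.nan
            continue
        xo, yo = x[ok], y[ok]
        sx, sy = xo.std(), yo.std()
        if sx == 0 or sy == 0:
            out[name] = np.nan
            continue
        out[name] = float(((xo - xo.mean()) * (yo - yo.mean())).mean() / (sx * sy))
    return pd.Series(out, name="pearson_r")


def importance_table(
    vi: pd.DataFrame,
    spad: np.ndarray | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Importance and correlation side by side for one analysis cell."""
    imp = rf_importance(vi, spad, n_trees=n_trees, seed=seed)
    r = correlate_with_spad(vi, spad)
    return pd.DataFrame({"importance": imp, "pearson_r": r})


def select_indices(importance: pd.DataFrame, k_top: int = 5) -> SelectionResult:
    """Union of top-``k_top`` by importance and argmax |Pearson r|.

    Order: descending importance, then the correlation pick if it is not
    already present. Ties are broken by alphabetical index name.
    """
    if importance.empty:
        raise ValueError("empty importance table")
    tab = importance.copy()
    tab["_name"] = tab.index
    by_imp = tab.sort_values(
        ["importance", "_name"], ascending=[False, True]
    ).index.tolist()
    top = by_imp[:k_top]
    prov = {name: "importance-rank" for name in top}
    r = tab["pearson_r"].abs()
    if r.notna().any():
        rmax = r.max()
        best_r = sorted(r[r == rmax].index)[0]
        if best_r not in prov:
            prov[best_r] = "correlation-max"
            top = top + [best_r]
    return SelectionResult(indices=top, provenance=prov)
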