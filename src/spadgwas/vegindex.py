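"""The 18 five-band vegetation indices.

Band arguments are reflectance fractions: blue, green, red, red edge
(``rededge``) and near infrared (``nir``). Indices with a vanishing
denominator are flagged invalid (NaN + flag) rather than silently zeroed.

CARI as commonly printed, ``(Re - R)/0.2*(Re + R)``, is precedence-ambiguous;
the default here reads the 0.2 as part of the denominator,
``(Re - R) / (0.2*(Re + R))``, which keeps the index bounded; the literal
left-to-right reading ``((Re - R)/0.2) * (Re + R)`` is available via
``cari_literal=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INDEX_NAMES = (
    "NDVI",
    "GNDVI",
    "NGBDI",
    "NGRDI",
    "RERDVI",
    "SAVI",
    "GOSAVI",
    "REOSAVI",
    "OSAVI",
    "RVI",
    "DVI",
    "GRVI",
    "EXG",
    "TVI",
    "CARI",
    "VARIgreen",
    "VARIred",
    "EVI",
)

_EPS = 0.0  # denominators are flagged on exact zero only


def _ratio(num, den):
    den = np.asarray(den, dtype=float)
    num = np.asarray(num, dtype=float)
    bad = den == 0
    out = np.divide(num, np.where(bad, 1.0, den))
    return np.where(bad, np.nan, out)


def compute_vi(name, blue, green, red, rededge, nir, cari_literal: bool = False):
    """Evaluate one named vegetation index; NaN where the denominator is 0.

    Accepts scalars or aligned arrays. Raises on an unknown index name.
    """
    b, g, r = (np.asarray(x, dtype=float) for x in (blue, green, red))
    re, n = np.asarray(rededge, dtype=float), np.asarray(nir, dtype=float)
    scalar = all(np.ndim(x) == 0 for x in (b, g, r, re, n))
    if name == "NDVI":
        out = _ratio(n - r, n + r)
    elif name == "GNDVI":
        out = _ratio(n - g, n + g)
    elif name == "NGBDI":
        out = _ratio(g - b, g + b)
    elif name == "NGRDI":
        out = _ratio(g - r, g + r)
    elif name == "RERDVI":
        out = _ratio(n - re, n + re)
    elif name == "SAVI":
        out = 2.5 * _ratio(n - r, n + r + 0.5)
    elif name == "GOSAVI":
        out = 1.16 * _ratio(n - g, n + g + 0.16)
    elif name == "REOSAVI":
        out = 1.16 * _ratio(n - r, n + r + 0.16)
    elif name == "OSAVI":
        out = _ratio(n - r, n + r + 0.16)
    elif name == "RVI":
        out = _ratio(n, r)
    elif name == "DVI":
        out = n - r
    elif name == "GRVI":
        out = _ratio(n, g)
    elif name == "EXG":
        out = 2 * g - r - b
    elif name == "TVI":
        out = 0.5 * (120 * (n - g) - 200 * (r - g))
    elif name == "CARI":
        if cari_literal:
            out = ((re - r) / 0.2) * (re + r)
        else:
            out = _ratio(re - r, 0.2 * (re + r))
    elif name == "VARIgreen":
        out = _ratio(g - r, g + r - b)
    elif name == "VARIred":
        out = _ratio(re - 1.7 * r + 0.7 * b, re + 2.3 * r - 1.3 * b)
    elif name == "EVI":
        out = 2.5 * _ratio(n - r, n + 6 * r - 7.5 * b + 1)
    else:
        raise ValueError(
            f"unknown vegetation index {name!r}; valid names: "
            + ", ".join(INDEX_NAMES)
        )
    return float(out) if scalar else out


def compute_all_vi(
    plots: pd.DataFrame, cari_literal: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All 18 indices for a table of plot reflectances.

    ``plots`` must carry ``r_blue, r_green, r_red, r_rededge, r_nir``.
    Returns ``(values, valid)``: the key columns plus one column per index,
    and an aligned boolean validity mask (False where a denominator was 0;
    those values are NaN, never fabricated zeros).
    """
    if plots.empty:
        raise ValueError("no plot rows")
    needed = ["r_blue", "r_green", "r_red", "r_rededge", "r_nir"]
    missing = [c for c in needed if c not in plots.columns]
    if missing:
        raise ValueError(f"missing band columns: {missing}")
    key_cols = [c for c in plots.columns if not c.startswith("r_")]
    args = {c.removeprefix("r_"): plots[c].to_numpy(dtype=float) for c in needed}
    values = plots[key_cols].copy()
    valid = plots[key_cols].copy()
    for name in INDEX_NAMES:
        v = compute_vi(name, cari_literal=cari_literal, **args)
        values[name] = v
        valid[name] = np.isfinite(v)
    return values, valid
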