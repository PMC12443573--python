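"""Radiometric calibration, zonal plot reflectance extraction, stage dynamics.

Calibration is single-point against a whiteboard reference panel
(DN 65000 at 99.8% reflectance): reflectance = DN x 0.998 / 65000. Per-plot
band reflectance is the mean of calibrated values over pixels whose centers
fall inside the plot polygon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .synthio import BANDS, SyntheticScene

DEFAULT_WHITEBOARD_DN = 65000.0
DEFAULT_WHITEBOARD_REFLECTANCE = 0.998


def dn_to_reflectance(
    dn,
    whiteboard_dn: float = DEFAULT_WHITEBOARD_DN,
    whiteboard_refl: float = DEFAULT_WHITEBOARD_REFLECTANCE,
):
    """Convert raw digital numbers to reflectance fractions.

    Linear through the origin: ``dn * whiteboard_refl / whiteboard_dn``.
    """
    if whiteboard_dn <= 0:
        raise ValueError("whiteboard_dn must be positive")
    arr = np.asarray(dn, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative DN values are not valid sensor output")
    out = arr * (whiteboard_refl / whiteboard_dn)
    return float(out) if np.isscalar(dn) else out


def _plot_polygons(plots: pd.DataFrame) -> list[Polygon]:
    """Build shapely polygons from a layout table.

    Accepts either rectangle columns (x0, y0, x1, y1) or a WKT ``polygon``
    column. Coordinates are in pixel units, x = column, y = row, with the
    pixel at (row i, col j) having center (j + 0.5, i + 0.5).
    """
    if "polygon" in plots.columns:
        return [shapely.from_wkt(w) for w in plots["polygon"]]
    return [
        shapely.box(x0, y0, x1, y1)
        for x0, y0, x1, y1 in plots[["x0", "y0", "x1", "y1"]].to_numpy()
    ]


def extract_plot_reflectance(
    scene,
    plots: pd.DataFrame | None = None,
    whiteboard_dn: float | None = None,
    whiteboard_refl: float = DEFAULT_WHITEBOARD_REFLECTANCE,
) -> pd.DataFrame:
    """Mean calibrated reflectance per plot and band.

    ``scene`` is a :class:`~spadgwas.synthio.SyntheticScene` or a mapping of
    band name to 2-D DN array. When ``whiteboard_dn`` is None and the scene
    carries a whiteboard region, the calibration reference is the measured
    mean DN of that region; otherwise the nominal 65000 is used.

    Returns one row per plot with the plot key columns, ``r_<band>``
    reflectances and the contributing ``n_pixels``.
    """
    if isinstance(scene, SyntheticScene):
        bands = scene.bands
        if plots is None:
            plots = scene.plots
        if whiteboard_dn is None:
            r0, r1, c0, c1 = scene.whiteboard
            whiteboard_dn = float(
                next(iter(bands.values()))[r0:r1, c0:c1].mean()
            )
        key_cols = dict(zip(("env", "treatment", "stage"), scene.key))
    else:
        bands = scene
        key_cols = {}
        if whiteboard_dn is None:
            whiteboard_dn = DEFAULT_WHITEBOARD_DN
    if plots is None:
        raise ValueError("a plot layout table is required")

    ref = next(iter(bands.values()))
    h, w = ref.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = xx + 0.5, yy + 0.5

    polygons = _plot_polygons(plots)
    rows = []
    for (_, plot), poly in zip(plots.iterrows(), polygons):
        minx, miny, maxx, maxy = poly.bounds
        j0, j1 = max(int(minx) - 1, 0), min(int(maxx) + 2, w)
        i0, i1 = max(int(miny) - 1, 0), min(int(maxy) + 2, h)
        inside = shapely.contains_xy(
            poly, cx[i0:i1, j0:j1].ravel(), cy[i0:i1, j0:j1].ravel()
        ).reshape(i1 - i0, j1 - j0)
        n_px = int(inside.sum())
        if n_px == 0:
            raise ValueError(
                f"plot {plot.get('plot_id', '?')} contains no pixel centers"
            )
        rec = {
            "plot_id": plot.get("plot_id"),
            "genotype": plot.get("genotype"),
            **key_cols,
            "n_pixels": n_px,
        }
        for name in bands:
            dn = bands[name][i0:i1, j0:j1][inside]
            rec[f"r_{name}"] = float(
                dn_to_reflectance(dn, whiteboard_dn, whiteboard_refl).mean()
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    for col in ("env", "treatment", "stage"):
        if col in plots.columns and col not in out.columns:
            out[col] = plots[col].to_numpy()
    return out


def band_stage_summary(plots: pd.DataFrame) -> pd.DataFrame:
    """Mean reflectance (percent) per (treatment, band, stage).

    The mean is taken over plot-level reflectances (the cultivar is the unit
    of analysis). Missing (treatment, stage) cells are omitted with a
    warning. Output is long format: treatment, band, stage, reflectance_pct.
    """
    if plots.empty:
        raise ValueError("no plot reflectance rows to summarize")
    band_cols = [f"r_{b}" for b in BANDS if f"r_{b}" in plots.columns]
    long = plots.melt(
        id_vars=["treatment", "stage"],
        value_vars=band_cols,
        var_name="band",
        value_name="reflectance",
    )
    long["band"] = long["band"].str.removeprefix("r_")
    out = (
        long.groupby(["treatment", "band", "stage"], as_index=False, observed=True)[
            "reflectance"
        ]
        .mean()
        .rename(columns={"reflectance": "reflectance_pct"})
    )
    out["reflectance_pct"] *= 100.0
    expected = {
        (t, s)
        for t in plots["treatment"].unique()
        for s in ("HS", "FL", "GF")
    }
    present = set(zip(out["treatment"], out["stage"]))
    for t, s in sorted(expected - present):
        warnings.warn(f"no plots for treatment={t}, stage={s}; row omitted")
    return out


def percent_decrease(prev: float, curr: float, ndigits: int = 2) -> float:
    """Relative decrease 100*(prev - curr)/prev, rounded for reporting."""
    if prev <= 0:
        raise ValueError("percent_decrease requires prev > 0")
    return round(100.0 * (prev - curr) / prev, ndigits)


def stage_decreases(summary: pd.DataFrame) -> pd.DataFrame:
    """Stage-over-stage percent decreases per (treatment, band).

    Consumes the output of :func:`band_stage_summary` and reports the
    HS->FL and FL->GF relative declines, mirroring how canopy reflectance
    dynamics are tabulated.
    """
    wide = summary.pivot_table(
        index=["treatment", "band"],
        columns="stage",
        values="reflectance_pct",
        observed=True,
    )
    rows = []
    for (trt, band), r in wide.iterrows():
        for prev_s, curr_s in (("HS", "FL"), ("FL", "GF")):
            if pd.notna(r.get(prev_s)) and pd.notna(r.get(curr_s)):
                rows.append(
                    {
                        "treatment": trt,
                        "band": band,
                        "transition": f"{prev_s}->{curr_s}",
                        "decrease_pct": percent_decrease(r[prev_s], r[curr_s]),
                    }
                )
    return pd.DataFrame(rows)
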