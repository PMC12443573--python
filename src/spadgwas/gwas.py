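"""Mixed-linear-model Q+K genome scan, LD-decay locus merging and summaries.

The association model per marker j is

    y = mu + Q v + x_j beta_j + u + e,   u ~ (0, s_u^2 K),  e ~ (0, s_e^2 I)

with K the VanRaden centered genomic relationship matrix and Q principal
components of the scaled dosage matrix standing in for population-structure
covariates. Variance components are estimated once on the null model by
REML through the spectral decomposition of K (the P3D/EMMAX approximation),
then every marker is tested by generalized least squares with a Wald t-test;
exact per-marker REML is available via ``method="exact"``. Marker R² is the
partial R² of the marker in the whitened model.

Significant markers (strictly P < 0.001 by default) are merged into loci by
single-linkage chaining within the LD decay distance; measured- and
predicted-trait loci are paired greedily by representative-position distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_LD_DECAY_BP = 5_000_000


# ---------------------------------------------------------------------------
# genotype handling


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Wheat chromosome ordering: (group number, subgenome letter)."""
    s = str(label)
    digits = "".join(ch for ch in s if ch.isdigit())
    letters = "".join(ch for ch in s if ch.isalpha())
    return (int(digits) if digits else 0, letters)


def impute_and_filter(
    G: np.ndarray, snp_map: pd.DataFrame, maf_floor: float = 0.05
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Mean-impute missing dosages per marker, then apply the MAF filter.

    Missing values may be NaN or negative sentinels. Returns the filtered
    matrix, map, and a small log dict (missing rate, markers dropped).
    """
    X = np.asarray(G, dtype=float).copy()
    X[X < 0] = np.nan
    miss = ~np.isfinite(X)
    n_missing = int(miss.sum())
    if n_missing:
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_floor
    log = {
        "missing_rate": n_missing / X.size,
        "n_dropped_maf": int((~keep).sum()),
    }
    return X[:, keep], snp_map.loc[keep].reset_index(drop=True), log


def compute_kinship(G: np.ndarray) -> np.ndarray:
    """VanRaden centered genomic relationship matrix.

    K = Z Z' / (2 * sum_j p_j (1 - p_j)), Z the column-centered dosage
    matrix. Requires at least two polymorphic markers.
    """
    X = np.asarray(G, dtype=float)
    p = X.mean(axis=0) / 2.0
    poly = (X.var(axis=0) > 0) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("kinship needs >= 2 polymorphic markers")
    Xp = X[:, poly]
    pp = p[poly]
    Z = Xp - 2.0 * pp
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    return (Z @ Z.T) / denom


def compute_q(G: np.ndarray, q: int = 3) -> np.ndarray:
    """Top-q principal components of the centered/scaled dosage matrix.

    Columns are centered and mutually orthogonal; the sign of each PC is
    fixed (largest-magnitude loading positive) for determinism.
    """
    X = np.asarray(G, dtype=float)
    n = X.shape[0]
    if q >= n:
        raise ValueError(f"q={q} must be < n={n}")
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :q] * S[:q]
    for k in range(q):
        i = np.argmax(np.abs(pcs[:, k]))
        if pcs[i, k] < 0:
            pcs[:, k] = -pcs[:, k]
    return pcs - pcs.mean(axis=0)


# ---------------------------------------------------------------------------
# REML machinery (EMMA-style spectral form)


def _reml_neg_loglik(log_delta, yt, Xt, s):
    delta = np.exp(log_delta)
    d = s + delta
    w = 1.0 / d
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r * w))
    n, p = Xt.shape
    df = n - p
    sign, logdet_A = np.linalg.slogdet(A)
    _, logdet_XX = np.linalg.slogdet(Xt.T @ Xt)
    ll = -0.5 * (
        df * np.log(2 * np.pi * rss / df)
        + df
        + np.sum(np.log(d))
        + logdet_A
        - logdet_XX
    )
    return -ll


def _fit_null_reml(yt, Xt, s) -> tuple[float, float, float]:
    """REML variance ratio delta = s_e^2/s_u^2 on the rotated null model.

    Grid search over log delta in [-10, 10] refined by bounded Brent.
    Returns (delta, sigma_u2, sigma_e2).
    """
    grid = np.linspace(-10.0, 10.0, 41)
    vals = [_reml_neg_loglik(g, yt, Xt, s) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(yt, Xt, s), method="bounded"
    )
    delta = float(np.exp(res.x))
    d = s + delta
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ XtW, XtW.T @ yt)
    r = yt - Xt @ beta
    n, p = Xt.shape
    sigma_u2 = float(np.sum(r * r * w) / (n - p))
    return delta, sigma_u2, sigma_u2 * delta


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Drop trailing columns until X has full column rank (with warning)."""
    while X.shape[1] > 1 and np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("dropping collinear structure covariate column")
        X = X[:, :-1]
    return X


def mlm_scan(
    y: np.ndarray,
    G: np.ndarray,
    snp_map: pd.DataFrame,
    K: np.ndarray | None = None,
    Q: np.ndarray | None = None,
    method: str = "p3d",
) -> pd.DataFrame:
    """Q+K mixed-model association scan.

    Returns one row per marker: marker, chrom, pos, beta, se, p,
    marker_r2 (partial R² in the whitened model) and marker_r2_pheno
    (beta² var(x_j) / var(y), the share of raw phenotypic variance).
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    X = np.asarray(G, dtype=float)[ok]
    y = y[ok]
    n, m = X.shape
    if len(snp_map) != m:
        raise ValueError("snp_map length does not match marker count")

    if K is None:
        K = compute_kinship(X)
    K = np.asarray(K, dtype=float)[np.ix_(ok.nonzero()[0], ok.nonzero()[0])] if K.shape[0] != n else K
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6:
        s = s + (1e-6 - s.min())  # jitter
        if s.min() < -1e-8:
            raise ValueError("kinship matrix is not PSD even after jitter")
    s = np.clip(s, 0.0, None)

    X0 = np.ones((n, 1))
    if Q is not None and np.size(Q):
        Qm = np.atleast_2d(np.asarray(Q, dtype=float))
        if Qm.shape[0] != n:
            Qm = Qm.T
        X0 = _drop_collinear(np.hstack([X0, Qm]))

    yt = U.T @ y
    X0t = U.T @ X0
    Gt = U.T @ X

    delta, sigma_u2, sigma_e2 = _fit_null_reml(yt, X0t, s)

    if method == "exact":
        return _scan_exact(yt, X0t, Gt, s, snp_map, y, X)
    if method != "p3d":
        raise ValueError(f"unknown method {method!r}")

    w = 1.0 / (s + delta)
    sw = np.sqrt(w)
    ys = yt * sw
    X0s = X0t * sw[:, None]
    Gs = Gt * sw[:, None]

    # Frisch-Waugh-Lovell: residualize on the whitened null design
    Qx, _ = np.linalg.qr(X0s)
    yr = ys - Qx @ (Qx.T @ ys)
    Gr = Gs - Qx @ (Qx.T @ Gs)

    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    sse0 = float(yr @ yr)
    p_cov = X0s.shape[1]
    df = n - p_cov - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    safe_gg = np.where(gg > 1e-12, gg, np.nan)
    beta = gy / safe_gg
    sse1 = sse0 - beta**2 * safe_gg
    sse1 = np.clip(sse1, 0.0, None)
    sigma2 = sse1 / df
    se = np.sqrt(sigma2 / safe_gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    r2 = np.where(sse0 > 0, (sse0 - sse1) / sse0, np.nan)

    mono = ~np.isfinite(safe_gg)
    pvals = np.where(mono, 1.0, pvals)
    beta = np.where(mono, 0.0, beta)
    r2 = np.where(mono, 0.0, r2)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    var_y = y.var()
    var_x = X.var(axis=0)
    r2_pheno = np.where(var_y > 0, beta**2 * var_x / var_y, np.nan)

    out = snp_map.reset_index(drop=True).copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pvals
    out["marker_r2"] = r2
    out["marker_r2_pheno"] = r2_pheno
    out.attrs["delta"] = delta
    out.attrs["sigma_u2"] = sigma_u2
    out.attrs["sigma_e2"] = sigma_e2
    return out


def _scan_exact(yt, X0t, Gt, s, snp_map, y_raw, X_raw) -> pd.DataFrame:
    """Per-marker REML (slow; for small panels and cross-checks)."""
    n = yt.shape[0]
    rows = []
    for j in range(Gt.shape[1]):
        Xt = np.hstack([X0t, Gt[:, [j]]])
        if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
            rows.append((0.0, np.nan, 1.0, 0.0))
            continue
        delta, _, _ = _fit_null_reml(yt, Xt, s)
        w = 1.0 / (s + delta)
        sw = np.sqrt(w)
        ys, Xs = yt * sw, Xt * sw[:, None]
        coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        r = ys - Xs @ coef
        df = n - Xs.shape[1]
        sigma2 = float(r @ r) / df
        XtX_inv = np.linalg.inv(Xs.T @ Xs)
        se = np.sqrt(sigma2 * XtX_inv[-1, -1])
        t = coef[-1] / se
        p = float(2 * stats.t.sf(abs(t), df))
        # partial R2 vs the null at this delta
        Q0, _ = np.linalg.qr(X0t * sw[:, None])
        yr = ys - Q0 @ (Q0.T @ ys)
        sse0 = float(yr @ yr)
        sse1 = float(r @ r)
        r2 = (sse0 - sse1) / sse0 if sse0 > 0 else np.nan
        rows.append((float(coef[-1]), float(se), p, r2))
    out = snp_map.reset_index(drop=True).copy()
    out[["beta", "se", "p", "marker_r2"]] = pd.DataFrame(rows)
    var_y = y_raw.var()
    out["marker_r2_pheno"] = out["beta"] ** 2 * X_raw.var(axis=0) / var_y
    return out


def filter_significant(
    results: pd.DataFrame, threshold: float = DEFAULT_P_THRESHOLD
) -> pd.DataFrame:
    """Markers with strictly P < threshold (P = threshold is excluded)."""
    if results.empty:
        raise ValueError("empty association results")
    return results[results["p"] < threshold].reset_index(drop=True)


def lambda_gc(pvalues) -> float:
    """Genomic-control inflation factor from two-sided P-values."""
    chi2 = stats.chi2.isf(np.asarray(pvalues, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# LD decay


@dataclass
class LDDecayResult:
    distance: float  # bp
    crossed: bool  # False when the curve never falls below the threshold
    threshold: float
    curve: pd.DataFrame = field(repr=False, default=None)

    def __float__(self) -> float:
        return float(self.distance)


def estimate_ld_decay(
    G: np.ndarray,
    snp_map: pd.DataFrame,
    n_bins: int = 50,
    smooth_window: int = 3,
    min_pairs: int = 100,
    default: float = DEFAULT_LD_DECAY_BP,
) -> LDDecayResult:
    """LD decay distance from binned intra-chromosomal r² versus distance.

    Pairwise marker r² within chromosomes is binned by distance (equal-width
    bins), bin means are smoothed by a centered rolling mean, and the decay
    distance is the center of the first bin where the smoothed curve falls
    below max(0.1, background r²), background being the mean of the
    upper-quartile-distance bins. Deterministic. Falls back to ``default``
    (with a warning) when fewer than ``min_pairs`` pairs exist.
    """
    X = np.asarray(G, dtype=float)
    dists, r2s = [], []
    for chrom, grp in snp_map.groupby("chrom", observed=True):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            continue
        pos = grp["pos"].to_numpy(dtype=float)
        sub = X[:, idx]
        sd = sub.std(axis=0)
        keep = sd > 0
        sub, pos = sub[:, keep], pos[keep]
        if sub.shape[1] < 2:
            continue
        C = np.corrcoef(sub.T)
        iu = np.triu_indices(sub.shape[1], k=1)
        dists.append(np.abs(pos[iu[1]] - pos[iu[0]]))
        r2s.append(C[iu] ** 2)
    if not dists or sum(d.size for d in dists) < min_pairs:
        warnings.warn(
            f"too few intra-chromosomal pairs; using default decay {default} bp"
        )
        return LDDecayResult(float(default), False, np.nan, None)
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)

    edges = np.linspace(0.0, dist.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    smoothed = (
        pd.Series(means)
        .rolling(smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    far = counts[3 * n_bins // 4 :].sum()
    background = (
        np.nansum(sums[3 * n_bins // 4 :]) / far if far > 0 else np.nanmean(r2)
    )
    threshold = max(0.1, float(background))
    curve = pd.DataFrame(
        {"distance": centers, "mean_r2": means, "smoothed_r2": smoothed, "n": counts}
    )
    below = np.flatnonzero((smoothed < threshold - 1e-6) & (counts > 0))
    if below.size == 0:
        return LDDecayResult(float(dist.max()), False, threshold, curve)
    return LDDecayResult(float(centers[below[0]]), True, threshold, curve)


# ---------------------------------------------------------------------------
# locus merging, overlap, summaries


def merge_loci(
    significant: pd.DataFrame,
    decay_distance: float,
    meta_cols: tuple[str, ...] = ("source", "env", "treatment", "stage"),
) -> pd.DataFrame:
    """Single-linkage chaining of significant markers into loci.

    Markers on the same chromosome join one cluster when within
    ``decay_distance`` of any member (for sorted positions this is
    consecutive-gap chaining). The representative is the member with the
    smallest P (ties: smaller bp). Empty input yields an empty table.
    """
    decay_distance = float(decay_distance)
    if decay_distance <= 0:
        raise ValueError("decay_distance must be > 0")
    cols = [
        "chrom",
        "start",
        "end",
        "n_markers",
        "rep_marker",
        "rep_pos",
        "min_p",
        "max_r2",
        "min_r2",
        "members",
    ]
    carried = [c for c in meta_cols if c in getattr(significant, "columns", [])]
    if significant is None or len(significant) == 0:
        return pd.DataFrame(columns=carried + cols)
    group_keys = carried + ["chrom"]
    rows = []
    for key, grp in significant.groupby(group_keys, observed=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(pos) > decay_distance)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for a, b in zip(starts, ends):
            cl = grp.iloc[a:b]
            best = cl.sort_values(["p", "pos"]).iloc[0]
            rows.append(
                dict(zip(group_keys, key))
                | {
                    "start": int(cl["pos"].min()),
                    "end": int(cl["pos"].max()),
                    "n_markers": len(cl),
                    "rep_marker": best["marker"],
                    "rep_pos": int(best["pos"]),
                    "min_p": float(best["p"]),
                    "max_r2": float(cl["marker_r2"].max())
                    if "marker_r2" in cl
                    else np.nan,
                    "min_r2": float(cl["marker_r2"].min())
                    if "marker_r2" in cl
                    else np.nan,
                    "members": ";".join(cl["marker"].astype(str)),
                }
            )
    out = pd.DataFrame(rows)
    return out[carried + cols].sort_values(
        group_keys + ["start"], key=_chrom_aware_key
    ).reset_index(drop=True)


def _chrom_aware_key(col: pd.Series):
    if col.name == "chrom":
        return col.map(lambda c: "%02d%s" % chrom_sort_key(c))
    return col


def overlap_loci(
    measured: pd.DataFrame, predicted: pd.DataFrame, window: float
) -> pd.DataFrame:
    """Greedy same-chromosome pairing of measured and predicted loci.

    A pair is eligible when representative positions differ by at most
    ``window`` bp; pairs are taken in order of increasing distance and each
    locus participates in at most one pair.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(measured) == 0 or len(predicted) == 0:
        return pd.DataFrame(
            columns=[
                "chrom",
                "measured_marker",
                "measured_pos",
                "predicted_marker",
                "predicted_pos",
                "distance",
            ]
        )
    cand = []
    for i, mrow in measured.reset_index(drop=True).iterrows():
        for j, prow in predicted.reset_index(drop=True).iterrows():
            if mrow["chrom"] != prow["chrom"]:
                continue
            d = abs(float(mrow["rep_pos"]) - float(prow["rep_pos"]))
            if d <= window:
                cand.append((d, i, j, mrow, prow))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_m, used_p, rows = set(), set(), []
    for d, i, j, mrow, prow in cand:
        if i in used_m or j in used_p:
            continue
        used_m.add(i)
        used_p.add(j)
        rows.append(
            {
                "chrom": mrow["chrom"],
                "measured_marker": mrow["rep_marker"],
                "measured_pos": int(mrow["rep_pos"]),
                "predicted_marker": prow["rep_marker"],
                "predicted_pos": int(prow["rep_pos"]),
                "distance": d,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LocusSummary:
    cells: pd.DataFrame  # per-(treatment, stage, source) counts and ranges
    overall: dict  # totals and per-source means


def summarize_loci(
    loci: pd.DataFrame,
    cell_counts: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("treatment", "stage", "source"),
) -> LocusSummary:
    """Cell-level locus counts/ranges and overall per-source aggregates.

    ``loci`` has one row per locus with at least ``min_p`` (or ``p``) and
    marker-R² columns; grouping uses whichever of ``by`` are present. When a
    pre-aggregated ``cell_counts`` table (with a ``count`` column) is given,
    totals come from it; otherwise from ``loci`` row counts. Overall means of
    P and marker R² are arithmetic means over the supplied locus rows.
    """
    df = loci.copy()
    pcol = "min_p" if "min_p" in df.columns else "p"
    r2col = next(
        (c for c in ("max_r2", "marker_r2", "r2") if c in df.columns), None
    )
    keys = [c for c in by if c in df.columns]
    if keys:
        agg = {pcol: ["count", "min"]}
        if r2col:
            agg[r2col] = ["min", "max"]
        cells = df.groupby(keys, observed=True).agg(agg)
        cells.columns = ["count", "min_p"] + (["r2_min", "r2_max"] if r2col else [])
        cells = cells.reset_index()
    else:
        cells = pd.DataFrame(
            {
                "count": [len(df)],
                "min_p": [df[pcol].min()],
                **({"r2_min": [df[r2col].min()], "r2_max": [df[r2col].max()]} if r2col else {}),
            }
        )

    if cell_counts is not None:
        total = int(cell_counts["count"].sum())
        by_source = (
            cell_counts.groupby("source", observed=True)["count"].sum().to_dict()
            if "source" in cell_counts.columns
            else {}
        )
    else:
        total = int(len(df))
        by_source = (
            df.groupby("source", observed=True)[pcol].count().to_dict()
            if "source" in df.columns
            else {}
        )

    overall: dict = {"total_loci": total, "loci_by_source": by_source}
    if "source" in df.columns:
        for src, grp in df.groupby("source", observed=True):
            overall[f"mean_p_{src}"] = float(grp[pcol].mean())
            if r2col:
                overall[f"mean_r2_{src}"] = float(grp[r2col].mean())
    overall["mean_p"] = float(df[pcol].mean())
    if r2col:
        overall["mean_r2"] = float(df[r2col].mean())
    return LocusSummary(cells=cells, overall=overall)


# ---------------------------------------------------------------------------
# GFF3 annotation


def read_gff3_features(path, feature_types: tuple[str, ...] | None = ("gene",)):
    """Parse GFF3 features with gffutils; malformed lines are skipped.

    Returns (DataFrame[seqid, start, end, feature_id, featuretype],
    n_malformed).
    """
    from gffutils.feature import feature_from_line

    rows, malformed = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
                start, end = int(f.start), int(f.end)
            except Exception:
                malformed += 1
                continue
            if feature_types and f.featuretype not in feature_types:
                continue
            fid = (
                f.attributes.get("ID", [None])[0]
                or f.attributes.get("Name", [None])[0]
                or f"{f.seqid}:{start}-{end}"
            )
            rows.append((f.seqid, start, end, fid, f.featuretype))
    df = pd.DataFrame(
        rows, columns=["seqid", "start", "end", "feature_id", "featuretype"]
    )
    return df, malformed


def annotate_loci(
    loci: pd.DataFrame,
    gff,
    flank: int = 0,
    feature_types: tuple[str, ...] | None = ("gene",),
) -> pd.DataFrame:
    """Genes whose 1-based inclusive span intersects each locus ± flank.

    ``gff`` is a GFF3 path or a pre-parsed feature DataFrame. Returns one
    row per (locus, gene) intersection.
    """
    if isinstance(gff, pd.DataFrame):
        feats = gff
    else:
        feats, _ = read_gff3_features(gff, feature_types)
    rows = []
    for _, locus in loci.iterrows():
        lo = float(locus["start"]) - flank
        hi = float(locus["end"]) + flank
        hits = feats[
            (feats["seqid"].astype(str) == str(locus["chrom"]))
            & (feats["start"] <= hi)
            & (feats["end"] >= lo)
        ]
        for _, g in hits.iterrows():
            rows.append(
                {
                    "chrom": locus["chrom"],
                    "locus_start": locus["start"],
                    "locus_end": locus["end"],
                    "rep_marker": locus.get("rep_marker"),
                    "gene_id": g["feature_id"],
                    "gene_start": g["start"],
                    "gene_end": g["end"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "locus_start",
            "locus_end",
            "rep_marker",
            "gene_id",
            "gene_start",
            "gene_end",
        ],
    )


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: marker, chrom, pos, -log10 P, chromosome order."""
    out = assoc[["marker", "chrom", "pos", "p"]].copy()
    out["neglog10_p"] = -np.log10(out["p"])
    out["chrom_order"] = out["chrom"].map(lambda c: "%02d%s" % chrom_sort_key(c))
    return out.sort_values(["chrom_order", "pos"]).drop(columns="chrom_order")
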