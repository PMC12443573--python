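"""Descriptive trait statistics and broad-sense heritability.

Broad-sense heritability follows h_B² = σ_g² / (σ_g² + σ_e²), with the
variance components estimated by one-way ANOVA over genotypes with r
replicates: σ_e² = MS_within, σ_g² = max(0, (MS_between − MS_within)/r).
Descriptive summaries are computed over genotype means (replicates averaged
first), the same unit that enters the genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    r: float  # replicate count (harmonic mean when unbalanced)


def _pivot(values: pd.DataFrame, value_col: str = "spad") -> pd.DataFrame:
    """Genotype x replicate table from a long frame."""
    need = {"genotype", "replicate", value_col}
    if not need.issubset(values.columns):
        raise ValueError(f"long input needs columns {sorted(need)}")
    return values.pivot_table(
        index="genotype", columns="replicate", values=value_col, observed=True
    )


def summarize_trait(
    values: pd.DataFrame,
    value_col: str = "spad",
    per_replicate: bool = False,
) -> dict[str, float]:
    """Mean, median, CV (%), sd, min, max, n over genotype means.

    ``values`` is long format with genotype/replicate columns. With
    ``per_replicate=True`` the raw replicate values are summarized instead
    of genotype means.
    """
    table = _pivot(values, value_col)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    x = (
        table.to_numpy(dtype=float).ravel()
        if per_replicate
        else table.mean(axis=1).to_numpy(dtype=float)
    )
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("all values missing")
    mu = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return {
        "mean": mu,
        "median": float(np.median(x)),
        "cv_pct": 100.0 * sd / mu if mu > 0 else np.nan,
        "sd": sd,
        "max": float(x.max()),
        "min": float(x.min()),
        "n": int(x.size),
    }


def estimate_heritability(
    values: pd.DataFrame, value_col: str = "spad"
) -> tuple[VarianceComponents, float]:
    """One-way ANOVA broad-sense heritability from replicated values.

    Requires ≥ 2 replicates per genotype (missing cells allowed as long as
    every genotype keeps ≥ 2). Negative genetic variance is truncated to 0,
    so h_B² ∈ [0, 1]; h_B² = 0 when both components vanish.
    """
    table = _pivot(values, value_col)
    counts = table.notna().sum(axis=1)
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()[:5]
        raise ValueError(f"genotypes with < 2 replicates (inestimable): {bad}")
    arr = table.to_numpy(dtype=float)
    n_g = arr.shape[0]
    ni = counts.to_numpy(dtype=float)
    n_tot = float(ni.sum())
    gmeans = np.nanmean(arr, axis=1)
    grand = float(np.nansum(arr) / n_tot)
    ss_between = float(np.sum(ni * (gmeans - grand) ** 2))
    ss_within = float(np.nansum((arr - gmeans[:, None]) ** 2))
    ms_between = ss_between / (n_g - 1)
    ms_within = ss_within / (n_tot - n_g)
    # effective replicate number (Snedecor-Cochran n0 for unbalanced data)
    r_eff = (n_tot - np.sum(ni**2) / n_tot) / (n_g - 1)
    sigma_e2 = ms_within
    sigma_g2 = max(0.0, (ms_between - ms_within) / r_eff)
    denom = sigma_g2 + sigma_e2
    h2 = sigma_g2 / denom if denom > 0 else 0.0
    return VarianceComponents(sigma_g2, sigma_e2, float(r_eff)), h2


def trait_summary_table(
    spad: pd.DataFrame, source: str = "measured", value_col: str = "spad"
) -> pd.DataFrame:
    """One summary row per (env, treatment, stage): μ, median, CV, σ, h_B², extremes.

    ``spad`` is long format keyed by genotype/env/treatment/stage/replicate.
    """
    rows = []
    for (env, trt, stage), grp in spad.groupby(
        ["env", "treatment", "stage"], observed=True
    ):
        s = summarize_trait(grp, value_col)
        _, h2 = estimate_heritability(grp, value_col)
        rows.append(
            {
                "env": env,
                "treatment": trt,
                "stage": stage,
                "source": source,
                **{
                    "mean" if k == "mean" else k: v
                    for k, v in s.items()
                },
                "h2": h2,
            }
        )
    return pd.DataFrame(rows)
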