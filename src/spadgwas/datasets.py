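"""Bundled reference tables.

Three small CSVs transcribe the published summary tables of the wheat
UAV/SPAD study this package reimplements: stage-wise mean band reflectance
under the two irrigation regimes, the per-cell significant-locus counts of
the measured- and predicted-trait genome scans, and the 18 + 18 overlapping
loci with their P-values and marker R². They are the desk-reproducible
inputs for the summary operations and the acceptance checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("spadgwas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def band_stage_reflectance() -> pd.DataFrame:
    """Mean band reflectance (%) per (treatment, band, stage)."""
    return _read("band_stage_reflectance.csv")


def locus_cell_counts() -> pd.DataFrame:
    """Significant-locus counts per (treatment, source, stage) cell."""
    df = _read("locus_cell_counts.csv")
    df["min_p"] = df["min_p"].astype(float)
    return df


def overlap_locus_table() -> pd.DataFrame:
    """The 18 measured + 18 predicted overlapping loci (P, marker R² %)."""
    df = _read("overlap_loci.csv")
    df["p"] = df["p"].astype(float)
    return df
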