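"""Locus summaries for the synthetic run, plus the desk-recomputable
aggregates of the published locus tables (counts, mean P, mean marker R2,
stage-wise reflectance declines)."""

import json

import common
import pandas as pd

from spadgwas import datasets, gwas, reflectance

# synthetic-run summary
loci = pd.read_csv(common.RESULTS / "loci.csv")
s = gwas.summarize_loci(loci)
s.cells.to_csv(common.RESULTS / "locus_summary.csv", index=False)
print("synthetic run: %d loci (%s)" % (
    s.overall["total_loci"],
    ", ".join(f"{k} {v}" for k, v in s.overall["loci_by_source"].items()),
))

# published-table aggregates, recomputed by the same operations
pub_loci = datasets.overlap_locus_table().rename(
    columns={"marker_r2_pct": "marker_r2"}
)
pub = gwas.summarize_loci(pub_loci, cell_counts=datasets.locus_cell_counts())
decl = reflectance.stage_decreases(datasets.band_stage_reflectance())
key = decl.set_index(["treatment", "band", "transition"])["decrease_pct"]
out = {
    "total_loci": pub.overall["total_loci"],
    "predicted_loci": pub.overall["loci_by_source"]["predicted"],
    "measured_loci": pub.overall["loci_by_source"]["measured"],
    "mean_p_measured": pub.overall["mean_p_measured"],
    "mean_p_predicted": pub.overall["mean_p_predicted"],
    "mean_marker_r2_measured_pct": pub.overall["mean_r2_measured"],
    "mean_marker_r2_predicted_pct": pub.overall["mean_r2_predicted"],
    "nir_decline_w_fl_to_gf_pct": key[("W", "nir", "FL->GF")],
    "nir_decline_d_fl_to_gf_pct": key[("D", "nir", "FL->GF")],
}
(common.RESULTS / "published_aggregates.json").write_text(
    json.dumps(out, indent=1, default=float)
)
print("published tables:")
for k, v in out.items():
    print(f"  {k}: {v:g}")
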