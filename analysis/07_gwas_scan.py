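"""Q+K mixed-model genome scan on measured and predicted SPAD, significance
filtering at P < 0.001, LD-decay locus merging and measured/predicted
overlap."""

import common
import pandas as pd

from spadgwas import gwas

geno = pd.read_csv(common.BUNDLE / "genotypes.csv")
snp_map = pd.read_csv(common.BUNDLE / "map.csv")
spad = pd.read_csv(common.BUNDLE / "spad.csv")
predicted = pd.read_csv(common.RESULTS / "predicted_spad.csv")

geno_ids = geno["genotype"].tolist()
G, snp_map_f, log = gwas.impute_and_filter(
    geno.drop(columns="genotype").to_numpy(float), snp_map
)
K = gwas.compute_kinship(G)
Q = gwas.compute_q(G, q=common.N_PCS)
decay = gwas.estimate_ld_decay(G, snp_map_f)
decay_bp = float(decay) if decay.crossed else gwas.DEFAULT_LD_DECAY_BP
print(f"markers: {G.shape[1]}  LD decay window: {decay_bp/1e6:.2f} Mb"
      f" ({'estimated' if decay.crossed else 'default'})")

spad_mean = (
    spad.groupby(["genotype"] + common.CELL_KEYS, observed=True)["spad"]
    .mean().reset_index().rename(columns={"spad": "value"})
)
traits = {
    "measured": spad_mean,
    "predicted": predicted.rename(columns={"spad_pred": "value"}),
}

assoc_parts, loci_parts = [], []
for source, tab in traits.items():
    for key, grp in tab.groupby(common.CELL_KEYS, observed=True):
        y = grp.set_index("genotype")["value"].reindex(geno_ids).to_numpy()
        res = gwas.mlm_scan(y, G, snp_map_f, K=K, Q=Q)
        res[["source"] + common.CELL_KEYS] = (source, *key)
        assoc_parts.append(res)
        cell_loci = gwas.merge_loci(res[res["p"] < common.P_THRESHOLD], decay_bp)
        if len(cell_loci):
            loci_parts.append(cell_loci)
assoc = pd.concat(assoc_parts, ignore_index=True)
assoc.to_csv(common.RESULTS / "assoc.csv", index=False)
gwas.manhattan_table(assoc).to_csv(common.RESULTS / "manhattan.csv", index=False)
loci = pd.concat(loci_parts, ignore_index=True)
loci.to_csv(common.RESULTS / "loci.csv", index=False)

overlap_parts = []
for key, grp in loci.groupby(common.CELL_KEYS, observed=True):
    ov = gwas.overlap_loci(
        grp[grp["source"] == "measured"],
        grp[grp["source"] == "predicted"],
        window=decay_bp,
    )
    if len(ov):
        ov[common.CELL_KEYS] = key
        overlap_parts.append(ov)
overlap = pd.concat(overlap_parts, ignore_index=True) if overlap_parts else pd.DataFrame()
overlap.to_csv(common.RESULTS / "overlap.csv", index=False)

by_source = loci.groupby("source")["rep_marker"].count()
print(f"significant loci: {len(loci)} total "
      f"({by_source.get('predicted', 0)} predicted, {by_source.get('measured', 0)} measured)")
print(f"measured/predicted overlapping locus pairs: {len(overlap)}")
print("lambda_gc across scans: %.3f" % gwas.lambda_gc(assoc["p"]))
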