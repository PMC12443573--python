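"""Rank vegetation indices by random-forest importance and SPAD correlation,
and pick the per-cell feature set for the inversion network."""

import json

import common
import pandas as pd

from spadgwas import featsel

vi = pd.read_csv(common.RESULTS / "vegindex.csv")
spad = pd.read_csv(common.BUNDLE / "spad.csv")
spad_mean = (
    spad.groupby(["genotype"] + common.CELL_KEYS, observed=True)["spad"]
    .mean()
    .reset_index()
)
merged = vi.merge(spad_mean, on=["genotype"] + common.CELL_KEYS)

imp_rows, selections = [], {}
for i, (key, grp) in enumerate(merged.groupby(common.CELL_KEYS, observed=True)):
    tab = featsel.importance_table(grp, grp["spad"], seed=common.SEED + i)
    t = tab.reset_index(names="index_name")
    t[common.CELL_KEYS] = key
    imp_rows.append(t)
    sel = featsel.select_indices(tab, k_top=common.K_TOP)
    selections["/".join(key)] = sel.indices

pd.concat(imp_rows, ignore_index=True).to_csv(
    common.RESULTS / "importance.csv", index=False
)
(common.RESULTS / "selection.json").write_text(json.dumps(selections, indent=1))

print(f"selections per cell (top-{common.K_TOP} importance + strongest |r|):")
for key, names in selections.items():
    print(f"  {key:10s} {', '.join(names)}")
counts = pd.Series(
    [n for names in selections.values() for n in names]
).value_counts()
print("most frequently selected indices:", ", ".join(counts.index[:5]))
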