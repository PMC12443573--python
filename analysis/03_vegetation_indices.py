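"""Compute the 18 vegetation indices for every plot scene."""

import common
import pandas as pd

from spadgwas import vegindex

plot_refl = pd.read_csv(common.RESULTS / "plot_reflectance.csv")
vi, valid = vegindex.compute_all_vi(plot_refl)
vi.to_csv(common.RESULTS / "vegindex.csv", index=False)
valid.to_csv(common.RESULTS / "vegindex_valid.csv", index=False)

n_invalid = (~valid[list(vegindex.INDEX_NAMES)]).to_numpy().sum()
print(f"{len(vi)} plots x {len(vegindex.INDEX_NAMES)} indices")
print(f"invalid (zero-denominator) values: {n_invalid}")
print("NDVI range: %.3f .. %.3f" % (vi["NDVI"].min(), vi["NDVI"].max()))
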