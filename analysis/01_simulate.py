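"""Generate the synthetic trial: genotypes, SPAD phenotypes, plot scenes.

Writes the full input bundle (five-band TIFF scenes per env x treatment x
stage, plot layout, replicated SPAD table, dosage matrix + marker map, QTL
truth) under scratch/bundle.
"""

import json
import shutil

import common
import pandas as pd

from spadgwas import pipeline

common.ensure_dirs()
if common.BUNDLE.exists():
    shutil.rmtree(common.BUNDLE)
info = pipeline.make_fixtures(common.SIM, common.BUNDLE)

spad = pd.read_csv(common.BUNDLE / "spad.csv")
truth = json.loads((common.BUNDLE / "truth.json").read_text())
print(f"bundle: {info['dir']}")
print(f"scenes: {info['n_scenes']} (2 envs x 2 treatments x 3 stages)")
print(f"markers after MAF filter: {info['n_markers']} on 21 chromosomes")
print(f"SPAD rows: {len(spad)} (119 genotypes x 12 cells x 2 replicates)")
print(f"planted QTLs: {len(truth['qtl'])}")
print(
    "SPAD grand mean %.2f, sd %.2f"
    % (spad["spad"].mean(), spad["spad"].std())
)
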