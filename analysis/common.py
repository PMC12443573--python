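"""Shared paths and study-scale configuration for the analysis scripts.

The synthetic bundle (multiband TIFF scenes; binary) lives under scratch/,
tabular results under results/. Scripts are numbered in execution order and
each can be re-run independently once its inputs exist.
"""

from pathlib import Path

from spadgwas import synthio
from spadgwas.inversion import Hyperparams

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
BUNDLE = SCRATCH / "bundle"
RESULTS = ROOT / "results"

SEED = 9
SIM = synthio.SimConfig(seed=SEED)  # 119 genotypes, 2000 SNPs, 3 subpops
HYPERPARAMS = Hyperparams(epochs=5000)
P_THRESHOLD = 1e-3
K_TOP = 5
N_PCS = 3

CELL_KEYS = ["env", "treatment", "stage"]


def ensure_dirs():
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
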