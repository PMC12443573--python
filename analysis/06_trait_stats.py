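"""Descriptive statistics and broad-sense heritability for measured and
network-predicted SPAD."""

import common
import numpy as np
import pandas as pd

from spadgwas import traitstats

spad = pd.read_csv(common.BUNDLE / "spad.csv")
predicted = pd.read_csv(common.RESULTS / "predicted_spad.csv")

meas = traitstats.trait_summary_table(spad, source="measured")
pred_rows = []
for key, grp in predicted.groupby(common.CELL_KEYS, observed=True):
    x = grp["spad_pred"].to_numpy()
    sd, mu = float(np.std(x, ddof=1)), float(np.mean(x))
    pred_rows.append(
        dict(zip(common.CELL_KEYS, key))
        | {
            "source": "predicted", "mean": mu, "median": float(np.median(x)),
            "cv_pct": 100 * sd / mu, "sd": sd, "max": float(x.max()),
            "min": float(x.min()), "n": len(x), "h2": np.nan,
        }
    )
summary = pd.concat([meas, pd.DataFrame(pred_rows)], ignore_index=True)
summary.to_csv(common.RESULTS / "trait_summary.csv", index=False)

m = summary[summary["source"] == "measured"]
p = summary[summary["source"] == "predicted"]
print("measured:  mean %.1f-%.1f, CV %.1f-%.1f%%, h2 %.2f-%.2f"
      % (m["mean"].min(), m["mean"].max(), m["cv_pct"].min(),
         m["cv_pct"].max(), m["h2"].min(), m["h2"].max()))
print("predicted: mean %.1f-%.1f, CV %.1f-%.1f%%"
      % (p["mean"].min(), p["mean"].max(), p["cv_pct"].min(), p["cv_pct"].max()))
print("predicted values are more conservative (smaller CV) in "
      f"{int((p.set_index(common.CELL_KEYS)['cv_pct'] < m.set_index(common.CELL_KEYS)['cv_pct']).sum())}"
      f"/{len(p)} cells")
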