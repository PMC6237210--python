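"""Bar charts of both indices per condition (mean ± SD over movies).

Reads the battery tables written by 03_run_battery.py and saves
results/analysis/figures/indices.png. Requires matplotlib (the `plot`
extra).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

battery = Path("results/analysis/battery")
if not (battery / "group_summaries.csv").exists():
    raise SystemExit("run analysis/03_run_battery.py first")

summaries = pd.read_csv(battery / "group_summaries.csv")
order = ["untreated", "ris_12h", "aln_12h", "mino_12h",
         "ris_24h", "aln_24h", "mino_24h"]

fig, axes = plt.subplots(1, 2, figsize=(11, 4))
titles = {"resorption_index": "Bone-resorbing index",
          "deformation_index": "Cell deformation index"}
for ax, metric in zip(axes, ["resorption_index", "deformation_index"]):
    sub = summaries[summaries.metric == metric].set_index("group").loc[order]
    ax.bar(range(len(order)), sub["mean"], yerr=sub["sd"], capsize=3,
           color=["0.4"] + ["tab:red"] * 3 + ["tab:blue"] * 3)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=45, ha="right")
    ax.set_title(titles[metric])
    ax.set_ylabel("index (mean ± SD over movies)")
fig.tight_layout()

out = Path("results/analysis/figures")
out.mkdir(parents=True, exist_ok=True)
fig.savefig(out / "indices.png", dpi=150)
print(f"wrote {out / 'indices.png'}")
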