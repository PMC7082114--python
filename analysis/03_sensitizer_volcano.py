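"""Detect sensitizers and rescuers between the treated and DMSO screen arms:
median gene summaries, blocked NB GLM over the cell lines, likelihood-ratio
treatment contrast, mean-logFC volcano. Reports planted-sensitizer recovery.

Usage: python analysis/03_sensitizer_volcano.py  (after 01)
"""

import json
from pathlib import Path

import numpy as np

from chemoscreen import core_io
from chemoscreen.chemo import sensitizer_volcano

data = Path("results/data")
lib = core_io.read_sgrna_library(data / "library.tsv")
screen = core_io.read_count_table(data / "screen_counts.tsv", kind="sgrna", library=lib)
truth = json.loads((data / "ground_truth.json").read_text())["screen"]

table = sensitizer_volcano(screen)
table.round(5).to_csv(Path("results") / "sensitizer_volcano.tsv", sep="\t")

planted = set(truth["sensitizers"]) | set(truth["rescuers"])
null_lfc = table.loc[[g for g in table.index if g not in planted], "mean_logfc"]
threshold = np.quantile(null_lfc, 0.01)
sens = table.loc[truth["sensitizers"]]
hit = ((sens["mean_logfc"] < threshold) & (sens["padj"] < 0.1)).mean()
print(f"volcano over {len(table)} genes; null 1% tail threshold {threshold:+.3f} log2")
print(f"planted sensitizers recovered in the extreme tail (padj<0.1): {hit:.0%} of {len(sens)}")
print(f"mean logFC of sensitizers {sens['mean_logfc'].mean():+.2f}, "
      f"rescuers {table.loc[truth['rescuers'], 'mean_logfc'].mean():+.2f}")
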