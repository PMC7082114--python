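"""Generate the synthetic study data: chemogenomic screen counts, the
12-line expression panel, and spike-in coverage tracks, all with planted
ground truth, written under results/data/.

Usage: python analysis/01_simulate_data.py [--seed 7]
"""

import argparse
import json
from pathlib import Path

from chemoscreen import core_io
from chemoscreen.signature import compute_cpm
from chemoscreen.simulate import (
    CoverageSimConfig,
    ExpressionSimConfig,
    ScreenSimConfig,
    simulate_coverage,
    simulate_expression_panel,
    simulate_screen,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=7)
args = ap.parse_args()

out = Path("results/data")
out.mkdir(parents=True, exist_ok=True)

screen, screen_truth = simulate_screen(ScreenSimConfig(), args.seed)
core_io.write_count_table(screen, out / "screen_counts.tsv")
screen.library.entries.to_csv(out / "library.tsv", sep="\t", index=False)

panel, expr_truth = simulate_expression_panel(ExpressionSimConfig(), args.seed + 1)
core_io.write_count_table(panel, out / "expression_counts.tsv")

# coverage follows mean expression of a 200-gene subsample to keep tracks small
small_panel, _ = simulate_expression_panel(ExpressionSimConfig(n_genes=200), args.seed + 2)
cpm = compute_cpm(small_panel.counts).mean(axis=1)
cpm.rename("cpm").to_csv(out / "coverage_gene_cpm.tsv", sep="\t")
tracks, anno, cov_truth = simulate_coverage(CoverageSimConfig(), cpm, args.seed + 3)
for name, track in tracks.items():
    core_io.write_coverage(track, out / f"coverage_{name}.bedGraph")
core_io.write_gene_annotation(anno, out / "genes.bed")

truth = {
    "screen": {
        "essential": screen_truth.essential,
        "sensitizers": screen_truth.sensitizers,
        "rescuers": screen_truth.rescuers,
    },
    "expression": {
        "module": expr_truth.module,
        "baseline_up": expr_truth.baseline_up,
        "baseline_down": expr_truth.baseline_down,
    },
}
(out / "ground_truth.json").write_text(json.dumps(truth, indent=2))

print(f"screen: {screen.counts.shape[0]} sgRNAs x {screen.counts.shape[1]} samples")
print(f"expression: {panel.counts.shape[0]} genes x {panel.counts.shape[1]} samples")
print(f"coverage: {len(tracks)} tracks over {len(anno.records)} genes -> {out}")
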