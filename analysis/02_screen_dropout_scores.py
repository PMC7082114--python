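"""Score the synthetic screen for day-14 dropout: TMM pairing against the
plasmid pool, shrunken per-sgRNA logFC, quantile normalization, Q1 gene
summaries. Reports how far planted essentials separate from null genes.

Usage: python analysis/02_screen_dropout_scores.py  (after 01)
"""

import json
from pathlib import Path

from chemoscreen import core_io
from chemoscreen.screen import score_screen

data = Path("results/data")
out = Path("results")
lib = core_io.read_sgrna_library(data / "library.tsv")
screen = core_io.read_count_table(data / "screen_counts.tsv", kind="sgrna", library=lib)
truth = json.loads((data / "ground_truth.json").read_text())["screen"]

sgrna_scores, gene_scores = score_screen(screen)
gene_scores.round(4).to_csv(out / "gene_q1_scores.tsv", sep="\t")

planted = set(truth["essential"]) | set(truth["sensitizers"]) | set(truth["rescuers"])
null = [g for g in gene_scores.index if g not in planted]
print(f"Q1 scores: {gene_scores.shape[0]} genes x {gene_scores.shape[1]} day-14 samples")
for col in gene_scores.columns:
    ess = gene_scores.loc[truth["essential"], col].mean()
    nul = gene_scores.loc[null, col].mean()
    print(f"  {col}: essential mean Q1 {ess:+.2f}, null {nul:+.2f}, separation {nul - ess:.2f} log2")
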