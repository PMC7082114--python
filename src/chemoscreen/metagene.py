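"""Spike-in-normalized, strand-aware TSS metagene profiling.

ChIP-seq coverage carrying an exogenous spike-in reference (e.g. Drosophila
chromatin added at a fixed proportion) is rescaled so every sample has the
same total spike signal; differences that survive this normalization reflect
genuine global shifts of the mark rather than sequencing depth. Signal is
then averaged in fixed-width bins around each gene's TSS, oriented so that
upstream is always on the left, and summarized over gene sets — including
expression-quantile groups and expression-matched control sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CoverageTrack, GenomicAnnotation

__all__ = [
    "SpikeInStats",
    "spike_scale_factor",
    "tss_signal_matrix",
    "metagene_average",
    "expression_bins",
    "ExpressionMatchedControls",
    "matched_control_set",
]


@dataclass(frozen=True)
class SpikeInStats:
    """Spike-in scaling of one sample against a reference spike total."""

    sample_spike_signal: float
    reference_spike_signal: float

    @property
    def scale_factor(self) -> float:
        return self.reference_spike_signal / self.sample_spike_signal


def spike_scale_factor(track: CoverageTrack, reference_spike_signal: float) -> SpikeInStats:
    """Scale factor bringing the track's spike signal to the reference total.

    The sample's spike signal is the sum of ``(end - start) * value`` over the
    flagged spike contigs; all experimental signal is multiplied by
    ``reference / sample`` downstream. Rescaling the whole track by any
    constant therefore leaves normalized experimental signal unchanged.
    """
    if not track.spike_contigs:
        raise ValueError("track has no spike-in contigs")
    spike = track.total_signal(track.spike_contigs)
    if spike <= 0:
        raise ValueError("zero spike-in signal")
    return SpikeInStats(sample_spike_signal=spike, reference_spike_signal=reference_spike_signal)


def _dense_contig(iv: np.ndarray, length: int) -> np.ndarray:
    """Materialize a step function as a per-base array of the given length."""
    arr = np.zeros(length)
    for s, e, v in iv:
        arr[int(s) : min(int(e), length)] = v
    return arr


def tss_signal_matrix(
    track: CoverageTrack,
    annotation: GenomicAnnotation,
    gene_ids: list[str] | None = None,
    window: int = 5000,
    bin_size: int = 50,
    spike: SpikeInStats | None = None,
) -> pd.DataFrame:
    """Genes x bins matrix of mean per-base signal around each TSS.

    The window spans ``[tss - window, tss + window)`` for '+' genes and the
    mirror image ``[tss - window + 1, tss + window + 1)`` for '-' genes,
    split into bins of ``bin_size`` bp; '-'-strand rows are reversed so
    upstream is always the left edge. The one-base shift makes profiles
    exactly invariant under reversing the contig and flipping all strands. Windows extending past the covered extent of a
    contig are dropped with a warning. When ``spike`` is given every value is
    multiplied by its scale factor. Columns are bin-center offsets from the
    TSS.
    """
    if 2 * window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    recs = annotation.records
    if gene_ids is None:
        gene_ids = list(recs.index)
    unknown = [g for g in gene_ids if g not in recs.index]
    if unknown:
        raise KeyError(f"unknown gene id(s): {unknown[:3]}")
    scale = spike.scale_factor if spike is not None else 1.0
    tss = annotation.tss
    n_bins = 2 * window // bin_size
    extents = {c: int(iv[:, 1].max()) for c, iv in track.contigs.items()}
    dense: dict[str, np.ndarray] = {}
    rows, kept = [], []
    dropped = 0
    for g in gene_ids:
        contig = recs.at[g, "contig"]
        if contig not in track.contigs:
            raise KeyError(f"gene {g!r} on contig {contig!r} absent from track")
        minus = recs.at[g, "strand"] == "-"
        lo = int(tss[g]) - window + (1 if minus else 0)
        hi = lo + 2 * window
        if lo < 0 or hi > extents[contig]:
            dropped += 1
            continue
        if contig not in dense:
            dense[contig] = _dense_contig(track.contigs[contig], extents[contig])
        win = dense[contig][lo:hi]
        prof = win.reshape(n_bins, bin_size).mean(axis=1) * scale
        if minus:
            prof = prof[::-1]
        rows.append(prof)
        kept.append(g)
    if dropped:
        warnings.warn(f"dropped {dropped} gene(s) with windows beyond contig extent")
    centers = np.arange(n_bins) * bin_size - window + bin_size / 2
    return pd.DataFrame(np.array(rows).reshape(len(kept), n_bins), index=kept, columns=centers)


def metagene_average(matrix: pd.DataFrame, gene_set: list[str] | None = None) -> pd.DataFrame:
    """Column-wise mean and standard error over a gene set."""
    sub = matrix if gene_set is None else matrix.loc[list(gene_set)]
    if len(sub) == 0:
        raise ValueError("empty gene set")
    mean = sub.mean(axis=0)
    sem = sub.std(axis=0, ddof=1) / np.sqrt(len(sub)) if len(sub) > 1 else mean * 0.0
    return pd.DataFrame({"mean": mean, "sem": sem})


def expression_bins(expression: pd.Series, n_groups: int) -> list[pd.Index]:
    """Quantile groups of genes by log2(cpm + 1), lowest expression first.

    Ties are broken by stable gene-id order; group sizes differ by at most
    one (larger groups first).
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if len(expression) < n_groups:
        raise ValueError("fewer genes than groups")
    key = np.log2(expression.astype(float) + 1.0)
    order = key.to_numpy().argsort(kind="stable")
    return [expression.index[chunk] for chunk in np.array_split(order, n_groups)]


@dataclass(frozen=True)
class ExpressionMatchedControls:
    """A control gene set matched to the targets' expression distribution."""

    targets: frozenset
    controls: frozenset
    n_bins: int
    seed: int
    partial: bool  # True when some bin had fewer candidates than targets


def matched_control_set(
    targets: list[str],
    universe: list[str],
    expression: pd.Series,
    n_bins: int = 20,
    seed: int = 0,
) -> ExpressionMatchedControls:
    """Sample a control set with the targets' basal expression distribution.

    Expression quantile bins are computed on the pooled targets-plus-universe
    distribution; within each bin, as many universe genes as there are targets
    are drawn without replacement with the seeded generator. Bins with too few
    candidates contribute all of them and mark the match as partial.
    """
    targets = list(dict.fromkeys(targets))
    universe = [g for g in dict.fromkeys(universe) if g not in set(targets)]
    if not universe:
        raise ValueError("empty candidate universe after excluding targets")
    pool = pd.Index(targets + universe)
    vals = np.log2(expression.loc[pool].astype(float) + 1.0)
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_of = pd.Series(np.searchsorted(edges, vals, side="right") - 1, index=pool).clip(0, n_bins - 1)
    rng = np.random.default_rng(seed)
    controls: list[str] = []
    partial = False
    for b in range(n_bins):
        t_in = [g for g in targets if bin_of[g] == b]
        if not t_in:
            continue
        candidates = [g for g in universe if bin_of[g] == b]
        if len(candidates) <= len(t_in):
            controls.extend(candidates)
            if len(candidates) < len(t_in):
                partial = True
                warnings.warn(f"expression bin {b}: only {len(candidates)} candidates for {len(t_in)} targets")
        else:
            controls.extend(rng.choice(candidates, size=len(t_in), replace=False))
    return ExpressionMatchedControls(
        targets=frozenset(targets),
        controls=frozenset(controls),
        n_bins=n_bins,
        seed=seed,
        partial=partial,
    )
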