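"""Day-14 dropout scoring of a pooled CRISPR screen.

Each day-14 sample is normalized *in a pair* against the plasmid pool with TMM
(trimmed mean of M-values), a negative-binomial-motivated shrunken log2
fold change per sgRNA is computed with a fixed prior count, sgRNA logFC
columns are quantile-normalized across cell lines, and each gene is
summarized as the first quartile (Q1) of its guides' scores.

Defaults follow the screen analysis they re-implement: common dispersion 0.2,
prior count 12, TMM trims of 0.30 on M and 0.05 on A, all logs base 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ScreenCounts

__all__ = [
    "tmm_pair_factor",
    "sgrna_dropout_logfc",
    "quantile_normalize",
    "gene_q1",
    "score_screen",
]

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05
DEFAULT_DISPERSION = 0.2
DEFAULT_PRIOR_COUNT = 12.0


def tmm_pair_factor(
    sample: np.ndarray,
    reference: np.ndarray,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> float:
    """TMM scale factor of ``sample`` relative to its paired ``reference``.

    M-values (log2 ratio of library-size-scaled counts) and A-values (average
    log2 abundance) are computed over features observed in both members; the
    top/bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A are
    discarded, and the factor is 2 to the precision-weighted mean of the
    surviving M-values (weights = inverse asymptotic binomial variance).

    The trimming is rank-symmetric, so ``tmm_pair_factor(a, b) *
    tmm_pair_factor(b, a) == 1`` up to float rounding.
    """
    ys = np.asarray(sample, dtype=float)
    yr = np.asarray(reference, dtype=float)
    if ys.shape != yr.shape:
        raise ValueError("sample and reference must have equal length")
    ns, nr = ys.sum(), yr.sum()
    if ns <= 0 or nr <= 0:
        raise ValueError("both members of the pair need a positive total count")
    both = (ys > 0) & (yr > 0)
    ys, yr = ys[both], yr[both]
    ps, pr = ys / ns, yr / nr
    m = np.log2(ps / pr)
    a = 0.5 * np.log2(ps * pr)
    # rank-based double trim, symmetric under sample/reference swap
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} co-observed sgRNAs survive trimming; "
            "use smaller trim fractions"
        )
    var = (ns - ys[keep]) / (ns * ys[keep]) + (nr - yr[keep]) / (nr * yr[keep])
    w = 1.0 / var
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def sgrna_dropout_logfc(
    sample: np.ndarray,
    reference: np.ndarray,
    tmm_factor_sample: float = 1.0,
    tmm_factor_reference: float = 1.0,
    dispersion: float = DEFAULT_DISPERSION,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> np.ndarray:
    """Prior-shrunken per-sgRNA log2 fold change of ``sample`` vs ``reference``.

    Effective library sizes are raw totals times the TMM factors. Each count is
    augmented by a library-size-proportional share of the prior,
    ``y' = y + p * L_j / mean(L)``, library sizes by twice that share, and the
    logFC is the log2 ratio of augmented counts-per-library. The prior keeps
    the logFC finite for zero counts; ``dispersion`` is carried for interface
    symmetry with the downstream model (the point estimate does not use it).
    """
    del dispersion  # point estimate; kept in the signature as pipeline state
    ys = np.asarray(sample, dtype=float)
    yr = np.asarray(reference, dtype=float)
    ls = ys.sum() * tmm_factor_sample
    lr = yr.sum() * tmm_factor_reference
    if ls <= 0 or lr <= 0:
        raise ValueError("zero effective library size")
    lbar = 0.5 * (ls + lr)
    ps, pr = prior_count * ls / lbar, prior_count * lr / lbar
    return np.log2(((ys + ps) / (ls + 2 * ps)) / ((yr + pr) / (lr + 2 * pr)))


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-based quantile normalization across columns.

    The target distribution is the across-column mean of column-sorted values;
    ties within a column receive the mean of the target quantiles they span.
    A single-row matrix degenerates to the row mean in every column.
    """
    values = mat.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values: drop incomplete rows before normalizing")
    n, k = values.shape
    if n == 1:
        return pd.DataFrame(
            np.full_like(values, values.mean()), index=mat.index, columns=mat.columns
        )
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    # cumulative mean of the target resolves tied ranks exactly: a tie group
    # occupying sorted positions i..j gets mean(target[i..j])
    csum = np.concatenate([[0.0], np.cumsum(target)])
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # group boundaries of equal values in sorted order
        starts = np.flatnonzero(np.concatenate([[True], sorted_col[1:] != sorted_col[:-1]]))
        ends = np.concatenate([starts[1:], [n]])
        group_means = (csum[ends] - csum[starts]) / (ends - starts)
        ranks = np.empty(n, dtype=int)
        for g, (s, e) in enumerate(zip(starts, ends)):
            ranks[order[s:e]] = g
        out[:, j] = group_means[ranks]
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def gene_q1(scores: pd.DataFrame, gene_of_sgrna: pd.Series) -> pd.DataFrame:
    """First-quartile gene summary of per-sgRNA scores.

    Q1 is the empirical quantile at probability 0.25 with linear interpolation
    on (n - 1) spacing (``numpy`` default); a singleton gene returns its own
    value. Returns a gene x sample frame.
    """
    genes = gene_of_sgrna.loc[scores.index]
    out = scores.groupby(genes.to_numpy()).quantile(0.25)
    out.index.name = "gene_id"
    return out


def score_screen(
    screen: ScreenCounts,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
    dispersion: float = DEFAULT_DISPERSION,
    prior_count: float = DEFAULT_PRIOR_COUNT,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full dropout-scoring pipeline.

    Every selected day-14 column is TMM-paired with the plasmid pool and scored
    with :func:`sgrna_dropout_logfc`; the resulting logFC matrix is
    quantile-normalized jointly over the selected columns (all non-plasmid
    columns by default) and summarized per gene with :func:`gene_q1`.

    Returns ``(sgrna_scores, gene_scores)``.
    """
    plasmid = screen.counts[screen.plasmid_column].to_numpy()
    cols = columns if columns is not None else screen.sample_columns()
    logfc = {}
    for c in cols:
        y = screen.counts[c].to_numpy()
        f = tmm_pair_factor(y, plasmid, trim_m=trim_m, trim_a=trim_a)
        # rescale the pair so the two factors multiply to 1
        fs, fr = np.sqrt(f), 1.0 / np.sqrt(f)
        logfc[c] = sgrna_dropout_logfc(
            y, plasmid, fs, fr, dispersion=dispersion, prior_count=prior_count
        )
    mat = pd.DataFrame(logfc, index=screen.counts.index)
    sgrna_scores = quantile_normalize(mat)
    gene_scores = gene_q1(sgrna_scores, screen.library.sgrna_to_gene)
    return sgrna_scores, gene_scores
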