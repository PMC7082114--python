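"""Sensitizer / rescuer detection between treated and DMSO screen arms.

Per sample, each gene is summarized as the median count of the sgRNAs
targeting it; a negative-binomial generalized log-linear model with fixed
dispersion is fitted to the summarized counts with cell-line blocking, and the
treatment-vs-DMSO contrast is tested gene-wise by likelihood ratio. The
volcano view reports, per gene, the mean of per-line log2 fold changes across
the selected cell lines against the combined significance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core_io import ScreenCounts, SgRNALibrary
from .glm import (
    LN2,
    NbGlmFit,
    bh_adjust,
    lrt_pvalues,
    nb_glm_fit,
    nb_glm_fit_many,
    stouffer_combine,
)
from .screen import tmm_pair_factor

__all__ = [
    "median_summarize",
    "nb_glm_fit",
    "treatment_contrast_test",
    "bh_adjust",
    "effective_library_sizes",
    "blocked_treatment_test",
    "per_line_treatment_logfc",
    "volcano_table",
    "sensitizer_volcano",
]

DEFAULT_DISPERSION = 0.2


def median_summarize(counts: pd.DataFrame, library: SgRNALibrary) -> pd.DataFrame:
    """Gene x sample matrix of per-gene median sgRNA counts.

    Even guide numbers take the mean of the two central order statistics, so
    medians may be non-integer; the downstream NB likelihood is continuous.
    """
    genes = library.sgrna_to_gene
    missing = [i for i in counts.index if i not in genes.index]
    if missing:
        raise ValueError(f"sgRNA id(s) not in library: {missing[:3]}")
    out = counts.groupby(genes.loc[counts.index].to_numpy()).median()
    out.index.name = "gene_id"
    return out


def treatment_contrast_test(full: NbGlmFit, null: NbGlmFit, treatment_col: int = -1):
    """Gene-wise likelihood-ratio test of the treatment column.

    ``full`` and ``null`` must be nested fits differing by exactly the
    treatment column. Returns a DataFrame-ready dict with the treatment log2FC
    (coefficient / ln 2), the LRT statistic and its chi-square(1) p-value;
    negative statistics beyond rounding are flagged as NaN.
    """
    if full.design.shape[1] != null.design.shape[1] + 1:
        raise ValueError("designs must be nested and differ by one column")
    stat, p = lrt_pvalues(full, null, df=1)
    logfc = full.coefficients[:, treatment_col] / LN2
    return {"logfc": logfc, "lrt_stat": stat, "pvalue": p}


def effective_library_sizes(gene_counts: pd.DataFrame, reference: np.ndarray) -> pd.Series:
    """Column totals scaled by TMM factors against a reference profile.

    The reference is typically the mean of the DMSO columns of the summarized
    matrix; each returned value is ``total * factor`` for use as a GLM offset
    after taking logs.
    """
    libs = {}
    ref = np.asarray(reference, dtype=float)
    for c in gene_counts.columns:
        y = gene_counts[c].to_numpy(dtype=float)
        f = tmm_pair_factor(y, ref)
        libs[c] = y.sum() * f
    return pd.Series(libs)


def _design_blocked(meta: pd.DataFrame, lines: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + cell-line blocks + treatment indicator."""
    cols = [np.ones(len(meta))]
    for line in lines[1:]:
        cols.append((meta["cell_line"] == line).to_numpy(dtype=float))
    full = np.column_stack(cols + [(meta["arm"] == "treated").to_numpy(dtype=float)])
    return full, full[:, :-1]


def blocked_treatment_test(
    gene_counts: pd.DataFrame,
    meta: pd.DataFrame,
    lines: list[str],
    dispersion: float = DEFAULT_DISPERSION,
) -> pd.DataFrame:
    """Joint NB GLM over the selected lines (~ cell_line + treatment), LRT p.

    ``meta`` rows must match the columns of ``gene_counts``; only dmso/treated
    columns of the selected lines enter the fit. Effective library sizes are
    recomputed from the summarized matrix with TMM against the mean DMSO
    profile.
    """
    keep = meta["cell_line"].isin(lines) & meta["arm"].isin(["dmso", "treated"])
    sub_meta = meta.loc[keep]
    sub = gene_counts[sub_meta.index]
    dmso_ref = sub[sub_meta.index[sub_meta["arm"] == "dmso"]].mean(axis=1).to_numpy()
    libs = effective_library_sizes(sub, dmso_ref)
    offsets = np.log(libs.to_numpy())
    full_x, null_x = _design_blocked(sub_meta, lines)
    y = sub.to_numpy(dtype=float)
    full = nb_glm_fit_many(y, full_x, offsets, dispersion)
    null = nb_glm_fit_many(y, null_x, offsets, dispersion)
    res = treatment_contrast_test(full, null)
    out = pd.DataFrame(res, index=sub.index)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def per_line_treatment_logfc(
    gene_counts: pd.DataFrame,
    meta: pd.DataFrame,
    line: str,
    dispersion: float = DEFAULT_DISPERSION,
) -> pd.DataFrame:
    """Treatment-vs-DMSO NB GLM restricted to one cell line."""
    keep = (meta["cell_line"] == line) & meta["arm"].isin(["dmso", "treated"])
    sub_meta = meta.loc[keep]
    sub = gene_counts[sub_meta.index]
    dmso_ref = sub[sub_meta.index[sub_meta["arm"] == "dmso"]].mean(axis=1).to_numpy()
    libs = effective_library_sizes(sub, dmso_ref)
    offsets = np.log(libs.to_numpy())
    treated = (sub_meta["arm"] == "treated").to_numpy(dtype=float)
    full_x = np.column_stack([np.ones(len(sub_meta)), treated])
    y = sub.to_numpy(dtype=float)
    full = nb_glm_fit_many(y, full_x, offsets, dispersion)
    null = nb_glm_fit_many(y, full_x[:, :1], offsets, dispersion)
    res = treatment_contrast_test(full, null)
    return pd.DataFrame(res, index=sub.index)


def volcano_table(
    per_line: dict[str, pd.DataFrame],
    cell_lines: list[str],
    combined_p: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean per-line logFC with a combined significance per gene.

    ``per_line`` maps cell line -> frame with ``logfc`` and ``pvalue``. Genes
    missing from any selected line are dropped with a warning. If
    ``combined_p`` (e.g. from the blocked joint GLM) is not given, the
    per-line p-values are combined with a directional Stouffer z.
    """
    missing_lines = [ln for ln in cell_lines if ln not in per_line]
    if missing_lines:
        raise ValueError(f"no results for line(s): {missing_lines}")
    common = per_line[cell_lines[0]].index
    for ln in cell_lines[1:]:
        common = common.intersection(per_line[ln].index)
    dropped = len(per_line[cell_lines[0]].index) - len(common)
    if dropped:
        warnings.warn(f"dropped {dropped} gene(s) missing from some selected line")
    lfc = pd.DataFrame({ln: per_line[ln].loc[common, "logfc"] for ln in cell_lines})
    out = pd.DataFrame(index=common)
    out["mean_logfc"] = lfc.mean(axis=1)
    if combined_p is not None:
        out["pvalue"] = combined_p.loc[common]
    else:
        pmat = np.column_stack([per_line[ln].loc[common, "pvalue"] for ln in cell_lines])
        out["pvalue"] = stouffer_combine(pmat, lfc.to_numpy())
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def sensitizer_volcano(
    screen: ScreenCounts,
    lines: list[str] | None = None,
    dispersion: float = DEFAULT_DISPERSION,
    combine: str = "blocked",
) -> pd.DataFrame:
    """End-to-end sensitizer/rescuer volcano from raw screen counts.

    Median-summarizes the sgRNA counts, computes per-line treatment logFC, and
    combines significance either with the joint blocked GLM (default) or a
    Stouffer combination of per-line p-values.
    """
    if lines is None:
        lines = sorted(set(screen.meta.loc[screen.meta["arm"] != "plasmid", "cell_line"]))
    gene_counts = median_summarize(screen.counts, screen.library)
    per_line = {
        ln: per_line_treatment_logfc(gene_counts, screen.meta, ln, dispersion) for ln in lines
    }
    combined = None
    if combine == "blocked":
        joint = blocked_treatment_test(gene_counts, screen.meta, lines, dispersion)
        combined = joint["pvalue"]
    elif combine != "stouffer":
        raise ValueError("combine must be 'blocked' or 'stouffer'")
    return volcano_table(per_line, lines, combined)
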