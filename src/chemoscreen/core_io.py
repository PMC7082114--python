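"""Readers, writers and validated containers for the tabular and genomic formats
used throughout the pipeline.

Conventions
-----------
* All genomic coordinates are 0-based, half-open (BED convention). The TSS of a
  '-'-strand gene is ``end - 1``.
* Counts must be non-negative integers at ingest; downstream summaries (medians,
  normalized scores) may be fractional.
* Sample metadata travels in a sidecar TSV keyed by column name, never encoded
  in column names.
* TSV files are tab-separated, UTF-8, with ``#`` comment lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SgRNALibrary",
    "ScreenCounts",
    "ExpressionMatrix",
    "GenomicAnnotation",
    "CoverageTrack",
    "ValidationError",
    "read_sgrna_library",
    "read_count_table",
    "write_count_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_coverage",
    "write_coverage",
]

SCREEN_ARMS = ("plasmid", "dmso", "treated")


class ValidationError(ValueError):
    """Raised when an input file or container violates a format contract."""


@dataclass(frozen=True)
class SgRNALibrary:
    """Map from sgRNA id to target gene (each sgRNA targets exactly one gene)."""

    entries: pd.DataFrame  # columns: sgrna_id, gene_id

    def __post_init__(self) -> None:
        df = self.entries
        if list(df.columns[:2]) != ["sgrna_id", "gene_id"]:
            raise ValidationError("library must have columns (sgrna_id, gene_id)")
        dup = df["sgrna_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate sgRNA id(s): {df.loc[dup, 'sgrna_id'].iloc[0]!r}"
            )
        counts = df.groupby("gene_id").size()
        if (counts < 1).any():  # pragma: no cover - groupby cannot produce 0
            raise ValidationError("every gene needs at least one sgRNA")

    @property
    def genes(self) -> dict[str, list[str]]:
        """gene_id -> list of sgRNA ids (library order preserved)."""
        return {
            g: list(sub["sgrna_id"]) for g, sub in self.entries.groupby("gene_id", sort=False)
        }

    @property
    def sgrna_to_gene(self) -> pd.Series:
        return self.entries.set_index("sgrna_id")["gene_id"]

    def __len__(self) -> int:
        return len(self.entries)


def _check_count_frame(counts: pd.DataFrame, what: str) -> None:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValidationError(f"duplicate {what} id {dup!r}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{what} counts must be numeric")
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"missing count at row {counts.index[r]!r}, column {counts.columns[c]!r}"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative count at row {counts.index[r]!r}, column {counts.columns[c]!r}"
        )
    if not np.array_equal(arr, np.floor(arr)):
        r, c = np.argwhere(arr != np.floor(arr))[0]
        raise ValidationError(
            f"non-integer count at row {counts.index[r]!r}, column {counts.columns[c]!r}"
        )


@dataclass
class ScreenCounts:
    """sgRNA x sample integer count matrix with its plasmid reference column.

    ``meta`` has one row per sample column with fields ``cell_line``, ``arm``
    (plasmid / dmso / treated), ``day`` and optionally ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    library: SgRNALibrary

    def __post_init__(self) -> None:
        _check_count_frame(self.counts, "sgRNA")
        if list(self.meta.index) != list(self.counts.columns):
            raise ValidationError("metadata rows must match count columns in order")
        bad = set(self.meta["arm"]) - set(SCREEN_ARMS)
        if bad:
            raise ValidationError(f"unknown arm value(s): {sorted(bad)}")
        n_plasmid = int((self.meta["arm"] == "plasmid").sum())
        if n_plasmid != 1:
            raise ValidationError(
                f"exactly one plasmid column required, found {n_plasmid}"
            )
        known = set(self.library.entries["sgrna_id"])
        missing = [i for i in self.counts.index if i not in known]
        if missing:
            raise ValidationError(f"sgRNA id(s) absent from library: {missing[:3]}")

    @property
    def plasmid_column(self) -> str:
        return str(self.meta.index[self.meta["arm"] == "plasmid"][0])

    def sample_columns(self, arm: str | None = None, cell_line: str | None = None) -> list[str]:
        m = self.meta["arm"] != "plasmid"
        if arm is not None:
            m = self.meta["arm"] == arm
        if cell_line is not None:
            m &= self.meta["cell_line"] == cell_line
        return list(self.meta.index[m])


@dataclass
class ExpressionMatrix:
    """Gene x sample RNA-seq count matrix with sample metadata.

    ``meta`` fields: ``cell_line``, ``group`` (sensitive / insensitive),
    ``treatment`` (dmso / treated or condition labels), ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_count_frame(self.counts, "gene")
        if list(self.meta.index) != list(self.counts.columns):
            raise ValidationError("metadata rows must match count columns in order")
        # every line with a treated column needs its own vehicle column
        for line, sub in self.meta.groupby("cell_line"):
            tr = set(sub["treatment"])
            if tr - {"dmso"} and "dmso" not in tr:
                raise ValidationError(f"cell line {line!r} has treated but no dmso sample")

    def columns_for(self, cell_line: str, treatment: str) -> list[str]:
        m = (self.meta["cell_line"] == cell_line) & (self.meta["treatment"] == treatment)
        return list(self.meta.index[m])


@dataclass(frozen=True)
class GenomicAnnotation:
    """Per-gene TSS coordinates derived from a BED6+1 annotation."""

    records: pd.DataFrame  # gene_id (index), contig, start, end, strand, gene_length_bp

    def __post_init__(self) -> None:
        df = self.records
        if df.index.duplicated().any():
            raise ValidationError("duplicate gene_id in annotation")
        if (df["start"] >= df["end"]).any():
            g = df.index[df["start"] >= df["end"]][0]
            raise ValidationError(f"start >= end for gene {g!r}")
        bad = set(df["strand"]) - {"+", "-"}
        if bad:
            raise ValidationError(f"invalid strand value(s): {sorted(bad)}")
        if (df["gene_length_bp"] <= 0).any():
            raise ValidationError("gene_length_bp must be positive")

    @property
    def tss(self) -> pd.Series:
        """0-based TSS: start for '+' genes, end - 1 for '-' genes."""
        df = self.records
        return pd.Series(
            np.where(df["strand"] == "+", df["start"], df["end"] - 1),
            index=df.index,
            name="tss",
        )


@dataclass
class CoverageTrack:
    """Step-function coverage per contig, with spike-in contigs flagged.

    ``contigs`` maps contig name to a float array of shape (n_intervals, 3)
    holding (start, end, value) with sorted, non-overlapping intervals.
    """

    contigs: dict[str, np.ndarray]
    spike_contigs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, iv in self.contigs.items():
            iv = np.asarray(iv, dtype=float)
            if iv.ndim != 2 or iv.shape[1] != 3:
                raise ValidationError(f"contig {name!r}: intervals must be (n, 3)")
            if not np.isfinite(iv).all():
                raise ValidationError(f"contig {name!r}: non-finite interval or value")
            if (iv[:, 2] < 0).any():
                raise ValidationError(f"contig {name!r}: negative coverage value")
            if (iv[:, 0] >= iv[:, 1]).any():
                raise ValidationError(f"contig {name!r}: empty or inverted interval")
            if len(iv) > 1 and (iv[1:, 0] < iv[:-1, 1]).any():
                raise ValidationError(f"contig {name!r}: overlapping or unsorted intervals")
            self.contigs[name] = iv

    def total_signal(self, contigs: set[str] | None = None) -> float:
        """Sum of (end - start) * value over the selected contigs."""
        names = self.contigs.keys() if contigs is None else contigs
        tot = 0.0
        for n in names:
            iv = self.contigs[n]
            tot += float(((iv[:, 1] - iv[:, 0]) * iv[:, 2]).sum())
        return tot

    @property
    def experimental_contigs(self) -> set[str]:
        return set(self.contigs) - self.spike_contigs


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_sgrna_library(path: str | Path) -> SgRNALibrary:
    df = _read_tsv(path, dtype=str)
    return SgRNALibrary(entries=df.iloc[:, :2].set_axis(["sgrna_id", "gene_id"], axis=1))


def read_count_table(
    path: str | Path,
    kind: str,
    meta_path: str | Path | None = None,
    library: SgRNALibrary | None = None,
) -> ScreenCounts | ExpressionMatrix:
    """Read a feature x sample count TSV plus its metadata sidecar.

    Parameters
    ----------
    kind:
        ``"sgrna"`` returns a :class:`ScreenCounts` (requires ``library`` and a
        plasmid column in the metadata); ``"gene"`` returns an
        :class:`ExpressionMatrix`.
    meta_path:
        Sidecar TSV whose first column is the sample column name. Defaults to
        ``<path stem>.meta.tsv`` next to ``path``.
    """
    if kind not in ("sgrna", "gene"):
        raise ValueError(f"kind must be 'sgrna' or 'gene', got {kind!r}")
    path = Path(path)
    counts = _read_tsv(path, index_col=0)
    if meta_path is None:
        meta_path = path.with_suffix("").with_suffix(".meta.tsv")
    meta = _read_tsv(meta_path, index_col=0)
    meta = meta.loc[list(counts.columns)] if set(counts.columns) <= set(meta.index) else meta
    if kind == "sgrna":
        if library is None:
            raise ValueError("kind='sgrna' requires the sgRNA library")
        return ScreenCounts(counts=counts, meta=meta, library=library)
    return ExpressionMatrix(counts=counts, meta=meta)


def write_count_table(
    obj: ScreenCounts | ExpressionMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    path = Path(path)
    obj.counts.to_csv(path, sep="\t")
    if meta_path is None:
        meta_path = path.with_suffix("").with_suffix(".meta.tsv")
    obj.meta.to_csv(meta_path, sep="\t")


def read_gene_annotation(path: str | Path) -> GenomicAnnotation:
    """Read a BED6+1 file: chrom, start, end, gene_id, score, strand, length."""
    df = _read_tsv(
        path,
        header=None,
        names=["contig", "start", "end", "gene_id", "score", "strand", "gene_length_bp"],
        dtype={"contig": str, "gene_id": str, "strand": str},
    )
    rec = df.set_index("gene_id")[["contig", "start", "end", "strand", "gene_length_bp"]]
    return GenomicAnnotation(records=rec)


def write_gene_annotation(anno: GenomicAnnotation, path: str | Path) -> None:
    df = anno.records.reset_index()
    out = df[["contig", "start", "end", "gene_id"]].copy()
    out["score"] = "."
    out["strand"] = df["strand"]
    out["gene_length_bp"] = df["gene_length_bp"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_coverage(path: str | Path, spike_prefix: str) -> CoverageTrack:
    """Read a bedGraph; contigs whose name starts with ``spike_prefix`` are
    flagged as exogenous spike-in reference."""
    df = _read_tsv(path, header=None, names=["contig", "start", "end", "value"], dtype={"contig": str})
    contigs: dict[str, np.ndarray] = {}
    for name, sub in df.groupby("contig", sort=False):
        iv = sub[["start", "end", "value"]].to_numpy(dtype=float)
        iv = iv[np.argsort(iv[:, 0], kind="stable")]
        contigs[name] = iv
    spikes = {c for c in contigs if c.startswith(spike_prefix)} if spike_prefix else set()
    return CoverageTrack(contigs=contigs, spike_contigs=spikes)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in track.contigs:
            iv = track.contigs[name]
            for s, e, v in iv:
                fh.write(f"{name}\t{int(s)}\t{int(e)}\t{v:.10g}\n")


def validate_file(path: str | Path, kind: str, **kw) -> str:
    """Validate a file of the given kind; returns a short summary, raises
    :class:`ValidationError` on contract violations. Used by the CLI."""
    if kind == "annotation":
        anno = read_gene_annotation(path)
        return f"annotation OK: {len(anno.records)} genes"
    if kind == "coverage":
        track = read_coverage(path, kw.get("spike_prefix", ""))
        return f"coverage OK: {len(track.contigs)} contigs, {len(track.spike_contigs)} spike"
    if kind == "library":
        lib = read_sgrna_library(path)
        return f"library OK: {len(lib)} sgRNAs, {lib.entries['gene_id'].nunique()} genes"
    if kind in ("sgrna", "gene"):
        obj = read_count_table(path, kind=kind, **kw)
        return f"counts OK: {obj.counts.shape[0]} features x {obj.counts.shape[1]} samples"
    raise ValueError(f"unknown kind {kind!r}")
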