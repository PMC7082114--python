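"""Seeded synthetic-data generators with planted ground truth.

Three generators emulate the data modalities the pipeline consumes:

* a pooled CRISPR screen (negative-binomial sgRNA counts over a plasmid pool,
  with planted essential, sensitizer and rescuer genes),
* a 12-line expression panel (6 sensitive + 6 insensitive lines, DMSO and
  treated arms, with a treatment-suppressed gene module present only in
  sensitive lines and optional baseline group differences),
* TSS-anchored ChIP-seq-like coverage whose per-gene amplitude tracks
  expression, carrying an exogenous spike-in contig at a fixed fraction of
  total signal (5%, matching the spike-in chromatin proportion used in the
  experiments being emulated).

Every generator is a pure function of (config, seed): the same pair yields
bit-identical output. Counts follow NB(mean mu, dispersion phi) with
variance ``mu + phi * mu**2``, matching the analysis model so that recovery
tests are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CoverageTrack, ExpressionMatrix, GenomicAnnotation, ScreenCounts, SgRNALibrary

__all__ = [
    "ScreenSimConfig",
    "ExpressionSimConfig",
    "CoverageSimConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_expression_panel",
    "simulate_coverage",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the synthetic chemogenomic screen.

    Defaults mirror the screen design being emulated: 10 sgRNAs per gene,
    4 (sensitive) cell lines screened with and without the compound, day-14
    readout against the initial plasmid pool, NB dispersion 0.2. Planted
    effects are in log2 units: essentials drop out in both arms, sensitizers
    deplete and rescuers enrich only under treatment.
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 10
    n_lines: int = 4
    replicates_per_arm: int = 2
    plasmid_log2_mean: float = 6.0
    plasmid_log2_sigma: float = 1.0
    dispersion: float = 0.2
    essential_fraction: float = 0.05
    essential_effect: float = -2.0
    sensitizer_fraction: float = 0.02
    sensitizer_effect: float = -1.5
    rescuer_fraction: float = 0.01
    rescuer_effect: float = 1.5
    sgrna_jitter_sd: float = 0.3
    depth_log_sigma: float = 0.1

    def __post_init__(self) -> None:
        total = self.essential_fraction + self.sensitizer_fraction + self.rescuer_fraction
        if not 0 <= total < 1:
            raise ValueError("planted fractions must be disjoint and sum below 1")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Study conditions of the synthetic 12-line expression panel.

    Six sensitive and six insensitive lines, one DMSO and one treated sample
    each. A module of ``module_size`` genes is suppressed by ``module_effect``
    log2 units in treated sensitive lines only; a ``baseline_de_fraction`` of
    genes differ 8-fold between groups in all arms. The module is planted in
    genes of above-median basal expression (the transcriptional programs it
    emulates are well-expressed), which keeps prior-count shrinkage of the
    recovered effect small.
    """

    n_genes: int = 5000
    n_sensitive: int = 6
    n_insensitive: int = 6
    module_size: int = 20
    module_effect: float = -1.0
    baseline_de_fraction: float = 0.01
    baseline_de_log2fc: float = 3.0  # 8-fold group shift
    dispersion: float = 0.1
    base_log_mean: float = float(np.log(150.0))
    base_log_sigma: float = 1.0
    depth_log_sigma: float = 0.15
    module_genes: tuple | None = None  # explicit module membership override

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module larger than the gene universe")


@dataclass(frozen=True)
class CoverageSimConfig:
    """Study conditions of the synthetic spike-in coverage tracks.

    One experimental contig per ``genes_per_contig`` genes plus one spike
    contig. Per-gene signal is a triangle decaying over ``decay_bp`` each side
    of the TSS with amplitude proportional to log2(cpm + 1); the spike contig
    carries ``spike_fraction`` (default 5%) of total expected base signal.
    ``sample_depths`` scales each sample's whole track; ``treatment_factor``
    shrinks only experimental signal of the listed samples, emulating a global
    loss of the mark under treatment.
    """

    genes_per_contig: int = 50
    gene_spacing_bp: int = 20_000
    decay_bp: int = 2_000
    step_bp: int = 50
    spike_fraction: float = 0.05
    spike_contig: str = "spike_chr"
    spike_length_bp: int = 100_000
    amplitude_per_log2cpm: float = 1.0
    noise_log_sigma: float = 0.05
    sample_depths: tuple = (("dmso", 1.0), ("treated", 1.0))
    treated_samples: tuple = ("treated",)
    treatment_factor: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted simulation effects consumed by recovery tests."""

    essential: list[str] = field(default_factory=list)
    sensitizers: list[str] = field(default_factory=list)
    rescuers: list[str] = field(default_factory=list)
    module: list[str] = field(default_factory=list)
    baseline_up: list[str] = field(default_factory=list)
    baseline_down: list[str] = field(default_factory=list)
    true_logfc: pd.DataFrame | None = None
    amplitudes: pd.Series | None = None


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, phi) draws with variance mu + phi*mu^2 (gamma-Poisson mixture)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_screen(config: ScreenSimConfig, seed: int) -> tuple[ScreenCounts, GroundTruth]:
    """Generate sgRNA counts for a chemogenomic dropout screen.

    Per-sgRNA day-14 expected counts are ``plasmid_abundance * 2**(gene
    effect + sgRNA jitter) * arm effect`` scaled by a log-normal sample depth;
    the plasmid column is an NB draw around the abundances themselves.
    """
    rng = np.random.default_rng(seed)
    c = config
    genes = [f"g{i:05d}" for i in range(c.n_genes)]
    perm = rng.permutation(c.n_genes)
    n_ess = round(c.essential_fraction * c.n_genes)
    n_sen = round(c.sensitizer_fraction * c.n_genes)
    n_res = round(c.rescuer_fraction * c.n_genes)
    essential = [genes[i] for i in perm[:n_ess]]
    sensitizers = [genes[i] for i in perm[n_ess : n_ess + n_sen]]
    rescuers = [genes[i] for i in perm[n_ess + n_sen : n_ess + n_sen + n_res]]

    sgrnas = [f"{g}_sg{j}" for g in genes for j in range(c.sgrnas_per_gene)]
    lib = SgRNALibrary(
        entries=pd.DataFrame(
            {"sgrna_id": sgrnas, "gene_id": np.repeat(genes, c.sgrnas_per_gene)}
        )
    )
    n_sg = len(sgrnas)
    abundance = rng.lognormal(c.plasmid_log2_mean * LN2, c.plasmid_log2_sigma * LN2, n_sg)
    jitter = rng.normal(0.0, c.sgrna_jitter_sd, n_sg)

    dropout = pd.Series(0.0, index=genes)
    dropout[essential] = c.essential_effect
    arm_extra = pd.Series(0.0, index=genes)
    arm_extra[sensitizers] = c.sensitizer_effect
    arm_extra[rescuers] = c.rescuer_effect
    per_sg_drop = np.repeat(dropout.to_numpy(), c.sgrnas_per_gene)
    per_sg_arm = np.repeat(arm_extra.to_numpy(), c.sgrnas_per_gene)

    cols, meta_rows = {}, []
    cols["plasmid"] = _nb(rng, abundance, c.dispersion)
    meta_rows.append(("plasmid", "pool", "plasmid", 0, 0))
    for i in range(c.n_lines):
        line = f"line_{i + 1}"
        for arm in ("dmso", "treated"):
            for rep in range(1, c.replicates_per_arm + 1):
                depth = rng.lognormal(0.0, c.depth_log_sigma)
                eff = per_sg_drop + jitter + (per_sg_arm if arm == "treated" else 0.0)
                mean = abundance * 2.0**eff * depth
                name = f"{line}_{arm}_r{rep}"
                cols[name] = _nb(rng, mean, c.dispersion)
                meta_rows.append((name, line, arm, 14, rep))

    counts = pd.DataFrame(cols, index=sgrnas)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "cell_line", "arm", "day", "replicate"]
    ).set_index("sample")
    truth = GroundTruth(
        essential=essential,
        sensitizers=sensitizers,
        rescuers=rescuers,
        true_logfc=pd.DataFrame({"dropout": dropout, "treated_extra": arm_extra}),
    )
    return ScreenCounts(counts=counts, meta=meta, library=lib), truth


def simulate_expression_panel(
    config: ExpressionSimConfig, seed: int
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the 12-line expression panel with a planted responsive module."""
    rng = np.random.default_rng(seed)
    c = config
    genes = [f"g{i:05d}" for i in range(c.n_genes)]
    base = rng.lognormal(c.base_log_mean, c.base_log_sigma, c.n_genes)

    if c.module_genes is not None:
        missing = [g for g in c.module_genes if g not in genes]
        if missing:
            raise ValueError(f"module gene(s) outside the universe: {missing[:3]}")
        module = list(c.module_genes)
        module_idx = np.array([genes.index(g) for g in module])
    else:
        eligible = np.flatnonzero(base >= np.median(base))
        module_idx = rng.choice(eligible, size=c.module_size, replace=False)
        module = [genes[i] for i in module_idx]
    remaining = np.setdiff1d(np.arange(c.n_genes), module_idx)
    n_de = round(c.baseline_de_fraction * c.n_genes)
    de_idx = rng.choice(remaining, size=n_de, replace=False)
    up_idx, down_idx = de_idx[: n_de // 2], de_idx[n_de // 2 :]
    baseline_shift = np.zeros(c.n_genes)
    baseline_shift[up_idx] = c.baseline_de_log2fc  # higher in sensitive lines
    baseline_shift[down_idx] = -c.baseline_de_log2fc
    module_mask = np.zeros(c.n_genes, dtype=bool)
    module_mask[module_idx] = True

    lines = [f"sens_{i + 1}" for i in range(c.n_sensitive)] + [
        f"ins_{i + 1}" for i in range(c.n_insensitive)
    ]
    groups = ["sensitive"] * c.n_sensitive + ["insensitive"] * c.n_insensitive
    cols, meta_rows = {}, []
    for line, group in zip(lines, groups):
        for treatment in ("dmso", "treated"):
            depth = rng.lognormal(0.0, c.depth_log_sigma)
            eff = np.zeros(c.n_genes)
            if group == "sensitive":
                eff = eff + baseline_shift
                if treatment == "treated":
                    eff = eff + np.where(module_mask, c.module_effect, 0.0)
            mean = base * 2.0**eff * depth
            name = f"{line}_{treatment}"
            cols[name] = _nb(rng, mean, c.dispersion)
            meta_rows.append((name, line, group, treatment, 1))

    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "cell_line", "group", "treatment", "replicate"]
    ).set_index("sample")
    truth = GroundTruth(
        module=module,
        baseline_up=[genes[i] for i in up_idx],
        baseline_down=[genes[i] for i in down_idx],
        true_logfc=pd.DataFrame(
            {"module_effect": np.where(module_mask, c.module_effect, 0.0)}, index=genes
        ),
    )
    return ExpressionMatrix(counts=counts, meta=meta), truth


def _triangle_steps(
    tss: int, amp: float, decay: int, step: int
) -> list[tuple[int, int, float]]:
    """Step-function intervals of a triangular peak centered on the TSS."""
    out = []
    for s in range(tss - decay, tss + decay, step):
        center = s + step / 2
        v = amp * max(0.0, 1.0 - abs(center - tss) / decay)
        if v > 0:
            out.append((s, s + step, v))
    return out


def simulate_coverage(
    config: CoverageSimConfig, expression_cpm: pd.Series, seed: int
) -> tuple[dict[str, CoverageTrack], GenomicAnnotation, GroundTruth]:
    """Generate per-sample spike-in coverage tracks over a synthetic genome.

    Returns one track per configured sample, the gene annotation laying the
    genes out on contigs (alternating strands), and the planted per-gene
    amplitudes. Per-sample tracks share one base track: depth scales
    everything, the treatment factor scales experimental contigs only.
    """
    if (expression_cpm <= 0).all():
        raise ValueError("expression vector is all zero")
    rng = np.random.default_rng(seed)
    c = config
    genes = list(expression_cpm.index)
    amps = pd.Series(
        c.amplitude_per_log2cpm * np.log2(expression_cpm.to_numpy(dtype=float) + 1.0),
        index=genes,
    )

    records, base_intervals = [], {}
    margin = c.gene_spacing_bp // 2
    for ci in range(0, len(genes), c.genes_per_contig):
        contig = f"chr{ci // c.genes_per_contig + 1}"
        chunk = genes[ci : ci + c.genes_per_contig]
        iv: list[tuple[int, int, float]] = []
        for k, g in enumerate(chunk):
            strand = "+" if k % 2 == 0 else "-"
            tss = margin + k * c.gene_spacing_bp
            start, end = (tss, tss + 1500) if strand == "+" else (tss - 1499, tss + 1)
            records.append((g, contig, start, end, strand, 1500))
            noise = rng.lognormal(0.0, c.noise_log_sigma)
            iv.extend(_triangle_steps(tss, amps[g] * noise, c.decay_bp, c.step_bp))
        # tail pad so every window of the last gene stays inside the extent
        extent = margin + len(chunk) * c.gene_spacing_bp
        iv.append((extent - 1, extent, 1e-9))
        base_intervals[contig] = np.array(sorted(iv), dtype=float)

    anno = GenomicAnnotation(
        records=pd.DataFrame(
            records, columns=["gene_id", "contig", "start", "end", "strand", "gene_length_bp"]
        ).set_index("gene_id")
    )

    exp_total = sum(
        float(((iv[:, 1] - iv[:, 0]) * iv[:, 2]).sum()) for iv in base_intervals.values()
    )
    spike_total = c.spike_fraction / (1.0 - c.spike_fraction) * exp_total
    spike_value = spike_total / c.spike_length_bp

    tracks = {}
    for sample, depth in c.sample_depths:
        tf = c.treatment_factor if sample in c.treated_samples else 1.0
        contigs = {
            name: np.column_stack([iv[:, 0], iv[:, 1], iv[:, 2] * depth * tf])
            for name, iv in base_intervals.items()
        }
        contigs[c.spike_contig] = np.array(
            [[0.0, float(c.spike_length_bp), spike_value * depth]]
        )
        tracks[sample] = CoverageTrack(contigs=contigs, spike_contigs={c.spike_contig})
    truth = GroundTruth(amplitudes=amps)
    return tracks, anno, truth
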