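"""Synthetic genomes, planted sRNA truth sets, simulated alignments, count
matrices and CT tables.

The generator emulates the study design the pipeline targets: a small
bacterial chromosome with non-overlapping annotated genes, planted sRNA loci
of the three positional classes (antisense, UTR-proximal, intergenic), five
fermentation sampling phases T0–T4 with three biological replicates each,
negative-binomial read counts with planted fold changes, perfect ungapped
single-end alignments, and qPCR CT tables with a constant-CT 16S-like
reference gene.

Planted effect model
--------------------
A fraction ``fraction_de`` of planted loci carry a true effect.  Over the
comparison phases (T1..T4 by default) an affected locus follows a log2 ramp
with step ``planted_log2fc``: up-regulated loci have per-phase offsets
(0, Δ, 2Δ, 3Δ), down-regulated loci the reverse.  Every pairwise comparison
of those phases therefore carries a true fold change of at least |2^Δ|, so
affected loci are "always-DE" (the planted core set), and adjacent-phase
comparisons carry exactly |Δ|.  Up and down loci alternate so that library
composition stays balanced across phases.  Pre-comparison phases (T0) sit at
the first ramp value.

Reproducibility: one seed governs everything through named substreams (one
independent generator per stage), so any stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .expression import CountMatrix
from .io import GeneFeature

_BASES = np.array(list("ACGT"))

# fixed substream indices per generator stage
_STAGES = {"genome": 0, "loci": 1, "alignments": 2, "counts": 3, "ct": 4,
           "effects": 5, "extras": 6}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the targeted design: 5 sampling phases × 3 biological
    replicates, 20 planted loci per positional class, sRNA lengths within the
    50–400 nt prior (drawn 50–150 here so every locus fits its placement
    window), per-locus depth around 50 reads, a 2-unit log2 planted effect.
    """

    seed: int = 0
    genome_length: int = 120_000
    n_genes: int = 40
    n_planted_per_class: int = 20
    srna_length_range: tuple[int, int] = (50, 150)
    read_depth_per_locus: float = 50.0
    nb_dispersion: float = 0.05
    n_phases: int = 5
    n_replicates: int = 3
    planted_log2fc: float = 2.0
    fraction_de: float = 0.5
    read_length: int = 50
    background_depth_per_gene: float = 20.0
    #: expected per-sample reads mapping outside candidate loci (rRNA leftovers,
    #: known RNAs, coding fragments); candidate sRNAs are a small share of a
    #: real library, and this ballast keeps CPM denominators stable
    library_background_reads: float = 1_000_000.0
    gene_length_range: tuple[int, int] = (600, 1100)
    contig: str = "chr"
    ct_reference_gene: str = "16S"
    ct_reference_ct: float = 15.0
    ct_base_delta_ct: float = 8.0
    ct_noise_sd: float = 0.0  # 0 = noiseless (exact 2^-ΔΔCT recovery)

    def __post_init__(self) -> None:
        lo, hi = self.srna_length_range
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not (20 <= lo <= hi <= 500):
            raise ValueError("srna_length_range must lie within [20, 500]")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (0 <= self.fraction_de <= 1):
            raise ValueError("fraction_de must be in [0, 1]")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")

    @property
    def phases(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_phases)]

    @property
    def comparison_phases(self) -> list[str]:
        """Post-lag phases used for pairwise comparisons (all but the first)."""
        return self.phases[1:]

    @property
    def min_gene_gap(self) -> int:
        # room for a 500-nt UTR window on each side plus a planted intergenic
        # locus of any configured length, with margin; never below 1100
        return max(1100, 1000 + self.srna_length_range[1] + 100)

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream: an independent generator per pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGES[stage],))
        )


@dataclass
class PlantedLocus:
    """Ground-truth sRNA locus with its class and per-comparison effect."""

    locus_id: str
    contig: str
    start: int
    end: int
    strand: str
    true_class: str
    anchor_gene: str = ""
    is_expressed: bool = True
    is_de: bool = False
    direction: int = 0  # +1 ramp up, -1 ramp down, 0 null
    phase_log2_offset: dict[str, float] = field(default_factory=dict)
    true_log2fc_by_comparison: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def mean_depth(self, phase: str, base_depth: float) -> float:
        return base_depth * 2.0 ** self.phase_log2_offset.get(phase, 0.0)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[GeneFeature]]:
    """Random genome plus non-overlapping gene features on both strands.

    Genes are laid out left to right separated by intergenic gaps of at least
    ``config.min_gene_gap`` (>= 1100) bases; strands alternate so both are
    always represented.  Deterministic for a fixed seed.
    """
    rng = config.rng("genome")
    glo, ghi = config.gene_length_range
    gap = config.min_gene_gap
    worst = config.n_genes * ghi + (config.n_genes + 1) * gap
    if worst > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} cannot fit n_genes={config.n_genes} "
            f"genes of up to {ghi} bp with {gap}-bp gaps (needs {worst} bp); "
            "increase genome_length or decrease n_genes"
        )
    seq = "".join(rng.choice(_BASES, size=config.genome_length))
    genes: list[GeneFeature] = []
    pos = gap + 1  # 1-based start of the first gene
    for i in range(config.n_genes):
        length = int(rng.integers(glo, ghi + 1))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneFeature(
                gene_id=f"gene{i + 1:04d}",
                contig=config.contig,
                start=pos,
                end=pos + length - 1,
                strand=strand,
                biotype="protein_coding",
            )
        )
        pos += length + gap
    return {config.contig: seq}, genes


# ---------------------------------------------------------------------------
# Planted loci
# ---------------------------------------------------------------------------

def _assign_effects(loci: list[PlantedLocus], config: SimulationConfig) -> None:
    """Mark a deterministic fraction of loci as affected and give them the
    ramp effect profile described in the module docstring."""
    rng = config.rng("effects")
    n_de = int(round(config.fraction_de * len(loci)))
    de_idx = sorted(rng.choice(len(loci), size=n_de, replace=False)) if n_de else []
    comp_phases = config.comparison_phases
    delta = config.planted_log2fc
    for j, idx in enumerate(de_idx):
        locus = loci[idx]
        locus.is_de = True
        locus.direction = 1 if j % 2 == 0 else -1
        m = len(comp_phases)
        for k, phase in enumerate(comp_phases):
            step = k if locus.direction > 0 else (m - 1 - k)
            locus.phase_log2_offset[phase] = delta * step
        # pre-comparison phases sit at the first ramp value
        first = locus.phase_log2_offset[comp_phases[0]]
        for phase in config.phases:
            locus.phase_log2_offset.setdefault(phase, first)
    for locus in loci:
        if not locus.is_de:
            for phase in config.phases:
                locus.phase_log2_offset[phase] = 0.0
        for (pa, pb) in _pairs(comp_phases):
            locus.true_log2fc_by_comparison[(pa, pb)] = (
                locus.phase_log2_offset[pb] - locus.phase_log2_offset[pa]
            )


def _pairs(phases: Sequence[str]) -> list[tuple[str, str]]:
    return [(phases[i], phases[j]) for i in range(len(phases)) for j in range(i + 1, len(phases))]


def plant_srna_loci(
    genes: Sequence[GeneFeature], config: SimulationConfig
) -> list[PlantedLocus]:
    """Plant ``n_planted_per_class`` truth loci per positional class.

    Antisense loci lie strictly inside a gene on the opposite strand; UTR loci
    sit on the same strand as their anchor gene within 500 nt of its edge
    without overlapping any gene; intergenic loci keep more than 500 nt clear
    of every gene on both sides.  The three classes are disjoint by
    construction, which makes class recovery an exact test downstream.
    """
    rng = config.rng("loci")
    lo, hi = config.srna_length_range
    n = config.n_planted_per_class
    genes = sorted(genes, key=lambda g: g.start)
    contig = config.contig
    loci: list[PlantedLocus] = []

    # antisense: inside a gene, opposite strand, round-robin over genes
    eligible = [g for g in genes if g.length >= hi + 2]
    if n > 0 and not eligible:
        raise ValueError("annotation too dense to place class antisense: no gene long enough")
    for i in range(n):
        g = eligible[i % len(eligible)]
        length = int(rng.integers(lo, hi + 1))
        # strictly inside: start >= gene start + 1 and end <= gene end - 1
        start = int(rng.integers(g.start + 1, g.end - length + 1))
        loci.append(
            PlantedLocus(
                locus_id=f"anti{i + 1:03d}",
                contig=contig,
                start=start,
                end=start + length - 1,
                strand="-" if g.strand == "+" else "+",
                true_class="antisense",
                anchor_gene=g.gene_id,
            )
        )

    # utr: within 500 nt downstream (genomic right) of the anchor gene, on
    # the gene's own strand; the inter-gene gap guarantees the next gene is
    # far enough away that the anchor stays nearest
    if n > len(genes):
        raise ValueError(
            f"annotation too dense to place class utr: {n} loci need {n} anchor genes, "
            f"only {len(genes)} available"
        )
    for i in range(n):
        g = genes[i % len(genes)]
        length = int(rng.integers(lo, hi + 1))
        max_gap = 500 - length  # whole locus within the 500-nt window
        d = int(rng.integers(0, max_gap + 1))
        start = g.end + 1 + d
        loci.append(
            PlantedLocus(
                locus_id=f"utr{i + 1:03d}",
                contig=contig,
                start=start,
                end=start + length - 1,
                strand=g.strand,
                true_class="utr",
                anchor_gene=g.gene_id,
            )
        )

    # intergenic: centre region of an interior gap, >500 nt from both genes;
    # one locus per gap
    gaps = [
        (genes[i].end, genes[i + 1].start) for i in range(len(genes) - 1)
    ]
    usable = [(a, b) for a, b in gaps if (b - a - 1) >= 1002 + hi]
    if n > len(usable):
        raise ValueError(
            f"annotation too dense to place class intergenic: {n} loci, "
            f"{len(usable)} usable gaps"
        )
    for i in range(n):
        a, b = usable[i]
        length = int(rng.integers(lo, hi + 1))
        # strictly more than 500 nt clear of both flanking genes
        left = a + 502
        right = b - 502 - length + 1
        start = int(rng.integers(left, right + 1))
        loci.append(
            PlantedLocus(
                locus_id=f"igr{i + 1:03d}",
                contig=contig,
                start=start,
                end=start + length - 1,
                strand="+" if i % 2 == 0 else "-",
                true_class="intergenic",
            )
        )

    _assign_effects(loci, config)
    return loci


def truth_table(loci: Sequence[PlantedLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "contig": l.contig,
                "start": l.start,
                "end": l.end,
                "strand": l.strand,
                "true_class": l.true_class,
                "anchor_gene": l.anchor_gene,
                "is_expressed": l.is_expressed,
                "is_de": l.is_de,
                "direction": l.direction,
            }
            for l in loci
        ]
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def simulate_alignments(
    loci: Sequence[PlantedLocus],
    genes: Sequence[GeneFeature],
    genome: Mapping[str, str],
    config: SimulationConfig,
    path: str | Path,
    phase: Optional[str] = None,
    counts_override: Optional[Mapping[str, int]] = None,
) -> dict[str, int]:
    """Write simulated single-end alignments for one library to a SAM file.

    Per expressed locus the read count is Poisson around
    ``read_depth_per_locus`` scaled by 2^(true effect) in the given phase
    (``counts_override`` pins exact counts per locus id).  Reads are perfect
    ungapped full matches on the locus strand, tiled evenly across the locus
    so coverage is gap-free and the cluster span equals the locus span.
    Background reads are also emitted inside each protein-coding gene on its
    own strand, to exercise the coding-read filter.  Returns the per-locus
    read counts actually emitted.
    """
    rng = config.rng("alignments")
    contig = config.contig
    contig_len = len(genome[contig])
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": contig_len}],
    }
    emitted: dict[str, int] = {}
    serial = 0

    def make_read(name: str, start0: int, length: int, strand: str) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment()
        a.query_name = name
        seq = genome[contig][start0 : start0 + length]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        a.query_sequence = seq
        a.flag = 16 if strand == "-" else 0
        a.reference_id = 0
        a.reference_start = start0
        a.mapping_quality = 60
        a.cigarstring = f"{length}M"
        return a

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for locus in loci:
            if counts_override is not None and locus.locus_id in counts_override:
                count = int(counts_override[locus.locus_id])
            elif not locus.is_expressed:
                count = 0
            else:
                mean = locus.mean_depth(phase, config.read_depth_per_locus) if phase \
                    else config.read_depth_per_locus
                count = int(rng.poisson(mean))
            emitted[locus.locus_id] = count
            if count == 0:
                continue
            rl = min(config.read_length, locus.length)
            span = locus.length - rl
            for i in range(count):
                # even tiling: first read at the locus start, last ending at
                # the locus end, consecutive reads overlapping
                offset = round(i * span / (count - 1)) if count > 1 else 0
                serial += 1
                out.write(
                    make_read(f"r{serial:07d}_{locus.locus_id}",
                              locus.start - 1 + offset, rl, locus.strand)
                )
        for gene in genes:
            if gene.biotype != "protein_coding":
                continue
            count = int(rng.poisson(config.background_depth_per_gene))
            rl = min(config.read_length, gene.length)
            for _ in range(count):
                start0 = int(rng.integers(gene.start - 1, gene.end - rl + 1))
                serial += 1
                out.write(make_read(f"r{serial:07d}_bg", start0, rl, gene.strand))
    return emitted


# ---------------------------------------------------------------------------
# Counts and CT tables
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_count_matrix(
    loci: Sequence[PlantedLocus], config: SimulationConfig
) -> CountMatrix:
    """Negative-binomial counts per locus per (phase, replicate).

    Means are ``read_depth_per_locus * 2^(phase offset)``; dispersion is
    ``nb_dispersion`` (0 reduces to Poisson).  Unexpressed loci draw zeros.
    """
    rng = config.rng("counts")
    phases = config.phases
    cols = [f"{p}_{r + 1}" for p in phases for r in range(config.n_replicates)]
    means = np.zeros((len(loci), len(cols)))
    for i, locus in enumerate(loci):
        if not locus.is_expressed:
            continue
        for j, col in enumerate(cols):
            phase = col.rpartition("_")[0]
            means[i, j] = locus.mean_depth(phase, config.read_depth_per_locus)
    values = _nb_draw(rng, means, config.nb_dispersion)
    counts = pd.DataFrame(values, index=[l.locus_id for l in loci], columns=cols)
    counts.index.name = "srna_id"
    # library size = candidate counts plus the non-candidate library mass
    background = rng.poisson(config.library_background_reads, size=len(cols))
    library_sizes = counts.sum(axis=0) + pd.Series(background, index=cols)
    return CountMatrix(counts, library_sizes.astype(float))


def simulate_ct_table(
    loci: Sequence[PlantedLocus],
    config: SimulationConfig,
    n_technical: int = 3,
) -> pd.DataFrame:
    """CT table (sample, gene, ct) with a constant-CT reference per sample.

    The reference gene (16S-like) has CT ``ct_reference_ct`` in every sample;
    target ΔCT starts at ``ct_base_delta_ct`` in the calibrator (first phase)
    and *decreases* by the locus's true log2 offset in later phases, so the
    2^-ΔΔCT method recovers exactly 2^(planted effect).  With
    ``ct_noise_sd > 0`` Gaussian noise of that SD (cycles) is added to every
    CT value.
    """
    rng = config.rng("ct")
    rows = []
    for phase in config.phases:
        sample = phase
        for _ in range(n_technical):
            ct = config.ct_reference_ct
            if config.ct_noise_sd > 0:
                ct += rng.normal(0, config.ct_noise_sd)
            rows.append({"sample": sample, "gene": config.ct_reference_gene, "ct": ct})
        for locus in loci:
            base = locus.phase_log2_offset.get(config.phases[0], 0.0)
            delta_ct = config.ct_base_delta_ct - (
                locus.phase_log2_offset.get(phase, 0.0) - base
            )
            for _ in range(n_technical):
                ct = config.ct_reference_ct + delta_ct
                if config.ct_noise_sd > 0:
                    ct += rng.normal(0, config.ct_noise_sd)
                rows.append({"sample": sample, "gene": locus.locus_id, "ct": ct})
    return pd.DataFrame(rows, columns=["sample", "gene", "ct"])


def make_null_loci(n: int, prefix: str = "null") -> list[PlantedLocus]:
    """Cheap loci without genome placement, for count-level simulations
    (e.g. calibration of the differential-expression test under the null)."""
    return [
        PlantedLocus(
            locus_id=f"{prefix}{i + 1:05d}",
            contig="none",
            start=1,
            end=100,
            strand="+",
            true_class="intergenic",
        )
        for i in range(n)
    ]


def simulate_null_counts(n_loci: int, config: SimulationConfig) -> CountMatrix:
    """Count matrix for ``n_loci`` loci with no true effect anywhere."""
    loci = make_null_loci(n_loci)
    cfg = replace(config, fraction_de=0.0)
    _assign_effects(loci, cfg)
    return simulate_count_matrix(loci, cfg)
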