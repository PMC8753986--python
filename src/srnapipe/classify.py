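"""Positional classification of candidate sRNAs.

Each candidate gets exactly one class relative to the gene annotation:

``antisense``
    overlaps at least one base of a gene on the opposite strand — bacterial
    asRNAs are cis-encoded and fully complementary to their target transcript;
``utr``
    on the same strand as a gene and within the UTR window (500 nt by
    default) of its edge, or partially overlapping the gene body itself —
    the 5'/3' untranslated-region-derived class;
``intergenic``
    everything else — the classic trans-encoded sRNA class.

Precedence is antisense > utr > intergenic: overlap on the opposite strand is
the stronger, unambiguous condition, proximity the weaker one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .io import GeneFeature, STRANDS

CLASSES = ("antisense", "intergenic", "utr")


@dataclass
class SrnaCandidate:
    """A discovered sRNA candidate with its positional class."""

    contig: str
    start: int  # 1-based inclusive, start <= end
    end: int
    strand: str
    srna_id: str = ""
    positional_class: str = ""
    anchor_gene: str = ""
    sequence: str = ""
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"candidate interval ({self.start}, {self.end}) inverted")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClassifierParams:
    utr_window: int = 500  # nt up/downstream of a gene that counts as UTR
    require_same_strand_utr: bool = True

    def __post_init__(self) -> None:
        if self.utr_window < 0:
            raise ValueError("utr_window must be >= 0")


class AnnotationIndex:
    """Strand-aware interval index over gene features for one annotation."""

    def __init__(self, genes: Sequence[GeneFeature]):
        self.genes = list(genes)
        self.contigs = {g.contig for g in self.genes}
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in self.genes:
            # interval tree is half-open; store [start, end+1)
            self._trees[g.contig].addi(g.start, g.end + 1, g)

    def overlapping(self, contig: str, start: int, end: int) -> list[GeneFeature]:
        return [iv.data for iv in self._trees[contig].overlap(start, end + 1)]

    def genes_on(self, contig: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.contig == contig]


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def _gap(start: int, end: int, gene: GeneFeature) -> int:
    """Distance in bases between an interval and a gene edge; 0 on overlap."""
    if end < gene.start:
        return gene.start - end - 1
    if start > gene.end:
        return start - gene.end - 1
    return 0


def classify_candidate(
    candidate: SrnaCandidate,
    index: AnnotationIndex | Sequence[GeneFeature],
    params: ClassifierParams = ClassifierParams(),
) -> tuple[str, str]:
    """Classify one candidate interval; returns ``(positional_class, anchor_gene)``.

    Tie-breaks are deterministic: antisense anchors prefer greatest overlap,
    then the gene whose start is nearest the candidate start, then the
    leftmost gene; UTR anchors prefer the smallest gap, then the leftmost gene.
    """
    if not isinstance(index, AnnotationIndex):
        index = AnnotationIndex(index)
    if candidate.contig not in index.contigs:
        raise ValueError(
            f"candidate contig {candidate.contig!r} absent from the annotation"
        )
    s, e = candidate.start, candidate.end

    hits = index.overlapping(candidate.contig, s, e)
    anti = [g for g in hits if g.strand != candidate.strand]
    if anti:
        best = min(
            anti,
            key=lambda g: (
                -_overlap_len(s, e, g.start, g.end),
                abs(g.start - s),
                g.start,
            ),
        )
        return "antisense", best.gene_id

    same = [g for g in index.genes_on(candidate.contig)
            if not params.require_same_strand_utr or g.strand == candidate.strand]
    if same:
        best = min(same, key=lambda g: (_gap(s, e, g), g.start))
        if _gap(s, e, best) <= params.utr_window:
            return "utr", best.gene_id
    return "intergenic", ""


def classify_all(
    candidates: Iterable[SrnaCandidate],
    genes: Sequence[GeneFeature],
    params: ClassifierParams = ClassifierParams(),
) -> list[SrnaCandidate]:
    """Classify every candidate in place (returns the same objects, updated)."""
    index = AnnotationIndex(genes)
    out = []
    for c in candidates:
        cls, anchor = classify_candidate(c, index, params)
        c.positional_class = cls
        c.anchor_gene = anchor
        out.append(c)
    return out


@dataclass
class ClassificationSummary:
    counts: dict[str, int]
    total: int
    candidates: list[SrnaCandidate] = field(default_factory=list)


def summarize_classification(
    candidates: Sequence[SrnaCandidate], id_prefix: str = "sts"
) -> ClassificationSummary:
    """Tally classes and assign stable ``sts``-style IDs in genome order.

    IDs are assigned in ``(contig, start)`` order as sts001, sts002, …
    (zero-padded to at least three digits), so reruns over the same candidate
    set produce identical names.  Raises if any candidate is unclassified.
    """
    for c in candidates:
        if c.positional_class not in CLASSES:
            raise ValueError(f"unclassified candidate at {c.contig}:{c.start}-{c.end}")
    ordered = sorted(candidates, key=lambda c: (c.contig, c.start, c.end, c.strand))
    width = max(3, len(str(len(ordered))))
    for i, c in enumerate(ordered, start=1):
        c.srna_id = f"{id_prefix}{i:0{width}d}"
    counts = {cls: 0 for cls in CLASSES}
    for c in ordered:
        counts[c.positional_class] += 1
    return ClassificationSummary(counts=counts, total=len(ordered), candidates=ordered)
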