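"""Candidate sRNA discovery from strand-specific alignments.

The discovery chain is: remove reads that belong to coding transcripts
(same-strand overlap with a protein-coding gene), merge the surviving reads
into strand-aware coverage clusters, keep clusters with copy number strictly
greater than 10 that are not already explained by a known RNA family, enforce
the small-RNA length bounds, and finally collapse near-identical sequences
(paralogous loci) with a seed-and-extend similarity rule equivalent to a
Megablast screen at word length 26 and 90% identity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io import AlignedRead, GeneFeature, KnownRnaHit


@dataclass
class CoverageCluster:
    """A contiguous transcribed region on one strand.

    ``read_count`` is the cluster's copy number — the (weight) sum of member
    reads — the quantity the copy-number filter applies to.
    """

    contig: str
    start: int
    end: int
    strand: str
    read_count: int
    max_depth: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DiscoveryParams:
    min_copy_number: int = 11  # strictly > 10 reads
    min_length: int = 50
    max_length: int = 500
    max_join_gap: int = 0  # reads must overlap or abut to merge
    coding_overlap_discard_fraction: float = 0.5
    known_overlap_fraction: float = 0.5
    dedup_word_length: int = 26
    dedup_identity_cutoff: float = 0.90

    def __post_init__(self) -> None:
        if not (self.min_length <= self.max_length <= 500):
            raise ValueError("need min_length <= max_length <= 500")
        if not (0 < self.dedup_identity_cutoff <= 1):
            raise ValueError("dedup_identity_cutoff must be in (0, 1]")
        if self.dedup_word_length < 4:
            raise ValueError("dedup_word_length must be >= 4")


def _overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def filter_coding_reads(
    reads: Iterable[AlignedRead],
    genes: Sequence[GeneFeature],
    discard_fraction: float = 0.5,
) -> tuple[list[AlignedRead], int]:
    """Split reads into non-coding signal and coding background.

    A read is *coding* iff at least ``discard_fraction`` of its length
    overlaps a protein-coding gene on the **same** strand.  Opposite-strand
    overlaps are retained deliberately: they are the antisense-RNA signal.

    Returns ``(noncoding_reads, n_coding_removed)``.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        if g.biotype == "protein_coding":
            trees[(g.contig, g.strand)].addi(g.start, g.end + 1, g)

    noncoding: list[AlignedRead] = []
    n_coding = 0
    for r in reads:
        tree = trees.get((r.contig, r.strand))
        best = 0
        if tree is not None:
            for iv in tree.overlap(r.start, r.end + 1):
                g = iv.data
                best = max(best, _overlap_len(r.start, r.end, g.start, g.end))
        if best >= discard_fraction * r.length:
            n_coding += 1
        else:
            noncoding.append(r)
    return noncoding, n_coding


def build_clusters(
    reads: Iterable[AlignedRead], params: DiscoveryParams = DiscoveryParams()
) -> list[CoverageCluster]:
    """Merge reads into coverage clusters per (contig, strand).

    Reads whose intervals overlap or lie within ``max_join_gap`` bases of each
    other are merged transitively; the cluster interval is the union span,
    ``read_count`` the weight sum of members, and ``max_depth`` the maximum
    per-base read depth inside the cluster.
    """
    by_key: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for r in reads:
        by_key[(r.contig, r.strand)].append(r)

    clusters: list[CoverageCluster] = []
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.start, r.end))
        current: list[AlignedRead] = []
        cur_end = None
        for r in group:
            if current and r.start > cur_end + 1 + params.max_join_gap:
                clusters.append(_finish_cluster(contig, strand, current))
                current = []
                cur_end = None
            current.append(r)
            cur_end = r.end if cur_end is None else max(cur_end, r.end)
        if current:
            clusters.append(_finish_cluster(contig, strand, current))
    clusters.sort(key=lambda c: (c.contig, c.strand, c.start))
    return clusters


def _finish_cluster(contig: str, strand: str, members: list[AlignedRead]) -> CoverageCluster:
    start = min(r.start for r in members)
    end = max(r.end for r in members)
    # sweep-line max depth over member intervals, weighted
    events: dict[int, int] = defaultdict(int)
    for r in members:
        events[r.start] += r.weight
        events[r.end + 1] -= r.weight
    depth = 0
    max_depth = 0
    for pos in sorted(events):
        depth += events[pos]
        max_depth = max(max_depth, depth)
    return CoverageCluster(
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        read_count=sum(r.weight for r in members),
        max_depth=max_depth,
    )


def select_candidates(
    clusters: Sequence[CoverageCluster],
    known_hits: Sequence[KnownRnaHit] = (),
    params: DiscoveryParams = DiscoveryParams(),
) -> tuple[list[CoverageCluster], list[CoverageCluster], dict[str, int]]:
    """Apply the copy-number, known-RNA and length filters.

    Clusters with copy number below ``min_copy_number`` (i.e. <= 10 at the
    default) are dropped; clusters covered >= ``known_overlap_fraction`` of
    their length by a same-strand known-RNA hit are routed to the *annotated*
    list (reported, not candidates); remaining clusters outside
    ``[min_length, max_length]`` are dropped.  Returns
    ``(novel, annotated, stats)`` where stats record the count removed at
    each filter.
    """
    known_trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for h in known_hits:
        known_trees[(h.contig, h.strand)].addi(h.start, h.end + 1, h)

    novel: list[CoverageCluster] = []
    annotated: list[CoverageCluster] = []
    stats = {"dropped_by_copy": 0, "annotated": 0, "dropped_by_length": 0, "novel": 0}
    for c in clusters:
        if c.read_count < params.min_copy_number:
            stats["dropped_by_copy"] += 1
            continue
        tree = known_trees.get((c.contig, c.strand))
        covered = 0
        if tree is not None:
            for iv in tree.overlap(c.start, c.end + 1):
                h = iv.data
                covered = max(covered, _overlap_len(c.start, c.end, h.start, h.end))
        if covered >= params.known_overlap_fraction * c.length:
            stats["annotated"] += 1
            annotated.append(c)
            continue
        if not (params.min_length <= c.length <= params.max_length):
            stats["dropped_by_length"] += 1
            continue
        stats["novel"] += 1
        novel.append(c)
    return novel, annotated, stats


# ---------------------------------------------------------------------------
# Seed-and-extend deduplication
# ---------------------------------------------------------------------------

@dataclass
class DedupComponent:
    """One similarity component: a representative cluster plus the members it
    absorbed."""

    representative: CoverageCluster
    members: list[CoverageCluster] = field(default_factory=list)  # incl. representative


def cluster_sequence(cluster: CoverageCluster, genome: dict[str, str]) -> str:
    """Extract the strand-oriented sequence of a cluster from the genome."""
    contig_seq = genome[cluster.contig]
    if cluster.end > len(contig_seq) or cluster.start < 1:
        raise ValueError(
            f"cluster {cluster.contig}:{cluster.start}-{cluster.end} "
            f"extends past the contig end ({len(contig_seq)} bp)"
        )
    seq = contig_seq[cluster.start - 1 : cluster.end]
    if cluster.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def seeded_identity(a: str, b: str, word_length: int) -> float:
    """Best ungapped identity between two sequences over any alignment offset
    anchored at a shared exact word of ``word_length``.

    For every pair of positions (i, j) where ``a`` and ``b`` share an exact
    ``word_length``-mer, the two sequences are overlaid at offset ``i - j``
    and extended ungapped in both directions; identity is the number of
    matching bases divided by the length of the shorter sequence.  Returns
    0.0 if no word is shared.
    """
    if len(a) < word_length or len(b) < word_length:
        return 0.0
    words: dict[str, list[int]] = defaultdict(list)
    for j in range(len(b) - word_length + 1):
        words[b[j : j + word_length]].append(j)
    offsets: set[int] = set()
    for i in range(len(a) - word_length + 1):
        for j in words.get(a[i : i + word_length], ()):
            offsets.add(i - j)
    if not offsets:
        return 0.0
    shorter = min(len(a), len(b))
    best = 0.0
    for off in offsets:
        lo = max(0, off)
        hi = min(len(a), len(b) + off)
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - off])
        best = max(best, matches / shorter)
    return best


def sequences_similar(a: str, b: str, params: DiscoveryParams) -> bool:
    """Two sequences are similar iff a shared word (in either relative
    orientation) extends to >= the identity cutoff over the shorter one."""
    w = params.dedup_word_length
    cutoff = params.dedup_identity_cutoff
    if seeded_identity(a, b, w) >= cutoff:
        return True
    b_rc = str(Seq(b).reverse_complement())
    return seeded_identity(a, b_rc, w) >= cutoff


def dedup_candidates(
    novel: Sequence[CoverageCluster],
    genome: dict[str, str],
    params: DiscoveryParams = DiscoveryParams(),
) -> list[DedupComponent]:
    """Collapse similar candidate sequences into components.

    Similarity (see :func:`sequences_similar`) is closed transitively; each
    component is represented by its highest-copy-number member, ties broken by
    leftmost coordinate.  Every novel cluster lands in exactly one component.
    """
    seqs = [cluster_sequence(c, genome) for c in novel]
    n = len(novel)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    # candidate pairs share at least one word (either orientation); the
    # word index keeps this subquadratic for dissimilar sets
    w = params.dedup_word_length
    word_index: dict[str, set[int]] = defaultdict(set)
    for idx, s in enumerate(seqs):
        for i in range(len(s) - w + 1):
            word_index[s[i : i + w]].add(idx)
        rc = str(Seq(s).reverse_complement())
        for i in range(len(rc) - w + 1):
            word_index[rc[i : i + w]].add(idx)
    candidate_pairs: set[tuple[int, int]] = set()
    for members in word_index.values():
        if len(members) > 1:
            ms = sorted(members)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    candidate_pairs.add((ms[i], ms[j]))
    for i, j in sorted(candidate_pairs):
        if find(i) != find(j) and sequences_similar(seqs[i], seqs[j], params):
            union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for idx in range(n):
        groups[find(idx)].append(idx)

    components = []
    for members in groups.values():
        rep_idx = min(
            members,
            key=lambda k: (-novel[k].read_count, novel[k].contig, novel[k].start),
        )
        components.append(
            DedupComponent(
                representative=novel[rep_idx],
                members=[novel[k] for k in sorted(members)],
            )
        )
    components.sort(key=lambda c: (c.representative.contig, c.representative.start))
    return components
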