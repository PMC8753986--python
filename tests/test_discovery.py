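"""Discovery chain: coding filter, strand-aware clustering (vs a per-base
coverage oracle), copy-number/length selection, and seed-and-extend dedup
(vs an all-pairs quadratic oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe.discovery import (
    DiscoveryParams,
    build_clusters,
    cluster_sequence,
    dedup_candidates,
    filter_coding_reads,
    select_candidates,
    seeded_identity,
    sequences_similar,
    CoverageCluster,
)
from srnapipe.io import AlignedRead, GeneFeature, KnownRnaHit


def _read(start, end, strand="+", contig="chr", name="r"):
    return AlignedRead(name, contig, start, end, strand)


def _gene(start, end, strand, biotype="protein_coding"):
    return GeneFeature(f"g{start}", "chr", start, end, strand, biotype)


# -- coding filter ----------------------------------------------------------

@pytest.mark.parametrize(
    "read, removed",
    [
        (_read(1200, 1260, "+"), True),    # fully inside a +-strand gene, same strand
        (_read(1200, 1260, "-"), False),   # opposite strand: the asRNA signal
        (_read(940, 1039, "+"), False),    # only 40% of the read overlaps
        (_read(950, 1049, "+"), True),     # exactly 50% overlap
    ],
)
def test_coding_read_filter_rules(read, removed):
    genes = [_gene(1000, 2000, "+")]
    kept, n_removed = filter_coding_reads([read], genes)
    assert (n_removed == 1) == removed
    assert (len(kept) == 0) == removed


def test_coding_filter_ignores_non_coding_biotypes():
    genes = [_gene(1000, 2000, "+", biotype="rRNA")]
    kept, n_removed = filter_coding_reads([_read(1200, 1260, "+")], genes)
    assert n_removed == 0 and len(kept) == 1


# -- clustering -------------------------------------------------------------

def _brute_force_clusters(reads, max_join_gap=0):
    """Oracle: mark covered bases (dilated by the join gap) on a per-base
    array per (contig, strand), then read off maximal runs."""
    out = []
    keys = sorted({(r.contig, r.strand) for r in reads})
    for key in keys:
        group = [r for r in reads if (r.contig, r.strand) == key]
        hi = max(r.end for r in group) + max_join_gap + 2
        covered = np.zeros(hi + 2, dtype=bool)
        for r in group:
            covered[r.start : r.end + 1 + max_join_gap] = True
        pos = 1
        while pos <= hi:
            if not covered[pos]:
                pos += 1
                continue
            run_start = pos
            while pos <= hi and covered[pos]:
                pos += 1
            run_end = pos - 1
            members = [r for r in group if r.start >= run_start and r.end <= run_end + max_join_gap]
            end = max(r.end for r in members)
            depth = np.zeros(hi + 2, dtype=int)
            for r in members:
                depth[r.start : r.end + 1] += r.weight
            out.append(
                CoverageCluster(key[0], run_start, end, key[1],
                                sum(r.weight for r in members), int(depth.max()))
            )
    return sorted(out, key=lambda c: (c.contig, c.strand, c.start))


def test_cluster_example_matches_oracle():
    reads = [_read(100, 140), _read(130, 170), _read(400, 440)]
    clusters = build_clusters(reads)
    assert [(c.start, c.end, c.strand, c.read_count) for c in clusters] == [
        (100, 170, "+", 2),
        (400, 440, "+", 1),
    ]
    assert clusters == _brute_force_clusters(reads)


def test_opposite_strands_never_merge():
    clusters = build_clusters([_read(100, 140, "+"), _read(100, 140, "-")])
    assert len(clusters) == 2
    assert {c.strand for c in clusters} == {"+", "-"}


def test_single_read_is_its_own_cluster():
    (c,) = build_clusters([_read(250, 300)])
    assert (c.start, c.end, c.read_count, c.max_depth) == (250, 300, 1, 1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(1, 500), st.integers(1, 60), st.sampled_from("+-")),
        min_size=1,
        max_size=40,
    ),
    st.integers(0, 5),
)
def test_clustering_matches_coverage_oracle_and_conserves_reads(raw, gap):
    reads = [
        _read(s, s + l - 1, strand, name=f"r{i}") for i, (s, l, strand) in enumerate(raw)
    ]
    params = DiscoveryParams(max_join_gap=gap)
    clusters = build_clusters(reads, params)
    assert clusters == _brute_force_clusters(reads, gap)
    # read conservation and per-strand disjointness
    assert sum(c.read_count for c in clusters) == len(reads)
    by_key = {}
    for c in clusters:
        by_key.setdefault((c.contig, c.strand), []).append(c)
    for group in by_key.values():
        group.sort(key=lambda c: c.start)
        for left, right in zip(group, group[1:]):
            assert left.end < right.start


# -- selection --------------------------------------------------------------

def _cluster(start, end, strand="+", count=20):
    return CoverageCluster("chr", start, end, strand, count, count)


def test_copy_number_boundary_is_strictly_greater_than_ten():
    ten = _cluster(100, 199, count=10)
    eleven = _cluster(300, 399, count=11)
    novel, _, stats = select_candidates([ten, eleven])
    assert [c.start for c in novel] == [300]
    assert stats["dropped_by_copy"] == 1


def test_known_rna_routing_and_length_bounds():
    known = [KnownRnaHit("chr", 100, 180, "+", "tmRNA")]
    in_known = _cluster(100, 199, count=50)          # 80% covered, same strand
    wrong_strand = _cluster(100, 199, "-", count=50)  # hit is on +
    short = _cluster(500, 529, count=50)              # 30 bases < min_length
    novel, annotated, stats = select_candidates([in_known, wrong_strand, short], known)
    assert annotated == [in_known]
    assert novel == [wrong_strand]
    assert stats == {"dropped_by_copy": 0, "annotated": 1,
                     "dropped_by_length": 1, "novel": 1}


def test_selection_monotone_in_copy_threshold():
    rng = np.random.default_rng(5)
    clusters = [
        _cluster(i * 1000, i * 1000 + 99, count=int(rng.integers(1, 40)))
        for i in range(30)
    ]
    previous = None
    for threshold in (1, 5, 11, 20, 40):
        novel, _, _ = select_candidates(
            clusters, params=DiscoveryParams(min_copy_number=threshold)
        )
        ids = {(c.start, c.end) for c in novel}
        if previous is not None:
            assert ids <= previous
        previous = ids


# -- dedup ------------------------------------------------------------------

def _quadratic_similar(a, b, w=26, cutoff=0.90):
    """Independent oracle: try *every* overlay offset; an offset counts only
    if it contains a run of >= w consecutive matches (the shared word)."""
    def one_orientation(x, y):
        best = 0.0
        for off in range(-(len(y) - 1), len(x)):
            lo, hi = max(0, off), min(len(x), len(y) + off)
            if hi - lo < w:
                continue
            matches = 0
            run = best_run = 0
            for i in range(lo, hi):
                if x[i] == y[i - off]:
                    matches += 1
                    run += 1
                    best_run = max(best_run, run)
                else:
                    run = 0
            if best_run >= w:
                best = max(best, matches / min(len(x), len(y)))
        return best

    from Bio.Seq import Seq

    rc = str(Seq(b).reverse_complement())
    return max(one_orientation(a, b), one_orientation(a, rc)) >= cutoff


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def test_identical_sequences_merge_to_higher_count_representative():
    rng = np.random.default_rng(11)
    insert = "".join(rng.choice(list("ACGT"), 100))
    genome = {"chr": "A" * 50 + insert + "T" * 200 + insert + "G" * 50}
    low = CoverageCluster("chr", 51, 150, "+", 15, 15)
    high = CoverageCluster("chr", 351, 450, "+", 40, 40)
    components = dedup_candidates([low, high], genome)
    assert len(components) == 1
    assert components[0].representative is high
    assert len(components[0].members) == 2


def test_no_shared_word_means_no_merge():
    rng = np.random.default_rng(13)
    a = "".join(rng.choice(list("ACGT"), 100))
    b = "".join(rng.choice(list("ACGT"), 100))
    assert seeded_identity(a, b, 26) == 0.0
    assert not sequences_similar(a, b, DiscoveryParams())


def test_eight_scattered_mismatches_with_intact_word_merge():
    """100-nt pair differing at 8 scattered positions (92% identity) with one
    intact 26-mer window is merged at the 90% cutoff."""
    rng = np.random.default_rng(17)
    a = "".join(rng.choice(list("ACGT"), 100))
    b = _mutate(a, [2, 10, 40, 55, 80, 88, 93, 99], rng)  # positions 11..39 intact
    params = DiscoveryParams()
    assert seeded_identity(a, b, 26) == pytest.approx(0.92)
    assert sequences_similar(a, b, params)
    assert _quadratic_similar(a, b)
    # nine more mismatches pushes identity below the cutoff
    c = _mutate(a, [2, 10, 40, 44, 48, 55, 60, 66, 72, 80, 88, 93, 99], rng)
    assert not sequences_similar(a, c, params)
    assert not _quadratic_similar(a, c)


def test_dedup_partition_matches_all_pairs_oracle():
    """Dedup partitions a mixed set of ~repeated loci exactly as the
    quadratic all-offsets oracle does, including reverse-strand copies."""
    rng = np.random.default_rng(19)
    base1 = "".join(rng.choice(list("ACGT"), 120))
    base2 = "".join(rng.choice(list("ACGT"), 90))
    from Bio.Seq import Seq

    segments = [
        base1,
        _mutate(base1, [5, 30, 70], rng),            # near-copy of base1
        str(Seq(base1).reverse_complement()),        # minus-strand copy
        base2,
        _mutate(base2, list(range(0, 90, 4)), rng),  # heavily diverged
        "".join(rng.choice(list("ACGT"), 110)),      # unrelated
    ]
    spacer = "T" * 40
    genome_seq = spacer + spacer.join(segments) + spacer
    genome = {"chr": genome_seq}
    clusters = []
    pos = len(spacer) + 1
    for i, seg in enumerate(segments):
        clusters.append(CoverageCluster("chr", pos, pos + len(seg) - 1, "+", 10 + i, 10))
        pos += len(seg) + len(spacer)

    components = dedup_candidates(clusters, genome)
    # oracle partition by transitive closure over the quadratic similarity
    seqs = [cluster_sequence(c, genome) for c in clusters]
    n = len(seqs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if _quadratic_similar(seqs[i], seqs[j]):
                adj[i].add(j)
                adj[j].add(i)
    seen, oracle_parts = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        oracle_parts.append(frozenset(clusters[k].start for k in comp))

    got_parts = {
        frozenset(m.start for m in comp.members) for comp in components
    }
    assert got_parts == set(oracle_parts)
    # partition property: every cluster in exactly one component
    all_members = [m.start for comp in components for m in comp.members]
    assert sorted(all_members) == sorted(c.start for c in clusters)


def test_cluster_past_contig_end_raises():
    genome = {"chr": "ACGT" * 10}
    with pytest.raises(ValueError, match="contig end"):
        cluster_sequence(CoverageCluster("chr", 30, 60, "+", 12, 12), genome)


# -- end-to-end on planted truth --------------------------------------------

def test_planted_loci_recovered_exactly(tmp_path, sim_config, planted):
    """On clean synthetic data the novel-candidate set equals the planted
    locus set exactly (intervals, strands and counts >= 11)."""
    from srnapipe import io as gio
    from srnapipe.simulate import simulate_alignments

    genome, genes, loci = planted
    sam = tmp_path / "reads.sam"
    simulate_alignments(loci, genes, genome, sim_config, sam)
    reads = gio.read_alignments(sam)
    noncoding, n_coding = filter_coding_reads(reads, genes)
    assert n_coding > 0  # the background actually exercises the filter
    clusters = build_clusters(noncoding)
    novel, annotated, _ = select_candidates(clusters)
    assert not annotated
    assert {(c.start, c.end, c.strand) for c in novel} == {
        (l.start, l.end, l.strand) for l in loci
    }
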