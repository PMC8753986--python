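"""Quantification, CPM, differential expression and overlap analysis."""

import numpy as np
import pandas as pd
import pytest

from srnapipe.classify import SrnaCandidate
from srnapipe.expression import (
    CountMatrix,
    all_pairwise_comparisons,
    differential_expression,
    normalize_cpm,
    overlap_analysis,
    quantify,
    run_comparisons,
)
from srnapipe.io import AlignedRead
from srnapipe.simulate import (
    SimulationConfig,
    make_null_loci,
    simulate_count_matrix,
    simulate_null_counts,
    _assign_effects,
)


def _read(start, end, strand="+", name="r"):
    return AlignedRead(name, "chr", start, end, strand)


def _cand(srna_id, start, end, strand="+"):
    return SrnaCandidate(contig="chr", start=start, end=end, strand=strand,
                         srna_id=srna_id, positional_class="intergenic")


# -- quantify ---------------------------------------------------------------

def test_quantify_overlap_and_strand_rules():
    cands = [_cand("s1", 90, 200, "+"), _cand("s2", 90, 200, "-")]
    reads = [
        _read(100, 140, "+"),   # fully inside s1
        _read(100, 140, "-"),   # strand belongs to s2
        _read(180, 260, "+"),   # only 21/81 bases overlap: unassigned
    ]
    matrix, unassigned = quantify({"T0_1": reads}, cands)
    assert matrix.counts["T0_1"].tolist() == [1, 1]
    assert unassigned == {"T0_1": 1}
    assert matrix.library_sizes["T0_1"] == 3  # pre-filter total


def test_quantify_ambiguous_read_goes_to_greater_overlap_then_leftmost():
    cands = [_cand("left", 100, 199), _cand("right", 180, 279)]
    # 60 bases in `left`, 21 in `right`
    matrix, _ = quantify({"T0_1": [_read(140, 200)]}, cands)
    assert matrix.counts["T0_1"].tolist() == [1, 0]
    # exact tie: 50 bases in each -> leftmost
    tie_cands = [_cand("left", 100, 199), _cand("right", 200, 299)]
    matrix2, _ = quantify({"T0_1": [_read(150, 249)]}, tie_cands)
    assert matrix2.counts["T0_1"].tolist() == [1, 0]


def test_quantify_conserves_planted_reads(tmp_path, sim_config, planted):
    from srnapipe import io as gio
    from srnapipe.simulate import simulate_alignments

    genome, genes, loci = planted
    sam = tmp_path / "reads.sam"
    emitted = simulate_alignments(loci, genes, genome, sim_config, sam)
    cands = [
        _cand(l.locus_id, l.start, l.end, l.strand) for l in loci
    ]
    reads = gio.read_alignments(sam)
    matrix, unassigned = quantify({"T0_1": reads}, cands)
    for locus in loci:
        assert matrix.counts.loc[locus.locus_id, "T0_1"] == emitted[locus.locus_id]
    assert matrix.counts["T0_1"].sum() + unassigned["T0_1"] == len(reads)


# -- CPM --------------------------------------------------------------------

def test_cpm_definition_and_column_sums():
    counts = pd.DataFrame(
        {"T0_1": [50, 0], "T0_2": [25, 25]}, index=["a", "b"]
    )
    m = CountMatrix(counts, pd.Series({"T0_1": 1_000_000, "T0_2": 50}))
    cpm = normalize_cpm(m)
    assert cpm.loc["a", "T0_1"] == 50.0
    assert np.allclose(cpm["T0_2"].sum(), 1e6)
    zero_row = CountMatrix(pd.DataFrame({"T0_1": [0], "T0_2": [0]}, index=["z"]),
                           pd.Series({"T0_1": 10, "T0_2": 10}))
    assert (normalize_cpm(zero_row).values == 0).all()


def test_cpm_zero_library_raises_with_sample_name():
    m = CountMatrix(pd.DataFrame({"T0_1": [1], "T1_1": [0]}),
                    pd.Series({"T0_1": 5, "T1_1": 0}))
    with pytest.raises(ValueError, match="T1_1"):
        normalize_cpm(m)


# -- differential expression ------------------------------------------------

def _matrix_from(arrays: dict) -> CountMatrix:
    return CountMatrix(pd.DataFrame(arrays, index=[f"s{i}" for i in
                                                   range(len(next(iter(arrays.values()))))]))


def test_de_identity_and_antisymmetry():
    rng = np.random.default_rng(3)
    counts = {f"{ph}_{r}": rng.poisson(100, 50)
              for ph in ("T1", "T2") for r in (1, 2, 3)}
    m = _matrix_from(counts)
    fwd = differential_expression(m, ("T1", "T2")).table
    rev = differential_expression(m, ("T2", "T1")).table
    assert np.allclose(fwd["log2fc"], -rev["log2fc"])
    assert np.allclose(fwd["p_value"], rev["p_value"])
    # identical groups: log2fc 0, never significant
    same = {f"{ph}_{r}": np.arange(1, 51) * 3 for ph in ("T1", "T2") for r in (1, 2, 3)}
    m2 = CountMatrix(pd.DataFrame(same, index=[f"s{i}" for i in range(50)]),
                     pd.Series({c: 1e6 for c in same}))
    t = differential_expression(m2, ("T1", "T2")).table
    assert (t["log2fc"] == 0).all()
    assert not t["significant"].any()
    assert (t["p_value"] == 1.0).all()


def test_fold_change_signed_magnitude_convention():
    """A 3.6-fold drop is reported as -3.6, never as 0.28."""
    lib = pd.Series({f"{ph}_{r}": 1e6 for ph in ("T1", "T2") for r in (1, 2, 3)})
    counts = pd.DataFrame(
        {"T1_1": [3600], "T1_2": [3600], "T1_3": [3600],
         "T2_1": [1000], "T2_2": [1000], "T2_3": [1000]},
        index=["s0"],
    )
    t = differential_expression(CountMatrix(counts, lib), ("T1", "T2"),
                                pseudocount=0).table
    assert t.loc["s0", "fold_change"] == pytest.approx(-3.6)
    assert t.loc["s0", "log2fc"] == pytest.approx(-np.log2(3.6))


def test_significance_monotone_in_thresholds():
    cfg = SimulationConfig(seed=9, fraction_de=0.5)
    loci = make_null_loci(200)
    _assign_effects(loci, cfg)
    m = simulate_count_matrix(loci, cfg)
    strict = differential_expression(m, ("T1", "T2"), fc_threshold=4, p_threshold=0.001)
    loose = differential_expression(m, ("T1", "T2"), fc_threshold=2, p_threshold=0.01)
    assert strict.significant_ids <= loose.significant_ids


def test_de_null_calibration_small():
    """Null NB counts: raw p <= 0.01 rate near nominal, significant-call rate
    (adding the fold-change gate) well below it."""
    cm = simulate_null_counts(2000, SimulationConfig(seed=21))
    de = differential_expression(cm, ("T1", "T2"))
    p_rate = (de.table["p_value"] <= 0.01).mean()
    assert 0.002 <= p_rate <= 0.03
    assert de.table["significant"].mean() <= 0.015


def test_missing_phase_and_single_replicate_raise():
    m = _matrix_from({"T1_1": np.arange(5), "T1_2": np.arange(5),
                      "T2_1": np.arange(5), "T2_2": np.arange(5)})
    with pytest.raises(ValueError, match="absent"):
        differential_expression(m, ("T1", "T9"))
    m1 = _matrix_from({"T1_1": np.arange(5), "T2_1": np.arange(5)})
    with pytest.raises(ValueError, match="replicates"):
        differential_expression(m1, ("T1", "T2"))


# -- overlap ----------------------------------------------------------------

def test_four_phases_give_six_comparisons():
    comps = all_pairwise_comparisons(["T1", "T2", "T3", "T4"])
    assert len(comps) == 6
    assert comps[0] == ("T1", "T2") and comps[-1] == ("T3", "T4")


def test_overlap_tallies_and_core_set():
    cfg = SimulationConfig(seed=30, fraction_de=0.05, read_depth_per_locus=500,
                           planted_log2fc=3)
    loci = make_null_loci(60)
    _assign_effects(loci, cfg)
    m = simulate_count_matrix(loci, cfg)
    results = run_comparisons(m)
    summary = overlap_analysis(results)
    de_ids = {l.locus_id for l in loci if l.is_de}
    assert summary.core_set == de_ids
    for comp in summary.comparisons:
        assert (summary.up_counts[comp] + summary.down_counts[comp]
                == len(summary.significant_sets[comp]))
        assert summary.core_set <= summary.significant_sets[comp]
    # single comparison: core set is its significant set
    single = overlap_analysis({("T1", "T2"): results[("T1", "T2")]})
    assert single.core_set == results[("T1", "T2")].significant_ids


def test_overlap_rejects_mismatched_universes():
    cm = simulate_null_counts(20, SimulationConfig(seed=4))
    a = differential_expression(cm, ("T1", "T2"))
    b = differential_expression(cm, ("T3", "T4"))
    b.table.drop(b.table.index[:1], inplace=True)
    with pytest.raises(ValueError, match="universe"):
        overlap_analysis({a.comparison: a, b.comparison: b})
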