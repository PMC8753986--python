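"""Quantification, differential expression and cross-phase overlap analysis.

Differential expression follows the survey's stated decision rule — an sRNA
is called significant in a phase comparison when its fold change is at least
|2| and its raw p-value is at most 0.01 — with the test itself defined here as
a two-sided Welch t-test on log2(CPM + 1) across biological replicates.  No
multiple-testing adjustment is applied by default (the rule is a raw-p rule);
Benjamini–Hochberg is available behind a flag.

Fold changes are reported in signed-magnitude style: ``-3.6`` means 3.6-fold
*down*, i.e. ``fold_change = sign(log2fc) * 2**abs(log2fc)``.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .classify import SrnaCandidate
from .io import AlignedRead

DEFAULT_COMPARISON_PHASES = ("T1", "T2", "T3", "T4")


class CountMatrix:
    """Candidate × sample read counts with phase/replicate metadata.

    Columns are named ``<phase>_<replicate>`` (e.g. ``T2_1``).  Library sizes
    are the per-sample totals of the *full* table before any row filtering and
    are the denominators for CPM normalization.
    """

    def __init__(self, counts: pd.DataFrame, library_sizes: Optional[pd.Series] = None):
        if (counts.values < 0).any():
            raise ValueError("count matrix contains negative values")
        self.counts = counts
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        self.library_sizes = library_sizes.astype(float)
        samples = list(counts.columns)
        if len(samples) != len(set(samples)):
            raise ValueError("duplicate (phase, replicate) columns")
        for col in samples:
            phase, _, rep = col.rpartition("_")
            if not phase or not rep.isdigit():
                raise ValueError(f"column {col!r} is not of the form <phase>_<replicate>")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def phases(self) -> list[str]:
        seen: list[str] = []
        for col in self.counts.columns:
            phase = col.rpartition("_")[0]
            if phase not in seen:
                seen.append(phase)
        return seen

    def columns_for_phase(self, phase: str) -> list[str]:
        cols = [c for c in self.counts.columns if c.rpartition("_")[0] == phase]
        if not cols:
            raise ValueError(f"phase {phase!r} absent from the count matrix")
        return cols

    def cpm(self) -> pd.DataFrame:
        return normalize_cpm(self)


def quantify(
    alignments_by_sample: Mapping[str, Iterable[AlignedRead]],
    candidates: Sequence[SrnaCandidate],
    min_overlap_fraction: float = 0.5,
) -> tuple[CountMatrix, dict[str, int]]:
    """Count reads per candidate per sample.

    A read is counted for a candidate iff at least ``min_overlap_fraction`` of
    the read overlaps the candidate interval on the same strand; a read
    eligible for two candidates goes to the one with the greater overlap
    (ties to the leftmost).  Library sizes are the total input reads per
    sample, recorded before any assignment filtering.

    Returns ``(matrix, unassigned)`` with per-sample unassigned-read counts.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for c in candidates:
        trees[(c.contig, c.strand)].addi(c.start, c.end + 1, c)

    ids = [c.srna_id for c in candidates]
    data: dict[str, pd.Series] = {}
    library_sizes: dict[str, float] = {}
    unassigned: dict[str, int] = {}
    for sample, reads in alignments_by_sample.items():
        counts = dict.fromkeys(ids, 0)
        total = 0
        miss = 0
        for r in reads:
            total += 1
            tree = trees.get((r.contig, r.strand))
            best: Optional[SrnaCandidate] = None
            best_ov = 0
            if tree is not None:
                for iv in tree.overlap(r.start, r.end + 1):
                    c = iv.data
                    ov = min(r.end, c.end) - max(r.start, c.start) + 1
                    if ov > best_ov or (ov == best_ov and best is not None and c.start < best.start):
                        best, best_ov = c, ov
            if best is not None and best_ov >= min_overlap_fraction * r.length:
                counts[best.srna_id] += r.weight
            else:
                miss += 1
        data[sample] = pd.Series(counts)
        library_sizes[sample] = total
        unassigned[sample] = miss
    matrix = pd.DataFrame(data, index=ids)
    return CountMatrix(matrix, pd.Series(library_sizes)), unassigned


def normalize_cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: value * 1e6 / library size, per sample."""
    for sample, size in matrix.library_sizes.items():
        if size <= 0:
            raise ValueError(f"sample {sample!r} has zero library size")
    return matrix.counts * 1e6 / matrix.library_sizes


@dataclass
class DeTable:
    """Differential-expression results for one phase comparison."""

    comparison: tuple[str, str]  # (phase_a, phase_b); fold is b over a
    table: pd.DataFrame  # srna_id index; log2fc, fold_change, p_value, significant, direction

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def differential_expression(
    matrix: CountMatrix,
    comparison: tuple[str, str],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    pseudocount: float = 1.0,
    test: str = "student",
    adjust: Optional[str] = None,
) -> DeTable:
    """t-test differential expression of phase_b over phase_a.

    ``log2fc`` is the mean over replicates of log2(CPM + pseudocount) in
    phase_b minus phase_a; ``fold_change`` is the signed-magnitude form; the
    p-value is a two-sided t-test on the same log2 values.  ``test`` selects
    the pooled-variance Student form (default) or ``"welch"``; with three
    replicates the pooled form keeps its degrees of freedom (Welch's
    Satterthwaite df can collapse to ~2 when a low-count group meets a
    high-count one, which costs most of the power).  ``adjust`` may be
    ``"bh"`` for Benjamini–Hochberg; the significance call always uses the
    (possibly adjusted) p against ``p_threshold`` and |fold| against
    ``fc_threshold``.
    """
    phase_a, phase_b = comparison
    if test not in {"student", "welch"}:
        raise ValueError(f"unknown test {test!r}")
    cpm = normalize_cpm(matrix)
    a = np.log2(cpm[matrix.columns_for_phase(phase_a)].to_numpy() + pseudocount)
    b = np.log2(cpm[matrix.columns_for_phase(phase_b)].to_numpy() + pseudocount)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each phase needs at least two replicates")

    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicate vectors trip scipy's precision-loss
        # warning; the nan fallback below handles the degenerate rows
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(b, a, axis=1, equal_var=(test == "student"))
    # zero variance in both groups leaves the statistic undefined; identical
    # constant groups carry no evidence (p=1), distinct ones maximal evidence
    p = np.where(np.isnan(p), np.where(log2fc == 0.0, 1.0, 0.0), p)

    if adjust is not None:
        if adjust.lower() not in {"bh", "fdr_bh"}:
            raise ValueError(f"unknown adjustment {adjust!r}")
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]

    fold = np.sign(log2fc) * np.exp2(np.abs(log2fc))
    fold = np.where(log2fc == 0.0, 1.0, fold)
    significant = (np.abs(fold) >= fc_threshold) & (p <= p_threshold)
    direction = np.where(
        ~significant, "ns", np.where(log2fc > 0, "up", "down")
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fold,
            "p_value": p,
            "significant": significant,
            "direction": direction,
        },
        index=matrix.counts.index,
    )
    table.index.name = "srna_id"
    return DeTable(comparison=(phase_a, phase_b), table=table)


def all_pairwise_comparisons(phases: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered phase pairs in list order: 4 phases → 6 comparisons."""
    return list(combinations(phases, 2))


def run_comparisons(
    matrix: CountMatrix,
    phases: Sequence[str] = DEFAULT_COMPARISON_PHASES,
    **kwargs,
) -> dict[tuple[str, str], DeTable]:
    return {
        comp: differential_expression(matrix, comp, **kwargs)
        for comp in all_pairwise_comparisons(phases)
    }


@dataclass
class OverlapSummary:
    """Per-comparison up/down tallies and intersection structure of the
    significant sets across comparisons."""

    comparisons: list[tuple[str, str]]
    up_counts: dict[tuple[str, str], int]
    down_counts: dict[tuple[str, str], int]
    significant_sets: dict[tuple[str, str], set[str]]
    core_set: set[str]

    def intersection(self, subset: Iterable[tuple[str, str]]) -> set[str]:
        subset = list(subset)
        if not subset:
            return set()
        out = set(self.significant_sets[subset[0]])
        for comp in subset[1:]:
            out &= self.significant_sets[comp]
        return out

    def to_dict(self) -> dict:
        def key(comp):
            return f"{comp[0]}_vs_{comp[1]}"

        return {
            "comparisons": [key(c) for c in self.comparisons],
            "up": {key(c): self.up_counts[c] for c in self.comparisons},
            "down": {key(c): self.down_counts[c] for c in self.comparisons},
            "n_significant": {
                key(c): len(self.significant_sets[c]) for c in self.comparisons
            },
            "core_set": sorted(self.core_set),
        }


def overlap_analysis(de_results: Mapping[tuple[str, str], DeTable]) -> OverlapSummary:
    """Cross-comparison overlap of significant sRNAs.

    Requires the same sRNA universe in every comparison; the core set is the
    sRNAs significant in *every* supplied comparison.
    """
    comps = list(de_results)
    if not comps:
        raise ValueError("no comparisons supplied")
    universe = set(de_results[comps[0]].table.index)
    for comp in comps[1:]:
        other = set(de_results[comp].table.index)
        if other != universe:
            diff = sorted(universe.symmetric_difference(other))
            raise ValueError(f"mismatched sRNA universes across comparisons: {diff}")

    up_counts, down_counts, sig_sets = {}, {}, {}
    for comp, de in de_results.items():
        t = de.table
        sig = t["significant"]
        up_counts[comp] = int((sig & (t["log2fc"] > 0)).sum())
        down_counts[comp] = int((sig & (t["log2fc"] < 0)).sum())
        sig_sets[comp] = set(t.index[sig])
    core = set.intersection(*sig_sets.values()) if sig_sets else set()
    return OverlapSummary(
        comparisons=comps,
        up_counts=up_counts,
        down_counts=down_counts,
        significant_sets=sig_sets,
        core_set=core,
    )


def write_de_table(de: DeTable, path) -> None:
    out = de.table.reset_index()
    out.insert(1, "comparison", f"{de.comparison[0]}_vs_{de.comparison[1]}")
    out.to_csv(path, sep="\t", index=False)
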