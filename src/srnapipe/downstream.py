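"""Coexpression pairing, term enrichment, and 2^-ΔΔCT qPCR quantification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import TargetLink


@dataclass(frozen=True)
class CoexpressionPair:
    """One sRNA/target pair judged by the joint fold-change rule.

    ``passes`` iff both members change at least |2|-fold; ``concordant`` iff
    their fold changes share a sign (signed-magnitude convention: negative is
    down-regulated).
    """

    srna_id: str
    gene_id: str
    srna_fold_change: float
    target_fold_change: float

    @property
    def concordant(self) -> bool:
        return self.srna_fold_change * self.target_fold_change > 0

    def passes(self, fc_threshold: float = 2.0) -> bool:
        return (
            abs(self.srna_fold_change) >= fc_threshold
            and abs(self.target_fold_change) >= fc_threshold
        )


def coexpression_select(
    srna_de: pd.DataFrame,
    target_de: pd.DataFrame,
    links: Sequence[TargetLink],
    fc_threshold: float = 2.0,
) -> tuple[list[CoexpressionPair], list[TargetLink]]:
    """Pair predicted sRNA/target links with their fold changes.

    ``srna_de`` is indexed by srna_id, ``target_de`` by gene_id; both need a
    ``fold_change`` column and, if present, matching ``comparison`` values.
    Links whose sRNA or gene lacks DE data are returned in the skipped list,
    never dropped silently.
    """
    for name, df in (("srna", srna_de), ("target", target_de)):
        if "fold_change" not in df.columns:
            raise ValueError(f"{name} DE table lacks a fold_change column")
    if "comparison" in srna_de.columns and "comparison" in target_de.columns:
        sc = set(srna_de["comparison"].unique())
        tc = set(target_de["comparison"].unique())
        if sc != tc:
            raise ValueError(f"comparison mismatch between DE tables: {sc} vs {tc}")

    pairs: list[CoexpressionPair] = []
    skipped: list[TargetLink] = []
    for link in links:
        if link.srna_id not in srna_de.index or link.gene_id not in target_de.index:
            skipped.append(link)
            continue
        pairs.append(
            CoexpressionPair(
                srna_id=link.srna_id,
                gene_id=link.gene_id,
                srna_fold_change=float(srna_de.loc[link.srna_id, "fold_change"]),
                target_fold_change=float(target_de.loc[link.gene_id, "fold_change"]),
            )
        )
    return pairs, skipped


def coexpression_table(pairs: Sequence[CoexpressionPair], fc_threshold: float = 2.0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "srna_id": p.srna_id,
                "gene_id": p.gene_id,
                "srna_fold_change": p.srna_fold_change,
                "target_fold_change": p.target_fold_change,
                "concordant": p.concordant,
                "passes": p.passes(fc_threshold),
            }
            for p in pairs
        ]
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one term in a study gene set."""

    term_id: str
    term_name: str
    k: int  # term hits in the study set
    n: int  # study-set size
    K: int  # term hits in the population
    N: int  # population size
    p_value: float  # upper-tail P(X >= k)
    adjusted_p: float  # Benjamini-Hochberg across tested terms


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"impossible configuration k={k}, N={N}, K={K}, n={n}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    study_genes: Sequence[str],
    population_genes: Sequence[str],
    term_map: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Term enrichment of a study gene set against a population background.

    ``term_map`` has columns ``gene_id``, ``term_id`` and optionally
    ``term_name``.  Per term with at least one study hit, the p-value is the
    upper-tail hypergeometric probability of drawing >= k term genes in a
    study set of size n from a population of size N containing K term genes;
    adjusted p-values are Benjamini–Hochberg across all tested terms.
    Results are sorted by adjusted then raw p.
    """
    study = set(study_genes)
    population = set(population_genes)
    stray = sorted(study - population)
    if stray:
        raise ValueError(f"study genes absent from the population: {stray}")
    if "term_name" not in term_map.columns:
        term_map = term_map.assign(term_name=term_map["term_id"])

    N = len(population)
    n = len(study)
    rows = []
    for (term_id, term_name), group in term_map.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(group["gene_id"]) & population
        K = len(term_genes)
        k = len(term_genes & study)
        if k == 0:
            continue
        rows.append((term_id, term_name, k, K, hypergeom_upper_tail(k, N, K, n)))
    if not rows:
        return []
    raw = [r[4] for r in rows]
    adjusted = multipletests(raw, method="fdr_bh")[1]
    results = [
        EnrichmentResult(term_id, term_name, k, n, K, N, p, float(adj))
        for (term_id, term_name, k, K, p), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term_id))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ΔΔCT relative quantity of one sRNA in one sample vs a calibrator."""

    sample: str
    srna_id: str
    delta_ct: float  # mean CT(target) - mean CT(reference), cycles
    delta_delta_ct: float  # ΔCT(sample) - ΔCT(calibrator)
    value: float  # 2 ** -ΔΔCT


def relative_expression_ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> list[RelativeExpression]:
    """Relative expression by the 2^-ΔΔCT method.

    ``ct_table`` has one row per technical replicate with columns ``sample``,
    ``gene``, ``ct``.  CT values are averaged over technical replicates;
    ΔCT normalizes each target to the reference gene (e.g. 16S rRNA) within a
    sample, ΔΔCT to the calibrator sample, and the reported quantity is
    2^-ΔΔCT.  The calibrator's own value is exactly 1.
    """
    if ct_table.empty:
        raise ValueError("empty CT table")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean()
    samples = sorted(ct_table["sample"].unique())
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from the CT table")
    for sample in samples:
        if (sample, reference_gene) not in mean_ct.index:
            raise ValueError(f"reference gene {reference_gene!r} missing in sample {sample!r}")

    targets = sorted(g for g in ct_table["gene"].unique() if g != reference_gene)
    out: list[RelativeExpression] = []
    for target in targets:
        if (calibrator_sample, target) not in mean_ct.index:
            raise ValueError(f"target {target!r} missing in calibrator sample")
        calib_dct = mean_ct[(calibrator_sample, target)] - mean_ct[(calibrator_sample, reference_gene)]
        for sample in samples:
            if (sample, target) not in mean_ct.index:
                continue
            dct = mean_ct[(sample, target)] - mean_ct[(sample, reference_gene)]
            ddct = dct - calib_dct
            out.append(
                RelativeExpression(
                    sample=sample,
                    srna_id=target,
                    delta_ct=float(dct),
                    delta_delta_ct=float(ddct),
                    value=float(2.0 ** -ddct),
                )
            )
    return out


def relative_expression_table(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "srna_id": r.srna_id,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "value": r.value,
            }
            for r in results
        ]
    )
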