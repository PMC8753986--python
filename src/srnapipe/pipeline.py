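"""End-to-end orchestration: simulate → discover → classify → quantify → de →
overlap → coexpress/enrich/qpcr, with a run manifest.

The manifest records the tool version, a hash of the configuration, per-stage
record counts (the accounting of reads and clusters removed at each filter),
and SHA-256 digests of every output file, so a rerun with the same seed and
inputs can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierParams, SrnaCandidate, classify_all, summarize_classification
from .discovery import (
    DiscoveryParams,
    build_clusters,
    dedup_candidates,
    filter_coding_reads,
    select_candidates,
)
from .downstream import (
    coexpression_select,
    coexpression_table,
    enrich_terms,
    enrichment_table,
    relative_expression_ddct,
    relative_expression_table,
)
from .expression import (
    CountMatrix,
    overlap_analysis,
    quantify,
    run_comparisons,
    write_de_table,
)
from . import io as gio
from .simulate import (
    SimulationConfig,
    generate_genome,
    plant_srna_loci,
    simulate_alignments,
    simulate_ct_table,
    truth_table,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; unset optional inputs skip their stage."""

    outdir: str = "srnapipe_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    comparison_phases: Optional[list[str]] = None  # default: post-lag phases
    # optional external inputs; when None the synthetic stage supplies them
    # (ct) or the stage is skipped (targets / terms)
    ct_table: Optional[str] = None
    target_links: Optional[str] = None
    target_de: Optional[str] = None
    term_map: Optional[str] = None
    qpcr_reference_gene: str = "16S"
    qpcr_calibrator_sample: str = "T0"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = SimulationConfig(**{
            **raw.get("simulation", {}),
            "seed": raw.get("seed", raw.get("simulation", {}).get("seed", 0)),
        })
        disc = DiscoveryParams(**raw.get("discovery", {}))
        clf = ClassifierParams(**raw.get("classifier", {}))
        keys = {k: v for k, v in raw.items()
                if k not in {"simulation", "discovery", "classifier"}}
        return cls(simulation=sim, discovery=disc, classifier=clf, **keys)

    def config_hash(self) -> str:
        def canon(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: canon(v) for k, v in asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [canon(v) for v in obj]
            if isinstance(obj, dict):
                return {k: canon(v) for k, v in sorted(obj.items())}
            return obj
        payload = canon(self)
        payload.pop("outdir", None)  # where results land does not change them
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    Stages run in fixed order; a stage whose configured inputs are absent is
    recorded as skipped.  With a fixed seed the run is deterministic: output
    digests are identical across reruns.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = replace(config.simulation, seed=config.seed)
    manifest: dict = {
        "version": __version__,
        "config_hash": replace(config, simulation=sim).config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"status": "ok", **counts}
        log.info("stage=%s %s", stage,
                 " ".join(f"{k}={v}" for k, v in counts.items()))

    def skip(stage: str, reason: str) -> None:
        manifest["stages"][stage] = {"status": "skipped", "reason": reason}
        log.info("stage=%s skipped (%s)", stage, reason)

    # -- simulate -----------------------------------------------------------
    genome, genes = generate_genome(sim)
    loci = plant_srna_loci(genes, sim)
    gio.write_genome(genome, outdir / "genome.fa")
    gio.write_annotation(genes, outdir / "genes.gff3")
    truth_table(loci).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sample_sams: dict[str, Path] = {}
    for phase in sim.phases:
        for rep in range(1, sim.n_replicates + 1):
            sample = f"{phase}_{rep}"
            path = outdir / f"reads_{sample}.sam"
            simulate_alignments(loci, genes, genome, sim, path, phase=phase)
            sample_sams[sample] = path
    pooled = outdir / "reads_pooled.sam"
    simulate_alignments(loci, genes, genome, sim, pooled, phase=None)
    record("simulate", n_genes=len(genes), n_planted_loci=len(loci),
           n_sample_libraries=len(sample_sams))

    # -- discover -----------------------------------------------------------
    stats: dict = {}
    reads = list(gio.iter_alignments(pooled, stats=stats))
    noncoding, n_coding = filter_coding_reads(
        reads, genes, config.discovery.coding_overlap_discard_fraction
    )
    clusters = build_clusters(noncoding, config.discovery)
    novel, annotated, sel_stats = select_candidates(clusters, (), config.discovery)
    components = dedup_candidates(novel, genome, config.discovery)
    record(
        "discover",
        input_reads=stats["n_emitted"],
        coding_reads_removed=n_coding,
        noncoding_reads=len(noncoding),
        clusters=len(clusters),
        **sel_stats,
        dedup_representatives=len(components),
        dedup_absorbed=sum(len(c.members) - 1 for c in components),
    )

    # -- classify -----------------------------------------------------------
    candidates = [
        SrnaCandidate(
            contig=c.representative.contig,
            start=c.representative.start,
            end=c.representative.end,
            strand=c.representative.strand,
            read_count=c.representative.read_count,
        )
        for c in components
    ]
    classify_all(candidates, genes, config.classifier)
    summary = summarize_classification(candidates)
    gio.write_candidate_table(summary.candidates, outdir / "candidates.tsv")
    record("classify", total=summary.total, **summary.counts)

    # -- quantify -----------------------------------------------------------
    alignments_by_sample = {
        sample: gio.read_alignments(path) for sample, path in sample_sams.items()
    }
    matrix, unassigned = quantify(alignments_by_sample, summary.candidates)
    gio.write_counts_table(matrix.counts, outdir / "counts.tsv")
    record("quantify", n_srnas=matrix.counts.shape[0],
           n_samples=matrix.counts.shape[1],
           total_counted=int(matrix.counts.values.sum()),
           total_unassigned=int(sum(unassigned.values())))

    # -- de + overlap -------------------------------------------------------
    phases = config.comparison_phases or sim.phases[1:]
    de_results = run_comparisons(
        matrix, phases, fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
    )
    for comp, de in de_results.items():
        write_de_table(de, outdir / f"de_{comp[0]}_vs_{comp[1]}.tsv")
    record("de", n_comparisons=len(de_results),
           n_significant_total=sum(len(d.significant_ids) for d in de_results.values()))
    overlap = overlap_analysis(de_results)
    with open(outdir / "overlap.json", "w") as fh:
        json.dump(overlap.to_dict(), fh, indent=2, sort_keys=True)
    record("overlap", n_comparisons=len(overlap.comparisons),
           core_set_size=len(overlap.core_set))

    # -- coexpress ----------------------------------------------------------
    if config.target_links and config.target_de:
        links = gio.read_target_table(config.target_links)
        target_de = pd.read_csv(config.target_de, sep="\t", index_col="gene_id")
        comp = list(de_results)[0]
        srna_de = de_results[comp].table
        pairs, skipped = coexpression_select(srna_de, target_de, links,
                                             config.fc_threshold)
        coexpression_table(pairs, config.fc_threshold).to_csv(
            outdir / "coexpression.tsv", sep="\t", index=False
        )
        record("coexpress", n_pairs=len(pairs), n_skipped_links=len(skipped))
    else:
        skip("coexpress", "no target link/DE tables configured")

    # -- enrich -------------------------------------------------------------
    if config.term_map and config.target_links:
        term_map = gio.read_term_map(config.term_map)
        links = gio.read_target_table(config.target_links)
        population = [g.gene_id for g in genes]
        study = sorted({l.gene_id for l in links} & set(population))
        results = enrich_terms(study, population, term_map)
        enrichment_table(results).to_csv(outdir / "enrichment.tsv",
                                         sep="\t", index=False)
        record("enrich", n_terms_tested=len(results), n_study_genes=len(study))
    else:
        skip("enrich", "no term map configured")

    # -- qpcr ---------------------------------------------------------------
    ct_path = config.ct_table
    if ct_path is None:
        ct_path = outdir / "ct.tsv"
        gio.write_ct_table(simulate_ct_table(loci, sim), ct_path)
    if Path(ct_path).exists():
        ct = gio.read_ct_table(ct_path)
        rel = relative_expression_ddct(
            ct, config.qpcr_reference_gene, config.qpcr_calibrator_sample
        )
        relative_expression_table(rel).to_csv(outdir / "qpcr.tsv",
                                              sep="\t", index=False)
        record("qpcr", n_values=len(rel))
    else:
        skip("qpcr", "no CT table")

    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
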