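"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 1-based inclusive (GFF3's frame) with an explicit
strand flag and ``start <= end``.  SAM's 0-based half-open positions are
converted at the boundary, in :func:`iter_alignments`.  The only place the
internal frame is ever broken is :func:`write_candidate_table`, which prints
minus-strand candidates with start and end swapped — the convention used in
published candidate tables for this kind of survey — and
:func:`read_candidate_table` restores the normalized frame on the way back in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam
from gffutils.feature import feature_from_line
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: reads longer than this on the reference are outside the low-molecular-weight
#: library (<500 nt) and are skipped by the alignment reader
MAX_READ_SPAN = 500


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene interval, the reference frame for filtering and
    classification."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid interval ({self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its reference span and strand."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    weight: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"read {self.read_id}: start > end")
        if self.strand not in STRANDS:
            raise FormatError(f"read {self.read_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class KnownRnaHit:
    """A hit to a known RNA family (Rfam-style annotation table)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"known-RNA hit {self.family}: start > end")


@dataclass(frozen=True)
class TargetLink:
    """A predicted sRNA → target-gene link from an external prediction tool."""

    srna_id: str
    gene_id: str
    source: str = ""
    energy: Optional[float] = None  # pairing energy, kcal/mol

    def __post_init__(self) -> None:
        if not self.srna_id or not self.gene_id:
            raise FormatError("target link with empty srna_id or gene_id")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a dict of contig name → uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneFeature]:
    """Read gene features from a GFF3 file (1-based inclusive coordinates).

    Only ``gene`` lines are kept.  Features without a strand or with
    ``end < start`` are rejected; errors carry the offending line number.
    """
    features: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            if feat.end < feat.start:
                raise FormatError(f"{path}:{lineno}: end < start")
            if feat.strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: feature lacks a strand")
            ids = feat.attributes.get("ID")
            if not ids:
                raise FormatError(f"{path}:{lineno}: feature lacks an ID attribute")
            gene_id = ids[0]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
            features.append(
                GeneFeature(gene_id, feat.seqid, feat.start, feat.end, feat.strand, biotype)
            )
    return features


def write_annotation(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id};biotype={f.biotype}"
            fh.write(
                f"{f.contig}\tsrnapipe\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

def iter_alignments(
    path: str | Path,
    max_read_span: int = MAX_READ_SPAN,
    stats: Optional[dict] = None,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are skipped; records whose
    reference span exceeds ``max_read_span`` bases are skipped with a logged
    count (they fall outside the small-RNA library).  If ``stats`` is given it
    accumulates ``n_emitted``, ``n_unmapped_or_secondary`` and
    ``n_skipped_long``.
    """
    if stats is None:
        stats = {}
    stats.setdefault("n_emitted", 0)
    stats.setdefault("n_unmapped_or_secondary", 0)
    stats.setdefault("n_skipped_long", 0)
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                stats["n_unmapped_or_secondary"] += 1
                continue
            start = rec.reference_start + 1  # to 1-based inclusive
            end = rec.reference_end  # pysam's reference_end is half-open
            span = end - start + 1
            if span > max_read_span:
                stats["n_skipped_long"] += 1
                continue
            stats["n_emitted"] += 1
            yield AlignedRead(
                read_id=rec.query_name,
                contig=rec.reference_name,
                start=start,
                end=end,
                strand="-" if rec.is_reverse else "+",
            )
    if stats["n_skipped_long"]:
        log.info("skipped %d alignments spanning > %d bases on the reference",
                 stats["n_skipped_long"], max_read_span)


def read_alignments(path: str | Path, max_read_span: int = MAX_READ_SPAN) -> list[AlignedRead]:
    """Eager form of :func:`iter_alignments`."""
    return list(iter_alignments(path, max_read_span=max_read_span))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = ["srna_id", "contig", "start", "end", "strand", "class", "anchor_gene"]


def write_candidate_table(candidates, path: str | Path) -> None:
    """Write classified candidates as TSV in the published-table convention.

    Minus-strand candidates are printed with start and end swapped
    (``start > end``); plus-strand candidates keep ``start <= end``.
    """
    ids = [c.srna_id for c in candidates]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate sRNA ids: {dupes}")
    rows = []
    for c in candidates:
        start, end = (c.end, c.start) if c.strand == "-" else (c.start, c.end)
        rows.append(
            {
                "srna_id": c.srna_id,
                "contig": c.contig,
                "start": start,
                "end": end,
                "strand": c.strand,
                "class": c.positional_class,
                "anchor_gene": c.anchor_gene or "",
            }
        )
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path):
    """Read a candidate TSV back into :class:`~srnapipe.classify.SrnaCandidate`
    objects, restoring the normalized internal frame (start <= end)."""
    from .classify import SrnaCandidate  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"anchor_gene": str}, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        start, end = sorted((int(row["start"]), int(row["end"])))
        out.append(
            SrnaCandidate(
                srna_id=row["srna_id"],
                contig=row["contig"],
                start=start,
                end=end,
                strand=row["strand"],
                positional_class=row["class"],
                anchor_gene=row["anchor_gene"] or "",
            )
        )
    return out


def write_counts_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Count matrix TSV: ``srna_id`` column then one column per phase_replicate."""
    counts.to_csv(path, sep="\t", index_label="srna_id")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="srna_id")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """CT table with columns ``sample``, ``gene``, ``ct`` (one row per
    technical replicate)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "ct"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing CT columns {sorted(missing)}")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_known_rna_table(path: str | Path) -> list[KnownRnaHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        KnownRnaHit(r.contig, int(r.start), int(r.end), r.strand, r.family)
        for r in df.itertuples(index=False)
    ]


def write_known_rna_table(hits: Iterable[KnownRnaHit], path: str | Path) -> None:
    pd.DataFrame(
        [{"contig": h.contig, "start": h.start, "end": h.end, "strand": h.strand,
          "family": h.family} for h in hits]
    ).to_csv(path, sep="\t", index=False)


def read_target_table(path: str | Path) -> list[TargetLink]:
    df = pd.read_csv(path, sep="\t")
    links = []
    for r in df.itertuples(index=False):
        energy = getattr(r, "energy", None)
        energy = None if energy is None or pd.isna(energy) else float(energy)
        links.append(TargetLink(r.srna_id, r.gene_id, getattr(r, "source", ""), energy))
    return links


def write_target_table(links: Iterable[TargetLink], path: str | Path) -> None:
    pd.DataFrame(
        [{"srna_id": l.srna_id, "gene_id": l.gene_id, "source": l.source,
          "energy": l.energy} for l in links]
    ).to_csv(path, sep="\t", index=False)


def read_term_map(path: str | Path) -> pd.DataFrame:
    """Term map TSV with columns ``gene_id``, ``term_id``, ``term_name``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "term_id"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing term-map columns {sorted(missing)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df
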