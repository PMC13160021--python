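"""Gene assignment: GFF3 CDS parsing, interval indexing, and overlap queries.

Alignment coordinates from the taxonomic assigner (0-based half-open, forward
strand) are queried against per-accession interval trees built over the CDS
features of the reference annotation.  GFF3 stores 1-based inclusive
coordinates; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

from .assign import AlignmentResult
from .errors import InputError

logger = logging.getLogger(__name__)

INTERGENIC = "intergenic"

GENE_REPORT_COLUMNS = [
    "read_id",
    "taxid",
    "accession",
    "feature_id",
    "gene_name",
    "product",
    "protein_id",
    "overlap_bases",
    "status",
]


@dataclass(frozen=True)
class GeneFeature:
    """One CDS feature, in 0-based half-open internal coordinates."""

    feature_id: str
    accession: str
    start: int
    end: int
    strand: str
    gene_name: str = ""
    product: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"feature {self.feature_id}: start {self.start} >= end {self.end}"
            )

    @property
    def source_start_1based(self) -> int:
        return self.start + 1


@dataclass
class GeneIndex:
    trees: dict[str, IntervalTree] = field(default_factory=dict)
    feature_count: int = 0

    def query_overlaps(self, accession: str, start: int, end: int) -> list[GeneFeature]:
        tree = self.trees.get(accession)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda f: (f.start, f.feature_id),
        )


@dataclass(frozen=True)
class GeneAssignment:
    read_id: str
    taxid: int
    accession: str
    feature_id: str  # INTERGENIC when no CDS qualifies
    overlap_bases: int
    gene_name: str = ""
    product: str = ""
    protein_id: str = ""


def _attr_first(attributes, key: str) -> str:
    values = attributes.get(key, [])
    return values[0] if values else ""


def parse_gff(
    gff3_path: str | Path, accession_filter: set[str] | None = None
) -> list[GeneFeature]:
    """Parse CDS rows from a GFF3 file.

    feature_id resolves to the first available of locus_tag, ID, Name.  With
    an accession filter, rows on other sequences are skipped (counted in the
    log); rows whose start exceeds their end are rejected.
    """
    # gffutils tolerates malformed rows silently; validate structure first so
    # errors can name the offending line.
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(
                    f"{gff3_path} line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if not (cols[3].isdigit() and cols[4].isdigit()):
                raise InputError(
                    f"{gff3_path} line {lineno}: non-numeric coordinates "
                    f"{cols[3]!r}..{cols[4]!r}"
                )
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise InputError(f"{gff3_path}: unparseable GFF3 ({exc})") from exc
    features: list[GeneFeature] = []
    skipped = 0
    for row in db.features_of_type("CDS"):
        if accession_filter is not None and row.seqid not in accession_filter:
            skipped += 1
            continue
        if row.start > row.end:
            raise InputError(
                f"{gff3_path}: CDS on {row.seqid} has start {row.start} > end {row.end}"
            )
        feature_id = (
            _attr_first(row.attributes, "locus_tag")
            or _attr_first(row.attributes, "ID")
            or _attr_first(row.attributes, "Name")
        )
        if not feature_id:
            raise InputError(
                f"{gff3_path}: CDS at {row.seqid}:{row.start}-{row.end} lacks "
                "locus_tag/ID/Name"
            )
        features.append(
            GeneFeature(
                feature_id=feature_id,
                accession=row.seqid,
                start=row.start - 1,  # GFF 1-based inclusive -> half-open
                end=row.end,
                strand=row.strand if row.strand in "+-" else "+",
                gene_name=_attr_first(row.attributes, "gene"),
                product=_attr_first(row.attributes, "product"),
                protein_id=_attr_first(row.attributes, "protein_id"),
            )
        )
    if skipped:
        logger.info("parse_gff(%s): skipped %d rows outside accession filter", gff3_path, skipped)
    return features


def build_gene_index(features: Iterable[GeneFeature]) -> GeneIndex:
    index = GeneIndex()
    for feature in features:
        index.trees.setdefault(feature.accession, IntervalTree()).addi(
            feature.start, feature.end, feature
        )
        index.feature_count += 1
    return index


def _overlap_bases(feature: GeneFeature, start: int, end: int) -> int:
    return max(0, min(feature.end, end) - max(feature.start, start))


def assign_genes(
    alignment: AlignmentResult,
    gene_index: GeneIndex,
    min_overlap: int = 1,
    stranded: bool = False,
) -> GeneAssignment:
    """Primary gene assignment for one taxonomic alignment.

    Among CDS features overlapping the aligned span by at least ``min_overlap``
    bases, the one with the largest overlap wins (ties to the smallest start,
    then the lexicographically smallest feature_id).  No qualifying feature,
    or an accession absent from the index, yields an intergenic assignment.
    """
    if alignment.accession not in gene_index.trees:
        logger.warning("no annotation for accession %s; read %s intergenic",
                       alignment.accession, alignment.read_id)
    strand_symbol = "+" if alignment.strand == "forward" else "-"
    best: tuple[tuple[int, int, str], GeneFeature, int] | None = None
    for feature in gene_index.query_overlaps(
        alignment.accession, alignment.ref_start, alignment.ref_end
    ):
        if stranded and feature.strand != strand_symbol:
            continue
        overlap = _overlap_bases(feature, alignment.ref_start, alignment.ref_end)
        if overlap < min_overlap:
            continue
        key = (-overlap, feature.start, feature.feature_id)
        if best is None or key < best[0]:
            best = (key, feature, overlap)
    if best is None:
        return GeneAssignment(
            read_id=alignment.read_id,
            taxid=alignment.taxid,
            accession=alignment.accession,
            feature_id=INTERGENIC,
            overlap_bases=0,
        )
    _, feature, overlap = best
    return GeneAssignment(
        read_id=alignment.read_id,
        taxid=alignment.taxid,
        accession=alignment.accession,
        feature_id=feature.feature_id,
        overlap_bases=overlap,
        gene_name=feature.gene_name,
        product=feature.product,
        protein_id=feature.protein_id,
    )


def assign_genes_all(
    alignment: AlignmentResult,
    gene_index: GeneIndex,
    min_overlap: int = 1,
    stranded: bool = False,
) -> list[GeneAssignment]:
    """All qualifying overlaps for one alignment (secondary/audit report)."""
    strand_symbol = "+" if alignment.strand == "forward" else "-"
    out: list[GeneAssignment] = []
    for feature in gene_index.query_overlaps(
        alignment.accession, alignment.ref_start, alignment.ref_end
    ):
        if stranded and feature.strand != strand_symbol:
            continue
        overlap = _overlap_bases(feature, alignment.ref_start, alignment.ref_end)
        if overlap >= min_overlap:
            out.append(
                GeneAssignment(
                    read_id=alignment.read_id,
                    taxid=alignment.taxid,
                    accession=alignment.accession,
                    feature_id=feature.feature_id,
                    overlap_bases=overlap,
                    gene_name=feature.gene_name,
                    product=feature.product,
                    protein_id=feature.protein_id,
                )
            )
    return out


def export_proteins(
    gene_assignments: Iterable[GeneAssignment],
    protein_fasta_path: str | Path,
    out_path: str | Path,
) -> int:
    """Write each distinct assigned feature's protein once; returns the count.

    The input protein FASTA is keyed by protein_id; output records use the
    feature_id as the record id (ortholog-annotator-friendly headers).
    Features without a protein record are skipped and counted in the log.
    """
    wanted: dict[str, str] = {}
    for assignment in gene_assignments:
        if assignment.feature_id != INTERGENIC and assignment.protein_id:
            wanted.setdefault(assignment.feature_id, assignment.protein_id)
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta_path), "fasta")}
    written = 0
    missing = 0
    with open(out_path, "w") as fh:
        for feature_id in sorted(wanted):
            seq = proteins.get(wanted[feature_id])
            if seq is None:
                missing += 1
                continue
            fh.write(f">{feature_id}\n{seq}\n")
            written += 1
    if missing:
        logger.warning("export_proteins: %d assigned features had no protein record", missing)
    return written


def write_gene_assignments(
    assignments: Iterable[tuple[GeneAssignment, str]], path: str | Path
) -> None:
    """Write (assignment, read status) rows as the gene report TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_REPORT_COLUMNS)
        for assignment, status in assignments:
            writer.writerow(
                [
                    assignment.read_id,
                    assignment.taxid,
                    assignment.accession,
                    assignment.feature_id,
                    assignment.gene_name,
                    assignment.product,
                    assignment.protein_id,
                    assignment.overlap_bases,
                    status,
                ]
            )
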