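"""Reference collection handling: sequences, taxonomy, and chunk partitioning.

A reference collection is a multi-record genome FASTA plus a tab-separated
metadata table mapping each accession to a species taxid and its genus.  The
collection is partitioned into size-bounded chunks that are indexed
independently, which keeps peak memory proportional to the chunk size rather
than the full database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import InputError

METADATA_COLUMNS = ["accession", "taxid", "species_name", "genus_taxid", "genus_name"]

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference genome sequence with its species taxid."""

    accession: str
    taxid: int
    sequence: str

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise InputError(f"taxid must be positive, got {self.taxid} for {self.accession}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TaxonomyMap:
    """Self-contained two-level taxonomy: species and their genera.

    Built from the metadata table so no external taxonomy database is needed.
    """

    accession_to_taxid: dict[str, int] = field(default_factory=dict)
    taxid_to_name: dict[int, str] = field(default_factory=dict)
    taxid_to_parent: dict[int, int] = field(default_factory=dict)
    rank_of: dict[int, str] = field(default_factory=dict)


@dataclass
class ReferenceChunk:
    """A contiguous partition of the collection, indexed independently."""

    chunk_id: int
    members: list[ReferenceSequence]

    @property
    def total_bases(self) -> int:
        return sum(m.length for m in self.members)


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    return _NON_ACGT.sub("N", seq.upper())


def load_metadata(metadata_path: str | Path) -> TaxonomyMap:
    """Parse the accession/taxid/genus metadata TSV into a TaxonomyMap."""
    taxonomy = TaxonomyMap()
    path = Path(metadata_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in METADATA_COLUMNS if c not in header]
        if missing:
            raise InputError(f"metadata {path} missing columns: {missing}")
        col = {c: header.index(c) for c in METADATA_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                accession = parts[col["accession"]]
                taxid = int(parts[col["taxid"]])
                genus_taxid = int(parts[col["genus_taxid"]])
            except (IndexError, ValueError) as exc:
                raise InputError(f"metadata {path} line {lineno}: {exc}") from exc
            taxonomy.accession_to_taxid[accession] = taxid
            taxonomy.taxid_to_name[taxid] = parts[col["species_name"]]
            taxonomy.taxid_to_name[genus_taxid] = parts[col["genus_name"]]
            taxonomy.taxid_to_parent[taxid] = genus_taxid
            taxonomy.rank_of[taxid] = "species"
            taxonomy.rank_of[genus_taxid] = "genus"
    return taxonomy


def load_references(
    fasta_path: str | Path, metadata_path: str | Path
) -> tuple[list[ReferenceSequence], TaxonomyMap]:
    """Load a reference FASTA and its metadata table.

    Every FASTA record id must have a metadata row; sequences are uppercased
    with ambiguous characters normalized to N.
    """
    taxonomy = load_metadata(metadata_path)
    sequences: list[ReferenceSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        accession = record.id
        if accession in seen:
            raise InputError(f"duplicate accession {accession} in {fasta_path}")
        seen.add(accession)
        if accession not in taxonomy.accession_to_taxid:
            raise InputError(
                f"accession {accession} in {fasta_path} has no metadata row in {metadata_path}"
            )
        sequences.append(
            ReferenceSequence(
                accession=accession,
                taxid=taxonomy.accession_to_taxid[accession],
                sequence=normalize_sequence(str(record.seq)),
            )
        )
    if not sequences:
        raise InputError(f"no FASTA records found in {fasta_path}")
    return sequences, taxonomy


def write_references(
    sequences: Iterable[ReferenceSequence],
    taxonomy: TaxonomyMap,
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the collection back out as FASTA + metadata TSV (load round-trips)."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.accession, description="") for s in sequences
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(metadata_path, "w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for s in sequences:
            genus = taxonomy.taxid_to_parent[s.taxid]
            fh.write(
                "\t".join(
                    [
                        s.accession,
                        str(s.taxid),
                        taxonomy.taxid_to_name.get(s.taxid, ""),
                        str(genus),
                        taxonomy.taxid_to_name.get(genus, ""),
                    ]
                )
                + "\n"
            )


def partition_references(
    sequences: list[ReferenceSequence], max_chunk_bases: int
) -> list[ReferenceChunk]:
    """Greedy first-fit partition of the collection in input order.

    Each chunk holds at most ``max_chunk_bases`` total bases, except that a
    single sequence larger than the cap sits alone in its own chunk.
    """
    if max_chunk_bases <= 0:
        raise InputError(f"max_chunk_bases must be positive, got {max_chunk_bases}")
    chunks: list[ReferenceChunk] = []
    current: list[ReferenceSequence] = []
    current_bases = 0
    for seq in sequences:
        if current and current_bases + seq.length > max_chunk_bases:
            chunks.append(ReferenceChunk(chunk_id=len(chunks), members=current))
            current, current_bases = [], 0
        current.append(seq)
        current_bases += seq.length
    if current:
        chunks.append(ReferenceChunk(chunk_id=len(chunks), members=current))
    return chunks


def genus_of(taxonomy: TaxonomyMap, species_taxid: int) -> int:
    """Walk parent links from a species taxid to its genus ancestor."""
    if species_taxid not in taxonomy.rank_of:
        raise InputError(f"unknown taxid {species_taxid}")
    taxid = species_taxid
    seen = {taxid}
    while taxonomy.rank_of.get(taxid) != "genus":
        parent = taxonomy.taxid_to_parent.get(taxid)
        if parent is None or parent in seen:
            raise InputError(f"taxid {species_taxid} has no genus ancestor")
        seen.add(parent)
        taxid = parent
    return taxid


def write_chunk_manifest(chunks: list[ReferenceChunk], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chunk_id\taccession\n")
        for chunk in chunks:
            for member in chunk.members:
                fh.write(f"{chunk.chunk_id}\t{member.accession}\n")
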