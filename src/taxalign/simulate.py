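"""Synthetic community simulator: annotated genomes, abundance profiles,
mutated reads with per-read truth labels, and accuracy scoring.

This module is the fixture engine for the whole pipeline.  It emulates a
CAMI2-style community (log-normal relative abundances), draws 150 bp
single-end reads from CDS features only (so every read has a defined gene
truth), and introduces sequencing mutations with an i.i.d. substitution +
rare geometric-length indel model, recording every mutation so each read can
be reconstructed exactly from its truth record.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .assign import ReadAssignment
from .errors import InputError
from .fm_index import reverse_complement
from .genes import GeneFeature
from .reference_db import ReferenceSequence, TaxonomyMap, write_references

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenome:
    accession: str
    taxid: int
    sequence: str
    features: list[GeneFeature]
    rng_seed: int
    genus_taxid: int
    species_name: str = ""
    genus_name: str = ""
    og_parent: dict[str, str] = field(default_factory=dict)  # diverged feature -> ancestor


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    true_taxid: int
    true_accession: str
    true_feature_id: str
    true_start: int  # forward-strand 0-based start of the source span
    strand: str      # '+' or '-'
    n_subs: int
    n_indels: int
    mutations: tuple = ()  # ('S', off, base) | ('I', off, bases) | ('D', off, length)


@dataclass
class AccuracyReport:
    """Assignment accuracy against truth labels.

    Fractions are None when their denominator is empty (no assigned or no
    correct reads).  Correctness uses containment semantics: a read counts as
    correct if its hit set contains the true taxon; uniqueness among correct
    reads is reported separately.
    """

    fraction_assigned: float
    fraction_correct: float | None
    fraction_unique_species: float | None
    unexpected_species_count: int
    reads_to_unexpected: int


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    taxid: int,
    length: int,
    n_genes: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    accession: str | None = None,
    genus_taxid: int | None = None,
    min_gene_codons: int = 50,
    max_gene_codons: int = 300,
) -> SyntheticGenome:
    """I.i.d. random genome at a given GC with non-overlapping CDS features.

    Gene lengths are uniform multiples of 3 in [3*min_gene_codons,
    3*max_gene_codons]; placement is uniform by rejection.  Deterministic
    under the seed.
    """
    if n_genes * 3 * min_gene_codons > length / 2:
        raise InputError("gene density too high: n_genes * min length exceeds half the genome")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    sequence = rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
    accession = accession or f"SYN_{taxid}.1"
    genus_taxid = genus_taxid if genus_taxid is not None else taxid + 1_000_000
    placed: list[tuple[int, int]] = []
    features: list[GeneFeature] = []
    attempts = 0
    max_attempts = 200 * max(1, n_genes)
    while len(features) < n_genes:
        if attempts >= max_attempts:
            raise InputError(
                f"could not place {n_genes} genes in {length} bp after {max_attempts} "
                "attempts; lower the gene density"
            )
        attempts += 1
        gene_len = 3 * int(rng.integers(min_gene_codons, max_gene_codons + 1))
        start = int(rng.integers(0, length - gene_len + 1))
        end = start + gene_len
        if any(start < e and s < end for s, e in placed):
            continue
        placed.append((start, end))
        i = len(features)
        feature_id = f"{accession}_{i:04d}"
        features.append(
            GeneFeature(
                feature_id=feature_id,
                accession=accession,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                gene_name=f"gene{i:04d}",
                product=f"synthetic protein {i:04d}",
                protein_id=f"{feature_id}_p",
            )
        )
    features.sort(key=lambda f: f.start)
    return SyntheticGenome(
        accession=accession,
        taxid=taxid,
        sequence=sequence,
        features=features,
        rng_seed=seed,
        genus_taxid=genus_taxid,
        species_name=f"Synthspecies sp{taxid}",
        genus_name=f"Synthgenus g{genus_taxid}",
    )


def diverge_genome(
    genome: SyntheticGenome,
    substitution_rate: float,
    new_taxid: int | None = None,
    seed: int = 0,
    accession: str | None = None,
    genus_taxid: int | None = None,
) -> SyntheticGenome:
    """Copy a genome with i.i.d. substitutions; features keep their coordinates.

    Models a strain (same taxid) or a sister species (new taxid) to exercise
    ambiguity handling and per-taxon early stopping.
    """
    if not 0 <= substitution_rate <= 0.3:
        raise InputError("substitution_rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    taxid = new_taxid if new_taxid is not None else genome.taxid
    accession = accession or f"{genome.accession}_d{seed}"
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(len(seq)) < substitution_rate
    idx = np.flatnonzero(mask)
    base_code = np.searchsorted(_BASES, seq[idx])  # _BASES is sorted (ACGT)
    new_code = (base_code + rng.integers(1, 4, size=len(idx))) % 4
    seq[idx] = _BASES[new_code]
    features = []
    og_parent = {}
    for i, f in enumerate(genome.features):
        new_id = f"{accession}_{i:04d}"
        og_parent[new_id] = genome.og_parent.get(f.feature_id, f.feature_id)
        features.append(
            replace(f, feature_id=new_id, accession=accession, protein_id=f"{new_id}_p")
        )
    genus = genus_taxid if genus_taxid is not None else (
        genome.genus_taxid if taxid == genome.taxid else taxid + 1_000_000
    )
    return SyntheticGenome(
        accession=accession,
        taxid=taxid,
        sequence=seq.tobytes().decode("ascii"),
        features=features,
        rng_seed=seed,
        genus_taxid=genus,
        species_name=f"Synthspecies sp{taxid}",
        genus_name=f"Synthgenus g{genus}",
        og_parent=og_parent,
    )


def community_profile(
    taxids: Sequence[int], sigma: float = 1.0, seed: int = 0
) -> dict[int, float]:
    """Log-normal relative abundances over the given taxa, summing to 1."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=len(taxids))
    raw /= raw.sum()
    return {int(t): float(a) for t, a in zip(taxids, raw)}


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _mutate_span(
    seq: str, start: int, read_length: int, sub_rate: float, indel_rate: float, rng
) -> tuple[str, list[tuple]]:
    """Emit a mutated read of read_length starting at ``start`` on the forward
    strand, recording ops as (type, ref_offset_from_start, payload)."""
    ops: list[tuple] = []
    if indel_rate == 0.0:
        span = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8, count=read_length, offset=start
        ).copy()
        if sub_rate > 0.0:
            mask = rng.random(read_length) < sub_rate
            idx = np.flatnonzero(mask)
            if len(idx):
                base_code = np.searchsorted(_BASES, span[idx])
                new_code = (base_code + rng.integers(1, 4, size=len(idx))) % 4
                span[idx] = _BASES[new_code]
                for off, code in zip(idx, new_code):
                    ops.append(("S", int(off), chr(_BASES[code])))
        return span.tobytes().decode("ascii"), ops
    out: list[str] = []
    pos = start
    n = len(seq)
    while len(out) < read_length and pos < n:
        r = rng.random()
        if r < indel_rate:
            ln = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                ins = "".join(chr(_BASES[c]) for c in rng.integers(0, 4, size=ln))
                ins = ins[: read_length - len(out)]
                ops.append(("I", pos - start, ins))
                out.extend(ins)
            else:
                ops.append(("D", pos - start, ln))
                pos += ln
            continue
        base = seq[pos]
        if rng.random() < sub_rate:
            new = chr(_BASES[(int(np.searchsorted(_BASES, ord(base))) + int(rng.integers(1, 4))) % 4])
            ops.append(("S", pos - start, new))
            out.append(new)
        else:
            out.append(base)
        pos += 1
    if len(out) < read_length:
        out.extend("A" * (read_length - len(out)))  # ran off the genome end (rare)
    return "".join(out), ops


def reconstruct_read(genome_sequence: str, truth: TruthRecord, read_length: int) -> str:
    """Re-derive a read from its truth record by replaying recorded mutations."""
    out: list[str] = []
    ref_off = 0
    for op in truth.mutations:
        kind, off = op[0], op[1]
        while ref_off < off and len(out) < read_length:
            out.append(genome_sequence[truth.true_start + ref_off])
            ref_off += 1
        if len(out) >= read_length:
            break
        if kind == "S":
            out.append(op[2])
            ref_off += 1
        elif kind == "I":
            out.extend(op[2])
        elif kind == "D":
            ref_off += op[2]
    while len(out) < read_length:
        pos = truth.true_start + ref_off
        if pos >= len(genome_sequence):
            out.append("A")
        else:
            out.append(genome_sequence[pos])
        ref_off += 1
    read = "".join(out[:read_length])
    return reverse_complement(read) if truth.strand == "-" else read


def simulate_reads(
    genomes: Sequence[SyntheticGenome],
    profile: Mapping[int, float],
    n_reads: int,
    read_length: int = 150,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Draw reads from CDS features according to the abundance profile.

    The source taxon follows the profile; the feature is chosen within the
    representative genome weighted by length; the start is uniform such that
    the read fits inside the feature; the strand is uniform.  Returns
    (read_id, sequence) pairs and matching truth records.
    """
    by_taxid: dict[int, SyntheticGenome] = {}
    for g in genomes:
        by_taxid.setdefault(g.taxid, g)  # first genome is the representative
    for taxid in profile:
        if taxid not in by_taxid:
            raise InputError(f"profile taxon {taxid} has no genome")
        g = by_taxid[taxid]
        if not g.features:
            raise InputError(f"genome {g.accession} has no CDS features to read from")
        shortest = min(f.end - f.start for f in g.features)
        if read_length > shortest:
            raise InputError(
                f"read_length {read_length} exceeds shortest feature ({shortest} bp) "
                f"of genome {g.accession}"
            )
    rng = np.random.default_rng(seed)
    taxids = sorted(profile)
    probs = np.array([profile[t] for t in taxids], dtype=float)
    probs /= probs.sum()
    taxon_draw = rng.choice(len(taxids), size=n_reads, p=probs)
    reads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    feature_weights = {
        t: np.array([f.end - f.start for f in by_taxid[t].features], dtype=float)
        for t in taxids
    }
    for t in feature_weights:
        feature_weights[t] /= feature_weights[t].sum()
    for i in range(n_reads):
        taxid = taxids[taxon_draw[i]]
        genome = by_taxid[taxid]
        fi = int(rng.choice(len(genome.features), p=feature_weights[taxid]))
        feature = genome.features[fi]
        start = int(rng.integers(feature.start, feature.end - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq, ops = _mutate_span(genome.sequence, start, read_length, sub_rate, indel_rate, rng)
        if strand == "-":
            seq = reverse_complement(seq)
        read_id = f"read_{i:07d}"
        reads.append((read_id, seq))
        truths.append(
            TruthRecord(
                read_id=read_id,
                true_taxid=taxid,
                true_accession=genome.accession,
                true_feature_id=feature.feature_id,
                true_start=start,
                strand=strand,
                n_subs=sum(1 for op in ops if op[0] == "S"),
                n_indels=sum(1 for op in ops if op[0] in "ID"),
                mutations=tuple(ops),
            )
        )
    return reads, truths


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

def build_taxonomy(genomes: Sequence[SyntheticGenome]) -> TaxonomyMap:
    taxonomy = TaxonomyMap()
    for g in genomes:
        taxonomy.accession_to_taxid[g.accession] = g.taxid
        taxonomy.taxid_to_name[g.taxid] = g.species_name
        taxonomy.taxid_to_name[g.genus_taxid] = g.genus_name
        taxonomy.taxid_to_parent[g.taxid] = g.genus_taxid
        taxonomy.rank_of[g.taxid] = "species"
        taxonomy.rank_of[g.genus_taxid] = "genus"
    return taxonomy


def translate_cds(genome_sequence: str, feature: GeneFeature) -> str:
    cds = genome_sequence[feature.start : feature.end]
    if feature.strand == "-":
        cds = reverse_complement(cds)
    protein = str(Seq(cds).translate())
    return protein.rstrip("*")


def write_truth_and_annotations(
    genomes: Sequence[SyntheticGenome],
    out_dir: str | Path,
    og_alias: bool = False,
) -> dict[str, Path]:
    """Write reference FASTA, GFF3, protein FASTA, metadata TSV, and OG map.

    With ``og_alias`` enabled, features of diverged genomes share the
    orthologous group of their ancestral feature; otherwise every feature is
    its own group.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "ref.fasta",
        "gff": out_dir / "ref.gff3",
        "proteins": out_dir / "proteins.faa",
        "metadata": out_dir / "metadata.tsv",
        "og_map": out_dir / "og_map.tsv",
    }
    taxonomy = build_taxonomy(genomes)
    refs = [
        ReferenceSequence(accession=g.accession, taxid=g.taxid, sequence=g.sequence)
        for g in genomes
    ]
    write_references(refs, taxonomy, paths["fasta"], paths["metadata"])
    with open(paths["gff"], "w") as gff, open(paths["proteins"], "w") as faa, open(
        paths["og_map"], "w"
    ) as og:
        gff.write("##gff-version 3\n")
        og.write("feature_id\tog_id\n")
        for g in genomes:
            for f in g.features:
                attrs = (
                    f"ID={f.feature_id};locus_tag={f.feature_id};gene={f.gene_name};"
                    f"product={f.product};protein_id={f.protein_id}"
                )
                gff.write(
                    f"{g.accession}\ttaxalign_sim\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t0\t{attrs}\n"
                )
                faa.write(f">{f.protein_id}\n{translate_cds(g.sequence, f)}\n")
                ancestor = g.og_parent.get(f.feature_id, f.feature_id) if og_alias else f.feature_id
                og.write(f"{f.feature_id}\tOG_{ancestor}\n")
    return paths


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Constant-quality FASTQ ('I' throughout); gzip if the path ends in .gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


TRUTH_COLUMNS = [
    "read_id", "true_taxid", "true_accession", "true_feature_id",
    "true_start", "strand", "n_subs", "n_indels", "mutations",
]


def _format_ops(ops: tuple) -> str:
    return ";".join(
        f"{k}:{off}:{payload}" for k, off, payload in ops
    )


def _parse_ops(text: str) -> tuple:
    if not text:
        return ()
    ops = []
    for item in text.split(";"):
        kind, off, payload = item.split(":", 2)
        ops.append((kind, int(off), int(payload) if kind == "D" else payload))
    return tuple(ops)


def write_truth(truths: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for t in truths:
            writer.writerow(
                [t.read_id, t.true_taxid, t.true_accession, t.true_feature_id,
                 t.true_start, t.strand, t.n_subs, t.n_indels, _format_ops(t.mutations)]
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    truths = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            truths.append(
                TruthRecord(
                    read_id=row["read_id"],
                    true_taxid=int(row["true_taxid"]),
                    true_accession=row["true_accession"],
                    true_feature_id=row["true_feature_id"],
                    true_start=int(row["true_start"]),
                    strand=row["strand"],
                    n_subs=int(row["n_subs"]),
                    n_indels=int(row["n_indels"]),
                    mutations=_parse_ops(row["mutations"]),
                )
            )
    return truths


def write_profile(profile: Mapping[int, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tabundance\n")
        for taxid in sorted(profile):
            fh.write(f"{taxid}\t{profile[taxid]:.10g}\n")


# ---------------------------------------------------------------------------
# Accuracy evaluation
# ---------------------------------------------------------------------------

def evaluate_assignments(
    truth: Sequence[TruthRecord],
    assignments: Mapping[str, ReadAssignment],
    expected_taxa: set[int],
) -> AccuracyReport:
    """Score assignments against truth labels.

    fraction_assigned: reads with >= 1 hit / all reads.
    fraction_correct: assigned reads whose hit set contains the true taxon /
    assigned reads.  fraction_unique_species: correct reads with exactly one
    hit / correct reads.  Unexpected species are hit taxa outside
    ``expected_taxa``; reads_to_unexpected counts assigned reads all of whose
    hits are unexpected.
    """
    truth_ids = {t.read_id for t in truth}
    if truth_ids != set(assignments):
        raise InputError(
            f"truth/assignment read-id mismatch: {len(truth_ids)} truth ids vs "
            f"{len(assignments)} assignment ids"
        )
    n_total = len(truth)
    n_assigned = 0
    n_correct = 0
    n_unique = 0
    hit_taxa: set[int] = set()
    reads_to_unexpected = 0
    for t in truth:
        hits = assignments[t.read_id].hits
        if not hits:
            continue
        n_assigned += 1
        hit_taxa.update(hits)
        if all(taxid not in expected_taxa for taxid in hits):
            reads_to_unexpected += 1
        if t.true_taxid in hits:
            n_correct += 1
            if len(hits) == 1:
                n_unique += 1
    unexpected = hit_taxa - set(expected_taxa)
    return AccuracyReport(
        fraction_assigned=n_assigned / n_total if n_total else 0.0,
        fraction_correct=n_correct / n_assigned if n_assigned else None,
        fraction_unique_species=n_unique / n_correct if n_correct else None,
        unexpected_species_count=len(unexpected),
        reads_to_unexpected=reads_to_unexpected,
    )
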