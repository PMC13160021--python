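"""Taxon-resolved count matrices: aggregation, OG collapse, genus roll-up,
and the low-abundance filter applied before differential expression.

A count matrix is a pandas DataFrame with a (taxid, feature) MultiIndex over
rows and sample ids as columns, wrapped with a level tag: species_gene counts
straight from read assignments, species_OG after collapsing genes to
orthologous groups, genus_OG after rolling species up to their genus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genes import INTERGENIC, GeneAssignment
from .reference_db import TaxonomyMap, genus_of

SPECIES_GENE = "species_gene"
SPECIES_OG = "species_OG"
GENUS_OG = "genus_OG"


@dataclass
class CountMatrix:
    data: pd.DataFrame  # rows: MultiIndex (taxid, feature); columns: sample ids
    level: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class OGMap:
    """Many-to-one feature_id -> orthologous-group mapping."""

    mapping: dict[str, str]
    unmapped_policy: str = "keep"  # keep features under their own id, or "drop"

    @classmethod
    def from_tsv(cls, path: str | Path, unmapped_policy: str = "keep") -> "OGMap":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:2] != ["feature_id", "og_id"]:
                raise InputError(f"{path}: expected columns feature_id, og_id")
            for row in reader:
                if row and row[0]:
                    if not row[1]:
                        raise InputError(f"{path}: empty og_id for {row[0]}")
                    mapping[row[0]] = row[1]
        return cls(mapping=mapping, unmapped_policy=unmapped_policy)


def _largest_remainder_round(values: pd.Series) -> pd.Series:
    """Round non-negative floats to ints preserving the (rounded) column sum."""
    target = int(round(values.sum()))
    floors = np.floor(values.to_numpy())
    deficit = target - int(floors.sum())
    out = floors.astype(np.int64)
    if deficit > 0:
        remainders = values.to_numpy() - floors
        order = np.lexsort((np.arange(len(values)), -remainders))
        out[order[:deficit]] += 1
    return pd.Series(out, index=values.index)


def aggregate_counts(
    gene_assignments_per_sample: Mapping[str, Sequence[tuple[GeneAssignment, str]]],
    multi_taxon_policy: str = "exclude",
) -> CountMatrix:
    """Tally primary gene assignments into a species_gene count matrix.

    Input maps sample id -> list of (primary GeneAssignment, read status).
    Intergenic assignments never count.  Reads with multi_taxon status are
    excluded by default; with policy "fractional" each such read is split
    evenly across its taxa and rounded per column by largest remainder.
    """
    if multi_taxon_policy not in ("exclude", "fractional"):
        raise InputError(f"unknown multi_taxon_policy {multi_taxon_policy!r}")
    columns: dict[str, pd.Series] = {}
    for sample in sorted(gene_assignments_per_sample):
        rows = gene_assignments_per_sample[sample]
        tally: dict[tuple[int, str], float] = {}
        weights: dict[str, float] = {}
        if multi_taxon_policy == "fractional":
            per_read: dict[str, int] = {}
            for assignment, status in rows:
                if status == "multi_taxon":
                    per_read[assignment.read_id] = per_read.get(assignment.read_id, 0) + 1
            weights = {rid: 1.0 / n for rid, n in per_read.items()}
        for assignment, status in rows:
            if assignment.feature_id == INTERGENIC:
                continue
            if status == "multi_taxon":
                if multi_taxon_policy == "exclude":
                    continue
                w = weights.get(assignment.read_id, 1.0)
            else:
                w = 1.0
            key = (assignment.taxid, assignment.feature_id)
            tally[key] = tally.get(key, 0.0) + w
        columns[sample] = pd.Series(tally, dtype=float)
    frame = pd.DataFrame(columns).fillna(0.0)
    frame = frame.sort_index()
    if multi_taxon_policy == "fractional" and not frame.empty:
        frame = frame.apply(_largest_remainder_round, axis=0)
    frame = frame.astype(np.int64)
    frame.index = pd.MultiIndex.from_tuples(
        list(frame.index) if len(frame) else [], names=["taxid", "feature"]
    )
    frame.columns.name = "sample"
    return CountMatrix(data=frame, level=SPECIES_GENE)


def collapse_to_og(matrix: CountMatrix, og_map: OGMap) -> CountMatrix:
    """Sum rows sharing (taxid, OG); unmapped features kept or dropped per policy."""
    if matrix.level != SPECIES_GENE:
        raise InputError(f"collapse_to_og expects a {SPECIES_GENE} matrix, got {matrix.level}")
    frame = matrix.data
    keep_mask = []
    og_ids = []
    for taxid, feature in frame.index:
        og = og_map.mapping.get(feature)
        if og is None:
            if og_map.unmapped_policy == "drop":
                keep_mask.append(False)
                og_ids.append(None)
                continue
            og = feature
        keep_mask.append(True)
        og_ids.append(og)
    kept = frame[np.asarray(keep_mask)]
    kept_ogs = [og for og in og_ids if og is not None]
    grouped = kept.groupby(
        [kept.index.get_level_values("taxid"), pd.Index(kept_ogs)]
    ).sum()
    grouped.index.names = ["taxid", "feature"]
    grouped = grouped.sort_index()
    return CountMatrix(data=grouped, level=SPECIES_OG)


def collapse_to_genus(matrix: CountMatrix, taxonomy: TaxonomyMap) -> CountMatrix:
    """Roll species up to their genus; column sums are conserved."""
    if matrix.level != SPECIES_OG:
        raise InputError(f"collapse_to_genus expects a {SPECIES_OG} matrix, got {matrix.level}")
    frame = matrix.data
    genera = [genus_of(taxonomy, t) for t in frame.index.get_level_values("taxid")]
    grouped = frame.groupby(
        [pd.Index(genera), frame.index.get_level_values("feature")]
    ).sum()
    grouped.index.names = ["taxid", "feature"]
    grouped = grouped.sort_index()
    return CountMatrix(data=grouped, level=GENUS_OG)


def filter_low_abundance(
    matrix: CountMatrix,
    sample_groups: Mapping[str, str],
    min_count: int = 5,
    min_samples: int = 3,
    mode: str = "each",
) -> CountMatrix:
    """Drop rows without >= min_count reads in >= min_samples samples per group.

    ``mode`` "each" (default) requires the threshold in every group; "any"
    requires it in at least one.  Surviving rows keep their values unchanged.
    """
    if mode not in ("each", "any"):
        raise InputError(f"unknown filter mode {mode!r}")
    missing = [s for s in matrix.data.columns if s not in sample_groups]
    if missing:
        raise InputError(f"samples missing a group label: {missing}")
    groups: dict[str, list[str]] = {}
    for sample in matrix.data.columns:
        groups.setdefault(sample_groups[sample], []).append(sample)
    per_group = pd.DataFrame(
        {
            g: (matrix.data[samples] >= min_count).sum(axis=1) >= min_samples
            for g, samples in groups.items()
        }
    )
    keep = per_group.all(axis=1) if mode == "each" else per_group.any(axis=1)
    return CountMatrix(data=matrix.data[keep], level=matrix.level)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_report(path: str | Path) -> list[tuple[GeneAssignment, str]]:
    """Load a per-sample gene report TSV back into assignment rows."""
    rows: list[tuple[GeneAssignment, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                (
                    GeneAssignment(
                        read_id=row["read_id"],
                        taxid=int(row["taxid"]),
                        accession=row["accession"],
                        feature_id=row["feature_id"],
                        overlap_bases=int(row["overlap_bases"]),
                        gene_name=row.get("gene_name", ""),
                        product=row.get("product", ""),
                        protein_id=row.get("protein_id", ""),
                    ),
                    row["status"],
                )
            )
    return rows


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    sheet: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["sample_id", "group"]:
            raise InputError(f"{path}: expected columns sample_id, group")
        for row in reader:
            if row:
                sheet[row[0]] = row[1]
    return sheet


def write_dense(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.insert(0, "feature", out.index.get_level_values("feature"))
    out.insert(0, "taxid", out.index.get_level_values("taxid"))
    out.to_csv(path, sep="\t", index=False)


def write_triplets(matrix: CountMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxid", "feature", "sample", "count"])
        for (taxid, feature), row in matrix.data.iterrows():
            for sample, count in row.items():
                if count:
                    writer.writerow([taxid, feature, sample, int(count)])


def read_dense(path: str | Path, level: str) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t")
    frame = frame.set_index(["taxid", "feature"])
    frame.index.names = ["taxid", "feature"]
    return CountMatrix(data=frame.astype(np.int64), level=level)
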