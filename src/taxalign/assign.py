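"""Taxonomic read assignment: seeding, candidate alignment, merging, resolution.

Each read is decomposed into fixed-length seeds on both strands; exact seed
hits from the FM-index are clustered by diagonal into candidate regions, which
are verified in descending order of seed support by a bounded-edit-distance
alignment of the full read within a padded reference window.  Once a taxon has
one passing alignment, its remaining candidates are skipped (per-taxon early
stop).  Per-chunk reports are merged and ambiguity is optionally resolved by
edit-distance slack and per-sample taxon support filters.

Alignment semantics: semi-global unit-cost edit distance — the whole read must
align, end gaps in the reference window are free.  The default kernel is
edlib's infix mode; a plain dynamic-programming kernel with identical score
semantics is provided both as a fallback and as the reference implementation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .fm_index import CODE_N, FMIndex, encode, reverse_complement
from .reference_db import TaxonomyMap

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover - edlib is a hard dependency in practice
    _HAVE_EDLIB = False

FORWARD = "forward"
REVERSE = "reverse"

UNASSIGNED = "unassigned"
UNIQUE = "unique"
MULTI_TAXON = "multi_taxon"

REPORT_COLUMNS = [
    "read_id",
    "taxid",
    "accession",
    "ref_start",
    "ref_end",
    "strand",
    "edit_distance",
    "status",
]


@dataclass(frozen=True)
class SeedingParams:
    """Seeding schedule and candidate thresholds.

    Defaults suit 150 bp reads: 18-mer seeds every 9 bases give 16 seeds per
    strand, so a read tolerates several mismatches while still leaving
    multiple clean seeds to anchor its true locus.
    """

    seed_length: int = 18
    seed_interval: int = 9
    min_seed_hits: int = 2
    diagonal_tolerance: int = 5

    def __post_init__(self) -> None:
        if self.seed_length < 10:
            raise InputError("seed_length must be >= 10")
        if self.seed_interval < 1:
            raise InputError("seed_interval must be >= 1")
        if self.min_seed_hits < 1:
            raise InputError("min_seed_hits must be >= 1")


DEFAULT_MAX_EDITS = 7  # ~5% of a 150 bp read


@dataclass(frozen=True)
class CandidateRegion:
    accession: str
    taxid: int
    strand: str
    projected_start: int  # reference position implied by the seed diagonal
    support: int          # seeds agreeing with this diagonal within tolerance


@dataclass(frozen=True)
class AlignmentResult:
    read_id: str
    accession: str
    taxid: int
    strand: str
    ref_start: int  # 0-based half-open span on the forward reference strand
    ref_end: int
    edit_distance: int


@dataclass
class ReadAssignment:
    read_id: str
    hits: dict[int, AlignmentResult] = field(default_factory=dict)  # taxid -> hit
    status: str = UNASSIGNED

    def update_status(self) -> None:
        n = len(self.hits)
        self.status = UNASSIGNED if n == 0 else UNIQUE if n == 1 else MULTI_TAXON


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def seed_offsets(read_length: int, params: SeedingParams) -> list[int]:
    """Seed start offsets: a tiled schedule plus a final end-anchored seed."""
    if read_length < params.seed_length:
        return []
    offsets = list(range(0, read_length - params.seed_length + 1, params.seed_interval))
    last = read_length - params.seed_length
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def extract_seeds(
    read_sequence: str, params: SeedingParams
) -> list[tuple[int, str, str]]:
    """Decompose a read into (offset, seed, strand) tuples on both strands.

    Reverse-strand offsets are measured on the reverse-complemented read.
    Seeds containing N are omitted; reads shorter than one seed yield nothing.
    """
    read_sequence = read_sequence.upper()
    out: list[tuple[int, str, str]] = []
    for strand, seq in ((FORWARD, read_sequence), (REVERSE, reverse_complement(read_sequence))):
        for off in seed_offsets(len(seq), params):
            seed = seq[off : off + params.seed_length]
            if "N" not in seed:
                out.append((off, seed, strand))
    return out


# ---------------------------------------------------------------------------
# Candidate collection
# ---------------------------------------------------------------------------

def collect_candidates(
    matches: Iterable[tuple[int, str, int, str]],
    taxonomy: TaxonomyMap,
    params: SeedingParams,
) -> list[CandidateRegion]:
    """Cluster seed matches into candidate regions by diagonal.

    ``matches`` carries (read_offset, accession, ref_offset, strand); the
    diagonal of a match is ref_offset - read_offset.  Matches on the same
    (accession, strand) whose consecutive sorted diagonals differ by at most
    ``diagonal_tolerance`` form one cluster; clusters below ``min_seed_hits``
    are dropped.  Output is sorted by support descending with deterministic
    tie-breaks (taxid, accession, projected_start ascending).
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for read_offset, accession, ref_offset, strand in matches:
        by_key.setdefault((accession, strand), []).append(ref_offset - read_offset)
    candidates: list[CandidateRegion] = []
    for (accession, strand), diagonals in by_key.items():
        diagonals.sort()
        start = 0
        for i in range(1, len(diagonals) + 1):
            if i == len(diagonals) or diagonals[i] - diagonals[i - 1] > params.diagonal_tolerance:
                support = i - start
                if support >= params.min_seed_hits:
                    candidates.append(
                        CandidateRegion(
                            accession=accession,
                            taxid=taxonomy.accession_to_taxid[accession],
                            strand=strand,
                            projected_start=diagonals[start],
                            support=support,
                        )
                    )
                start = i
    candidates.sort(
        key=lambda c: (-c.support, c.taxid, c.accession, c.projected_start)
    )
    return candidates


# ---------------------------------------------------------------------------
# Alignment kernels
# ---------------------------------------------------------------------------

def align_dp(read: str, window: str) -> tuple[int, int, int]:
    """Reference semi-global edit-distance DP (O(len(read)*len(window))).

    Returns (edit_distance, window_start, window_end) of the best alignment of
    the full read inside the window, with free end gaps in the window.  Ties
    prefer the smallest end position, then the widest span.
    """
    m, n = len(read), len(window)
    prev = list(range(0, 1))  # placeholder, rebuilt below
    # dist rows over window positions; start[j] = window offset where the
    # alignment ending at column j began.
    prev = [0] * (n + 1)
    prev_start = list(range(n + 1))
    for i in range(1, m + 1):
        ci = read[i - 1]
        cur = [i] + [0] * n
        cur_start = [0] * (n + 1)
        cur_start[0] = 0
        for j in range(1, n + 1):
            diag = prev[j - 1] + (ci != window[j - 1])
            up = prev[j] + 1
            left = cur[j - 1] + 1
            best = diag
            best_start = prev_start[j - 1]
            if up < best:
                best, best_start = up, prev_start[j]
            if left < best:
                best, best_start = left, cur_start[j - 1]
            cur[j], cur_start[j] = best, best_start
        prev, prev_start = cur, cur_start
    best_j = min(range(n + 1), key=lambda j: (prev[j], j))
    return prev[best_j], prev_start[best_j], best_j


def align_candidate(
    read_sequence: str,
    reference_window: str,
    max_edits: int,
    kernel: str = "auto",
) -> tuple[int, int, int] | None:
    """Align the full read inside a reference window under unit edit costs.

    Returns (edit_distance, window_start, window_end) iff the distance is at
    most ``max_edits``, else None.  Kernels ("edlib" or "dp") are score-exact
    equivalents; reported spans may differ between co-optimal alignments.
    """
    if not reference_window:
        return None
    if kernel == "auto":
        kernel = "edlib" if _HAVE_EDLIB else "dp"
    if kernel == "edlib":
        res = edlib.align(
            read_sequence, reference_window, mode="HW", task="locations", k=max_edits
        )
        if res["editDistance"] < 0:
            return None
        start, end_incl = res["locations"][0]
        return res["editDistance"], start, end_incl + 1
    dist, start, end = align_dp(read_sequence, reference_window)
    if dist > max_edits:
        return None
    return dist, start, end


def window_pad(max_edits: int) -> int:
    return max_edits + 5


# ---------------------------------------------------------------------------
# Per-read assignment
# ---------------------------------------------------------------------------

def _evaluate_candidates(
    read_id: str,
    read_sequence: str,
    candidates: Sequence[CandidateRegion],
    index: FMIndex,
    max_edits: int,
    exhaustive: bool = False,
    stats: dict | None = None,
) -> ReadAssignment:
    assignment = ReadAssignment(read_id=read_id)
    read_fwd = read_sequence.upper()
    read_rev = reverse_complement(read_fwd)
    pad = window_pad(max_edits)
    for cand in candidates:
        if not exhaustive and cand.taxid in assignment.hits:
            continue  # per-taxon early stop
        member = index.member_index(cand.accession)
        win_start = max(0, cand.projected_start - pad)
        win_end = cand.projected_start + len(read_fwd) + pad
        window = index.member_slice(member, win_start, win_end)
        query = read_fwd if cand.strand == FORWARD else read_rev
        if stats is not None:
            stats["alignment_calls"] = stats.get("alignment_calls", 0) + 1
        result = align_candidate(query, window, max_edits)
        if result is None:
            continue
        dist, span_start, span_end = result
        hit = AlignmentResult(
            read_id=read_id,
            accession=cand.accession,
            taxid=cand.taxid,
            strand=cand.strand,
            ref_start=win_start + span_start,
            ref_end=win_start + span_end,
            edit_distance=dist,
        )
        if cand.taxid not in assignment.hits:
            assignment.hits[cand.taxid] = hit
            if stats is not None:
                stats["accepted"] = stats.get("accepted", 0) + 1
    assignment.update_status()
    return assignment


def assign_read(
    read_id: str,
    read_sequence: str,
    index: FMIndex,
    taxonomy: TaxonomyMap,
    params: SeedingParams = SeedingParams(),
    max_edits: int = DEFAULT_MAX_EDITS,
    exhaustive: bool = False,
    stats: dict | None = None,
) -> ReadAssignment:
    """Assign one read against one chunk index.

    ``exhaustive`` disables the per-taxon early stop (used to audit that the
    early stop never changes the set of assigned taxa).  ``stats`` accumulates
    'alignment_calls' and 'accepted' counters when provided.
    """
    matches: list[tuple[int, str, int, str]] = []
    for read_offset, seed, strand in extract_seeds(read_sequence, params):
        for hit in index.locate(seed):
            matches.append((read_offset, hit.accession, hit.offset, strand))
    candidates = collect_candidates(matches, taxonomy, params)
    return _evaluate_candidates(
        read_id, read_sequence, candidates, index, max_edits, exhaustive, stats
    )


def assign_reads(
    reads: Sequence[tuple[str, str]],
    index: FMIndex,
    taxonomy: TaxonomyMap,
    params: SeedingParams = SeedingParams(),
    max_edits: int = DEFAULT_MAX_EDITS,
    stats: dict | None = None,
) -> dict[str, ReadAssignment]:
    """Batch driver: assign many reads against one chunk index.

    Equivalent read-by-read semantics to :func:`assign_read`, but all seeds of
    all reads are backward-searched in one vectorized pass before the per-read
    candidate evaluation loop.
    """
    k = params.seed_length
    seq_fwd = [r[1].upper() for r in reads]
    seq_rev = [reverse_complement(s) for s in seq_fwd]

    rows: list[np.ndarray] = []
    meta_read: list[int] = []
    meta_off: list[int] = []
    meta_strand: list[int] = []  # 0 forward, 1 reverse
    for ri, (fwd, rev) in enumerate(zip(seq_fwd, seq_rev)):
        offs = seed_offsets(len(fwd), params)
        for si, seq in enumerate((fwd, rev)):
            enc = encode(seq)
            for off in offs:
                rows.append(enc[off : off + k])
                meta_read.append(ri)
                meta_off.append(off)
                meta_strand.append(si)

    assignments: dict[str, ReadAssignment] = {}
    if not rows:
        for read_id, _ in reads:
            assignments[read_id] = ReadAssignment(read_id=read_id)
        return assignments

    patterns = np.vstack(rows)
    lo, hi = index.backward_search_batch(patterns)
    widths = hi - lo
    nz = widths > 0
    widths_nz = widths[nz]
    total = int(widths_nz.sum())

    read_arr = np.repeat(np.asarray(meta_read)[nz], widths_nz)
    off_arr = np.repeat(np.asarray(meta_off)[nz], widths_nz)
    strand_arr = np.repeat(np.asarray(meta_strand)[nz], widths_nz)
    cum = np.concatenate(([0], np.cumsum(widths_nz)))
    sa_rows = np.arange(total) - np.repeat(cum[:-1], widths_nz) + np.repeat(lo[nz], widths_nz)
    positions = index._sa_values(sa_rows)
    member_idx, local = index.global_to_local(positions)

    order = np.lexsort((local, strand_arr, member_idx, read_arr))
    read_s = read_arr[order]
    off_s = off_arr[order]
    strand_s = strand_arr[order]
    member_s = member_idx[order]
    local_s = local[order]

    seg_starts = np.searchsorted(read_s, np.arange(len(reads)), side="left")
    seg_ends = np.searchsorted(read_s, np.arange(len(reads)), side="right")
    strand_names = (FORWARD, REVERSE)
    for ri, (read_id, _) in enumerate(reads):
        a, b = seg_starts[ri], seg_ends[ri]
        matches = [
            (int(off_s[j]), index.member_ids[member_s[j]], int(local_s[j]), strand_names[strand_s[j]])
            for j in range(a, b)
        ]
        candidates = collect_candidates(matches, taxonomy, params)
        assignments[read_id] = _evaluate_candidates(
            read_id, seq_fwd[ri], candidates, index, max_edits, stats=stats
        )
    return assignments


# ---------------------------------------------------------------------------
# Merging and ambiguity resolution
# ---------------------------------------------------------------------------

def merge_reports(
    per_chunk_assignments: Sequence[dict[str, ReadAssignment]],
) -> dict[str, ReadAssignment]:
    """Union per-chunk hit sets per read.

    If one taxid was hit in several chunks, the hit with the lowest edit
    distance wins; ties go to the lexicographically smallest accession, then
    the smallest ref_start.  Exact duplicate rows deduplicate silently.
    """
    merged: dict[str, ReadAssignment] = {}
    for report in per_chunk_assignments:
        for read_id, assignment in report.items():
            target = merged.setdefault(read_id, ReadAssignment(read_id=read_id))
            for taxid, hit in assignment.hits.items():
                incumbent = target.hits.get(taxid)
                if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
                    target.hits[taxid] = hit
    for assignment in merged.values():
        assignment.update_status()
    return merged


def _hit_rank(hit: AlignmentResult) -> tuple[int, str, int]:
    return (hit.edit_distance, hit.accession, hit.ref_start)


def resolve_ambiguity(
    assignments: dict[str, ReadAssignment],
    edit_slack: int | float = 0,
    min_taxon_read_fraction: float = 0.0,
) -> dict[str, ReadAssignment]:
    """Filter multi-taxon hits by edit-distance slack and sample-level support.

    Per read, hits worse than (best edit distance + slack) are dropped.  Then
    each taxon's sample support — the fraction of reads whose hit set includes
    it — is computed, and hits to taxa below ``min_taxon_read_fraction`` are
    dropped unless that would leave a read with no hits at all (then its
    minimum-edit-distance hit survives, ties to the smallest taxid).
    Statuses are recomputed in place.
    """
    for assignment in assignments.values():
        if assignment.hits:
            best = min(h.edit_distance for h in assignment.hits.values())
            assignment.hits = {
                t: h
                for t, h in assignment.hits.items()
                if h.edit_distance <= best + edit_slack
            }
    n_reads = len(assignments)
    if n_reads and min_taxon_read_fraction > 0:
        support: dict[int, int] = {}
        for assignment in assignments.values():
            for taxid in assignment.hits:
                support[taxid] = support.get(taxid, 0) + 1
        low = {t for t, c in support.items() if c / n_reads < min_taxon_read_fraction}
        for assignment in assignments.values():
            kept = {t: h for t, h in assignment.hits.items() if t not in low}
            if not kept and assignment.hits:
                fallback = min(
                    assignment.hits.values(), key=lambda h: (h.edit_distance, h.taxid)
                )
                kept = {fallback.taxid: fallback}
            assignment.hits = kept
    for assignment in assignments.values():
        assignment.update_status()
    return assignments


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def write_assignments(assignments: dict[str, ReadAssignment], path: str | Path) -> None:
    """Write the merged report as TSV; unassigned reads get a single NA row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for read_id in sorted(assignments):
            assignment = assignments[read_id]
            if not assignment.hits:
                writer.writerow([read_id, "NA", "NA", "NA", "NA", "NA", "NA", UNASSIGNED])
                continue
            for taxid in sorted(assignment.hits):
                h = assignment.hits[taxid]
                writer.writerow(
                    [
                        read_id,
                        h.taxid,
                        h.accession,
                        h.ref_start,
                        h.ref_end,
                        h.strand,
                        h.edit_distance,
                        assignment.status,
                    ]
                )


def read_assignments(path: str | Path) -> dict[str, ReadAssignment]:
    assignments: dict[str, ReadAssignment] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != REPORT_COLUMNS:
            raise InputError(f"{path}: unexpected assignment report columns")
        for row in reader:
            assignment = assignments.setdefault(
                row["read_id"], ReadAssignment(read_id=row["read_id"])
            )
            if row["status"] == UNASSIGNED:
                continue
            hit = AlignmentResult(
                read_id=row["read_id"],
                taxid=int(row["taxid"]),
                accession=row["accession"],
                strand=row["strand"],
                ref_start=int(row["ref_start"]),
                ref_end=int(row["ref_end"]),
                edit_distance=int(row["edit_distance"]),
            )
            assignment.hits[hit.taxid] = hit
    for assignment in assignments.values():
        assignment.update_status()
    return assignments
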