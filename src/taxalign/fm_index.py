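"""FM-index over a reference chunk: BWT, suffix array, and backward search.

The chunk's member sequences are concatenated with a separator symbol between
records (so matches can never span a record boundary) and a terminal sentinel.
The alphabet is {sentinel, separator, A, C, G, N, T} encoded as small integers
in sorted order; N is indexed as its own symbol, so an N in the reference never
matches an A/C/G/T in a pattern, and patterns containing N are rejected
outright (ambiguous bases cannot anchor an exact seed).

Coordinates are 0-based throughout this layer.  Only the forward strand is
indexed; callers search the reverse strand by reverse-complementing the query.

Index files are written as NumPy ``.npz`` archives carrying a magic string and
a format version (see ``save_index``); the layout is documented in the file
``docs/index-format.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import IndexFormatError, InputError
from .reference_db import ReferenceChunk

MAGIC = "TAXALIGN-FMIDX"
FORMAT_VERSION = 1

SENTINEL = 0
SEPARATOR = 1
CODE_N = 5
ALPHABET_SIZE = 7  # $ # A C G N T

_ENCODE = np.zeros(256, dtype=np.int8)
for _ch, _code in zip(b"$#ACGNT", range(7)):
    _ENCODE[_ch] = _code
_DECODE = np.frombuffer(b"$#ACGNT", dtype=np.uint8)

_RC = {ord("A"): "T", ord("C"): "G", ord("G"): "C", ord("T"): "A", ord("N"): "N"}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string (plus separators/sentinel) to int8 codes."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes.astype(np.intp)].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), fully vectorized).

    Requires the text to end in a unique smallest symbol (the sentinel).
    """
    n = len(text)
    rank = text.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        r_o, k_o = rank[order], key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


@dataclass(frozen=True)
class SeedMatch:
    """One exact occurrence of a seed, in member-local forward coordinates."""

    accession: str
    offset: int
    strand: str = "forward"


@dataclass
class FMIndex:
    """BWT + suffix array over one reference chunk.

    The suffix array is kept in full by default; a sample rate > 1 stores only
    entries whose text position is a multiple of the rate and recovers the
    rest by LF-mapping walks, trading locate speed for memory.
    """

    text: np.ndarray            # encoded concatenated text incl. separators + sentinel
    bwt: np.ndarray             # int8
    c_table: np.ndarray         # int64, cumulative counts below each symbol
    occ: np.ndarray             # int64 (n+1, sigma): occ[i, c] = count of c in bwt[:i]
    boundaries: np.ndarray      # int64 start offset of each member in text
    member_ids: list[str]
    member_lengths: np.ndarray  # int64
    sa_sample_rate: int = 1
    suffix_array: np.ndarray | None = None   # full SA (rate == 1)
    sampled_rows: np.ndarray | None = None   # BWT rows holding sampled SA values
    sampled_values: np.ndarray | None = None
    _row_is_sampled: np.ndarray | None = field(default=None, repr=False)

    @property
    def text_length(self) -> int:
        return len(self.text)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, chunk: ReferenceChunk, sa_sample_rate: int = 1) -> "FMIndex":
        if not chunk.members:
            raise InputError("cannot build an FM-index over an empty chunk")
        if sa_sample_rate < 1:
            raise InputError("sa_sample_rate must be >= 1")
        parts: list[np.ndarray] = []
        boundaries = []
        pos = 0
        sep = np.array([SEPARATOR], dtype=np.int8)
        for i, member in enumerate(chunk.members):
            if i > 0:
                parts.append(sep)
                pos += 1
            boundaries.append(pos)
            enc = encode(member.sequence)
            parts.append(enc)
            pos += len(enc)
        parts.append(np.array([SENTINEL], dtype=np.int8))
        text = np.concatenate(parts)
        sa = suffix_array(text)
        bwt = text[(sa - 1) % len(text)]
        counts = np.bincount(bwt, minlength=ALPHABET_SIZE).astype(np.int64)
        c_table = np.concatenate(([0], np.cumsum(counts)[:-1]))
        occ = np.zeros((len(text) + 1, ALPHABET_SIZE), dtype=np.int64)
        for c in range(ALPHABET_SIZE):
            np.cumsum(bwt == c, out=occ[1:, c])
        index = cls(
            text=text,
            bwt=bwt.astype(np.int8),
            c_table=c_table,
            occ=occ,
            boundaries=np.array(boundaries, dtype=np.int64),
            member_ids=[m.accession for m in chunk.members],
            member_lengths=np.array([m.length for m in chunk.members], dtype=np.int64),
            sa_sample_rate=sa_sample_rate,
        )
        if sa_sample_rate == 1:
            index.suffix_array = sa
        else:
            mask = sa % sa_sample_rate == 0
            index.sampled_rows = np.flatnonzero(mask)
            index.sampled_values = sa[mask]
            bitmap = np.zeros(len(text), dtype=bool)
            bitmap[index.sampled_rows] = True
            index._row_is_sampled = bitmap
        return index

    # -- search primitives --------------------------------------------------

    def _lf(self, rows: np.ndarray) -> np.ndarray:
        symbols = self.bwt[rows]
        return self.c_table[symbols] + self.occ[rows, symbols]

    def backward_search_batch(
        self, patterns: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Backward search for a batch of equal-length encoded patterns.

        Returns (lo, hi) BWT-row intervals; empty matches have lo == hi.
        Patterns containing N are forced to an empty interval.
        """
        if patterns.ndim != 2:
            raise ValueError("patterns must be a 2-D (batch, length) array")
        batch, length = patterns.shape
        if length == 0:
            raise InputError("empty pattern")
        lo = np.zeros(batch, dtype=np.int64)
        hi = np.full(batch, self.text_length, dtype=np.int64)
        dead = (patterns == CODE_N).any(axis=1)
        hi[dead] = 0
        for j in range(length - 1, -1, -1):
            live = lo < hi
            if not live.any():
                break
            c = patterns[live, j].astype(np.intp)
            lo_l, hi_l = lo[live], hi[live]
            lo[live] = self.c_table[c] + self.occ[lo_l, c]
            hi[live] = self.c_table[c] + self.occ[hi_l, c]
        hi = np.maximum(lo, hi)
        return lo, hi

    def _sa_values(self, rows: np.ndarray) -> np.ndarray:
        """Text positions for BWT rows, via full or sampled suffix array."""
        if self.suffix_array is not None:
            return self.suffix_array[rows]
        values = np.zeros(len(rows), dtype=np.int64)
        steps = np.zeros(len(rows), dtype=np.int64)
        rows = rows.copy()
        unresolved = ~self._row_is_sampled[rows]
        while unresolved.any():
            rows[unresolved] = self._lf(rows[unresolved])
            steps[unresolved] += 1
            unresolved = ~self._row_is_sampled[rows]
        idx = np.searchsorted(self.sampled_rows, rows)
        values = self.sampled_values[idx] + steps
        return values % self.text_length

    def count(self, pattern: str) -> int:
        """Number of exact occurrences of the pattern in the indexed text."""
        if not pattern:
            raise InputError("empty pattern")
        lo, hi = self.backward_search_batch(encode(pattern)[None, :])
        return int(hi[0] - lo[0])

    def locate(self, pattern: str) -> list[SeedMatch]:
        """All exact occurrences as (accession, local offset) forward-strand
        matches, sorted by (accession, offset)."""
        if not pattern:
            raise InputError("empty pattern")
        lo, hi = self.backward_search_batch(encode(pattern)[None, :])
        if hi[0] == lo[0]:
            return []
        positions = self._sa_values(np.arange(lo[0], hi[0]))
        member_idx, local = self.global_to_local(positions)
        matches = [
            SeedMatch(accession=self.member_ids[m], offset=int(o))
            for m, o in zip(member_idx, local)
        ]
        matches.sort(key=lambda s: (s.accession, s.offset))
        return matches

    # -- coordinate conversion ----------------------------------------------

    def global_to_local(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        member_idx = np.searchsorted(self.boundaries, positions, side="right") - 1
        local = positions - self.boundaries[member_idx]
        return member_idx, local

    def local_to_global(self, member_idx: int, offset: int) -> int:
        return int(self.boundaries[member_idx]) + offset

    def member_slice(self, member_idx: int, start: int, end: int) -> str:
        """Decoded subsequence of one member, clamped to its bounds."""
        length = int(self.member_lengths[member_idx])
        start = max(0, start)
        end = min(length, end)
        if start >= end:
            return ""
        base = int(self.boundaries[member_idx])
        return decode(self.text[base + start : base + end])

    def member_index(self, accession: str) -> int:
        return self.member_ids.index(accession)


def build_fm_index(chunk: ReferenceChunk, sa_sample_rate: int = 1) -> FMIndex:
    return FMIndex.build(chunk, sa_sample_rate=sa_sample_rate)


def save_index(index: FMIndex, path: str | Path) -> None:
    """Serialize to an ``.npz`` archive with a magic string and format version."""
    arrays = {
        "magic": np.array(MAGIC),
        "version": np.array(FORMAT_VERSION, dtype=np.int64),
        "text": index.text,
        "bwt": index.bwt,
        "c_table": index.c_table,
        "occ": index.occ,
        "boundaries": index.boundaries,
        "member_ids": np.array(index.member_ids),
        "member_lengths": index.member_lengths,
        "sa_sample_rate": np.array(index.sa_sample_rate, dtype=np.int64),
    }
    if index.suffix_array is not None:
        arrays["suffix_array"] = index.suffix_array
    else:
        arrays["sampled_rows"] = index.sampled_rows
        arrays["sampled_values"] = index.sampled_values
    np.savez_compressed(str(path), **arrays)


def load_index(path: str | Path) -> FMIndex:
    try:
        with np.load(str(path), allow_pickle=False) as data:
            if "magic" not in data or str(data["magic"]) != MAGIC:
                raise IndexFormatError(f"{path}: not a taxalign index file")
            version = int(data["version"])
            if version != FORMAT_VERSION:
                raise IndexFormatError(
                    f"{path}: index format version {version} unsupported "
                    f"(expected {FORMAT_VERSION})"
                )
            rate = int(data["sa_sample_rate"])
            index = FMIndex(
                text=data["text"],
                bwt=data["bwt"],
                c_table=data["c_table"],
                occ=data["occ"],
                boundaries=data["boundaries"],
                member_ids=[str(x) for x in data["member_ids"]],
                member_lengths=data["member_lengths"],
                sa_sample_rate=rate,
            )
            if rate == 1:
                index.suffix_array = data["suffix_array"]
            else:
                index.sampled_rows = data["sampled_rows"]
                index.sampled_values = data["sampled_values"]
                bitmap = np.zeros(index.text_length, dtype=bool)
                bitmap[index.sampled_rows] = True
                index._row_is_sampled = bitmap
            return index
    except IndexFormatError:
        raise
    except Exception as exc:  # truncated zip, missing keys, bad dtype ...
        raise IndexFormatError(f"{path}: corrupt or unreadable index file ({exc})") from exc
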