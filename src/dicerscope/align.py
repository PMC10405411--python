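"""Small-RNA read processing: adapter trimming, exact / 1-mismatch
alignment over both strands, fractional multi-mapper weighting, size
histograms and 5'-end positional profiles.

The aligner returns *all* placements at the minimal achievable mismatch
count (0, or 1 when allowed and no perfect placement exists), over both
strands of every reference, each weighted 1/(number of placements).
This best-stratum semantics matches standard ungapped short-read
mappers; it is implemented with exact substring indices plus one-edit
enumeration, so its output is exactly checkable against a brute-force
scan of every offset and strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import revcomp


@dataclass(frozen=True)
class SmallReadAlignment:
    """A placed read: 0-based start on the reference plus strand.

    For '-' strand placements the read sequence equals the reverse
    complement of ``reference[start:start+length]``. ``weight`` is
    1/(number of equally good placements of the read).
    """

    read_id: str
    reference: str
    start: int
    length: int
    strand: str
    mismatches: int
    weight: float


class ReferenceIndex:
    """Exact substring index over a set of references, per read length."""

    def __init__(self, references: dict[str, str]):
        if not references:
            raise ValueError("empty reference set")
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.lengths = {name: len(seq) for name, seq in self.references.items()}
        self._by_len: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        tab = self._by_len.get(k)
        if tab is None:
            tab = {}
            for name, seq in self.references.items():
                for i in range(len(seq) - k + 1):
                    tab.setdefault(seq[i : i + k], []).append((name, i))
            self._by_len[k] = tab
        return tab

    def exact_hits(self, seq: str) -> list[tuple[str, int]]:
        return self._table(len(seq)).get(seq, [])


def trim_adapter(
    read: str, adapter: str, min_len: int = 17, max_len: int = 24, min_match: int = 8
) -> str | None:
    """Trim the leftmost adapter occurrence; filter by insert length.

    A match requires at least ``min_match`` nt of the adapter prefix,
    exact. Returns the trimmed insert, or ``None`` when the result falls
    outside ``[min_len, max_len]`` (including untrimmable reads that are
    too long).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = read.upper()
    adapter = adapter.upper()
    insert = read
    for i in range(len(read) - min_match + 1):
        m = min(len(adapter), len(read) - i)
        if m >= min_match and read[i : i + m] == adapter[:m]:
            insert = read[:i]
            break
    if min_len <= len(insert) <= max_len:
        return insert
    return None


def _placements(index: ReferenceIndex, seq: str, max_mismatch: int) -> tuple[list, int]:
    """(placements, mismatch stratum) at the minimal mismatch count."""
    hits = {(name, start, "+") for name, start in index.exact_hits(seq)}
    rc = revcomp(seq)
    hits |= {(name, start, "-") for name, start in index.exact_hits(rc)}
    if hits:
        return sorted(hits), 0
    if max_mismatch >= 1:
        one = set()
        for j, orig in enumerate(seq):
            for b in "ACGT":
                if b == orig:
                    continue
                v = seq[:j] + b + seq[j + 1 :]
                one |= {(name, start, "+") for name, start in index.exact_hits(v)}
                one |= {
                    (name, start, "-") for name, start in index.exact_hits(revcomp(v))
                }
        if one:
            return sorted(one), 1
    return [], 0


def align_read(
    sequence: str,
    references: dict[str, str] | ReferenceIndex,
    max_mismatch: int = 0,
    read_id: str = "read",
) -> list[SmallReadAlignment]:
    """Align one read; see module docstring for the placement semantics.

    Placements are ordered lexicographically by (reference, start,
    strand) and all carry weight 1/n_placements.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if len(sequence) < 15:
        raise ValueError("reads shorter than 15 nt are not alignable")
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    seq = sequence.upper()
    hits, stratum = _placements(index, seq, max_mismatch)
    if not hits:
        return []
    w = 1.0 / len(hits)
    return [
        SmallReadAlignment(read_id, name, start, len(seq), strand, stratum, w)
        for name, start, strand in hits
    ]


def align_reads(
    reads: list[tuple[str, str]],
    references: dict[str, str] | ReferenceIndex,
    max_mismatch: int = 0,
) -> list[SmallReadAlignment]:
    """Align many reads against a shared index; unaligned reads are dropped."""
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    out: list[SmallReadAlignment] = []
    for rid, seq in reads:
        out.extend(align_read(seq, index, max_mismatch, read_id=rid))
    return out


@dataclass
class SizeHistogram:
    """Weighted read-length distribution within a size window."""

    counts: dict[int, float]
    library_size: int
    mapped: float

    def ppm(self) -> dict[int, float]:
        return {k: ppm(v, self.library_size) for k, v in self.counts.items()}


def size_distribution(
    alignments: list[SmallReadAlignment],
    window: tuple[int, int] = (17, 24),
    library_size: int | None = None,
) -> SizeHistogram:
    """Weighted counts per read length, restricted to ``window``.

    Each multi-mapped read contributes its total weight (1) once, split
    across placements of identical length, so the histogram conserves
    aligned weight.
    """
    lo, hi = window
    if lo < 15 or hi > 30 or lo > hi:
        raise ValueError("window must lie within [15,30]")
    counts = {k: 0.0 for k in range(lo, hi + 1)}
    mapped = 0.0
    for a in alignments:
        if lo <= a.length <= hi:
            counts[a.length] += a.weight
            mapped += a.weight
    if library_size is None:
        library_size = int(round(sum(counts.values())))
    return SizeHistogram(counts, library_size, mapped)


def ppm(count: float, library_size: float) -> float:
    """Parts per million of a library."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / library_size * 1e6


@dataclass
class PositionalProfile:
    """Per-position stranded weighted counts of alignment 5' ends."""

    reference: str
    plus: np.ndarray
    minus: np.ndarray
    size_filter: tuple[int, ...] | None = None

    @property
    def total(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def combined(self) -> np.ndarray:
        return self.plus + self.minus


def five_prime_position(a: SmallReadAlignment) -> int:
    """5' end of a placement: start on '+', start+length-1 on '-'."""
    return a.start if a.strand == "+" else a.start + a.length - 1


def five_prime_profile(
    alignments: list[SmallReadAlignment],
    reference: str,
    reference_length: int,
    size_filter: tuple[int, ...] | None = None,
) -> PositionalProfile:
    """Accumulate alignment 5'-end weights per position and strand."""
    plus = np.zeros(reference_length)
    minus = np.zeros(reference_length)
    for a in alignments:
        if a.reference != reference:
            continue
        if size_filter is not None and a.length not in size_filter:
            continue
        pos = five_prime_position(a)
        if a.strand == "+":
            plus[pos] += a.weight
        else:
            minus[pos] += a.weight
    return PositionalProfile(reference, plus, minus, size_filter)


def count_unique_sequences(
    alignments: list[SmallReadAlignment],
    sequences: dict[str, str],
    reference: str,
    strand: str,
) -> int:
    """Distinct read sequences among reads placed on reference/strand."""
    seen = {
        sequences[a.read_id]
        for a in alignments
        if a.reference == reference and a.strand == strand
    }
    return len(seen)


def coverage_from_alignments(
    alignments: list[SmallReadAlignment],
    reference_lengths: dict[str, int],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Stranded per-position coverage (weighted reads overlapping)."""
    cov = {
        name: (np.zeros(n), np.zeros(n)) for name, n in reference_lengths.items()
    }
    for a in alignments:
        if a.reference not in cov:
            continue
        plus, minus = cov[a.reference]
        arr = plus if a.strand == "+" else minus
        arr[a.start : a.start + a.length] += a.weight
    return cov


ALIGNMENT_COLUMNS = ["read_id", "reference", "start0", "length", "strand", "mismatches", "weight"]


def write_alignments(alignments: list[SmallReadAlignment], path) -> None:
    rows = [
        (a.read_id, a.reference, a.start, a.length, a.strand, a.mismatches, a.weight)
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments(path) -> list[SmallReadAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "reference": str})
    return [
        SmallReadAlignment(
            r.read_id, r.reference, int(r.start0), int(r.length), r.strand,
            int(r.mismatches), float(r.weight),
        )
        for r in df.itertuples()
    ]

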