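"""k-mer histogram containers, histogram file I/O, and in-memory k-mer counting.

The central object is :class:`KmerHistogram`, the unique-k-mer frequency
spectrum: for each frequency ``x`` it records ``y``, the number of distinct
k-mers observed exactly ``x`` times in a read set.  Histograms travel on disk
in the ubiquitous two-column plain-text dialect ("frequency count" per line)
emitted by ``jellyfish histo`` and ``kmc_tools transform histogram``, so
spectra produced by external counters drop straight in.

A small exact counter (:func:`count_kmers`) is included for desk-scale inputs
(up to roughly 100 Mbp of reads); it encodes k-mers as integers and counts
with vectorised numpy operations.  Larger datasets should be counted with a
dedicated tool and ingested via :func:`read_histogram`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "KmerHistogram",
    "ReadSet",
    "read_histogram",
    "write_histogram",
    "read_sequences",
    "write_reads",
    "canonical_form",
    "reverse_complement",
    "count_kmers",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; anything outside ACGT (case-insensitive) maps to -1 and
# invalidates every window that covers it
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class KmerHistogram:
    """Unique-k-mer frequency spectrum.

    Parameters
    ----------
    entries
        Ordered ``(x, y)`` pairs: frequency ``x`` (positive integer, strictly
        increasing) and the number ``y`` of distinct k-mers seen exactly
        ``x`` times (non-negative).  Zero-``y`` entries are permitted.
    k
        The k-mer length the spectrum was counted at, or ``None`` when the
        histogram was loaded from a file that does not record it.
    """

    entries: tuple[tuple[int, int], ...]
    k: int | None = None

    def __post_init__(self) -> None:
        entries = tuple((int(x), int(y)) for x, y in self.entries)
        object.__setattr__(self, "entries", entries)
        if self.k is not None and self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        prev = 0
        for x, y in entries:
            if x < 1:
                raise ValueError(f"frequencies must be >= 1, got {x}")
            if x <= prev:
                raise ValueError(f"frequencies must be strictly increasing at x={x}")
            if y < 0:
                raise ValueError(f"counts must be >= 0, got y={y} at x={x}")
            prev = x

    @property
    def x(self) -> np.ndarray:
        """Frequencies as an int64 array."""
        return np.array([x for x, _ in self.entries], dtype=np.int64)

    @property
    def y(self) -> np.ndarray:
        """Distinct-k-mer counts as an int64 array."""
        return np.array([y for _, y in self.entries], dtype=np.int64)

    @property
    def n_instances(self) -> int:
        """Total number of k-mer instances, N = sum(x*y)."""
        return int(np.dot(self.x, self.y))

    @property
    def n_distinct(self) -> int:
        """Total number of distinct k-mers, sum(y)."""
        return int(self.y.sum())

    @property
    def max_frequency(self) -> int:
        if not self.entries:
            raise ValueError("empty histogram has no maximum frequency")
        return self.entries[-1][0]

    def y_at(self, x: int) -> int:
        """Count at frequency ``x``; missing frequencies count as 0."""
        lut = {ex: ey for ex, ey in self.entries}
        return lut.get(int(x), 0)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReadSet:
    """An ordered collection of sequencing reads held in memory."""

    records: tuple[tuple[str, str], ...]
    source_format: str = "fasta"

    def __post_init__(self) -> None:
        if self.source_format not in ("fasta", "fastq"):
            raise ValueError(f"unknown source format {self.source_format!r}")
        for ident, seq in self.records:
            if not ident:
                raise ValueError("read identifiers must be non-empty")
            if not seq:
                raise ValueError(f"read {ident!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> Iterator[str]:
        for _, seq in self.records:
            yield seq


# ---------------------------------------------------------------------------
# histogram file I/O
# ---------------------------------------------------------------------------

def read_histogram(path: str | Path, k: int | None = None) -> KmerHistogram:
    """Read a two-column "frequency count" histogram file.

    Entries are sorted by frequency on the way in, so files written with
    unsorted rows are accepted.  Duplicate frequencies and malformed lines
    are hard errors (with the offending line number), because they indicate
    a file that is not actually a k-mer histogram.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    seen: set[int] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two whitespace-separated "
                    f"integers, got {stripped!r}"
                )
            try:
                x, y = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer field in {stripped!r}"
                ) from exc
            if x in seen:
                raise ValueError(f"{path}:{lineno}: duplicate frequency {x}")
            seen.add(x)
            pairs.append((x, y))
    if not pairs:
        raise ValueError(f"{path}: no histogram entries")
    pairs.sort()
    return KmerHistogram(entries=tuple(pairs), k=k)


def write_histogram(hist: KmerHistogram, path: str | Path) -> None:
    """Write ``hist`` as two-column text, one "x y" pair per line.

    The output is byte-stable for a given histogram and round-trips through
    :func:`read_histogram`.
    """
    if not hist.entries:
        raise ValueError("refusing to write an empty histogram")
    path = Path(path)
    with open(path, "w") as handle:
        for x, y in hist.entries:
            handle.write(f"{x} {y}\n")


# ---------------------------------------------------------------------------
# sequence file I/O
# ---------------------------------------------------------------------------

def _open_text(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path, handle) -> str:
    # extension first, then first record character
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".fq", ".fastq") for s in suffixes):
        return "fastq"
    if any(s in (".fa", ".fasta", ".fna") for s in suffixes):
        return "fasta"
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise ValueError(f"{path}: cannot determine sequence format")


def read_sequences(path: str | Path) -> ReadSet:
    """Load a FASTA or FASTQ file (optionally gzipped) into a :class:`ReadSet`.

    Format is autodetected from the file extension, falling back to the first
    record character; gzip is detected from the magic bytes.
    """
    path = Path(path)
    with _open_text(path) as handle:
        fmt = _sniff_format(path, handle)
        records = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, fmt)
        )
    if not records:
        raise ValueError(f"{path}: no sequence records")
    return ReadSet(records=records, source_format=fmt)


def write_reads(reads: ReadSet, path: str | Path, fmt: str | None = None,
                quality_char: str = "I") -> None:
    """Write a :class:`ReadSet` as FASTA or FASTQ (constant quality)."""
    fmt = fmt or reads.source_format
    path = Path(path)
    with open(path, "w") as handle:
        for ident, seq in reads.records:
            if fmt == "fasta":
                handle.write(f">{ident}\n{seq}\n")
            elif fmt == "fastq":
                handle.write(f"@{ident}\n{seq}\n+\n{quality_char * len(seq)}\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement.

    K-mers containing characters outside ``{A,C,G,T}`` are rejected; windows
    containing ambiguity codes are skipped upstream, never canonicalised.
    """
    if not kmer:
        raise ValueError("empty k-mer")
    if any(b not in "ACGT" for b in kmer):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _encode_reads(reads: Iterable[str], k: int) -> np.ndarray:
    """Concatenate reads into one int8 code array separated by sentinels.

    Sentinels (-1) between reads guarantee that no window spans a read
    boundary; non-ACGT bases also encode to -1 and invalidate their windows.
    """
    parts: list[np.ndarray] = []
    sep = np.full(k, -1, dtype=np.int8)
    for seq in reads:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        parts.append(_CODE_LUT[raw])
        parts.append(sep)
    return np.concatenate(parts[:-1]) if parts else np.empty(0, dtype=np.int8)


def count_kmers(reads: ReadSet, k: int, canonical: bool = True,
                max_freq: int | None = None) -> KmerHistogram:
    """Count k-mers over every read and return the frequency spectrum.

    Every length-``k`` window consisting solely of ``{A,C,G,T}`` contributes
    one occurrence; windows containing any other character are skipped whole.
    With ``canonical=True`` (default) a k-mer and its reverse complement are
    counted as one, matching the convention of mainstream k-mer counters.

    Conservation: ``sum(x*y)`` over the result equals the number of valid
    windows, so the spectrum preserves the total instance count N that the
    genome-size model divides by the coverage.

    ``max_freq`` truncates (discards, does not aggregate) entries above the
    cap; because the estimator's N uses the full sum, truncation is logged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(reads) == 0:
        raise ValueError("empty read set")
    if all(len(seq) < k for seq in reads.sequences()):
        raise ValueError(f"no k-mers extractable: every read is shorter than k={k}")

    codes = _encode_reads(reads.sequences(), k)
    n_win = codes.size - k + 1
    if n_win <= 0:
        raise ValueError(f"no k-mers extractable: every read is shorter than k={k}")

    # window validity: no sentinel / ambiguous base among its k positions
    invalid = (codes < 0).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(invalid)))
    valid = (cs[k:] - cs[:-k]) == 0

    # forward 2-bit packing (Horner); int64 is safe for k <= 31
    if k > 31:
        raise ValueError("built-in counter supports k <= 31")
    fwd = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        fwd *= 4
        fwd += codes[j:j + n_win]
    if canonical:
        rc = np.zeros(n_win, dtype=np.int64)
        for j in range(k - 1, -1, -1):
            rc *= 4
            rc += 3 - codes[j:j + n_win]
        keys = np.minimum(fwd, rc)
    else:
        keys = fwd
    keys = keys[valid]
    if keys.size == 0:
        raise ValueError("no k-mers extractable: all windows contain non-ACGT bases")

    _, occurrences = np.unique(keys, return_counts=True)
    spectrum = np.bincount(occurrences)
    xs = np.nonzero(spectrum)[0]
    entries = tuple((int(x), int(spectrum[x])) for x in xs)
    if max_freq is not None:
        kept = tuple(e for e in entries if e[0] <= max_freq)
        if len(kept) < len(entries):
            dropped = sum(e[1] for e in entries) - sum(e[1] for e in kept)
            logger.warning(
                "max_freq=%d truncated %d distinct k-mers above the cap; "
                "the total instance count N no longer reflects the full data",
                max_freq, dropped,
            )
        entries = kept
    return KmerHistogram(entries=entries, k=k)
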