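"""K-mer-histogram genome-size estimation from FASTQ reads.

Canonical k-mers (lexicographic minimum of a window and its reverse
complement) are counted across all reads; the depth histogram then shows an
error peak at depth ~1 and a coverage peak near the effective sequencing
depth.  The genome size follows the classic k-mer-frequency rule

    size (bp) = k-mer number / depth of the coverage peak,

where the k-mer number excludes the error mass below the valley separating
the two peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from .errors import FormatError, NoCoveragePeakError

__all__ = [
    "KmerHistogram",
    "SizeEstimate",
    "count_kmers",
    "find_error_valley_and_peak",
    "estimate_genome_size",
    "write_histogram",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


@dataclass
class KmerHistogram:
    """Depth histogram of distinct canonical k-mers.

    ``counts[d]`` is the number of distinct canonical k-mers observed
    exactly ``d`` times; ``total_kmers`` is the number of k-mer tokens
    scanned (equal to ``sum(d * counts[d])`` by construction, checked on
    ingest).
    """

    k: int
    counts: np.ndarray
    total_kmers: int
    n_reads: int = 0
    n_short_reads: int = 0

    @property
    def max_depth(self) -> int:
        return len(self.counts) - 1

    def as_dict(self) -> dict[int, int]:
        return {d: int(c) for d, c in enumerate(self.counts) if d >= 1 and c > 0}

    @classmethod
    def from_depth_counts(cls, k: int, counts: dict[int, int]) -> "KmerHistogram":
        arr = np.zeros(max(counts) + 1, dtype=np.int64)
        for d, c in counts.items():
            if d < 1 or c < 0:
                raise ValueError("depths must be >= 1 and counts >= 0")
            arr[d] = c
        total = int(np.sum(np.arange(len(arr)) * arr))
        return cls(k=k, counts=arr, total_kmers=total)


@dataclass
class SizeEstimate:
    peak_depth: int
    valley_depth: int
    kmer_number: int
    genome_size_bp: float


def _canonical_values(seq: str, k: int) -> np.ndarray | None:
    """Canonical k-mer integer codes of one read; None if the read is short."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    L = codes.size
    if L < k:
        return None
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    fwd = win.astype(np.int64) @ powers
    rc = np.where(codes == 4, np.uint8(4), (3 - codes).astype(np.uint8))[::-1]
    rvals = (sliding_window_view(rc, k).astype(np.int64) @ powers)[::-1]
    return np.minimum(fwd, rvals)[valid]


def _iter_fastq(path: str | Path) -> Iterable[str]:
    parser = SeqIO.parse(str(path), "fastq")
    index = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FASTQ record {index}: {exc}") from exc
        index += 1
        yield str(record.seq)


def count_kmers(
    reads: str | Path | Sequence[tuple[str, str, str]] | Iterable[str],
    k: int = 17,
) -> KmerHistogram:
    """Count canonical k-mers from a FASTQ path or in-memory reads.

    Odd ``k`` is recommended (no k-mer is then its own reverse complement)
    and is the default; any ``k >= 3`` is accepted.  Windows containing
    non-ACGT characters are skipped; reads shorter than ``k`` are skipped
    and counted.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if isinstance(reads, (str, Path)):
        seqs: Iterable[str] = _iter_fastq(reads)
    else:
        seqs = (r[1] if isinstance(r, tuple) else str(r) for r in reads)

    chunks: list[np.ndarray] = []
    n_reads = 0
    n_short = 0
    for seq in seqs:
        n_reads += 1
        vals = _canonical_values(seq, k)
        if vals is None:
            n_short += 1
        elif vals.size:
            chunks.append(vals)

    if not chunks:
        return KmerHistogram(k=k, counts=np.zeros(1, dtype=np.int64), total_kmers=0,
                             n_reads=n_reads, n_short_reads=n_short)
    allvals = np.concatenate(chunks)
    _, depths = np.unique(allvals, return_counts=True)
    counts = np.bincount(depths).astype(np.int64)
    total = int(allvals.size)
    assert int(np.sum(np.arange(len(counts)) * counts)) == total
    return KmerHistogram(k=k, counts=counts, total_kmers=total,
                         n_reads=n_reads, n_short_reads=n_short)


def find_error_valley_and_peak(hist: KmerHistogram) -> tuple[int, int]:
    """Locate the error/coverage boundary and the coverage peak.

    The valley is the first depth ``d >= 1`` with ``counts[d] < counts[d+1]``
    (the histogram stops falling); the peak is the argmax over depths beyond
    the valley, ties resolved to the smaller depth.  A monotonically
    decreasing histogram has no coverage peak and raises
    :class:`NoCoveragePeakError`.
    """
    c = hist.counts
    if hist.total_kmers == 0 or len(c) < 3:
        raise NoCoveragePeakError("no diploid/haploid peak found")
    valley = None
    for d in range(1, len(c) - 1):
        if c[d] < c[d + 1]:
            valley = d
            break
    if valley is None:
        raise NoCoveragePeakError("no diploid/haploid peak found")
    peak = valley + 1 + int(np.argmax(c[valley + 1:]))
    return valley, peak


def estimate_genome_size(hist: KmerHistogram) -> SizeEstimate:
    """Genome size = error-filtered k-mer number / coverage-peak depth."""
    valley, peak = find_error_valley_and_peak(hist)
    depths = np.arange(len(hist.counts))
    mask = depths > valley
    kmer_number = int(np.sum(depths[mask] * hist.counts[mask]))
    return SizeEstimate(
        peak_depth=peak,
        valley_depth=valley,
        kmer_number=kmer_number,
        genome_size_bp=kmer_number / peak,
    )


def write_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tcount\n")
        for d, c in hist.as_dict().items():
            fh.write(f"{d}\t{c}\n")
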