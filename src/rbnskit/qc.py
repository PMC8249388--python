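"""FASTQ ingestion, adapter trimming, quality filtering and insert extraction.

The processing order is fixed: 3'-adapter trim (edit distance at a maximum
error rate, mirroring cutadapt semantics) -> mean-quality filter (reads with
mean Phred < 30 are discarded) -> extraction of the randomized insert
anchored on the constant flanks.  K-mers are only ever taken from extracted
inserts, never from flank sequence — the 5' flank itself contains a
GACGTGAC octamer and would otherwise contaminate the enrichment statistic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from math import floor
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import LibraryDesign
from .errors import FastqParseError

PHRED_OFFSET = 33
MAX_PHRED = 93


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities (offset-33 decoded)."""

    id: str
    sequence: str
    qualities: np.ndarray  # uint8 Phred integers

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __eq__(self, other) -> bool:  # array field needs explicit comparison
        return (
            isinstance(other, ReadRecord)
            and self.id == other.id
            and self.sequence == other.sequence
            and np.array_equal(self.qualities, other.qualities)
        )


@dataclass
class QCReport:
    """Stage counters; n_input = n_quality_failed + n_flank_failed + n_inserts."""

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_quality_failed: int = 0
    n_flank_failed: int = 0
    n_inserts: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def check(self) -> None:
        assert self.n_input == self.n_quality_failed + self.n_flank_failed + self.n_inserts


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ (optionally gzipped), Phred+33.

    Raises :class:`FastqParseError` naming the record index on truncated
    records, length mismatches or out-of-range quality characters.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"record {index}: {exc}") from exc
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            q -= PHRED_OFFSET
            if len(q) and (q.min() < 0 or q.max() > MAX_PHRED):
                raise FastqParseError(
                    f"record {index} ({title.split()[0]}): quality out of Phred+33 range"
                )
            yield ReadRecord(id=title.split()[0], sequence=seq.upper(),
                             qualities=q.astype(np.uint8))
            index += 1


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = (r.qualities + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    max_error_rate: float = 0.2,
    min_overlap: int = 3,
) -> ReadRecord:
    """Remove a 3' adapter occurrence and everything downstream of it.

    The adapter (or a prefix of it at the read's 3' end) qualifies when its
    edit distance is <= floor(max_error_rate * matched adapter length) and
    the overlap is >= min_overlap.  Qualities are trimmed in step.  A read
    with no qualifying occurrence is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    seq = read.sequence
    cut = _find_adapter(seq, adapter, max_error_rate, min_overlap)
    if cut is None:
        return read
    return ReadRecord(id=read.id, sequence=seq[:cut], qualities=read.qualities[:cut])


def _find_adapter(
    seq: str, adapter: str, max_error_rate: float, min_overlap: int
) -> int | None:
    """0-based cut position of the best qualifying adapter occurrence, else None."""
    if not seq:
        return None
    # Full adapter anywhere in the read (infix / "HW" alignment).
    k_full = floor(max_error_rate * len(adapter))
    res = edlib.align(adapter, seq, mode="HW", task="locations", k=k_full)
    if res["editDistance"] != -1:
        return min(start for start, _ in res["locations"])
    # Adapter prefix overhanging the 3' end; prefer the longest overlap.
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        allowed = floor(max_error_rate * ov)
        d = edlib.align(adapter[:ov], seq[-ov:], mode="NW", k=allowed)["editDistance"]
        if d != -1:
            return len(seq) - ov
    return None


def mean_quality(read: ReadRecord) -> float:
    """Arithmetic mean of the Phred integers; undefined for empty reads."""
    if len(read.qualities) == 0:
        raise ValueError(f"read {read.id!r} has no bases")
    return float(read.qualities.mean())


def filter_by_quality(
    reads: Iterable[ReadRecord], min_mean: float = 30.0
) -> tuple[list[ReadRecord], QCReport]:
    """Keep reads with mean Phred >= min_mean (strict-< rejection).

    Zero-length reads are rejected and counted, not raised.
    """
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        if len(read.qualities) == 0 or float(read.qualities.mean()) < min_mean:
            report.n_quality_failed += 1
        else:
            kept.append(read)
    report.n_inserts = len(kept)  # provisional; refined by extract stage
    return kept, report


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_random_region(
    read: ReadRecord,
    design: LibraryDesign,
    max_flank_mismatch: int = 2,
) -> str | None:
    """Extract the randomized insert anchored on the constant 5' flank.

    The 5' flank must match at a start offset in 0..5 with at most
    ``max_flank_mismatch`` Hamming mismatches (no indels; the construct is
    fixed-length).  When the read extends far enough, the first 4 bases of
    the 3' flank must follow the insert with <=1 mismatch.  Returns the
    insert (exactly ``design.random_length`` nt) or None for unusable
    reads; inserts containing N are rejected.
    """
    seq = read.sequence
    f5 = design.five_prime_flank
    L5 = len(f5)
    rl = design.random_length
    anchor3 = design.three_prime_flank[:4]
    for off in range(0, 6):
        if off + L5 + rl > len(seq):
            break
        if _hamming(seq[off:off + L5], f5) <= max_flank_mismatch:
            start = off + L5
            insert = seq[start:start + rl]
            if "N" in insert:
                return None
            tail = seq[start + rl:start + rl + 4]
            if len(tail) == 4 and _hamming(tail, anchor3) > 1:
                return None
            return insert
    return None


def extract_inserts(
    reads: Iterable[ReadRecord],
    design: LibraryDesign,
    min_mean_quality: float = 30.0,
    max_error_rate: float = 0.2,
    min_overlap: int = 3,
    max_flank_mismatch: int = 2,
) -> tuple[list[str], QCReport]:
    """Full QC pipeline: trim -> quality filter -> extract, with counters."""
    report = QCReport()
    inserts: list[str] = []
    adapter = design.sequencing_adapter
    for read in reads:
        report.n_input += 1
        trimmed = trim_adapter(read, adapter, max_error_rate, min_overlap)
        if len(trimmed.sequence) < len(read.sequence):
            report.n_adapter_trimmed += 1
        if len(trimmed.qualities) == 0 or float(trimmed.qualities.mean()) < min_mean_quality:
            report.n_quality_failed += 1
            continue
        insert = extract_random_region(trimmed, design, max_flank_mismatch)
        if insert is None:
            report.n_flank_failed += 1
        else:
            report.n_inserts += 1
            inserts.append(insert)
    report.check()
    return inserts, report


def extract_inserts_from_file(
    path: str | Path,
    design: LibraryDesign,
    **kwargs,
) -> tuple[list[str], QCReport]:
    """Convenience wrapper running :func:`extract_inserts` on a FASTQ file."""
    return extract_inserts(read_fastq(path), design, **kwargs)
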