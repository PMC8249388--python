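"""Motif summarization: alignment of enriched k-mers, PFM, logo, consensus.

Enriched hexamers are very short and share a common core, so a gapped
multiple aligner adds nothing; an ungapped center-star offset alignment is
used instead.  From the alignment we build a position frequency matrix, an
information-content (bits) logo matrix using the standard Schneider-
Stephens formulation without small-sample correction, and an IUPAC
consensus string.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import IUPAC_INVERSE

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class AlignedMotifSet:
    """Ungapped offset alignment: members is a list of (kmer, offset >= 0)."""

    members: list[tuple[str, int]]
    window_width: int


@dataclass
class PositionFrequencyMatrix:
    """Per-column A/C/G/T counts; coverage = members overlapping the column."""

    counts: np.ndarray  # shape (4, width), rows ordered A,C,G,T
    coverage: np.ndarray  # shape (width,)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(_BASES),
                          columns=range(1, self.width + 1))
        df.loc["coverage"] = self.coverage
        return df


@dataclass
class LogoMatrix:
    """Per-column information content (bits) and letter heights."""

    information: np.ndarray  # shape (width,), 0..2 bits
    heights: np.ndarray  # shape (4, width); per column sums to information
    low_confidence: np.ndarray  # boolean, coverage < min_coverage

    @property
    def width(self) -> int:
        return self.heights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, index=list(_BASES),
                          columns=range(1, self.width + 1))
        df.loc["information"] = self.information
        df.loc["low_confidence"] = self.low_confidence.astype(int)
        return df


def _fit_offset(kmer: str, profile: dict[int, np.ndarray], k: int) -> int:
    """Best offset in [-(k-1), k-1] by positional identity to the profile.

    Ties: smaller |offset|, then smaller signed offset.
    """
    best = None
    for off in range(-(k - 1), k):
        score = 0.0
        for j, base in enumerate(kmer):
            col = profile.get(off + j)
            if col is not None:
                score += col[_BASE_INDEX[base]]
        key = (-score, abs(off), off)
        if best is None or key < best[0]:
            best = (key, off)
    return best[1]


def align_kmers(
    kmers: Sequence[str], scores: Mapping[str, float] | None = None
) -> AlignedMotifSet:
    """Center-star ungapped alignment of equal-length k-mers.

    Members are processed in order of score descending (ties and the
    no-score case: lexicographic); the first is the center at offset 0,
    each following k-mer takes the offset maximizing identity to the
    running profile, and a single refinement pass re-fits each member
    against the profile of the others.  Deterministic.
    """
    if not kmers:
        raise ValueError("need at least one k-mer")
    k = len(kmers[0])
    if k < 2 or any(len(m) != k for m in kmers):
        raise ValueError("all k-mers must share one length >= 2")
    order = sorted(kmers, key=lambda m: (-(scores or {}).get(m, 0.0), m))

    profile: dict[int, np.ndarray] = {}

    def add(kmer: str, off: int, sign: float = 1.0) -> None:
        for j, base in enumerate(kmer):
            col = profile.setdefault(off + j, np.zeros(4))
            col[_BASE_INDEX[base]] += sign

    offsets: dict[int, int] = {}
    add(order[0], 0)
    offsets[0] = 0
    for i, kmer in enumerate(order[1:], start=1):
        off = _fit_offset(kmer, profile, k)
        add(kmer, off)
        offsets[i] = off
    # One refinement pass re-fitting each member against the others.
    if len(order) > 1:
        for i, kmer in enumerate(order):
            add(kmer, offsets[i], sign=-1.0)
            offsets[i] = _fit_offset(kmer, profile, k)
            add(kmer, offsets[i])
    shift = min(offsets.values())
    members = [(kmer, offsets[i] - shift) for i, kmer in enumerate(order)]
    window = max(off + k for _, off in members)
    return AlignedMotifSet(members=members, window_width=window)


def build_pfm(a: AlignedMotifSet) -> PositionFrequencyMatrix:
    """Tally member bases per column; each aligned k-mer counts once."""
    counts = np.zeros((4, a.window_width), dtype=np.int64)
    for kmer, off in a.members:
        for j, base in enumerate(kmer):
            counts[_BASE_INDEX[base], off + j] += 1
    return PositionFrequencyMatrix(counts=counts, coverage=counts.sum(axis=0))


def information_content(
    p: PositionFrequencyMatrix, min_coverage: int = 2
) -> LogoMatrix:
    """Schneider-Stephens logo math: IC = 2 + sum_b f_b log2 f_b per column.

    Letter height = f_b * IC; no small-sample correction.  Columns with
    coverage < min_coverage are flagged low-confidence (not rescored).
    """
    width = p.width
    ic = np.zeros(width)
    heights = np.zeros((4, width))
    for c in range(width):
        cov = p.coverage[c]
        if cov == 0:
            continue
        f = p.counts[:, c] / cov
        nz = f > 0
        ic[c] = 2.0 + float(np.sum(f[nz] * np.log2(f[nz])))
        ic[c] = min(max(ic[c], 0.0), 2.0)  # clamp fp rounding at the bounds
        heights[:, c] = f * ic[c]
    return LogoMatrix(information=ic, heights=heights,
                      low_confidence=p.coverage < min_coverage)


def iupac_consensus(
    p: PositionFrequencyMatrix,
    include_threshold: float = 0.25,
    min_coverage: int = 2,
) -> str:
    """Smallest IUPAC code per column covering bases at frequency >= threshold.

    Flanking columns with coverage < min_coverage are trimmed before
    summarization (they are supported by too few aligned members).
    """
    cols = np.where(p.coverage >= min_coverage)[0]
    if len(cols) == 0:  # tiny alignments: fall back to every covered column
        cols = np.where(p.coverage > 0)[0]
    letters = []
    for c in range(cols.min(), cols.max() + 1):
        cov = p.coverage[c]
        if cov == 0:
            letters.append("N")
            continue
        f = p.counts[:, c] / cov
        bases = frozenset(b for b, freq in zip(_BASES, f) if freq >= include_threshold)
        if not bases:  # nothing reaches the threshold: take the plurality base
            bases = frozenset(_BASES[int(np.argmax(f))])
        letters.append(IUPAC_INVERSE[bases])
    return "".join(letters)


def motif_summary(
    kmers: Sequence[str], scores: Mapping[str, float] | None = None
) -> tuple[AlignedMotifSet, PositionFrequencyMatrix, LogoMatrix, str]:
    """Align -> PFM -> logo -> consensus in one call."""
    aln = align_kmers(kmers, scores)
    pfm = build_pfm(aln)
    return aln, pfm, information_content(pfm), iupac_consensus(pfm)
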