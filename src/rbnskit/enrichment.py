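"""K-mer enrichment: the core Bind-n-Seq statistic.

Inserts are split into overlapping k-mers (a 20-mer yields 15 hexamers),
counts are normalized to frequencies over the full 4^k universe with a
pseudocount, and the enrichment of each k-mer is the ratio of its
normalized frequency in the pulldown to that in the control:

    relative_frequency(m) = freq_pulldown(m) / freq_control(m)

Ratios are standardized over the 4^k universe (sample mean and n-1 standard
deviation) and k-mers with Z > 3.0 are called enriched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def kmer_universe(k: int) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


@dataclass
class KmerCounts:
    k: int
    counts: Dict[str, int]
    total: int
    n_inserts: int


@dataclass
class KmerFrequencies:
    k: int
    freqs: Dict[str, float]
    pseudocount_used: float


@dataclass
class EnrichmentTable:
    """Ranked per-k-mer enrichment with Z-scores and the selected set.

    ``table`` columns: kmer, freq_pulldown, freq_control, rel_freq, zscore,
    rank, selected.  Rank is 1..4^k by rel_freq descending, ties broken
    lexicographically on the k-mer.
    """

    k: int
    table: pd.DataFrame
    threshold: float = 3.0

    @property
    def selected(self) -> list[str]:
        sub = self.table.loc[self.table["selected"]]
        return list(sub.sort_values("rank")["kmer"])

    def to_tsv(self, path: str | Path, pseudocount: float | None = None) -> None:
        with open(path, "w") as fh:
            meta = f"# k={self.k}\tthreshold={self.threshold}"
            if pseudocount is not None:
                meta += f"\tpseudocount={pseudocount}"
            fh.write(meta + "\n")
            out = self.table.copy()
            out["selected"] = out["selected"].astype(int)
            out.to_csv(fh, sep="\t", index=False)


def split_kmers(seq: str, k: int) -> list[str]:
    """Overlapping k-mers of *seq* in order; empty list when k > len(seq)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def count_kmers(inserts: Iterable[str], k: int) -> KmerCounts:
    """Exact overlapping k-mer tally over a stream of inserts.

    Inserts shorter than k contribute nothing; windows containing a
    non-ACGT character are skipped.  Uniform-length ACGT input is counted
    on an integer-encoded matrix for speed; anything else falls back to a
    per-window loop.  Both paths are exact.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    inserts = list(inserts)
    n_inserts = len(inserts)
    if n_inserts == 0:
        return KmerCounts(k=k, counts={}, total=0, n_inserts=0)

    lengths = {len(s) for s in inserts}
    if len(lengths) == 1 and (L := lengths.pop()) >= k:
        mat = np.frombuffer("".join(inserts).encode("ascii"), dtype=np.uint8)
        mat = _CODE[mat].reshape(n_inserts, L)
        if not (mat == 255).any():
            return _count_kmers_matrix(mat, k, n_inserts)
    counts: Dict[str, int] = {}
    total = 0
    valid = set(_BASES)
    for s in inserts:
        s = s.upper()
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if set(w) <= valid:
                counts[w] = counts.get(w, 0) + 1
                total += 1
    return KmerCounts(k=k, counts=counts, total=total, n_inserts=n_inserts)


def _count_kmers_matrix(mat: np.ndarray, k: int, n_inserts: int) -> KmerCounts:
    n, L = mat.shape
    starts = L - k + 1
    codes = np.zeros((n, starts), dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + mat[:, j:j + starts]
    tally = np.bincount(codes.ravel(), minlength=4 ** k)
    universe = kmer_universe(k)
    counts = {universe[i]: int(c) for i, c in enumerate(tally) if c}
    return KmerCounts(k=k, counts=counts, total=int(tally.sum()), n_inserts=n_inserts)


def normalize_counts(c: KmerCounts, pseudocount: float = 1.0) -> KmerFrequencies:
    """Normalized frequencies over the full 4^k universe.

    freq(m) = (count(m) + pseudocount) / sum over all 4^k k-mers of
    (count + pseudocount), so unseen k-mers receive pseudocount mass and
    every frequency is strictly positive when pseudocount > 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = c.total + pseudocount * (4 ** c.k)
    if denom == 0:
        raise InvalidInputError(
            "cannot normalize: zero total count with zero pseudocount"
        )
    freqs = {
        m: (c.counts.get(m, 0) + pseudocount) / denom for m in kmer_universe(c.k)
    }
    return KmerFrequencies(k=c.k, freqs=freqs, pseudocount_used=pseudocount)


def relative_frequencies(
    pulldown: KmerFrequencies, control: KmerFrequencies
) -> Dict[str, float]:
    """Per-k-mer pulldown/control frequency ratio over the 4^k universe."""
    if pulldown.k != control.k:
        raise ValueError(f"k mismatch: {pulldown.k} vs {control.k}")
    ratios = {}
    for m in kmer_universe(pulldown.k):
        denom = control.freqs.get(m, 0.0)
        if denom <= 0:
            raise InvalidInputError(
                f"zero control frequency for {m}; use a positive pseudocount"
            )
        ratios[m] = pulldown.freqs.get(m, 0.0) / denom
    return ratios


def zscore_select(
    ratios: Mapping[str, float],
    threshold: float = 3.0,
    pulldown: KmerFrequencies | None = None,
    control: KmerFrequencies | None = None,
) -> EnrichmentTable:
    """Standardize relative frequencies and select k-mers with Z > threshold.

    Z uses the sample mean and n-1 standard deviation over all supplied
    k-mers (the full 4^k universe in normal use).  With zero spread all Z
    are defined as 0, the selection is empty and a warning is emitted.
    """
    kmers = sorted(ratios)
    if len(kmers) < 2:
        raise ValueError("need at least 2 ratio values to standardize")
    k = len(kmers[0])
    vals = np.array([ratios[m] for m in kmers], dtype=float)
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0:
        warnings.warn("all relative frequencies equal; Z set to 0, empty selection")
        z = np.zeros_like(vals)
    else:
        z = (vals - mean) / sd
    df = pd.DataFrame({"kmer": kmers, "rel_freq": vals, "zscore": z})
    if pulldown is not None:
        df["freq_pulldown"] = [pulldown.freqs.get(m, np.nan) for m in kmers]
    if control is not None:
        df["freq_control"] = [control.freqs.get(m, np.nan) for m in kmers]
    df = df.sort_values(["rel_freq", "kmer"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["zscore"] > threshold
    cols = ["kmer"] + [c for c in ("freq_pulldown", "freq_control") if c in df] + [
        "rel_freq", "zscore", "rank", "selected"
    ]
    return EnrichmentTable(k=k, table=df[cols].reset_index(drop=True),
                           threshold=threshold)


def enrich(
    pulldown_inserts: Iterable[str],
    control_inserts: Iterable[str],
    k: int,
    pseudocount: float = 1.0,
    threshold: float = 3.0,
) -> EnrichmentTable:
    """Count -> normalize -> ratio -> Z-select in one call for a single k."""
    fp = normalize_counts(count_kmers(pulldown_inserts, k), pseudocount)
    fc = normalize_counts(count_kmers(control_inserts, k), pseudocount)
    return zscore_select(relative_frequencies(fp, fc), threshold,
                         pulldown=fp, control=fc)
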