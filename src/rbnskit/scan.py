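"""Bounded-gap IUPAC motif scanning and 3'-UTR metagene analysis.

Patterns are IUPAC strings with optional bounded spacers, e.g. ``GACR``,
``YGAC`` or ``GACN{1,3}GAC`` (two GAC cores separated by 1-3 arbitrary
bases).  A match is counted per distinct start position: a start counts
once even if several spacer lengths complete a match there.

The metagene side extracts the proximal *n* nucleotides of each 3'-UTR
(strand-aware when slicing a genome with BED intervals), removes duplicate
sequences, counts motif matches per region and places a query region within
the background count distribution via an add-one empirical upper-tail p.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import PatternSyntaxError

logger = logging.getLogger(__name__)

#: IUPAC degenerate base codes (U treated as T).
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Inverse map, base-set -> smallest covering IUPAC code.
IUPAC_INVERSE = {v: k for k, v in IUPAC.items() if k != "U"}

_GAP_RE = re.compile(r"N\{(\d+)(?:,(\d+))?\}")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled IUPAC motif with optional bounded gaps.

    ``elements`` is a tuple of ``("class", frozenset_of_bases)`` and
    ``("gap", (min, max))`` entries; ``min_span``/``max_span`` are the
    shortest and longest sequence length a match can cover.
    """

    raw: str
    elements: tuple = field(repr=False)
    min_span: int = 0
    max_span: int = 0

    @property
    def regex(self) -> "re.Pattern[str]":
        return _pattern_regex(self.elements)

    def expansions(self) -> list[tuple[frozenset, ...]]:
        """All fixed-span realizations: gaps expanded to runs of N.

        The number of expansions is the product of gap-width ranges, which
        is tiny for the motifs in use (e.g. 3 for GACN{1,3}GAC).
        """
        out: list[tuple[frozenset, ...]] = [()]
        any_base = IUPAC["N"]
        for kind, payload in self.elements:
            if kind == "class":
                out = [e + (payload,) for e in out]
            else:
                a, b = payload
                out = [e + (any_base,) * g for e in out for g in range(a, b + 1)]
        return out


@lru_cache(maxsize=None)
def _pattern_regex(elements: tuple) -> "re.Pattern[str]":
    parts = []
    for kind, payload in elements:
        if kind == "class":
            bases = "".join(sorted(payload))
            parts.append(bases if len(bases) == 1 else f"[{bases}]")
        else:
            a, b = payload
            parts.append(f"[ACGTN]{{{a},{b}}}" if a != b else f"[ACGTN]{{{a}}}")
    # Lookahead so overlapping matches are found at every start position.
    return re.compile("(?=" + "".join(parts) + ")")


@lru_cache(maxsize=None)
def compile_pattern(raw: str) -> MotifPattern:
    """Parse an IUPAC/bounded-gap motif string.

    Grammar: one or more of IUPAC letter | ``N{a}`` | ``N{a,b}`` with a<=b.
    Raises :class:`PatternSyntaxError` with the offending position.
    """
    if not raw:
        raise PatternSyntaxError("empty pattern")
    elements: list[tuple] = []
    i = 0
    while i < len(raw):
        ch = raw[i].upper()
        if ch == "N" and i + 1 < len(raw) and raw[i + 1] == "{":
            m = _GAP_RE.match(raw, i)
            if not m:
                raise PatternSyntaxError(f"malformed gap token in {raw!r}", position=i)
            a = int(m.group(1))
            b = int(m.group(2)) if m.group(2) is not None else a
            if a > b:
                raise PatternSyntaxError(
                    f"gap bounds reversed: N{{{a},{b}}}", position=i
                )
            elements.append(("gap", (a, b)))
            i = m.end()
        elif ch in IUPAC:
            elements.append(("class", IUPAC[ch]))
            i += 1
        else:
            raise PatternSyntaxError(f"invalid symbol {raw[i]!r} in {raw!r}", position=i)
    min_span = sum(p[0] if k == "gap" else 1 for k, p in elements)
    max_span = sum(p[1] if k == "gap" else 1 for k, p in elements)
    return MotifPattern(raw=raw, elements=tuple(elements),
                        min_span=min_span, max_span=max_span)


def count_matches(
    seq: str, pattern: MotifPattern | str, return_positions: bool = False
) -> int | tuple[int, list[int]]:
    """Count motif matches at distinct start positions (overlaps allowed).

    U in the input is treated as T; IUPAC positions never match an N in the
    sequence, gap positions match any base.
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    s = seq.upper().replace("U", "T")
    positions = [m.start() for m in pattern.regex.finditer(s)]
    if return_positions:
        return len(positions), positions
    return len(positions)


# ---------------------------------------------------------------------------
# Metagene analysis
# ---------------------------------------------------------------------------

@dataclass
class UTRRegion:
    """One 3'-UTR region, 5'->3' in mRNA orientation."""

    id: str
    sequence: str
    gene: str = ""
    contig: str | None = None
    start: int | None = None  # 0-based half-open genome coordinates
    end: int | None = None
    strand: str | None = None
    short: bool = False  # region shorter than the requested proximal length

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")


@dataclass
class MetageneResult:
    """Per-region motif counts with the query placed in the background."""

    pattern: str
    table: pd.DataFrame  # columns: id, length, count, count_per_100nt, is_query
    query_id: str
    query_count: int
    n_regions: int  # background regions (query excluded)
    mean_count: float
    empirical_p: float

    def histogram(self) -> pd.DataFrame:
        """Background count histogram (count value -> number of regions)."""
        bg = self.table.loc[~self.table["is_query"], "count"]
        h = bg.value_counts().sort_index()
        return pd.DataFrame({"count": h.index, "n_regions": h.values})


def _read_bed6(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return rows


def extract_proximal_regions(
    utr_fasta: str | Path | None = None,
    genome_fasta: str | Path | None = None,
    bed_path: str | Path | None = None,
    n: int = 200,
) -> list[UTRRegion]:
    """Extract the first *n* nt (5' end, mRNA sense) of each 3'-UTR.

    Either ``utr_fasta`` (sequences already in mRNA orientation) or
    ``genome_fasta`` + ``bed_path`` (BED6, 0-based half-open; minus-strand
    intervals are reverse-complemented before truncation).  UTRs shorter
    than *n* are returned whole with ``short=True``.
    """
    if (utr_fasta is None) == (genome_fasta is None or bed_path is None):
        raise ValueError("provide either utr_fasta or genome_fasta + bed_path")
    regions: list[UTRRegion] = []
    if utr_fasta is not None:
        for rec in SeqIO.parse(str(utr_fasta), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            regions.append(
                UTRRegion(id=rec.id, sequence=seq[:n], short=len(seq) < n)
            )
        return regions

    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    for contig, start, end, name, strand in _read_bed6(bed_path):
        if contig not in genome or start < 0 or end > len(genome[contig]) or start >= end:
            logger.warning("skipping BED interval off contig: %s:%d-%d (%s)",
                           contig, start, end, name)
            continue
        seq = str(genome[contig][start:end])
        if strand == "-":
            seq = reverse_complement(seq)
        regions.append(
            UTRRegion(id=name, sequence=seq[:n], contig=contig, start=start,
                      end=end, strand=strand, short=(end - start) < n)
        )
    return regions


def dedup_regions(regions: Sequence[UTRRegion]) -> list[UTRRegion]:
    """Drop regions whose exact sequence was already seen (keep first; idempotent)."""
    seen: set[str] = set()
    out = []
    for r in regions:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    return out


def metagene_analysis(
    regions: Sequence[UTRRegion],
    pattern: MotifPattern | str,
    query_id: str,
) -> MetageneResult:
    """Count motif matches per region and rank the query against the background.

    empirical_p = (1 + #{background with count >= query}) / (n_background + 1),
    an add-one upper-tail p over the background regions (query excluded).
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    ids = [r.id for r in regions]
    if query_id not in ids:
        raise ValueError(f"query id {query_id!r} not among the {len(regions)} regions")
    rows = []
    for r in regions:
        c = count_matches(r.sequence, pattern)
        length = len(r.sequence)
        rows.append({
            "id": r.id,
            "length": length,
            "count": c,
            "count_per_100nt": 100.0 * c / length if length else 0.0,
            "is_query": r.id == query_id,
        })
    table = pd.DataFrame(rows)
    query_count = int(table.loc[table["is_query"], "count"].iloc[0])
    bg = table.loc[~table["is_query"], "count"]
    n_bg = len(bg)
    mean_count = float(bg.mean()) if n_bg else float("nan")
    empirical_p = (1 + int((bg >= query_count).sum())) / (n_bg + 1)
    return MetageneResult(
        pattern=pattern.raw, table=table, query_id=query_id,
        query_count=query_count, n_regions=n_bg,
        mean_count=mean_count, empirical_p=empirical_p,
    )
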