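"""Synthetic Bind-n-Seq reads and 3'-UTR sets with ground-truth manifests.

The pulldown is modelled as affinity-weighted selection from a candidate
pool of uniform random inserts: an insert's selection weight is linear in
its motif content, 1 + sum_m w_m * count_matches(insert, m).  This is the
simplest model that yields the qualitative enrichment of motif-bearing
k-mers and has closed-form expectations.  The control sample is drawn
i.i.d. from the base composition (a mock pulldown; an ``input`` library
control is generatively identical and only labelled differently in the
manifest).

Reads carry the constant library flanks around the insert, are padded (or
truncated) to the read length, a configurable fraction reads through into
the sequencing adapter, and a two-level constant-Phred quality model marks
a fraction of reads as low quality.  Fixed seed => byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

import numpy as np

from .design import LibraryDesign
from .errors import InfeasibleSpecError
from .scan import MotifPattern, compile_pattern, count_matches

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class RBNSSimSpec:
    """Conditions for one simulated pulldown/control read pair."""

    n_pulldown: int
    n_control: int
    affinities: Dict[str, float] = field(default_factory=dict)
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    frac_low_quality: float = 0.05
    frac_adapter_readthrough: float = 0.2
    quality_high: int = 37
    quality_low: int = 20
    read_length: int = 150
    seed: int = 0
    control_kind: str = "mock"  # "mock" pulldown or sequenced "input" library
    pool_factor: int = 20  # candidate pool size as a multiple of n_pulldown

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        for name in ("frac_low_quality", "frac_adapter_readthrough"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(w < 0 for w in self.affinities.values()):
            raise ValueError("affinity weights must be >= 0")
        if self.control_kind not in ("mock", "input"):
            raise ValueError("control_kind must be 'mock' or 'input'")
        for m in self.affinities:
            compile_pattern(m)  # raises PatternSyntaxError on bad motifs

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["base_composition"] = list(self.base_composition)
        return d


@dataclass
class UTRSimSpec:
    """Conditions for a synthetic proximal-3'-UTR set with planted motifs."""

    n_regions: int
    motif: str
    query_id: str = "query"
    query_count: int = 3
    region_length: int = 200
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    background_count_mean: float = 0.0
    n_duplicates: int = 0  # extra records copying existing sequences
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.background_count_mean < 0 or self.query_count < 0:
            raise ValueError("planted counts must be >= 0")
        compile_pattern(self.motif)


def motif_count_matrix(mat: np.ndarray, pattern: MotifPattern) -> np.ndarray:
    """Vectorized per-row motif counts on a base-coded (0..3) uint8 matrix.

    Counts distinct start positions; bounded gaps are handled by OR-ing the
    pattern's fixed-span expansions at each start.  Equivalent to
    :func:`rbnskit.scan.count_matches` row by row.
    """
    n, L = mat.shape
    any_match: np.ndarray | None = None
    for exp in pattern.expansions():
        span = len(exp)
        starts = L - span + 1
        if starts <= 0:
            continue
        hit = np.ones((n, starts), dtype=bool)
        for j, allowed in enumerate(exp):
            if len(allowed) == 4:
                continue
            tbl = np.zeros(4, dtype=bool)
            for b in allowed:
                tbl[_BASE_INDEX[b]] = True
            hit &= tbl[mat[:, j:j + starts]]
        if any_match is None:
            any_match = np.zeros((n, L), dtype=bool)
        any_match[:, :starts] |= hit
    if any_match is None:
        return np.zeros(n, dtype=np.int64)
    return any_match.sum(axis=1).astype(np.int64)


def insert_weight(insert: str, affinities: Mapping[str, float]) -> float:
    """Selection weight 1 + sum_m w_m * count_matches(insert, m)."""
    total = 1.0
    for motif, w in affinities.items():
        total += w * count_matches(insert, compile_pattern(motif))
    return total


def _random_base_matrix(rng: np.random.Generator, n: int, length: int,
                        comp) -> np.ndarray:
    comp = np.asarray(comp, dtype=float)
    if np.allclose(comp, 0.25):
        return rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    return rng.choice(4, size=(n, length), p=comp).astype(np.uint8)


def _decode_rows(mat: np.ndarray) -> list[str]:
    blob = _BASE_BYTES[mat].tobytes().decode("ascii")
    L = mat.shape[1]
    return [blob[i:i + L] for i in range(0, len(blob), L)]


def _write_reads(
    path: Path,
    prefix: str,
    inserts: list[str],
    design: LibraryDesign,
    spec: RBNSSimSpec,
    rng: np.random.Generator,
) -> dict:
    n = len(inserts)
    low_q = rng.random(n) < spec.frac_low_quality
    readthrough = rng.random(n) < spec.frac_adapter_readthrough
    # Post-template signal is modelled as a poly-A run: neutral for insert
    # extraction and free of accidental adapter-like sequence, so the
    # adapter-trim counter recovers the planted read-through fraction.
    pad = "A" * spec.read_length
    q_high = chr(33 + spec.quality_high) * spec.read_length
    q_low = chr(33 + spec.quality_low) * spec.read_length
    lines: list[str] = []
    for i, insert in enumerate(inserts):
        seq = design.construct(insert)
        if readthrough[i]:
            seq += design.sequencing_adapter
        if len(seq) < spec.read_length:
            seq += pad[: spec.read_length - len(seq)]
        else:
            seq = seq[: spec.read_length]
        qual = q_low if low_q[i] else q_high
        lines.append(f"@{prefix}_{i:07d}\n{seq}\n+\n{qual[:len(seq)]}\n")
    path.write_text("".join(lines))
    return {
        "n_reads": n,
        "n_low_quality": int(low_q.sum()),
        "n_adapter_readthrough": int(readthrough.sum()),
    }


def _mean_motif_counts(mat: np.ndarray, motifs) -> dict:
    return {
        m: float(motif_count_matrix(mat, compile_pattern(m)).mean()) if len(mat) else 0.0
        for m in motifs
    }


def simulate_rbns_reads(
    spec: RBNSSimSpec,
    design: LibraryDesign | None = None,
    out_dir: str | Path = ".",
) -> dict:
    """Emit pulldown + control FASTQ files and a ground-truth manifest.

    Pulldown inserts are sampled (with replacement) from a candidate pool
    of ``pool_factor * n_pulldown`` uniform inserts with probability
    proportional to their affinity weight; control inserts are i.i.d.
    Returns the manifest dict (also written as ``manifest.json``).
    """
    design = design or LibraryDesign()
    if design.random_length < max(
        (compile_pattern(m).max_span for m in spec.affinities), default=1
    ):
        raise InfeasibleSpecError("a motif is longer than the randomized insert")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    pool_n = max(spec.pool_factor * spec.n_pulldown, 1)
    pool = _random_base_matrix(rng, pool_n, design.random_length, spec.base_composition)
    if spec.affinities:
        weights = np.ones(pool_n)
        for m, w in spec.affinities.items():
            if w:
                weights += w * motif_count_matrix(pool, compile_pattern(m))
        p = weights / weights.sum()
        idx = rng.choice(pool_n, size=spec.n_pulldown, replace=True, p=p)
    else:
        idx = rng.choice(pool_n, size=spec.n_pulldown, replace=True)
    pulldown_mat = pool[idx]
    control_mat = _random_base_matrix(
        rng, spec.n_control, design.random_length, spec.base_composition
    )

    pulldown_path = out_dir / "pulldown.fastq"
    control_path = out_dir / "control.fastq"
    stats_p = _write_reads(pulldown_path, "pd", _decode_rows(pulldown_mat),
                           design, spec, rng)
    stats_c = _write_reads(control_path, "ctl", _decode_rows(control_mat),
                           design, spec, rng)

    manifest = {
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "design": design.to_dict(),
        "pulldown_fastq": pulldown_path.name,
        "control_fastq": control_path.name,
        "pulldown": stats_p,
        "control": stats_c,
        "true_mean_motif_counts": {
            "pulldown": _mean_motif_counts(pulldown_mat, spec.affinities),
            "control": _mean_motif_counts(control_mat, spec.affinities),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plant(
    seq: list[str],
    pattern: MotifPattern,
    count: int,
    rng: np.random.Generator,
    comp,
) -> None:
    """Overwrite *count* non-overlapping concrete motif instances in place."""
    if count == 0:
        return
    L = len(seq)
    if pattern.max_span > L:
        raise InfeasibleSpecError(
            f"motif span {pattern.max_span} exceeds region length {L}"
        )
    occupied: list[tuple[int, int]] = []
    for _ in range(count):
        placed = False
        for _attempt in range(1000):
            inst = _instantiate(pattern, rng, comp)
            start = int(rng.integers(0, L - len(inst) + 1))
            iv = (start, start + len(inst))
            if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
                seq[iv[0]:iv[1]] = list(inst)
                occupied.append(iv)
                placed = True
                break
        if not placed:
            raise InfeasibleSpecError(
                f"could not place {count} non-overlapping copies of "
                f"{pattern.raw} in {L} nt"
            )


def _instantiate(pattern: MotifPattern, rng: np.random.Generator, comp) -> str:
    comp = np.asarray(comp, dtype=float)
    out = []
    for kind, payload in pattern.elements:
        if kind == "class":
            choices = sorted(payload)
            if len(choices) == 1:
                out.append(choices[0])
            else:
                probs = np.array([comp[_BASE_INDEX[b]] for b in choices])
                probs = probs / probs.sum() if probs.sum() else None
                out.append(str(rng.choice(choices, p=probs)))
        else:
            a, b = payload
            g = int(rng.integers(a, b + 1))
            out.append("".join(
                _BASES[i] for i in rng.choice(4, size=g, p=comp)
            ))
    return "".join(out)


def simulate_utr_set(
    spec: UTRSimSpec,
    fasta_path: str | Path = "utrs.fa",
    manifest_path: str | Path | None = None,
) -> dict:
    """Emit a multi-FASTA of background regions plus one query region.

    Background regions carry Poisson(background_count_mean) planted motif
    copies; the query region carries exactly ``query_count``.  Rescanning
    each emitted sequence yields at least the planted count (random
    background can add chance matches).  Optional exact-duplicate records
    exercise deduplication.  Returns the manifest dict.
    """
    pattern = compile_pattern(spec.motif)
    if pattern.max_span > spec.region_length:
        raise InfeasibleSpecError(
            f"motif span {pattern.max_span} exceeds region length {spec.region_length}"
        )
    rng = np.random.default_rng(spec.seed)
    comp = spec.base_composition
    max_copies = spec.region_length // max(pattern.min_span, 1)
    if spec.query_count > max_copies:
        raise InfeasibleSpecError(
            f"query_count {spec.query_count} cannot fit in {spec.region_length} nt"
        )

    records: list[tuple[str, str, int]] = []  # (id, sequence, planted)
    for i in range(spec.n_regions):
        n_plant = min(int(rng.poisson(spec.background_count_mean)), max_copies)
        seq = list(_decode_rows(
            _random_base_matrix(rng, 1, spec.region_length, comp))[0])
        _plant(seq, pattern, n_plant, rng, comp)
        records.append((f"utr_{i:05d}", "".join(seq), n_plant))
    qseq = list(_decode_rows(
        _random_base_matrix(rng, 1, spec.region_length, comp))[0])
    _plant(qseq, pattern, spec.query_count, rng, comp)
    records.append((spec.query_id, "".join(qseq), spec.query_count))

    duplicates = []
    if spec.n_duplicates:
        source = rng.choice(len(records), size=spec.n_duplicates, replace=True)
        for j, src in enumerate(source):
            rid, seq, planted = records[int(src)]
            duplicates.append((f"dup_{j:04d}_of_{rid}", seq, planted))
    all_records = records + duplicates

    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for rid, seq, _ in all_records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    manifest = {
        "seed": spec.seed,
        "spec": dict(spec.__dict__, base_composition=list(spec.base_composition)),
        "fasta": fasta_path.name,
        "planted_counts": {rid: planted for rid, _, planted in all_records},
        "n_records": len(all_records),
        "n_duplicates": len(duplicates),
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return manifest
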