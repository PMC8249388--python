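"""The fixed Bind-n-Seq library construct.

Every read in the assay has the same architecture: a constant 5' flank, a
randomized 20-mer insert (the only part that carries binding information),
and a constant 3' flank, optionally followed by sequencing adapter when the
read runs past the construct.  All sequences are handled internally as DNA
(U->T); the in-vitro library is RNA but FASTQ is DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

_DNA = frozenset("ACGT")

#: Constant flanks of the randomized library, DNA form of the transcribed
#: construct 5'-GGACGUGACACGACGUGCGC-[N20]-GCGUACGUCGGACCUCAGGUCGACCAUGGACGC-3'.
DEFAULT_FIVE_PRIME_FLANK = "GGACGTGACACGACGTGCGC"
DEFAULT_THREE_PRIME_FLANK = "GCGTACGTCGGACCTCAGGTCGACCATGGACGC"

#: Nextera-style transposase adapter read into when the insert is shorter
#: than the read length.
DEFAULT_SEQUENCING_ADAPTER = "CTGTCTCTTATACACATCT"


def _check_dna(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be nonempty")
    if not set(seq) <= _DNA:
        raise ValueError(f"{name} must be uppercase ACGT, got {seq!r}")


@dataclass(frozen=True)
class LibraryDesign:
    """Layout of the randomized RNA library in DNA coordinates.

    Note the 5' flank itself contains a GACGTGAC octamer, so k-mer analysis
    must never read into flank sequence; insert extraction is anchored on
    the flanks for exactly this reason.
    """

    five_prime_flank: str = DEFAULT_FIVE_PRIME_FLANK
    random_length: int = 20
    three_prime_flank: str = DEFAULT_THREE_PRIME_FLANK
    sequencing_adapter: str = DEFAULT_SEQUENCING_ADAPTER

    def __post_init__(self) -> None:
        _check_dna("five_prime_flank", self.five_prime_flank)
        _check_dna("three_prime_flank", self.three_prime_flank)
        _check_dna("sequencing_adapter", self.sequencing_adapter)
        if self.random_length < 1:
            raise ValueError("random_length must be >= 1")

    @property
    def construct_length(self) -> int:
        return len(self.five_prime_flank) + self.random_length + len(self.three_prime_flank)

    def construct(self, insert: str) -> str:
        """Full DNA sequence of one library molecule around *insert*."""
        if len(insert) != self.random_length:
            raise ValueError(
                f"insert length {len(insert)} != random_length {self.random_length}"
            )
        return self.five_prime_flank + insert + self.three_prime_flank

    def to_dict(self) -> dict:
        return {
            "five_prime_flank": self.five_prime_flank,
            "random_length": self.random_length,
            "three_prime_flank": self.three_prime_flank,
            "sequencing_adapter": self.sequencing_adapter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryDesign":
        return cls(**d)
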