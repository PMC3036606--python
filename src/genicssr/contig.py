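"""Basic sequence containers and nucleotide helpers.

A :class:`Contig` is a named transcript (unigene) sequence — the substrate
for SSR mining, primer design and ORF annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Bases allowed in contig sequences. ``N`` is tolerated but never
#: participates in a repeat, a primer or an ORF.
VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence (transcript contig)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content as a percentage of sequence length."""
    if not seq:
        raise ValueError("empty sequence has no GC content")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def validate_nucleotides(seq: str, *, allow_n: bool = True) -> None:
    """Raise ``ValueError`` naming the first offending position if *seq*
    contains a character outside the allowed alphabet."""
    allowed = VALID_BASES if allow_n else frozenset("ACGT")
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {i} (0-based)"
            )
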