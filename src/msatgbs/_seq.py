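"""Tiny DNA string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_DNA = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    if not _DNA.issuperset(seq):
        bad = sorted(set(seq) - _DNA)
        raise ValueError(f"{what}: non-ACGT characters {bad}")
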