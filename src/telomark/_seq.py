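"""Shared low-level sequence helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True, what: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside the A/C/G/T(/N) alphabet.

    Raises ValueError naming the first offending character.
    """
    seq = seq.upper()
    allowed = VALID_BASES if allow_n else frozenset("ACGT")
    for ch in seq:
        if ch not in allowed:
            raise ValueError(f"invalid character {ch!r} in {what}")
    return seq


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def g_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return seq.count("G") / len(seq)
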