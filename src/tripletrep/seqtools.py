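"""Small RNA string utilities shared across the package."""

from __future__ import annotations

RNA_BASES = "ACGU"
_BASESET = frozenset(RNA_BASES)
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, U}."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA-style T to U. Does not validate."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, *, name: str = "sequence") -> str:
    if not seq:
        raise AlphabetError(f"{name} is empty")
    bad = set(seq) - _BASESET
    if bad:
        raise AlphabetError(
            f"{name} contains non-ACGU characters: {sorted(bad)!r}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else float("nan")
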