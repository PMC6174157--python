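"""RNA sequence helpers.

All sequences are handled internally as uppercase RNA over {A, C, G, U};
DNA input (T) is accepted and mapped to U on normalization.
"""

from __future__ import annotations

from .errors import InputError

RNA_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase, map T->U and validate the alphabet.

    Raises :class:`InputError` naming the first offending position.
    """
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            raise InputError(
                f"{name}: non-nucleotide character {ch!r} at position {pos}"
            )
    return s


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
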