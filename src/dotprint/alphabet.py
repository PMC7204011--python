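"""Amino-acid alphabet, encoding, and sequence validation.

The working alphabet is the 20 standard amino acids plus two neutral
characters: ``X`` (unknown residue) and ``-`` (alignment gap / terminal
padding). Neutral characters score zero against everything so that they
neither create nor destroy dot-plot signal.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, in the conventional alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for an unknown residue; scores 0 against everything.
UNKNOWN = "X"

#: Alignment gap / terminal padding symbol; scores 0 against everything.
GAP = "-"

#: Full working alphabet (22 symbols) in fixed encoding order.
ALPHABET = AMINO_ACIDS + UNKNOWN + GAP

#: Ambiguity codes and rare residues rejected by default, mappable to X on request.
NONSTANDARD = "BZUOJ"

_CODE = {c: i for i, c in enumerate(ALPHABET)}

N_STANDARD = len(AMINO_ACIDS)
GAP_CODE = _CODE[GAP]
UNKNOWN_CODE = _CODE[UNKNOWN]


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the allowed alphabet."""


def encode(residues: str) -> np.ndarray:
    """Encode a residue string into integer codes over :data:`ALPHABET`.

    Raises :class:`SequenceAlphabetError` for any character outside the
    22-symbol working alphabet, reporting the first offending position.
    """
    try:
        return np.array([_CODE[c] for c in residues], dtype=np.int64)
    except KeyError:
        for pos, c in enumerate(residues):
            if c not in _CODE:
                raise SequenceAlphabetError(
                    f"illegal character {c!r} at position {pos}"
                ) from None
        raise  # pragma: no cover

def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


def clean_residues(residues: str, *, map_to_x: bool = False, allow_gap: bool = False) -> str:
    """Validate (and optionally sanitize) a residue string.

    Uppercases the input. Non-standard residue codes (B, Z, U, O, J) are
    rejected unless ``map_to_x`` is true, in which case they become ``X``.
    The gap symbol is only legal when ``allow_gap`` is set (alignment
    context). Returns the cleaned string.
    """
    s = residues.upper()
    if not s:
        raise SequenceAlphabetError("empty sequence")
    out = []
    for pos, c in enumerate(s):
        if c in AMINO_ACIDS or c == UNKNOWN:
            out.append(c)
        elif c == GAP:
            if not allow_gap:
                raise SequenceAlphabetError(f"gap character at position {pos} outside alignment context")
            out.append(c)
        elif c in NONSTANDARD:
            if map_to_x:
                out.append(UNKNOWN)
            else:
                raise SequenceAlphabetError(
                    f"non-standard residue {c!r} at position {pos} (use map_to_x to accept)"
                )
        else:
            raise SequenceAlphabetError(f"illegal character {c!r} at position {pos}")
    return "".join(out)
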