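"""Substitution matrices over the working alphabet.

Matrices are stored as a full integer table over the 22-symbol alphabet
(20 amino acids + X + gap). The neutral characters X and "-" always score
0 against everything, including themselves, so padded or trimmed alignment
columns contribute no dot-plot signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import ALPHABET, AMINO_ACIDS, N_STANDARD, _CODE


class MatrixFormatError(ValueError):
    """Substitution-matrix text could not be parsed or validated."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the working alphabet.

    ``scores`` is a 22x22 int array indexed by :data:`dotprint.alphabet.ALPHABET`
    order; the last two rows/columns (X, gap) are identically zero.
    """

    name: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        if s.shape != (len(ALPHABET), len(ALPHABET)):
            raise MatrixFormatError(f"expected {len(ALPHABET)}x{len(ALPHABET)} score table, got {s.shape}")
        if not np.array_equal(s, s.T):
            raise MatrixFormatError("substitution matrix is not symmetric")
        if s[N_STANDARD:, :].any() or s[:, N_STANDARD:].any():
            raise MatrixFormatError("X and gap rows/columns must be zero")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> int:
        """Score of the residue pair (a, b)."""
        return int(self.scores[_CODE[a], _CODE[b]])

    @property
    def standard_block(self) -> np.ndarray:
        """The 20x20 block over the standard amino acids."""
        return self.scores[:N_STANDARD, :N_STANDARD]

    def to_biopython(self) -> substitution_matrices.Array:
        """The 20x20 block as a Bio.Align substitution-matrix Array."""
        arr = substitution_matrices.Array(AMINO_ACIDS, dims=2)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                arr[a, b] = self.scores[i, j]
        return arr


def _from_standard_block(name: str, block: np.ndarray) -> SubstitutionMatrix:
    full = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    full[:N_STANDARD, :N_STANDARD] = block
    return SubstitutionMatrix(name=name, scores=full)


def _parse_ncbi_text(text: str) -> tuple[list[str], np.ndarray]:
    """Parse NCBI-format matrix text: '#' comments, a header row of column
    labels, then one labelled row per residue."""
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if header is None:
            if not all(len(f) == 1 for f in fields):
                raise MatrixFormatError(f"line {lineno}: expected single-letter column labels")
            header = fields
            continue
        label, *vals = fields
        if len(label) != 1:
            raise MatrixFormatError(f"line {lineno}: expected a single-letter row label, got {label!r}")
        if len(vals) != len(header):
            raise MatrixFormatError(
                f"line {lineno}: row {label!r} has {len(vals)} values, expected {len(header)}"
            )
        try:
            rows[label] = [int(v) for v in vals]
        except ValueError:
            raise MatrixFormatError(f"line {lineno}: non-integer score in row {label!r}") from None
    if header is None or not rows:
        raise MatrixFormatError("no matrix content found")
    if sorted(rows) != sorted(header):
        raise MatrixFormatError("row labels do not match column labels")
    mat = np.array([[rows[a][header.index(b)] for b in header] for a in header], dtype=np.int64)
    return header, mat


def load_substitution_matrix(source: str | os.PathLike = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix by built-in name, file path, or matrix text.

    Built-in names are those shipped with Biopython (e.g. ``"BLOSUM62"``,
    the default). A path to, or a string of, NCBI-format matrix text is
    also accepted; it must cover the 20 standard amino acids (extra labels
    like B, Z, X, * are ignored) and be symmetric. X and gap rows are set
    to zero regardless of the source.
    """
    if isinstance(source, str) and source.upper() in substitution_matrices.load():
        name = source.upper()
        bm = substitution_matrices.load(name)
        letters = bm.alphabet
        idx = [letters.index(a) for a in AMINO_ACIDS]
        block = np.asarray(bm, dtype=np.int64)[np.ix_(idx, idx)]
        return _from_standard_block(name, block)

    if isinstance(source, os.PathLike) or (isinstance(source, str) and os.path.exists(source)):
        with open(source) as fh:
            text = fh.read()
        name = os.path.basename(os.fspath(source))
    else:
        text = str(source)
        name = "custom"
        if "\n" not in text:
            raise MatrixFormatError(f"unknown built-in matrix or missing file: {source!r}")

    labels, mat = _parse_ncbi_text(text)
    if not np.array_equal(mat, mat.T):
        bad = next(
            (a, b) for i, a in enumerate(labels) for j, b in enumerate(labels) if mat[i, j] != mat[j, i]
        )
        raise MatrixFormatError(f"matrix not symmetric: scores({bad[0]},{bad[1]}) != scores({bad[1]},{bad[0]})")
    missing = [a for a in AMINO_ACIDS if a not in labels]
    if missing:
        raise MatrixFormatError(f"matrix lacks rows for residues: {''.join(missing)}")
    idx = [labels.index(a) for a in AMINO_ACIDS]
    return _from_standard_block(name, mat[np.ix_(idx, idx)])
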