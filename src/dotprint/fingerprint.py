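"""Windowed self-similarity matrices and their binarized dot-plot fingerprints.

A protein is compared against itself with a substitution matrix: the score
of cell (i, j) is the sum of pairwise scores over a window of length W
(default 25) centred on (i, j) and running parallel to the main diagonal,

    grey(i, j) = clamp( sum_{k=-h..h} M(seq[i+k], seq[j+k]), 0, 255 ),

with h = (W-1)/2 and out-of-range offsets contributing nothing (windows
truncate at the sequence ends). Cells at or above the black point (default
31) are the "pixels" of the fingerprint; the self-identity diagonal and
the lower triangle are never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import SubstitutionMatrix
from .sequence import ProteinSequence

DEFAULT_WINDOW = 25
DEFAULT_BLACK_POINT = 31
GREY_MAX = 255


@dataclass(frozen=True)
class GreyMatrix:
    """Dense windowed self-similarity scores, clamped to the 0-255 grey range."""

    n: int
    window: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")
        v = np.asarray(self.values)
        if v.shape != (self.n, self.n):
            raise ValueError(f"expected {self.n}x{self.n} values, got {v.shape}")


@dataclass(frozen=True)
class DotPlot:
    """Sparse binarized fingerprint: strict upper-triangle pixels of a GreyMatrix.

    ``pixels`` is an (m, 2) int array of 0-based (i, j) cells with i < j,
    sorted lexicographically. The plot has symmetric semantics: cell (j, i)
    is implied.
    """

    n: int
    window: int = DEFAULT_WINDOW
    black_point: int = DEFAULT_BLACK_POINT
    pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64), repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if px.size:
            if px.min() < 0 or px.max() >= self.n:
                raise ValueError("pixel coordinates out of range")
            if not (px[:, 0] < px[:, 1]).all():
                raise ValueError("pixels must be strictly upper-triangle (i < j)")
            px = np.unique(px, axis=0)  # sorts lexicographically, drops duplicates
        object.__setattr__(self, "pixels", px)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pixels}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DotPlot):
            return NotImplemented
        return (
            self.n == other.n
            and self.window == other.window
            and self.black_point == other.black_point
            and np.array_equal(self.pixels, other.pixels)
        )

    def to_dense(self, symmetric: bool = False) -> np.ndarray:
        """Boolean matrix of the pixels (upper triangle; mirrored if symmetric)."""
        m = np.zeros((self.n, self.n), dtype=bool)
        if self.n_pixels:
            m[self.pixels[:, 0], self.pixels[:, 1]] = True
            if symmetric:
                m |= m.T
        return m


def self_score_matrix(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix,
    window: int = DEFAULT_WINDOW,
) -> GreyMatrix:
    """Compute the windowed self-similarity matrix of ``seq``.

    Scores sum the substitution-matrix values over a diagonal window of
    length ``window`` centred on each cell, truncated at the sequence
    ends, and are clamped to [0, 255].
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    codes = seq.codes
    n = len(codes)
    pair = matrix.scores[np.ix_(codes, codes)]  # n x n residue-pair scores
    h = (window - 1) // 2
    # Sum of diagonal shifts of the zero-padded pair matrix == truncated window.
    padded = np.zeros((n + 2 * h, n + 2 * h), dtype=np.int64)
    padded[h : h + n, h : h + n] = pair
    acc = np.zeros((n, n), dtype=np.int64)
    for k in range(window):
        acc += padded[k : k + n, k : k + n]
    np.clip(acc, 0, GREY_MAX, out=acc)
    return GreyMatrix(n=n, window=window, values=acc)


def binarize(grey: GreyMatrix, black_point: int = DEFAULT_BLACK_POINT) -> DotPlot:
    """Threshold a grey matrix into a sparse fingerprint.

    A strict-upper-triangle cell becomes a pixel iff its grey value is at
    or above ``black_point``; the self-identity diagonal is ignored.
    """
    if not 1 <= black_point <= GREY_MAX:
        raise ValueError(f"black_point must be in [1, {GREY_MAX}], got {black_point}")
    mask = np.triu(grey.values >= black_point, k=1)
    ii, jj = np.nonzero(mask)
    return DotPlot(
        n=grey.n,
        window=grey.window,
        black_point=black_point,
        pixels=np.column_stack([ii, jj]),
    )


def fingerprint(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix,
    window: int = DEFAULT_WINDOW,
    black_point: int = DEFAULT_BLACK_POINT,
) -> DotPlot:
    """Convenience: self-score then binarize."""
    return binarize(self_score_matrix(seq, matrix, window), black_point)


def pixel_density(plot: DotPlot) -> float:
    """Upper-triangle pixels per residue — the repeat information content."""
    return plot.n_pixels / plot.n
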