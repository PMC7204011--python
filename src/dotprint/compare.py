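"""Sliding Jaccard comparison of fingerprints, and global sequence similarity.

Two fingerprints are compared by translating the smaller plot's pixels
along the self-identity diagonal of the larger and, at every offset with
at least one residue of overlap, computing the Jaccard index

    J_X = |A ∩ B| / |A ∪ B|,

where the union always counts all pixels of both plots. The maximal J_X
over offsets measures pattern similarity; J_D = 1 − J_X is the
corresponding distance. Sliding compensates for length differences and
terminal insertions/deletions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .fingerprint import DotPlot
from .matrices import SubstitutionMatrix
from .sequence import ProteinSequence


@dataclass(frozen=True)
class SlideResult:
    """Optimal diagonal positioning of one fingerprint over another.

    ``offset`` is the shift (in residues) applied to the smaller plot's
    origin along the larger plot's self-identity diagonal. Ties in J_X are
    broken toward the smallest |offset|, negative before positive.
    """

    offset: int
    jaccard: float
    n_intersection: int
    n_union: int


def _encode(plot: DotPlot, span: int) -> np.ndarray:
    """Pixels as scalars i*span + j for O(m log m) set intersection."""
    return plot.pixels[:, 0] * span + plot.pixels[:, 1]


def jaccard_at_offset(a: DotPlot, b: DotPlot, offset: int) -> tuple[float, int, int]:
    """Jaccard index of the two plots with the smaller translated by ``offset``.

    The smaller plot's pixels (i, j) move to (i+offset, j+offset);
    intersection counts coincidences with the larger plot's pixels, while
    the union counts every pixel of both plots, inside the overlap window
    or not. Both plots empty gives 0 by convention. Offsets leaving no
    residue overlap raise ``ValueError``.
    """
    small, large = (a, b) if a.n <= b.n else (b, a)
    off = offset
    if off <= -small.n or off >= large.n:
        raise ValueError(
            f"offset {offset} leaves no overlap between plots of size {a.n} and {b.n}"
        )
    total = small.n_pixels + large.n_pixels
    if total == 0:
        return 0.0, 0, 0
    span = large.n + small.n + abs(off) + 2
    inter = np.intersect1d(
        _encode(small, span) + off * (span + 1), _encode(large, span), assume_unique=True
    ).size
    union = total - inter
    return (inter / union if union else 0.0), int(inter), int(union)


def _intersections_by_offset(small: DotPlot, large: DotPlot) -> dict[int, int]:
    """Intersection size for every offset where it is non-zero.

    A translated pixel (i+o, j+o) matches iff the off-diagonal distance
    d = j − i agrees; within one d, matches per offset are the
    cross-correlation of the two plots' i-coordinate lists.
    """
    counts: dict[int, int] = {}
    if small.n_pixels == 0 or large.n_pixels == 0:
        return counts
    ds, dl = small.pixels[:, 1] - small.pixels[:, 0], large.pixels[:, 1] - large.pixels[:, 0]
    for d in np.intersect1d(ds, dl):
        i_s = small.pixels[ds == d, 0]
        i_l = large.pixels[dl == d, 0]
        offs, c = np.unique(i_l[:, None] - i_s[None, :], return_counts=True)
        for o, k in zip(offs, c):
            counts[int(o)] = counts.get(int(o), 0) + int(k)
    return counts


def slide_compare(a: DotPlot, b: DotPlot) -> SlideResult:
    """Slide the smaller fingerprint along the larger's diagonal and return
    the offset maximizing J_X.

    Ties are broken toward the smallest absolute offset, negative before
    positive, so comparing a plot with itself yields offset 0.
    """
    small, large = (a, b) if a.n <= b.n else (b, a)
    lo, hi = -(small.n - 1), large.n - 1
    total = small.n_pixels + large.n_pixels
    counts = _intersections_by_offset(small, large)

    best_off, best_inter = 0, counts.get(0, 0)
    for off, inter in counts.items():
        if not lo <= off <= hi:
            continue
        if inter > best_inter or (
            inter == best_inter
            and (abs(off) < abs(best_off) or (abs(off) == abs(best_off) and off < best_off))
        ):
            best_off, best_inter = off, inter
    union = total - best_inter
    jac = best_inter / union if union else 0.0
    return SlideResult(
        offset=best_off,
        jaccard=jac,
        n_intersection=best_inter,
        n_union=union,
    )


def jaccard_distance(a: DotPlot, b: DotPlot) -> float:
    """J_D = 1 − max-slide J_X; symmetric in its arguments."""
    return 1.0 - slide_compare(a, b).jaccard


def pairwise_table(plots: dict[str, DotPlot], threads: int = 1) -> "pandas.DataFrame":  # noqa: F821
    """All-pairs sliding comparison as a long-format table.

    Columns: id_a, id_b, offset, j_x, j_d — one row per unordered pair.
    Pairs may be computed concurrently (``threads`` > 1); the output is
    sorted by (id_a, id_b) either way, so concurrency never changes the
    result.
    """
    import pandas as pd

    ids = sorted(plots)
    pairs = [(a, b) for x, a in enumerate(ids) for b in ids[x + 1 :]]

    def one(pair: tuple[str, str]):
        id_a, id_b = pair
        res = slide_compare(plots[id_a], plots[id_b])
        return (id_a, id_b, res.offset, res.jaccard, 1.0 - res.jaccard)

    if threads > 1 and len(pairs) > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as pool:
            rows = list(pool.map(one, pairs))
    else:
        rows = [one(p) for p in pairs]
    rows.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "offset", "j_x", "j_d"])


def global_similarity(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: SubstitutionMatrix,
    gap_open: float = -11,
    gap_extend: float = -1,
) -> tuple[float, float]:
    """Needleman–Wunsch global alignment statistics for two sequences.

    Aligns with the given substitution matrix and affine gap penalties
    (defaults BLOSUM62-style −11/−1) and returns (percent identity,
    percent similarity): identical pairs, and pairs with a positive
    substitution score, each as a percentage of the alignment length
    (gap columns included).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix.to_biopython()
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.residues, b.residues)[0]
    sa, sb = aln[0], aln[1]
    length = len(sa)
    ident = sim = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
        if matrix.score(ca, cb) > 0:
            sim += 1
    return 100.0 * ident / length, 100.0 * sim / length


def sequence_identity(a: str, b: str) -> float:
    """Positionwise percent identity of two equal-length strings (no alignment)."""
    if len(a) != len(b):
        raise ValueError("positionwise identity requires equal lengths")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)
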