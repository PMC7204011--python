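"""Independent brute-force oracles used to freeze expected values.

These deliberately share no code path with the package implementation:
plain Python loops over explicit definitions.
"""

from __future__ import annotations

import numpy as np

from dotprint.alphabet import ALPHABET
from dotprint.fingerprint import DotPlot
from dotprint.matrices import SubstitutionMatrix


def naive_self_score(residues: str, matrix: SubstitutionMatrix, window: int) -> np.ndarray:
    """Triple-loop windowed self-score with truncation and clamping."""
    n = len(residues)
    h = (window - 1) // 2
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            total = 0
            for k in range(-h, h + 1):
                if 0 <= i + k < n and 0 <= j + k < n:
                    total += matrix.score(residues[i + k], residues[j + k])
            out[i, j] = min(max(total, 0), 255)
    return out


def brute_slide(a: DotPlot, b: DotPlot) -> tuple[int, float]:
    """Exhaustive per-offset scan with explicit tie-breaking.

    Translates the smaller plot's pixels by every offset with >= 1 residue
    of diagonal overlap; offsets visited in order 0, -1, +1, -2, +2, ...
    so the first strict improvement wins ties.
    """
    small, large = (a, b) if a.n <= b.n else (b, a)
    sa = {(int(i), int(j)) for i, j in small.pixels}
    sb = {(int(i), int(j)) for i, j in large.pixels}
    total = len(sa) + len(sb)
    best_off, best_j = 0, -1.0
    offsets = sorted(
        range(-(small.n - 1), large.n), key=lambda o: (abs(o), o > 0)
    )
    for off in offsets:
        moved = {(i + off, j + off) for i, j in sa}
        inter = len(moved & sb)
        union = total - inter
        j = inter / union if union else 0.0
        if j > best_j:
            best_off, best_j = off, j
    return best_off, best_j


def identity_markov_expectation(
    residues: str, matrix: SubstitutionMatrix, rounds: int
) -> float:
    """Exact expected percent identity after ``rounds`` single-site mutations.

    Each round hits a uniform site (w.p. 1/n per site) and substitutes
    b != a with probability proportional to 2^(M(a,b)/2); the per-site
    residue process is a 20-state Markov chain, so the expected identity
    (including reversions) is the diagonal of its r-th power.
    """
    n = len(residues)
    block = matrix.standard_block.astype(float)
    w = np.exp2(block / 2.0)
    np.fill_diagonal(w, 0.0)
    q = w / w.sum(axis=1, keepdims=True)
    t = (1 - 1 / n) * np.eye(20) + (1 / n) * q
    tr = np.linalg.matrix_power(t, rounds)
    from dotprint.alphabet import AMINO_ACIDS

    probs = [tr[AMINO_ACIDS.index(c), AMINO_ACIDS.index(c)] for c in residues]
    return 100.0 * float(np.mean(probs))
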