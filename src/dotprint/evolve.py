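"""In-silico sequence evolution and fingerprint decay.

Substitutions follow a BLOSUM-derived model: a mutating residue ``a`` is
replaced by ``b ≠ a`` with probability proportional to 2^(M(a,b)/2), the
Boltzmann-like back-transform of the half-bit log-odds scores. Repeated
rounds of single-site mutation (sites drawn with replacement) produce a
decay curve of fingerprint similarity J_X against measured sequence
identity, which for repeat proteins follows a single exponential
J_X = exp(−b·z) in the identity loss z (percent). The half-life
z50 = ln(2)/b summarizes how quickly the dot-plot pattern decays without
selective pressure.

Single-residue insertions degrade J_X much faster per percent sequence
change than substitutions do, because they shift all downstream pixels off
the established diagonals.

The alphabet-shuffling Monte Carlo optimizes a bijective residue
replacement dictionary to minimize the similarity of the remapped sequence
to the original; repeat proteins typically keep a recognizable fingerprint
(J_X ≥ 0.1) even with essentially no remaining sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .alphabet import AMINO_ACIDS, N_STANDARD
from .compare import sequence_identity, slide_compare
from .fingerprint import DEFAULT_BLACK_POINT, DEFAULT_WINDOW, DotPlot, fingerprint
from .matrices import SubstitutionMatrix
from .sequence import ProteinSequence


# ---------------------------------------------------------------------------
# Substitution model


def substitution_probabilities(matrix: SubstitutionMatrix, *, allow_self: bool = False) -> np.ndarray:
    """Conditional substitution probabilities P(b | a) ∝ 2^(M(a,b)/2).

    Rows index the current residue ``a`` (standard 20), columns the
    replacement ``b``. Self-substitution is excluded by default so every
    mutation round changes a residue.
    """
    block = matrix.standard_block.astype(float)
    w = np.exp2(block / 2.0)
    if not allow_self:
        np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def mutate_once(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    probs: np.ndarray | None = None,
) -> ProteinSequence:
    """Substitute one uniformly-random position under the BLOSUM model."""
    if probs is None:
        probs = substitution_probabilities(matrix)
    res = list(seq.residues)
    pos = int(rng.integers(len(res)))
    a = AMINO_ACIDS.index(res[pos])
    res[pos] = AMINO_ACIDS[int(rng.choice(N_STANDARD, p=probs[a]))]
    return ProteinSequence(seq.id, "".join(res))


# ---------------------------------------------------------------------------
# Substitution decay


@dataclass(frozen=True)
class DecayCurve:
    """Mean fingerprint similarity and sequence identity per mutation round."""

    steps: np.ndarray
    mean_jx: np.ndarray
    mean_identity: np.ndarray
    replicates: int

    @property
    def identity_loss(self) -> np.ndarray:
        """z = 100 − mean identity, the fitting abscissa (percent)."""
        return 100.0 - self.mean_identity


@dataclass(frozen=True)
class ExponentialFit:
    """Single-exponential decay J_X = exp(−b·z) fitted to a DecayCurve."""

    b: float
    r_squared: float

    @property
    def z50(self) -> float:
        """Half-life: identity loss (percent) at which J_X halves."""
        return np.log(2.0) / self.b if self.b > 0 else float("nan")

    @property
    def clean(self) -> bool:
        """A well-behaved single-exponential decay (R² ≥ 0.98, b > 0)."""
        return self.b > 0 and self.r_squared >= 0.98


def decay_experiment(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix,
    rounds: int | None = None,
    replicates: int = 1001,
    rng: np.random.Generator | None = None,
    window: int = DEFAULT_WINDOW,
    black_point: int = DEFAULT_BLACK_POINT,
    measure_every: int = 1,
) -> DecayCurve:
    """Measure fingerprint decay under cumulative random substitution.

    Each replicate mutates the sequence one residue at a time for
    ``rounds`` rounds (default: the sequence length); after each measured
    round the mutant's fingerprint is slide-compared against the
    original's, and its positionwise percent identity to the original
    recorded. Curves are averaged across replicates. ``measure_every``
    thins the measured rounds (round 0 and the final round always
    included) — the J_X-vs-identity relationship is unaffected.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(seq)
    if rounds is None:
        rounds = n
    if rounds < 0 or replicates < 1:
        raise ValueError("rounds must be >= 0 and replicates >= 1")
    probs = substitution_probabilities(matrix)
    original_plot = fingerprint(seq, matrix, window, black_point)
    measured = sorted({0, rounds, *range(0, rounds + 1, max(1, measure_every))})

    jx = np.zeros((replicates, len(measured)))
    ident = np.zeros((replicates, len(measured)))
    for r in range(replicates):
        mutant = seq
        col = 0
        for step in range(rounds + 1):
            if step > 0:
                mutant = mutate_once(mutant, matrix, rng, probs)
            if step == measured[col]:
                if step == 0:
                    jx[r, col], ident[r, col] = 1.0, 100.0
                else:
                    plot = fingerprint(mutant, matrix, window, black_point)
                    jx[r, col] = slide_compare(plot, original_plot).jaccard
                    ident[r, col] = sequence_identity(mutant.residues, seq.residues)
                col += 1
    return DecayCurve(
        steps=np.array(measured),
        mean_jx=jx.mean(axis=0),
        mean_identity=ident.mean(axis=0),
        replicates=replicates,
    )


def fit_exponential(curve: DecayCurve) -> ExponentialFit:
    """Fit J_X = exp(−b·z) to a decay curve by nonlinear least squares.

    z is the measured identity loss in percent. Requires at least 5 points
    with z > 0. A non-decaying curve (best b ≤ 0) is returned flagged, with
    undefined half-life.
    """
    mask = curve.identity_loss > 0
    if mask.sum() < 5:
        raise ValueError("need at least 5 curve points with identity loss > 0")
    z = curve.identity_loss[mask]
    j = curve.mean_jx[mask]
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat curves give a singular covariance
            (b,), _ = curve_fit(lambda zz, b: np.exp(-b * zz), z, j, p0=[0.1], maxfev=10000)
    except RuntimeError:
        b = 0.0
    resid = j - np.exp(-b * z)
    ss_tot = float(((j - j.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return ExponentialFit(b=float(b), r_squared=r2)


# ---------------------------------------------------------------------------
# Insertion decay


@dataclass(frozen=True)
class InsertionCurve:
    """Mean J_X against the number (and rate) of inserted residues."""

    n_inserted: np.ndarray
    rate_percent: np.ndarray  # insertions as percent of the original length
    mean_jx: np.ndarray
    replicates: int

    @property
    def half_loss_rate(self) -> float:
        """First insertion rate (percent) where mean J_X ≤ 0.5, linearly
        interpolated between bracketing measurements; NaN if never reached."""
        below = np.flatnonzero(self.mean_jx <= 0.5)
        if below.size == 0:
            return float("nan")
        k = int(below[0])
        if k == 0:
            return float(self.rate_percent[0])
        x0, x1 = self.rate_percent[k - 1], self.rate_percent[k]
        y0, y1 = self.mean_jx[k - 1], self.mean_jx[k]
        if y0 == y1:
            return float(x1)
        return float(x0 + (y0 - 0.5) * (x1 - x0) / (y0 - y1))


def insertion_experiment(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix,
    max_fraction: float = 0.20,
    replicates: int = 100,
    rng: np.random.Generator | None = None,
    window: int = DEFAULT_WINDOW,
    black_point: int = DEFAULT_BLACK_POINT,
    composition: str = "sequence",
) -> InsertionCurve:
    """Measure fingerprint decay under cumulative single-residue insertion.

    Per replicate, residues are inserted one at a time at uniform random
    positions, up to ``max_fraction`` of the original length; each grown
    sequence's fingerprint is slide-compared to the original's. Inserted
    residues are drawn from the original sequence's composition by default
    (``composition="uniform"`` draws uniformly over the 20 letters).
    """
    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    n = len(seq)
    max_ins = max(1, int(np.floor(max_fraction * n)))
    if composition == "sequence":
        pool = seq.residues
    elif composition == "uniform":
        pool = AMINO_ACIDS
    else:
        raise ValueError(f"unknown composition model {composition!r}")
    original_plot = fingerprint(seq, matrix, window, black_point)

    jx = np.zeros((replicates, max_ins + 1))
    jx[:, 0] = 1.0
    for r in range(replicates):
        res = list(seq.residues)
        for k in range(1, max_ins + 1):
            pos = int(rng.integers(len(res) + 1))
            res.insert(pos, pool[int(rng.integers(len(pool)))])
            plot = fingerprint(ProteinSequence(seq.id, "".join(res)), matrix, window, black_point)
            jx[r, k] = slide_compare(plot, original_plot).jaccard
    counts = np.arange(max_ins + 1)
    return InsertionCurve(
        n_inserted=counts,
        rate_percent=100.0 * counts / n,
        mean_jx=jx.mean(axis=0),
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# Alphabet shuffling


@dataclass(frozen=True)
class ReplacementMap:
    """A bijection over the 20 amino-acid letters with its similarity score."""

    mapping: dict[str, str]
    similarity_score: float  # per-residue BLOSUM score of mapped vs original

    def __post_init__(self) -> None:
        if sorted(self.mapping) != sorted(AMINO_ACIDS) or sorted(
            self.mapping.values()
        ) != sorted(AMINO_ACIDS):
            raise ValueError("replacement map must be a bijection over the 20 amino acids")

    def apply(self, seq: ProteinSequence) -> ProteinSequence:
        return ProteinSequence(
            seq.id + "|shuffled", "".join(self.mapping[c] for c in seq.residues)
        )


@dataclass(frozen=True)
class ShuffleResult:
    """Best replacement map found, and the fingerprint similarity it preserves."""

    map: ReplacementMap
    jaccard: float
    identity_percent: float
    plot: DotPlot = field(repr=False)


def _map_score(perm: np.ndarray, comp_counts: np.ndarray, block: np.ndarray, n: int) -> float:
    """Per-residue BLOSUM score of the remapped sequence against the
    original; depends only on composition since the map is positionwise."""
    return float(block[perm[: N_STANDARD], np.arange(N_STANDARD)] @ comp_counts) / n


def shuffle_alphabet_mc(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix,
    steps: int = 10000,
    kT: float = 0.04,
    restarts: int = 10,
    rng: np.random.Generator | None = None,
    window: int = DEFAULT_WINDOW,
    black_point: int = DEFAULT_BLACK_POINT,
) -> ShuffleResult:
    """Find a residue-replacement bijection minimizing sequence similarity.

    Monte-Carlo over permutations of the 20-letter alphabet: start from a
    random bijection, propose swaps of two keys' values, score the
    remapped sequence against the original by its per-residue BLOSUM
    similarity, and accept score decreases always and increases with
    probability exp(−Δ/kT). The best (lowest-similarity) map over
    ``restarts`` independent runs wins; its remapped sequence is then
    fingerprinted and slide-compared to the original.
    """
    if rng is None:
        rng = np.random.default_rng()
    codes = seq.codes
    if codes.max() >= N_STANDARD:
        raise ValueError("alphabet shuffling requires a standard 20-letter sequence")
    comp = np.bincount(codes, minlength=N_STANDARD).astype(float)
    block = matrix.standard_block.astype(float)
    n = len(seq)

    best_perm: np.ndarray | None = None
    best_score = np.inf
    for _ in range(max(1, restarts)):
        perm = rng.permutation(N_STANDARD)
        score = _map_score(perm, comp, block, n)
        if score < best_score:
            best_perm, best_score = perm.copy(), score
        for _ in range(steps):
            i, j = rng.choice(N_STANDARD, size=2, replace=False)
            cand = perm.copy()
            cand[i], cand[j] = cand[j], cand[i]
            cand_score = _map_score(cand, comp, block, n)
            delta = cand_score - score
            if delta < 0 or rng.random() < np.exp(-delta / kT):
                perm, score = cand, cand_score
                if score < best_score:
                    best_perm, best_score = perm.copy(), score

    mapping = {AMINO_ACIDS[a]: AMINO_ACIDS[int(best_perm[a])] for a in range(N_STANDARD)}
    rmap = ReplacementMap(mapping=mapping, similarity_score=best_score)
    mapped = rmap.apply(seq)
    plot = fingerprint(mapped, matrix, window, black_point)
    original = fingerprint(seq, matrix, window, black_point)
    return ShuffleResult(
        map=rmap,
        jaccard=slide_compare(plot, original).jaccard,
        identity_percent=sequence_identity(mapped.residues, seq.residues),
        plot=plot,
    )
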