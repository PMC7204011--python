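"""Synthetic protein generators with known ground truth.

Emulates the kinds of inputs the analysis consumes without any database
access: tandem-repeat proteins with controlled unit length, copy number
and divergence (repeat units in real proteins are typically 20–40 residues
and occur in 3–25 copies), length/composition-matched non-repeat controls,
and star-phylogeny homolog families for consensus experiments.

Residue composition defaults to the BLOSUM62 background frequencies, for
consistency with the scoring model. Every generator takes an explicit RNG
and is bitwise reproducible under a fixed seed; ground truth (unit
intervals, period, ancestor) is returned alongside each sequence and can
be serialized as a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, N_STANDARD
from .evolve import substitution_probabilities
from .matrices import SubstitutionMatrix
from .sequence import ProteinSequence

#: BLOSUM62 amino-acid background frequencies (order: ACDEFGHIKLMNPQRSTVWY).
BLOSUM62_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


def _composition_vector(composition: dict[str, float] | None) -> np.ndarray:
    comp = composition or BLOSUM62_BACKGROUND
    vec = np.array([comp.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    if vec.sum() <= 0:
        raise ValueError("composition must have positive total weight")
    return vec / vec.sum()


@dataclass(frozen=True)
class RepeatSpec:
    """Parameters of a synthetic tandem-repeat protein.

    ``unit_divergence`` may be a single expected substitution fraction
    applied to every copy, or a ``(low, high)`` range from which each
    copy's divergence is drawn uniformly — heterogeneous inter-unit
    identity, as in natural repeat arrays where some copies are recent
    duplicates and others ancient.
    """

    unit_length: int = 25
    copies: int = 6
    unit_divergence: float | tuple[float, float] = 0.20
    flank_length: int = 10
    insertion_rate: float = 0.0  # expected single-residue insertions per copy
    composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.unit_length < 1 or self.copies < 1 or self.flank_length < 0:
            raise ValueError("unit_length and copies must be >= 1, flank_length >= 0")
        div = self.unit_divergence
        rates = list(div) if isinstance(div, tuple) else [div]
        for rate in rates + [self.insertion_rate]:
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if isinstance(div, tuple) and div[0] > div[1]:
            raise ValueError("divergence range must be (low, high)")


@dataclass(frozen=True)
class TandemTruth:
    """Ground truth for a generated tandem-repeat protein."""

    unit_intervals: list[tuple[int, int]]  # 0-based half-open, per copy
    period: int
    ancestor_unit: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def random_protein(
    length: int,
    rng: np.random.Generator,
    composition: dict[str, float] | None = None,
    id: str = "random",
) -> ProteinSequence:
    """I.i.d. residues from the given (default BLOSUM62 background) composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    vec = _composition_vector(composition)
    codes = rng.choice(N_STANDARD, size=length, p=vec)
    return ProteinSequence(id, "".join(AMINO_ACIDS[c] for c in codes))


#: Non-repeat control generator (alias named for its role in benchmarks).
make_nonrepeat_protein = random_protein


def _diverge(
    residues: str,
    divergence: float,
    probs: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Substitute each position independently with probability ``divergence``
    under the BLOSUM-conditional model."""
    res = list(residues)
    hit = np.flatnonzero(rng.random(len(res)) < divergence)
    for pos in hit:
        a = AMINO_ACIDS.index(res[pos])
        res[pos] = AMINO_ACIDS[int(rng.choice(N_STANDARD, p=probs[a]))]
    return "".join(res)


def make_tandem_protein(
    spec: RepeatSpec,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    id: str = "tandem",
) -> tuple[ProteinSequence, TandemTruth]:
    """Generate a tandem-repeat protein and its ground truth.

    A random ancestor unit is drawn from the composition; each copy is an
    independently diverged instance of it (substitutions under the BLOSUM
    model; optionally single-residue insertions at ``insertion_rate``
    expected insertions per copy), flanked by random non-repeat sequence.
    """
    probs = substitution_probabilities(matrix)
    vec = _composition_vector(spec.composition)
    unit = "".join(AMINO_ACIDS[c] for c in rng.choice(N_STANDARD, size=spec.unit_length, p=vec))

    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    flank = (
        "".join(AMINO_ACIDS[c] for c in rng.choice(N_STANDARD, size=spec.flank_length, p=vec))
        if spec.flank_length
        else ""
    )
    pos = len(flank)
    parts.append(flank)
    for _ in range(spec.copies):
        div = spec.unit_divergence
        if isinstance(div, tuple):
            div = float(rng.uniform(div[0], div[1]))
        copy = _diverge(unit, div, probs, rng)
        if spec.insertion_rate > 0:
            for _ in range(rng.poisson(spec.insertion_rate)):
                at = int(rng.integers(len(copy) + 1))
                ins = AMINO_ACIDS[int(rng.choice(N_STANDARD, p=vec))]
                copy = copy[:at] + ins + copy[at:]
        parts.append(copy)
        intervals.append((pos, pos + len(copy)))
        pos += len(copy)
    if spec.flank_length:
        parts.append(
            "".join(AMINO_ACIDS[c] for c in rng.choice(N_STANDARD, size=spec.flank_length, p=vec))
        )
    seq = ProteinSequence(id, "".join(parts))
    truth = TandemTruth(unit_intervals=intervals, period=spec.unit_length, ancestor_unit=unit)
    return seq, truth


def shuffled_control(
    seq: ProteinSequence, rng: np.random.Generator, id: str | None = None
) -> ProteinSequence:
    """Composition-matched control: the same residues in random order."""
    res = np.array(list(seq.residues))
    rng.shuffle(res)
    return ProteinSequence(id or seq.id + "|shuffled", "".join(res))


def make_standard_set(
    count: int,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    unit_range: tuple[int, int] = (20, 40),
    copy_range: tuple[int, int] = (4, 8),
    divergence_range: tuple[float, float] = (0.40, 0.60),
    length_range: tuple[int, int] = (150, 450),
    min_density: float = 0.42,
) -> list[tuple[ProteinSequence, TandemTruth]]:
    """A benchmark set of natural-like tandem-repeat proteins.

    Emulates a curated standard set of repeat chains of known structure:
    unit lengths 20–40 residues, 4–8 copies, per-copy divergence drawn
    from ``divergence_range`` (heterogeneous inter-unit identity; the
    default range places fingerprint pixel densities in the band observed
    for natural repeat proteins rather than designed ones), total length
    within ``length_range``, and — like any curated dot-plot set — only
    chains whose fingerprints carry at least ``min_density`` pixels per
    residue are retained.
    """
    from .fingerprint import fingerprint, pixel_density

    out: list[tuple[ProteinSequence, TandemTruth]] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 100 * count:
            raise RuntimeError("could not generate enough informative chains")
        u = int(rng.integers(unit_range[0], unit_range[1] + 1))
        c = int(rng.integers(copy_range[0], copy_range[1] + 1))
        spec = RepeatSpec(unit_length=u, copies=c, unit_divergence=divergence_range)
        seq, truth = make_tandem_protein(spec, matrix, rng, id=f"std{len(out):03d}")
        if not length_range[0] <= len(seq) <= length_range[1]:
            continue
        if pixel_density(fingerprint(seq, matrix)) < min_density:
            continue
        out.append((seq, truth))
    return out


def make_family(
    ancestor: ProteinSequence,
    members: int,
    divergence: float,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
) -> list[ProteinSequence]:
    """Star-phylogeny homolog family: each member independently diverged
    from the ancestor (substitutions only, so the columnwise alignment is
    the trivial one)."""
    if members < 2:
        raise ValueError("a family needs at least 2 members")
    probs = substitution_probabilities(matrix)
    return [
        ProteinSequence(f"{ancestor.id}|m{k}", _diverge(ancestor.residues, divergence, probs, rng))
        for k in range(members)
    ]
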