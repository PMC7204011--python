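"""Consensus fingerprints for families of related proteins.

Starting from a multiple sequence alignment of homologs: columns where at
least 20% of members have a gap are trimmed; 25 gap symbols are padded
onto both termini (one full scoring window, to suppress edge effects of
the editing); each member's windowed self-similarity matrix is computed
on its edited, equal-length sequence (gap symbols score zero); the
matrices are averaged cell-wise and the average is binarized at the black
point to give the family-conserved consensus pattern.

Coherent family groups can also be discovered from a set of member
fingerprints by hierarchical clustering of pairwise Jaccard distances:
dendrograms from several linkages are cut at 50 evenly spaced heights and
each cut is scored by how many clusters are internally coherent
(median pairwise J_D ≤ 0.875).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alphabet import GAP
from .fingerprint import (
    DEFAULT_BLACK_POINT,
    DEFAULT_WINDOW,
    DotPlot,
    GreyMatrix,
    binarize,
    self_score_matrix,
)
from .compare import jaccard_distance
from .matrices import SubstitutionMatrix
from .sequence import ProteinSequence

DEFAULT_GAP_FRACTION = 0.20
DEFAULT_PAD = 25
DEFAULT_COHERENCE = 0.875
DEFAULT_CUT_LEVELS = 50

#: scipy names for the linkage methods searched; "mcquitty" is WPGMA.
LINKAGE_METHODS = {
    "mcquitty": "weighted",
    "average": "average",
    "complete": "complete",
    "single": "single",
    "ward": "ward",
}


@dataclass(frozen=True)
class ConsensusPlot:
    """Cell-wise average of member grey matrices, re-binarized."""

    n: int
    mean_grey: np.ndarray = field(repr=False)
    plot: DotPlot = field(repr=False)
    members: list[str] = field(default_factory=list)


def trim_alignment(
    msa: list[ProteinSequence], gap_fraction: float = DEFAULT_GAP_FRACTION
) -> list[ProteinSequence]:
    """Remove alignment columns where ≥ ``gap_fraction`` of members have a gap."""
    if not msa:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in msa}
    if len(lengths) > 1:
        raise ValueError(f"alignment members have unequal lengths: {sorted(lengths)}")
    cols = np.array([[c == GAP for c in s.residues] for s in msa])
    keep = cols.mean(axis=0) < gap_fraction
    if not keep.any():
        raise ValueError("trimming removed every alignment column")
    return [
        ProteinSequence(s.id, "".join(np.array(list(s.residues))[keep])) for s in msa
    ]


def pad_termini(seqs: list[ProteinSequence], pad: int = DEFAULT_PAD) -> list[ProteinSequence]:
    """Prepend and append ``pad`` gap symbols to every sequence.

    The pads score zero in fingerprinting, pushing window-truncation edge
    effects off the residues of interest.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    return [ProteinSequence(s.id, GAP * pad + s.residues + GAP * pad) for s in seqs]


def consensus_plot(
    seqs: list[ProteinSequence],
    matrix: SubstitutionMatrix,
    window: int = DEFAULT_WINDOW,
    black_point: int = DEFAULT_BLACK_POINT,
) -> ConsensusPlot:
    """Average the members' grey matrices and binarize at the black point.

    Members must already be edited and padded to a common length.
    """
    if len(seqs) < 2:
        raise ValueError("a consensus needs at least 2 member sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"member sequences have unequal lengths: {sorted(lengths)}")
    n = lengths.pop()
    mean = np.zeros((n, n), dtype=float)
    for s in seqs:
        mean += self_score_matrix(s, matrix, window).values
    mean /= len(seqs)
    plot = binarize(GreyMatrix(n=n, window=window, values=mean), black_point)
    return ConsensusPlot(n=n, mean_grey=mean, plot=plot, members=[s.id for s in seqs])


def consensus_pipeline(
    msa: list[ProteinSequence],
    matrix: SubstitutionMatrix,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
    pad: int = DEFAULT_PAD,
    window: int = DEFAULT_WINDOW,
    black_point: int = DEFAULT_BLACK_POINT,
) -> ConsensusPlot:
    """trim → pad → consensus, in one deterministic call."""
    return consensus_plot(
        pad_termini(trim_alignment(msa, gap_fraction), pad), matrix, window, black_point
    )


def consensus_score_profile(cons: ConsensusPlot) -> np.ndarray:
    """Per-residue maximum off-diagonal consensus score.

    A residue belongs to a repeat at deconvolution cutoff c (multiples of
    10 up to 50 are conventional) iff any cell in its row or column of the
    averaged matrix scores at least c; feeding this profile to
    ``detect.repeat_segments`` with ``cutoff=c`` applies exactly that rule.
    """
    g = cons.mean_grey.copy()
    np.fill_diagonal(g, 0.0)
    return np.maximum(g.max(axis=0), g.max(axis=1))


@dataclass(frozen=True)
class GroupingResult:
    """Best coherent grouping of member fingerprints."""

    linkage: str
    cut_height: float
    clusters: list[list[str]]  # all clusters at the chosen cut
    coherent: list[list[str]]  # clusters of size >= 2 with median J_D <= coherence
    n_coherent: int
    consensus: dict[int, ConsensusPlot] = field(default_factory=dict)


def _cluster_median_jd(ids: list[str], dist: dict[tuple[str, str], float]) -> float:
    pairs = [dist[tuple(sorted(p))] for p in combinations(ids, 2)]
    return float(np.median(pairs))


def detect_consensus_groups(
    plots: dict[str, DotPlot],
    coherence: float = DEFAULT_COHERENCE,
    cut_levels: int = DEFAULT_CUT_LEVELS,
    linkages: tuple[str, ...] = ("mcquitty", "average", "complete", "single", "ward"),
    statistic: str = "median",
    sequences: dict[str, ProteinSequence] | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> GroupingResult:
    """Search linkage methods and dendrogram cuts for coherent family groups.

    The pairwise J_D matrix of the fingerprints is clustered under each
    linkage; each dendrogram is cut at ``cut_levels`` evenly spaced
    heights, and every (linkage, height) is scored by the number of
    coherent clusters — clusters of ≥ 2 members whose pairwise J_D
    aggregate (median by default; "mean"/"max" available) is at most
    ``coherence``. The top-scoring grouping wins (ties: earlier linkage in
    the list, then lower cut height). If equal-length ``sequences`` and a
    ``matrix`` are supplied, a consensus fingerprint is built per coherent
    group.
    """
    ids = sorted(plots)
    if len(ids) < 2:
        raise ValueError("need at least 2 fingerprints")
    agg = {"median": np.median, "mean": np.mean, "max": np.max}.get(statistic)
    if agg is None:
        raise ValueError(f"unknown coherence statistic {statistic!r}")

    dist: dict[tuple[str, str], float] = {}
    m = len(ids)
    dmat = np.zeros((m, m))
    for x, y in combinations(range(m), 2):
        d = jaccard_distance(plots[ids[x]], plots[ids[y]])
        dmat[x, y] = dmat[y, x] = d
        dist[(ids[x], ids[y])] = d
    condensed = squareform(dmat, checks=False)

    best: GroupingResult | None = None
    best_key: tuple[int, int] = (-1, -1)
    for name in linkages:
        method = LINKAGE_METHODS.get(name)
        if method is None:
            raise ValueError(f"unknown linkage {name!r}")
        tree = linkage(condensed, method=method)
        hmax = tree[-1, 2] if len(tree) else 0.0
        for height in np.linspace(0.0, hmax, cut_levels):
            labels = fcluster(tree, t=height, criterion="distance")
            clusters: dict[int, list[str]] = {}
            for lab, cid in zip(labels, ids):
                clusters.setdefault(int(lab), []).append(cid)
            members = [sorted(v) for v in clusters.values()]
            coherent = [
                c
                for c in members
                if len(c) >= 2
                and float(agg([dist[tuple(sorted(p))] for p in combinations(c, 2)])) <= coherence
            ]
            # primary score: number of coherent clusters; ties go to the cut
            # covering more chains with coherent clusters, then to the
            # earlier linkage / lower height
            key = (len(coherent), sum(len(c) for c in coherent))
            if key > best_key:
                best_key = key
                best = GroupingResult(
                    linkage=name,
                    cut_height=float(height),
                    clusters=sorted(members),
                    coherent=sorted(coherent),
                    n_coherent=len(coherent),
                )
    assert best is not None

    if sequences is not None and matrix is not None:
        cons = {
            k: consensus_plot([sequences[i] for i in group], matrix)
            for k, group in enumerate(best.coherent)
        }
        best = GroupingResult(
            linkage=best.linkage,
            cut_height=best.cut_height,
            clusters=best.clusters,
            coherent=best.coherent,
            n_coherent=best.n_coherent,
            consensus=cons,
        )
    return best
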