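"""Desk-scale reproduction experiments on synthetic benchmark sets.

These drive the package end to end on generated data with known ground
truth: substitution-decay and insertion-decay experiments on a standard
set of natural-like tandem-repeat chains, alphabet shuffling, the
repeat-vs-control classification benchmark, and planted-family cluster
recovery. Problem sizes (chain counts, replicate counts, measurement
thinning) are parameters; defaults are the desk-scale settings described
in the methods notes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import hcluster, mcl_cluster, pairwise_matrix, sparsify_topk
from .detect import classify_repeat
from .evolve import (
    decay_experiment,
    fit_exponential,
    insertion_experiment,
    shuffle_alphabet_mc,
)
from .fingerprint import fingerprint
from .matrices import SubstitutionMatrix
from .sequence import ProteinSequence
from .synth import RepeatSpec, make_family, make_standard_set, make_tandem_protein, shuffled_control


def decay_benchmark(
    chains: list[ProteinSequence],
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    replicates: int = 24,
    measure_every: int = 4,
) -> pd.DataFrame:
    """Substitution-decay curves and exponential fits, one row per chain.

    Columns: id, n, b, z50, r_squared, clean.
    """
    rows = []
    for seq in chains:
        curve = decay_experiment(
            seq, matrix, replicates=replicates, rng=rng, measure_every=measure_every
        )
        fit = fit_exponential(curve)
        rows.append((seq.id, len(seq), fit.b, fit.z50, fit.r_squared, fit.clean))
    return pd.DataFrame(rows, columns=["id", "n", "b", "z50", "r_squared", "clean"])


def insertion_benchmark(
    chains: list[ProteinSequence],
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    replicates: int = 20,
    max_fraction: float = 0.08,
) -> pd.DataFrame:
    """Insertion-decay half-loss rates, one row per chain.

    Columns: id, n, half_loss_rate_percent.
    """
    rows = []
    for seq in chains:
        curve = insertion_experiment(
            seq, matrix, max_fraction=max_fraction, replicates=replicates, rng=rng
        )
        rows.append((seq.id, len(seq), curve.half_loss_rate))
    return pd.DataFrame(rows, columns=["id", "n", "half_loss_rate_percent"])


def shuffle_benchmark(
    chains: list[ProteinSequence],
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    steps: int = 2000,
    restarts: int = 3,
) -> pd.DataFrame:
    """Alphabet-shuffling results, one row per chain.

    Columns: id, identity_percent, similarity_score, j_x.
    """
    rows = []
    for seq in chains:
        res = shuffle_alphabet_mc(seq, matrix, steps=steps, restarts=restarts, rng=rng)
        rows.append((seq.id, res.identity_percent, res.map.similarity_score, res.jaccard))
    return pd.DataFrame(rows, columns=["id", "identity_percent", "similarity_score", "j_x"])


def classification_benchmark(
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    n_each: int = 50,
    min_length: int = 121,
    density_cutoff: float = 0.42,
) -> tuple[float, float]:
    """Sensitivity/specificity of the repeat census criterion.

    Generates ``n_each`` tandem-repeat proteins (unit 20–40, 3–8 copies,
    up to 30% homogeneous unit divergence, all at least ``min_length``
    residues) and the same number of composition-matched shuffles, and
    scores the density-plus-length classifier against the known labels.
    Returns (sensitivity, specificity).
    """
    tp = tn = 0
    made = 0
    while made < n_each:
        u = int(rng.integers(20, 41))
        c = int(rng.integers(3, 9))
        d = float(rng.uniform(0.0, 0.30))
        spec = RepeatSpec(unit_length=u, copies=c, unit_divergence=d, flank_length=10)
        seq, _ = make_tandem_protein(spec, matrix, rng, id=f"rep{made}")
        if len(seq) < min_length:
            continue
        made += 1
        if classify_repeat(fingerprint(seq, matrix), min_length, density_cutoff):
            tp += 1
        ctrl = shuffled_control(seq, rng)
        if not classify_repeat(fingerprint(ctrl, matrix), min_length, density_cutoff):
            tn += 1
    return tp / n_each, tn / n_each


def planted_family_plots(
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    families: int = 3,
    members: int = 5,
    member_divergence: float = 0.05,
) -> tuple[dict, dict[str, str]]:
    """Fingerprints for several distinct tandem families plus true labels."""
    plots: dict = {}
    labels: dict[str, str] = {}
    for f in range(families):
        unit = int(rng.integers(20, 41))
        anc, _ = make_tandem_protein(
            RepeatSpec(unit_length=unit, copies=6, unit_divergence=0.1, flank_length=5),
            matrix, rng, id=f"fam{f}",
        )
        for m in make_family(anc, members, member_divergence, matrix, rng):
            plots[m.id] = fingerprint(m, matrix)
            labels[m.id] = f"fam{f}"
    return plots, labels


def planted_cluster_purity(
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
    families: int = 3,
    members: int = 5,
) -> tuple[float, float]:
    """Best-cut hierarchical purity and MCL purity on planted families.

    Returns (hierarchical majority purity at the best cut with the true
    number of clusters, MCL majority purity).
    """
    plots, labels = planted_family_plots(matrix, rng, families, members)
    dist = pairwise_matrix(plots)
    hres = hcluster(dist, reference_labels=labels)
    at_k = hres.purity.loc[hres.purity.n_clusters == families]
    h_purity = float(at_k.majority_purity.max()) if len(at_k) else 0.0

    graph = sparsify_topk(1.0 - dist, k=len(plots))
    mres = mcl_cluster(graph, distances=dist)
    majority = 0
    for cid in mres.sizes:
        mem = mres.members(cid)
        labs = [labels[m] for m in mem]
        majority += max(labs.count(l) for l in set(labs))
    m_purity = majority / len(plots)
    return h_purity, m_purity


def standard_chains(
    matrix: SubstitutionMatrix, rng: np.random.Generator, count: int = 20
) -> list[ProteinSequence]:
    """The synthetic standard set used by the decay-type experiments."""
    return [seq for seq, _ in make_standard_set(count, matrix, rng)]
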