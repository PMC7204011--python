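import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dotprint import (
    DotPlot,
    export_mcl_abc,
    find_medoid,
    hcluster,
    mcl_cluster,
    pairwise_matrix,
    sparsify_topk,
)
from dotprint.cluster import SimilarityGraph


def planted_distance_matrix(rng, families, members, within=0.1, between=0.9, jitter=0.02):
    ids = [f"f{f}m{m}" for f in range(families) for m in range(members)]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = ids[i][:2] == ids[j][:2]
            base = within if same else between
            val = np.clip(base + rng.normal(0, jitter), 0.01, 1.0)
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=ids, columns=ids)


class TestPairwiseMatrix:
    def test_identical_plots_zero_matrix(self):
        plot = DotPlot(n=30, pixels=np.array([[2, 9], [4, 20]]))
        m = pairwise_matrix({"a": plot, "b": plot, "c": plot})
        assert np.allclose(m.to_numpy(), 0.0)

    def test_disjoint_plots_unit_distance(self):
        a = DotPlot(n=30, pixels=np.array([[0, 3]]))
        b = DotPlot(n=30, pixels=np.array([[0, 12]]))
        m = pairwise_matrix({"a": a, "b": b})
        assert m.loc["a", "b"] == 1.0
        assert m.loc["a", "a"] == 0.0


class TestHCluster:
    def test_wpgma_hand_example(self):
        """First merge {A,B} at 0.2; the merged cluster's distance to C is
        the unweighted mean (0.8 + 0.8)/2 = 0.8."""
        d = pd.DataFrame(
            [[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        res = hcluster(d, method="mcquitty", cut_levels=10)
        assert res.tree[0, 2] == pytest.approx(0.2)
        assert res.tree[1, 2] == pytest.approx(0.8)

    @pytest.mark.parametrize("method", ["mcquitty", "average", "complete", "single", "ward"])
    def test_planted_blobs_two_clusters_mid_height(self, method, rng):
        d = planted_distance_matrix(rng, families=2, members=5)
        res = hcluster(d, method=method, cut_levels=50)
        mid = res.assignments.iloc[:, 25]
        assert mid.nunique() == 2
        by_family = {i[:2] for i in d.index}
        for fam in by_family:
            labels = mid[[i for i in d.index if i.startswith(fam)]]
            assert labels.nunique() == 1

    def test_purity_on_planted_labels(self, rng):
        d = planted_distance_matrix(rng, families=3, members=4)
        labels = {i: i[:2] for i in d.index}
        res = hcluster(d, reference_labels=labels)
        assert res.purity is not None
        best = res.purity.loc[res.purity.n_clusters == 3]
        assert (best.fraction_pure == 1.0).any()
        assert (best.majority_purity == 1.0).any()

    def test_unknown_linkage_rejected(self, rng):
        d = planted_distance_matrix(rng, 2, 2)
        with pytest.raises(ValueError, match="unknown linkage"):
            hcluster(d, method="centroidish")

    def test_permutation_invariant_up_to_relabel(self, rng):
        d = planted_distance_matrix(rng, families=2, members=4)
        perm = list(rng.permutation(d.index))
        res1 = hcluster(d, cut_levels=20)
        res2 = hcluster(d.loc[perm, perm], cut_levels=20)
        for col in res1.assignments.columns:
            a = res1.assignments[col]
            b = res2.assignments[col].reindex(a.index)
            # same partition: equal co-membership relation
            for i in a.index:
                for j in a.index:
                    assert (a[i] == a[j]) == (b[i] == b[j])


class TestSparsify:
    def test_small_complete_graph_unchanged(self):
        ids = list("abcde")
        s = pd.DataFrame(0.5, index=ids, columns=ids)
        g = sparsify_topk(s, k=4).graph
        assert g.number_of_edges() == 10

    def test_union_symmetrization_keeps_one_sided_edges(self):
        # hub similar to 10 spokes; spokes dissimilar to each other
        ids = ["hub"] + [f"s{k}" for k in range(10)]
        s = pd.DataFrame(0.0, index=ids, columns=ids)
        for k in range(10):
            s.loc["hub", f"s{k}"] = s.loc[f"s{k}", "hub"] = 0.2 + 0.05 * k
        g = sparsify_topk(s, k=2).graph
        # hub's own list keeps 2, but every spoke retains its hub edge
        assert g.degree["hub"] == 10

    def test_large_k_is_identity(self, rng):
        ids = [f"n{k}" for k in range(6)]
        vals = rng.uniform(0.1, 1.0, size=(6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        s = pd.DataFrame(vals, index=ids, columns=ids)
        g = sparsify_topk(s, k=10**6).graph
        assert g.number_of_edges() == 15

    def test_zero_similarities_never_stored(self):
        ids = list("abc")
        s = pd.DataFrame(0.0, index=ids, columns=ids)
        s.loc["a", "b"] = s.loc["b", "a"] = 0.7
        g = sparsify_topk(s, k=3).graph
        assert set(map(frozenset, g.edges)) == {frozenset({"a", "b"})}


class TestMCL:
    @staticmethod
    def graph_from_blocks(rng, blocks, within=0.8, between=0.0, jitter=0.05):
        g = nx.Graph()
        ids = [f"b{b}n{k}" for b, size in enumerate(blocks) for k in range(size)]
        g.add_nodes_from(ids)
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                same = u.split("n")[0] == v.split("n")[0]
                w = within + rng.normal(0, jitter) if same else between
                if w > 0:
                    g.add_edge(u, v, weight=float(np.clip(w, 0.01, 1.0)))
        return SimilarityGraph(graph=g, k=len(ids))

    def test_two_disconnected_cliques(self, rng):
        for inflation in (1.2, 2.0, 4.0):
            g = self.graph_from_blocks(rng, [5, 6])
            res = mcl_cluster(g, inflation=inflation)
            assert len(res.sizes) == 2
            assert sorted(res.sizes.values()) == [5, 6]

    def test_planted_three_blocks_with_weak_bridges(self, rng):
        g = self.graph_from_blocks(rng, [6, 6, 6], between=0.05)
        res = mcl_cluster(g, inflation=2.0)
        assert len(res.sizes) == 3
        for cid in res.sizes:
            members = res.members(cid)
            assert len({m.split("n")[0] for m in members}) == 1

    def test_small_cluster_flagged_singleton(self, rng):
        g = self.graph_from_blocks(rng, [4, 7])
        res = mcl_cluster(g)
        flags = {res.sizes[c]: res.singleton[c] for c in res.sizes}
        assert flags[4] is True
        assert flags[7] is False

    def test_disjoint_union_equals_per_component(self, rng):
        g1 = self.graph_from_blocks(rng, [5])
        g2 = self.graph_from_blocks(rng, [6])
        # relabel to keep ids distinct
        h2 = nx.relabel_nodes(g2.graph, {n: "x" + n for n in g2.graph.nodes})
        union = nx.union(g1.graph, h2)
        res_union = mcl_cluster(union)
        res1 = mcl_cluster(g1.graph)
        res2 = mcl_cluster(h2)
        parts_union = {frozenset(res_union.members(c)) for c in res_union.sizes}
        parts_sep = {frozenset(res1.members(c)) for c in res1.sizes} | {
            frozenset(res2.members(c)) for c in res2.sizes
        }
        assert parts_union == parts_sep

    def test_medoid_member_of_cluster(self, rng):
        g = self.graph_from_blocks(rng, [5, 5])
        res = mcl_cluster(g)
        for cid, medoid in res.medoids.items():
            assert res.assignment[medoid] == cid


class TestMedoid:
    def test_singleton(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        assert find_medoid(["a"], d) == "a"

    def test_central_point(self):
        ids = list("abc")
        d = pd.DataFrame(
            [[0.0, 0.3, 0.3], [0.3, 0.0, 0.6], [0.3, 0.6, 0.0]],
            index=ids, columns=ids,
        )
        assert find_medoid(ids, d) == "a"

    def test_definitional_minimum(self, rng):
        ids = [f"n{k}" for k in range(8)]
        vals = rng.uniform(0.1, 1.0, size=(8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        d = pd.DataFrame(vals, index=ids, columns=ids)
        med = find_medoid(ids, d)
        med_sum = d.loc[med, ids].sum()
        for other in ids:
            assert med_sum <= d.loc[other, ids].sum() + 1e-12

    def test_tie_breaks_lexicographic(self):
        ids = list("ba")
        d = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=ids, columns=ids)
        assert find_medoid(ids, d) == "a"


def test_export_mcl_abc(tmp_path, rng):
    ids = list("abc")
    s = pd.DataFrame(
        [[0.0, 0.5, 0.0], [0.5, 0.0, 0.25], [0.0, 0.25, 0.0]],
        index=ids, columns=ids,
    )
    out = tmp_path / "edges.abc"
    export_mcl_abc(s, out)
    lines = out.read_text().strip().split("\n")
    assert lines == ["a\tb\t0.5", "b\tc\t0.25"]
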