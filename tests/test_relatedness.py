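import itertools

import numpy as np
import pytest

import skbio

from popdiff import (
    MISSING,
    distance_distribution,
    distance_matrix,
    loiselle_kinship,
    neighbor_joining,
)
from popdiff.relatedness import DistanceMatrix

from conftest import make_panel


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_identical_samples_zero(self):
        dosage = np.array([[0, 1, 2, 1], [0, 1, 2, 1]], dtype=np.int8)
        for method in ("rogers", "allele_sharing"):
            d = distance_matrix(make_panel(dosage), method)
            assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        dosage = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        assert distance_matrix(make_panel(dosage), "rogers").values[0, 1] == 1.0

    def test_single_locus_hom_vs_het(self):
        # AA vs Aa: sqrt(0.5 * (0.25 + 0.25)) = 0.5 per the frequency-vector rule
        dosage = np.array([[0], [1]], dtype=np.int8)
        assert distance_matrix(make_panel(dosage), "rogers").values[0, 1] == 0.5

    def test_symmetry_bounds_and_triangle_inequality(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(-1, 3, size=(10, 40)).astype(np.int8)
        D = distance_matrix(make_panel(dosage), "rogers").values
        np.testing.assert_allclose(D, D.T)
        assert np.nanmax(D) <= 1.0 and np.nanmin(D) >= 0.0
        assert np.allclose(np.diag(D), 0.0)
        for i, j, k in itertools.combinations(range(10), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_pairwise_complete_deletion(self):
        dosage = np.array([[0, MISSING, 2], [2, 1, MISSING]], dtype=np.int8)
        # only locus 0 shared -> distance |0-2|/2 / 1 locus = 1
        assert distance_matrix(make_panel(dosage)).values[0, 1] == 1.0

    def test_zero_shared_loci_strict_raises(self):
        dosage = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="zero shared"):
            distance_matrix(make_panel(dosage), strict=True)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def naive_loiselle(dosage):
    """Independent per-pair, per-locus transcription of the kinship estimator."""
    dosage = np.asarray(dosage, dtype=float)
    n, L = dosage.shape
    called = dosage != MISSING
    p = np.array([
        dosage[called[:, l], l].sum() / (2 * called[:, l].sum()) if called[:, l].any() else np.nan
        for l in range(L)
    ])
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for l in range(L):
                if not (called[i, l] and called[j, l]):
                    continue
                pl = p[l]
                if not np.isfinite(pl) or pl * (1 - pl) == 0:
                    continue
                nl = 2 * called[:, l].sum()
                for pa in (pl, 1 - pl):  # both alleles
                    xi = dosage[i, l] / 2 if pa == pl else 1 - dosage[i, l] / 2
                    xj = dosage[j, l] / 2 if pa == pl else 1 - dosage[j, l] / 2
                    num += (xi - pa) * (xj - pa) + pa * (1 - pa) / (nl - 1)
                    den += pa * (1 - pa)
            K[i, j] = max(num / den, 0.0) if den > 0 else np.nan
    return K


class TestLoiselleKinship:
    def test_matches_naive_transcription(self):
        rng = np.random.default_rng(8)
        dosage = rng.integers(-1, 3, size=(8, 25)).astype(np.int8)
        K = loiselle_kinship(make_panel(dosage)).values
        np.testing.assert_allclose(K, naive_loiselle(dosage), atol=1e-12)

    def test_symmetric_and_truncated(self):
        rng = np.random.default_rng(9)
        dosage = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        K = loiselle_kinship(make_panel(dosage)).values
        np.testing.assert_allclose(K, K.T)
        assert (K >= 0).all()

    def test_negative_pairs_reported_zero(self):
        # two maximally dissimilar homozygotes give a negative raw estimate
        dosage = np.array([[0, 0, 2, 2], [2, 2, 0, 0], [1, 1, 1, 1]], dtype=np.int8)
        K = loiselle_kinship(make_panel(dosage)).values
        assert K[0, 1] == 0.0

    def test_within_exceeds_between_on_structured_panel(self, sim_panel):
        panel, truth, _ = sim_panel
        K = loiselle_kinship(panel).values
        labels = np.array([panel.population[s] for s in panel.samples])
        iu, ju = np.triu_indices(len(labels), k=1)
        within = K[iu, ju][labels[iu] == labels[ju]].mean()
        between = K[iu, ju][labels[iu] != labels[ju]].mean()
        assert within > between

    def test_monomorphic_panel_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            loiselle_kinship(make_panel(np.zeros((4, 5))))


# ---------------------------------------------------------------------------
# neighbor joining, with a topology-enumeration oracle
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves, rng):
    """Random unrooted binary topology with positive branch lengths; returns
    (leaf names, distance matrix, set of non-trivial bipartitions)."""
    import networkx as nx

    leaves = [f"t{i}" for i in range(n_leaves)]
    G = nx.Graph()
    G.add_edge(leaves[0], leaves[1], length=rng.uniform(0.5, 2.0))
    node_id = 0
    for leaf in leaves[2:]:
        u, v = list(G.edges())[rng.integers(0, G.number_of_edges())]
        length = G[u][v]["length"]
        mid = f"internal{node_id}"
        node_id += 1
        G.remove_edge(u, v)
        f = rng.uniform(0.2, 0.8)
        G.add_edge(u, mid, length=length * f)
        G.add_edge(mid, v, length=length * (1 - f))
        G.add_edge(mid, leaf, length=rng.uniform(0.5, 2.0))
    D = np.zeros((n_leaves, n_leaves))
    paths = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            D[i, j] = paths[a][b]
    D = (D + D.T) / 2.0  # exact symmetry despite float path sums
    np.fill_diagonal(D, 0.0)
    return leaves, D, tree_bipartitions(G, leaves)


def tree_bipartitions(G, leaves):
    import networkx as nx

    splits = set()
    for u, v in list(G.edges()):
        H = G.copy()
        H.remove_edge(u, v)
        side = {l for l in leaves if nx.has_path(H, u, l)}
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset([frozenset(side), frozenset(set(leaves) - side)]))
    return splits


def enumerate_topologies(leaves):
    """All unrooted binary topologies by stepwise leaf insertion, as edge lists."""
    first = [("x0", leaves[0]), ("x0", leaves[1]), ("x0", leaves[2])]
    tops = [first]
    for k, leaf in enumerate(leaves[3:], start=1):
        new = []
        for edges in tops:
            for e_idx in range(len(edges)):
                u, v = edges[e_idx]
                mid = f"x{k}"
                out = [e for i, e in enumerate(edges) if i != e_idx]
                out += [(u, mid), (mid, v), (mid, leaf)]
                new.append(out)
        tops = new
    return tops


def ls_fit_sse(edges, leaves, D):
    """Least-squares branch lengths for a fixed topology; returns SSE."""
    import networkx as nx

    G = nx.Graph(edges)
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    edge_list = list(G.edges())
    A = np.zeros((len(pairs), len(edge_list)))
    y = np.array([D[i, j] for i, j in pairs])
    index = {frozenset(e): k for k, e in enumerate(edge_list)}
    for r, (i, j) in enumerate(pairs):
        path = nx.shortest_path(G, leaves[i], leaves[j])
        for u, v in zip(path[:-1], path[1:]):
            A[r, index[frozenset((u, v))]] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


def newick_bipartitions(newick, leaves):
    import io

    tree = skbio.TreeNode.read(io.StringIO(newick))
    splits = set()
    all_leaves = set(leaves)
    for node in tree.non_tips():
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset([frozenset(side), frozenset(all_leaves - side)]))
    return splits


class TestNeighborJoining:
    def test_three_taxa_three_point_branch_lengths(self):
        import io

        D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]])
        nwk = neighbor_joining(DistanceMatrix(["a", "b", "c"], D, "rogers"))
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point solution: a=1, b=2, c=4
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(4.0)

    def test_additive_four_taxon_split_recovered(self):
        # tree ((a,b),(c,d)) with internal edge 4
        D = np.array(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], dtype=float
        )
        leaves = ["a", "b", "c", "d"]
        nwk = neighbor_joining(DistanceMatrix(leaves, D, "rogers"))
        assert newick_bipartitions(nwk, leaves) == {
            frozenset([frozenset({"a", "b"}), frozenset({"c", "d"})])
        }

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_recovers_generating_topology_vs_enumeration_oracle(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(3):
            leaves, D, true_splits = random_additive_tree(n_leaves, rng)
            # oracle: the least-squares-best topology among all enumerated ones
            best = min(enumerate_topologies(leaves), key=lambda e: ls_fit_sse(e, leaves, D))
            import networkx as nx

            oracle_splits = tree_bipartitions(nx.Graph(best), leaves)
            assert oracle_splits == true_splits  # additive data: exact fit wins
            nwk = neighbor_joining(DistanceMatrix(leaves, D, "rogers"))
            assert newick_bipartitions(nwk, leaves) == true_splits

    def test_population_split_on_simulated_panel(self, sim_panel):
        panel, truth, _ = sim_panel
        nwk = neighbor_joining(distance_matrix(panel))
        import io

        tree = skbio.TreeNode.read(io.StringIO(nwk))
        labels = dict(zip(truth.samples["sample"], truth.samples["population"]))
        n = panel.n_samples
        # bipartition at the longest internal edge among non-trivial splits
        # (both sides >= 10% of samples; cherries of near-duplicate samples
        # can carry long edges without describing population structure)
        candidates = [nd for nd in tree.non_tips()
                      if 0.1 * n <= len(list(nd.tips())) <= 0.9 * n]
        best = max(candidates, key=lambda nd: nd.length or 0.0)
        side = {t.name for t in best.tips()}
        majority = max(set(labels.values()), key=lambda g: sum(labels[s] == g for s in side))
        concordant = sum((s in side) == (labels[s] == majority) for s in labels)
        assert concordant / n >= 0.9

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="not symmetric"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], D, "rogers"))


# ---------------------------------------------------------------------------
# distance distributions
# ---------------------------------------------------------------------------

class TestDistanceDistribution:
    def test_constant_distances(self):
        D = np.full((4, 4), 0.3)
        np.fill_diagonal(D, 0.0)
        dist = DistanceMatrix(["a", "b", "c", "d"], D, "rogers")
        groups = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        table = distance_distribution(dist, groups).set_index("set")
        assert table.loc["within:X", "mean"] == pytest.approx(0.3)
        assert table.loc["between", "mean"] == pytest.approx(0.3)

    def test_bin_counts_sum_to_pairs_and_between_exceeds_within(self, sim_panel):
        panel, _, _ = sim_panel
        dist = distance_matrix(panel)
        table = distance_distribution(dist, panel.population).set_index("set")
        n = panel.n_samples
        bins = [c for c in table.columns if c.startswith("bin_")]
        assert table.loc["all", bins].sum() == n * (n - 1) // 2
        assert table.loc["between", "mean"] > table.loc["within:CN", "mean"]
        assert table.loc["between", "mean"] > table.loc["within:US", "mean"]

    def test_singleton_group_empty_within(self):
        D = np.array([[0, 0.2], [0.2, 0.0]])
        dist = DistanceMatrix(["a", "b"], D, "rogers")
        table = distance_distribution(dist, {"a": "X", "b": "Y"}).set_index("set")
        assert table.loc["within:X", "n_pairs"] == 0
        assert np.isnan(table.loc["within:X", "mean"])
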