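"""Distances, neighbor joining (vs brute-force oracles), grouping and PCA."""

import io
import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_panel
from hevecore.errors import DegenerateTreeWarning, ZeroSharedLociError
from hevecore.popstruct import (
    DistanceMatrix,
    assign_groups,
    ibs_distance,
    neighbor_joining,
    pca,
    read_newick,
    to_newick,
)
from hevecore.syndata import SimulationConfig, simulate_panel

# ---------------------------------------------------------------------------
# oracles


def random_additive_matrix(rng, n):
    """Path distances of a random binary tree with positive branch lengths.

    Built by simulating the tree as an explicit parent-pointer forest, with
    distances computed by pure path summation (no NJ machinery).
    """
    parent = {}
    length = {}
    nodes = list(range(n))
    next_id = n
    while len(nodes) > 2:
        a, b = sorted(rng.choice(len(nodes), size=2, replace=False))
        nb, na = nodes.pop(b), nodes.pop(a)
        for child in (na, nb):
            parent[child] = next_id
            length[child] = float(rng.uniform(0.1, 2.0))
        nodes.append(next_id)
        next_id += 1
    root = next_id
    for child in nodes:
        parent[child] = root
        length[child] = float(rng.uniform(0.1, 2.0))

    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parent:
            out[x] = d
            d += length[x]
            x = parent[x]
        out[x] = d
        return out

    D = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(i)
        for j in range(i + 1, n):
            pj = path_to_root(j)
            common = min(
                (pi[x] + pj[x]) for x in pi.keys() & pj.keys()
            )
            D[i, j] = D[j, i] = common
    return D


def brute_force_ls_topology(D):
    """Best 4-taxon unrooted topology by least-squares branch fitting.

    Enumerates all three topologies AB|CD, AC|BD, AD|BC, solves the
    5-branch least-squares system for each, and returns the split of the
    one with the smallest residual.
    """
    splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    best = None
    for (a, b), (c, d) in splits:
        # design matrix: rows = 6 pairs, cols = [la, lb, lc, ld, internal]
        pairs = list(itertools.combinations(range(4), 2))
        X = np.zeros((6, 5))
        y = np.zeros(6)
        for r, (i, j) in enumerate(pairs):
            X[r, i] = X[r, j] = 1
            same_side = {i, j} in ({a, b}, {c, d})
            X[r, 4] = 0 if same_side else 1
            y[r] = D[i, j]
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((X @ beta - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, frozenset([frozenset((a, b)), frozenset((c, d))]), beta)
    return best[1], best[2]


def tree_split(tree):
    """The non-trivial leaf split of a 4-taxon unrooted tree."""
    names = sorted(t.name for t in tree.tips())
    for node in tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if len(below) == 2:
            other = frozenset(set(names) - below)
            return frozenset([below, other])
    raise AssertionError("no internal split found")


# ---------------------------------------------------------------------------
# IBS distances


class TestIbsDistance:
    def test_identical_rows_zero(self):
        G = np.tile([0, 1, 2, 1, 0], (2, 1)).astype(np.int8)
        dm = ibs_distance(make_panel(G))
        assert dm.values[0, 1] == 0

    def test_opposite_homozygotes_maximal(self):
        G = np.vstack([np.zeros(10), np.full(10, 2)]).astype(np.int8)
        dm = ibs_distance(make_panel(G))
        assert dm.values[0, 1] == 1.0

    def test_three_sample_hand_trace(self):
        G = np.array([[0, 1, 2], [1, 1, 0], [2, 9, 0]], dtype=np.int8)
        dm = ibs_distance(make_panel(G))
        # pair (1,2): per-locus shared fractions (1/2, 1, 0) -> d = 1/2
        assert dm.values[0, 1] == pytest.approx(0.5)
        # pair (1,3): locus 2 missing in S3; fractions (0, -, 0) -> d = 1
        assert dm.values[0, 2] == pytest.approx(1.0)
        # pair (2,3): fractions (1/2, -, 1) -> d = 1/4
        assert dm.values[1, 2] == pytest.approx(0.25)
        assert dm.n_shared[0, 2] == 2

    def test_zero_shared_loci_raises(self):
        G = np.array([[0, 9], [9, 1]], dtype=np.int8)
        with pytest.raises(ZeroSharedLociError):
            ibs_distance(make_panel(G))

    def test_symmetry_and_zero_diagonal(self):
        panel, _ = simulate_panel(
            SimulationConfig(n_samples_per_pop=(10,), n_loci=30, seed=3)
        )
        dm = ibs_distance(panel)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_four_taxon_exact_recovery(self):
        """Additive distances from ((A:1,B:2):1,(C:3,D:4)) are recovered
        exactly, matching the brute-force least-squares topology oracle."""
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(ids, D))
        split, beta = brute_force_ls_topology(D)
        oracle_split = frozenset(
            [frozenset(ids[i] for i in s) for s in [next(iter(split))]]
        )
        assert tree_split(tree) == frozenset(
            [frozenset({"A", "B"}), frozenset({"C", "D"})]
        )
        # oracle agrees on the split
        assert frozenset({0, 1}) in split
        # path distances reproduce the input exactly
        td = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert td[a, b] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    @pytest.mark.parametrize("seed", range(25))
    def test_additive_eight_taxon_matrices_recovered(self, seed):
        """NJ path distances reproduce random additive 8-taxon matrices to
        1e-9 (exactness of NJ on additive inputs)."""
        rng = np.random.default_rng(seed)
        D = random_additive_matrix(rng, 8)
        ids = [f"t{i}" for i in range(8)]
        tree = neighbor_joining(DistanceMatrix(ids, D))
        td = tree.tip_tip_distances()
        for i in range(8):
            for j in range(i + 1, 8):
                assert td[ids[i], ids[j]] == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_reference_nj_topology(self):
        """Same topology as scikit-bio's independent NJ on a random
        non-additive matrix (no ties)."""
        import skbio

        rng = np.random.default_rng(12)
        n = 10
        M = rng.uniform(0.2, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"s{i}" for i in range(n)]
        mine = neighbor_joining(DistanceMatrix(ids, D))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        assert mine.compare_rfd(ref) == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# newick round trips


class TestNewick:
    def test_round_trip_preserves_lengths(self):
        s = "((A:1,B:2):1,C:3);"
        tree = read_newick(s)
        back = read_newick(to_newick(tree))
        assert {t.name: t.length for t in back.tips()} == {
            "A": 1.0,
            "B": 2.0,
            "C": 3.0,
        }

    def test_names_with_spaces_survive(self):
        ids = ["sample one", "sample two", "s3", "s4"]
        D = random_additive_matrix(np.random.default_rng(1), 4)
        tree = neighbor_joining(DistanceMatrix(ids, D))
        back = read_newick(to_newick(tree))
        assert {t.name for t in back.tips()} == set(ids)

    def test_external_parser_reads_nj_output(self):
        """dendropy parses the exported Newick and sees the same leaf set."""
        import dendropy

        rng = np.random.default_rng(5)
        D = random_additive_matrix(rng, 8)
        ids = [f"t{i}" for i in range(8)]
        newick = to_newick(neighbor_joining(DistanceMatrix(ids, D)))
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in dtree.leaf_node_iter()} == set(ids)

    def test_negative_lengths_clamped_at_export(self):
        # non-additive matrix that produces a negative NJ branch
        D = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0.05]], dtype=float
        )
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = neighbor_joining(DistanceMatrix(list("abcd"), D))
        back = read_newick(to_newick(tree))
        assert all(
            (t.length or 0) >= 0 for t in back.traverse() if t.length is not None
        )


# ---------------------------------------------------------------------------
# group assignment


class TestAssignGroups:
    def test_two_population_recovery(self):
        """Median ARI >= 0.9 over 20 seeds at fst 0.15 for the k=2 cut."""
        aris = []
        for seed in range(20):
            panel, truth = simulate_panel(
                SimulationConfig(fst=0.15, seed=seed)
            )
            tree = neighbor_joining(ibs_distance(panel))
            labels_map = assign_groups(tree, k=2)
            labels = np.array([labels_map[s] for s in panel.sample_ids])
            aris.append(adjusted_rand_score(truth.pop_labels, labels))
        assert np.median(aris) >= 0.9

    def test_k_equals_n_singletons(self):
        D = random_additive_matrix(np.random.default_rng(2), 5)
        ids = [f"x{i}" for i in range(5)]
        tree = neighbor_joining(DistanceMatrix(ids, D))
        labels = assign_groups(tree, k=5)
        assert sorted(labels.values()) == list(range(5))

    def test_clonal_panel_degenerate_warning(self):
        G = np.tile([0, 1, 2], (4, 1)).astype(np.int8)
        tree = neighbor_joining(ibs_distance(make_panel(G)))
        with pytest.warns(DegenerateTreeWarning):
            labels = assign_groups(tree, k=2)
        assert set(labels.values()) == {0}


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_pc1_separates_diverged_pops(self):
        panel, truth = simulate_panel(
            SimulationConfig(
                n_samples_per_pop=(40, 40), n_loci=120, fst=0.4,
                missing_rate=0.0, seed=1,
            )
        )
        res = pca(panel, n_components=2)
        side = res.coordinates[:, 0] > 0
        ari = adjusted_rand_score(truth.pop_labels, side.astype(int))
        assert ari == 1.0

    def test_duplicate_samples_identical_coordinates(self):
        panel, _ = simulate_panel(
            SimulationConfig(n_samples_per_pop=(10,), n_loci=40,
                             missing_rate=0.0, seed=2)
        )
        G = np.vstack([panel.G, panel.G[:1]])
        dup = make_panel(G)
        res = pca(dup, n_components=3)
        np.testing.assert_allclose(
            res.coordinates[0], res.coordinates[-1], atol=1e-8
        )

    def test_explained_percentages_invariants(self):
        panel, _ = simulate_panel(
            SimulationConfig(n_samples_per_pop=(15, 5), n_loci=50, seed=3)
        )
        res = pca(panel, n_components=10)
        pct = res.explained_pct
        assert np.all(pct >= 0)
        assert np.all(np.diff(pct) <= 1e-9)
        assert pct.sum() <= 100 + 1e-6

    def test_sample_reordering_invariance_up_to_sign(self):
        panel, _ = simulate_panel(
            SimulationConfig(n_samples_per_pop=(12,), n_loci=40,
                             missing_rate=0.0, seed=4)
        )
        res1 = pca(panel, n_components=2)
        perm = np.random.default_rng(0).permutation(panel.n_samples)
        shuffled = panel.take_samples(perm)
        res2 = pca(shuffled, n_components=2)
        for c in range(2):
            a = res1.coordinates[perm, c]
            b = res2.coordinates[:, c]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_monomorphic_only_panel_rejected(self):
        with pytest.raises(ValueError):
            pca(make_panel(np.zeros((4, 5))))
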