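import math

import numpy as np
import pytest

from cogevo import (CogAlignment, complete_deletion, empirical_frequencies,
                    ml_pairwise_distance, nj_tree, nni_search,
                    tree_log_likelihood)
from cogevo.phylo import EmptyAlignmentError, _Pruner, infer_tree
from cogevo.simulate import SimulationTruth, simulate_cog
from cogevo.tree import PhyloTree
from conftest import random_binary_tree, tree_distance_matrix


def aln(seqs: dict[str, str], cog_id: str = "COG") -> CogAlignment:
    return CogAlignment(cog_id, list(seqs), list(seqs.values()))


class TestCompleteDeletion:
    def test_identity_without_gaps(self):
        a = aln({"s1": "ACDEF", "s2": "ACDEW"})
        out = complete_deletion(a)
        assert out.seqs == a.seqs and out.ids == a.ids

    def test_exact_columns_removed(self):
        a = aln({"s1": "A-CD?", "s2": "ACCDE", "s3": "AGCDH"})
        out = complete_deletion(a)
        assert out.seqs == ["ACD", "ACD", "ACD"]  # columns 1,3,4 survive

    def test_matches_column_scan_oracle(self, rng):
        cols = 80
        rows = {}
        for i in range(5):
            s = rng.choice(list("ACDE-?"), size=cols, p=[.3, .3, .2, .1, .05,
                                                         .05])
            rows[f"s{i}"] = "".join(s)
        out = complete_deletion(aln(rows))
        keep = [c for c in range(cols)
                if all(rows[k][c] not in "-?" for k in rows)]
        for k, filtered in zip(rows, out.seqs):
            assert filtered == "".join(rows[k][c] for c in keep)

    def test_idempotent(self, rng):
        a = aln({"s1": "A-CDE", "s2": "AAC-E", "s3": "AACWE"})
        once = complete_deletion(a)
        twice = complete_deletion(once)
        assert once.seqs == twice.seqs

    def test_all_columns_gapped_raises_with_cog_name(self):
        a = aln({"s1": "-A", "s2": "A-"}, cog_id="COG0042")
        with pytest.raises(EmptyAlignmentError, match="COG0042"):
            complete_deletion(a)


class TestEmpiricalFrequencies:
    def test_single_residue_dominates(self):
        pi = empirical_frequencies(aln({"s1": "AAAA"}))
        assert pi[0] > 0.999
        assert pi.min() > 0  # floored, never exactly zero

    def test_sums_to_one(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"),
                                            size=30)) for i in range(4)}
        assert abs(empirical_frequencies(aln(seqs)).sum() - 1.0) < 1e-12

    def test_uniform_alignment_within_3_se(self, rng):
        n = 20_000
        seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=n))
        pi = empirical_frequencies(aln({"s1": seq}))
        se = math.sqrt(0.05 * 0.95 / n)
        assert np.abs(pi - 0.05).max() < 3 * se


class TestMlPairwiseDistance:
    def test_identical_sequences_give_zero(self, wag_model):
        assert ml_pairwise_distance("ACDEF", "ACDEF", wag_model) == 0.0

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5])
    def test_matches_20_state_jukes_cantor_closed_form(self, poisson, p):
        """Equal-rate uniform model: d = -(19/20) ln(1 - 20p/19)."""
        n = 400
        k = int(p * n)
        s1 = "A" * n
        s2 = "R" * k + "A" * (n - k)
        expected = -(19 / 20) * math.log(1 - 20 * p / 19)
        assert ml_pairwise_distance(s1, s2, poisson) == pytest.approx(
            expected, abs=1e-4)

    def test_matches_dense_grid_search(self, wag_model, rng):
        letters = list("ARNDCQEGHILKMFPSTWYV")
        s1 = "".join(rng.choice(letters, size=200))
        s2 = "".join(c if rng.random() > 0.3 else rng.choice(letters)
                     for c in s1)
        d = ml_pairwise_distance(s1, s2, wag_model)
        grid = np.arange(1e-4, 3.0, 1e-4)
        from cogevo.phylo import _encode_one, _pair_counts
        counts = _pair_counts(_encode_one(s1), _encode_one(s2))
        log_pi = np.log(wag_model.frequencies)
        lls = [np.sum(counts * (log_pi[:, None]
                                + np.log(wag_model.transition_matrix(t))))
               for t in grid]
        assert abs(d - grid[int(np.argmax(lls))]) < 1e-3

    def test_saturation_flag(self, poisson):
        s1 = "A" * 100
        s2 = "R" * 95 + "A" * 5  # p beyond the 19/20 singularity
        d, saturated = ml_pairwise_distance(s1, s2, poisson, full=True)
        assert saturated

    def test_no_comparable_sites_rejected(self, wag_model):
        with pytest.raises(ValueError):
            ml_pairwise_distance("-?", "A-", wag_model)


class TestNeighborJoining:
    def test_three_leaves_star_from_three_point_formulas(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        t = nj_tree(d, ["A", "B", "C"])
        pend = t.pendant_lengths()
        assert pend["A"] == pytest.approx(1.0)
        assert pend["B"] == pytest.approx(2.0)
        assert pend["C"] == pytest.approx(3.0)

    def test_recovers_known_additive_quartet(self):
        """Distances of ((A:1,B:2):1,(C:3,D:4)) give split AB|CD exactly."""
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        t = nj_tree(d, labels)
        assert t.topology_id() == frozenset({frozenset({"A", "B"})})
        pend = t.pendant_lengths()
        assert pend["A"] == pytest.approx(1.0)
        assert pend["B"] == pytest.approx(2.0)
        assert pend["C"] == pytest.approx(3.0)
        assert pend["D"] == pytest.approx(4.0)
        (u, v) = t.internal_edges()[0]
        assert t.adj[u][v] == pytest.approx(1.0)

    def test_recovers_topology_from_random_additive_matrices(self, rng):
        for _ in range(25):
            truth = random_binary_tree([f"L{i}" for i in range(8)], rng)
            names, d = tree_distance_matrix(truth)
            recovered = nj_tree(d, names)
            assert recovered.topology_id() == truth.topology_id()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])
        bad = np.zeros((3, 3))
        bad[0, 1] = bad[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(bad, ["A", "B", "C"])


def brute_force_quartet_likelihood(tree, alignment, model):
    """Exhaustive sum over both internal-node states of a 4-leaf tree."""
    (u, v) = tree.internal_edges()[0]
    leaves_u = [w for w in tree.adj[u] if w != v]
    leaves_v = [w for w in tree.adj[v] if w != u]
    enc = alignment.encoded()
    row = {alignment.ids[i]: enc[i] for i in range(len(alignment.ids))}
    pi = model.frequencies
    p_uv = model.transition_matrix(tree.adj[u][v])
    p_leaf = {w: model.transition_matrix(tree.adj[u][w]) for w in leaves_u}
    p_leaf |= {w: model.transition_matrix(tree.adj[v][w]) for w in leaves_v}
    total = 0.0
    for site in range(alignment.n_sites):
        site_l = 0.0
        for su in range(20):
            for sv in range(20):
                term = pi[su] * p_uv[su, sv]
                for w in leaves_u:
                    term *= p_leaf[w][su, row[tree.label[w]][site]]
                for w in leaves_v:
                    term *= p_leaf[w][sv, row[tree.label[w]][site]]
                site_l += term
        total += math.log(site_l)
    return total


class TestTreeLogLikelihood:
    def test_invariant_column_zero_lengths_gives_log_pi(self, wag_model):
        t = PhyloTree()
        center = t.add_node()
        for name in ("a", "b", "c"):
            t.add_edge(center, t.add_node(name), 0.0)
        a = aln({"a": "R", "b": "R", "c": "R"})
        expected = math.log(wag_model.frequencies[1])  # pi_R
        assert tree_log_likelihood(t, a, wag_model) == pytest.approx(expected)

    def test_matches_exhaustive_state_summation(self, wag_model, rng):
        for _ in range(10):
            tree = random_binary_tree(["a", "b", "c", "d"], rng,
                                      0.05, 0.8)
            seqs = {n: "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"),
                                          size=10)) for n in "abcd"}
            a = aln(seqs)
            fast = tree_log_likelihood(tree, a, wag_model)
            slow = brute_force_quartet_likelihood(tree, a, wag_model)
            assert fast == pytest.approx(slow, rel=1e-8)

    def test_root_placement_invariance(self, wag_model, rng):
        tree = random_binary_tree([f"L{i}" for i in range(6)], rng)
        seqs = {f"L{i}": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"),
                                            size=20)) for i in range(6)}
        pruner = _Pruner(tree, aln(seqs), wag_model)
        values = [pruner.edge_log_likelihood(u, v) for u, v, _ in tree.edges()]
        assert max(values) - min(values) < 1e-9

    def test_label_mismatch_rejected(self, wag_model, rng):
        tree = random_binary_tree(["a", "b", "c", "d"], rng)
        with pytest.raises(ValueError, match="differ"):
            tree_log_likelihood(tree, aln({"a": "A", "b": "A", "x": "A",
                                           "d": "A"}), wag_model)


class TestNniSearch:
    def test_zero_rounds_returns_start_unchanged(self, wag_model, rng):
        tree = random_binary_tree(["a", "b", "c", "d"], rng)
        a = aln({n: "ACDEF" for n in "abcd"})
        out = nni_search(tree, a, wag_model, max_rounds=0)
        assert out.topology_id() == tree.topology_id()
        assert out.to_newick() == tree.to_newick()

    def test_never_decreases_likelihood(self, small_taxa, wag_model):
        truth = SimulationTruth("C1", "C1_A1", "B", seed=3)
        alignment, true_tree = simulate_cog(small_taxa, truth, n_sites=150,
                                            model=wag_model, seed=3)
        start_ll = tree_log_likelihood(true_tree, alignment, wag_model)
        refined = nni_search(true_tree, alignment, wag_model, max_rounds=1)
        assert tree_log_likelihood(refined, alignment, wag_model) \
            >= start_ll - 1e-6

    def test_restores_single_misjoined_quartet(self, wag_model, rng):
        """A deliberate wrong join at 1000 sites is corrected by one sweep."""
        restored = 0
        for rep in range(5):
            truth = random_binary_tree([f"L{i}" for i in range(6)],
                                       np.random.default_rng(100 + rep),
                                       0.1, 0.3)
            a, _ = _evolve_on_tree(truth, wag_model,
                                   np.random.default_rng(200 + rep), 1000)
            broken = _swap_two_leaves(truth, "L0", "L1")
            if broken.topology_id() == truth.topology_id():
                restored += 1
                continue
            out = nni_search(broken, a, wag_model, max_rounds=3)
            restored += out.topology_id() == truth.topology_id()
        assert restored >= 4


def _evolve_on_tree(tree, model, rng, n_sites):
    from cogevo.simulate import evolve_states
    from cogevo.wag_data import AMINO_ACIDS
    root = next(n for n in tree.adj if not tree.is_leaf(n))
    states = {root: rng.choice(20, size=n_sites, p=model.frequencies)}
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        for child, t in tree.adj[node].items():
            if child != parent:
                states[child] = evolve_states(
                    states[node], model.transition_matrix(t), rng)
                stack.append((child, node))
    chars = np.array(list(AMINO_ACIDS))
    seqs = {tree.label[n]: "".join(chars[states[n]]) for n in tree.leaves}
    return aln(seqs), states


def _swap_two_leaves(tree, name_a, name_b):
    out = tree.copy()
    na, nb = out.node_of(name_a), out.node_of(name_b)
    del out.label[na], out.label[nb]
    out.label[na], out.label[nb] = name_b, name_a
    out._node_of[name_a], out._node_of[name_b] = nb, na
    return out


def test_infer_tree_end_to_end_recovers_simulated_topology(small_taxa,
                                                           wag_model):
    truth = SimulationTruth("C9", "C9_A1", "HA", seed=21)
    alignment, true_tree = simulate_cog(small_taxa, truth, n_sites=500,
                                        model=wag_model, gap_fraction=0.05,
                                        seed=21)
    inferred = infer_tree(alignment, nni_rounds=1)
    shared = inferred.topology_id() & true_tree.topology_id()
    # most splits of a 31-leaf tree should be recovered at 500 sites
    assert len(shared) >= 0.8 * len(true_tree.topology_id())
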