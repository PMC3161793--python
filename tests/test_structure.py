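import itertools

import networkx as nx
import numpy as np
import pytest

from avpercept.density import binning_for, entropy
from avpercept.structure import (
    PDAG, IndependenceDecision, ThresholdPolicy, conditional_mi, elicit,
    factorization, learn_skeleton, make_binnings, mi_threshold,
    normalized_mi, orient, prune_by_cmi)

BIN_S = binning_for("S")
BIN_M = binning_for("M")


def data_from_pmf(pmf, levels):
    """Expand an exact joint pmf into data whose plug-in estimate is the pmf."""
    pmf = np.asarray(pmf)
    counts = np.round(pmf * 1000).astype(int)
    cols = [[] for _ in range(pmf.ndim)]
    for idx in np.ndindex(pmf.shape):
        for axis, i in enumerate(idx):
            cols[axis].extend([levels[axis][i]] * counts[idx])
    return [np.asarray(c, dtype=float) for c in cols]


def brute_force_nmi(pmf):
    pmf = np.asarray(pmf)
    px, py = pmf.sum(axis=1), pmf.sum(axis=0)
    mi = sum(pmf[i, j] * np.log2(pmf[i, j] / (px[i] * py[j]))
             for i, j in np.ndindex(pmf.shape) if pmf[i, j] > 0)
    return mi / entropy(pmf)


class TestNormalizedMI:
    def test_identical_binary_variable_scores_one(self):
        x = np.array([0.0, 1.0] * 50)
        assert normalized_mi(x, x, BIN_S, BIN_S) == pytest.approx(1.0)

    def test_independent_uniform_scores_zero(self):
        x, y = data_from_pmf([[0.25, 0.25], [0.25, 0.25]],
                             [(0, 1), (0, 1)])
        assert normalized_mi(x, y, BIN_S, BIN_M) == pytest.approx(0.0, abs=1e-12)

    def test_correlated_binary_example(self):
        pmf = [[0.4, 0.1], [0.1, 0.4]]
        x, y = data_from_pmf(pmf, [(0, 1), (0, 1)])
        # independent oracle: direct double sum over the 4 cells
        assert brute_force_nmi(pmf) == pytest.approx(0.1614, abs=5e-4)
        assert normalized_mi(x, y, BIN_S, BIN_M) == pytest.approx(
            brute_force_nmi(pmf), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_pmfs(self, seed):
        rng = np.random.default_rng(seed)
        pmf = rng.dirichlet(np.ones(4)).reshape(2, 2)
        pmf = np.round(pmf * 1000) / 1000
        pmf[0, 0] += 1 - pmf.sum()  # exact renormalization on the grid
        x, y = data_from_pmf(pmf, [(0, 1), (0, 1)])
        assert normalized_mi(x, y, BIN_S, BIN_M) == pytest.approx(
            brute_force_nmi(pmf), abs=1e-10)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 400).astype(float)
        y = rng.integers(0, 2, 400).astype(float)
        a = normalized_mi(x, y, BIN_S, BIN_S)
        b = normalized_mi(y, x, BIN_S, BIN_S)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            normalized_mi([0.0], [0.0, 1.0], BIN_S, BIN_S)


class TestConditionalMI:
    def test_entropy_identity(self):
        # I(X;Y|Z) = H(X|Z) + H(Y|Z) - H(X,Y|Z), checked numerically
        rng = np.random.default_rng(0)
        z = rng.integers(0, 2, 600).astype(float)
        x = (z + rng.integers(0, 2, 600)) % 2.0
        y = rng.integers(0, 2, 600).astype(float)
        from avpercept.density import joint_histogram
        p = joint_histogram([x, y, z], [BIN_S, BIN_S, BIN_S]).probs
        h_z = entropy(p.sum(axis=(0, 1)))
        h_xz = entropy(p.sum(axis=1))
        h_yz = entropy(p.sum(axis=0))
        h_xyz = entropy(p)
        expected = ((h_xz - h_z) + (h_yz - h_z) - (h_xyz - h_z)) / (h_xyz - h_z)
        got = conditional_mi(x, y, z, BIN_S, BIN_S, BIN_S)
        assert got == pytest.approx(max(expected, 0.0), abs=1e-10)

    def test_functional_chain_yields_zero(self):
        z = np.array([0.0, 1.0] * 100)
        assert conditional_mi(z, z, z, BIN_S, BIN_S, BIN_S) == pytest.approx(0.0)

    def test_common_cause_explained_away(self):
        # Z -> X, Z -> Y with strong links: marginal MI large, CMI ~ 0
        pmf = np.zeros((2, 2, 2))
        for z in (0, 1):
            for x in (0, 1):
                for y in (0, 1):
                    px = 0.9 if x == z else 0.1
                    py = 0.9 if y == z else 0.1
                    pmf[x, y, z] = 0.5 * px * py
        x, y, z = data_from_pmf(pmf, [(0, 1)] * 3)
        marginal = normalized_mi(x, y, BIN_S, BIN_S)
        conditional = conditional_mi(x, y, z, BIN_S, BIN_S, BIN_S)
        assert marginal > 0.1
        assert conditional == pytest.approx(0.0, abs=1e-10)


class TestThresholds:
    def test_seed_determinism(self):
        a = mi_threshold(BIN_S, BIN_M, 1000, rng=np.random.default_rng(5))
        b = mi_threshold(BIN_S, BIN_M, 1000, rng=np.random.default_rng(5))
        assert a == b

    def test_threshold_magnitude_tracks_plugin_bias(self):
        # 2x2 binning at the study's per-task sample size: the null MI is
        # dominated by the (|X|-1)(|Y|-1)/(2 n ln 2) plug-in bias
        thr = mi_threshold(BIN_S, BIN_M, 4500, reps=100, quantile=0.95,
                           rng=np.random.default_rng(0))
        assert thr < 0.01
        # mean null MI ~ bias, normalized by H ~ 2 bits; the 0.95 quantile
        # sits a small multiple above it
        expected_scale = 1.0 / (2 * 4500 * np.log(2)) / 2.0
        assert expected_scale / 2 < thr < 8 * expected_scale

    def test_threshold_vanishes_with_sample_size(self):
        small = mi_threshold(BIN_S, BIN_M, 100, reps=50,
                             rng=np.random.default_rng(1))
        large = mi_threshold(BIN_S, BIN_M, 1_000_000, reps=50,
                             rng=np.random.default_rng(1))
        assert large < small and large < 1e-5

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            mi_threshold(BIN_S, BIN_M, 100, quantile=1.5)


class TestSkeleton:
    def test_pure_noise_gives_empty_graph(self, default_table):
        rng = np.random.default_rng(21)
        noise = default_table.copy()
        n = len(noise)
        noise["task"] = rng.integers(0, 2, n).astype(float)
        noise["mode"] = rng.integers(0, 2, n).astype(float)
        noise["xp"] = rng.choice([-10, -5, 0, 5, 10], n).astype(float)
        noise["xs"] = rng.choice(
            [-20, -15, -10, -5, 0, 5, 10, 15, 20, np.nan], n)
        noise["response_norm"] = rng.uniform(-35, 35, n)
        noise["decision_time"] = rng.uniform(0.2, 2.0, n)
        skeleton, _ = learn_skeleton(noise, ThresholdPolicy(seed=0))
        # 15 pairs tested at the 0.95 null quantile: allow the ~5% per-pair
        # false-positive rate the threshold construction implies
        assert skeleton.number_of_edges() <= 2

    def test_default_dataset_core_edges(self, default_table):
        skeleton, _ = learn_skeleton(default_table, ThresholdPolicy(seed=0))
        edges = {frozenset(e) for e in skeleton.edges}
        for pair in [("XHAT", "XP"), ("XHAT", "XS"), ("XHAT", "S"),
                     ("XS", "M"), ("T", "S"), ("T", "M"), ("T", "XS")]:
            assert frozenset(pair) in edges
        for pair in [("XP", "S"), ("XP", "M"), ("XS", "S"), ("S", "M")]:
            assert frozenset(pair) not in edges

    def test_missing_column_raises(self, default_table):
        with pytest.raises(KeyError):
            learn_skeleton(default_table.drop(columns="response_norm"))


class TestPruneAndOrient:
    def test_redundant_mode_edge_removed_with_secondary_separator(
            self, default_table):
        policy = ThresholdPolicy(seed=0)
        binnings = make_binnings(default_table)
        skeleton, _ = learn_skeleton(default_table, policy, binnings)
        pruned, removals, _ = prune_by_cmi(
            skeleton, default_table, policy, binnings)
        removed = {frozenset(r["edge"]): r["separator"] for r in removals}
        assert frozenset(("T", "M")) in removed
        assert removed[frozenset(("T", "M"))] == ("XS",)
        assert pruned.has_edge("T", "XS")  # retained over the redundant T-M

    def test_collider_orientation_rule(self):
        g = nx.Graph([("X", "Z"), ("Y", "Z")])
        ind = [IndependenceDecision("X", "Y", (), 0.0, 0.1, False)]
        pdag = orient(g, ind)
        assert pdag.directed == {("X", "Z"), ("Y", "Z")}
        ind_sep = [IndependenceDecision("X", "Y", ("Z",), 0.0, 0.1, False)]
        pdag2 = orient(g, ind_sep)
        assert pdag2.directed == set()
        assert pdag2.undirected == {frozenset(("X", "Z")),
                                    frozenset(("Y", "Z"))}

    def test_meek_propagation_on_chain(self):
        # collider A -> C <- B plus undirected C - D: rule 1 gives C -> D
        g = nx.Graph([("A", "C"), ("B", "C"), ("C", "D")])
        ind = [IndependenceDecision("A", "B", (), 0.0, 0.1, False),
               IndependenceDecision("A", "D", ("C",), 0.0, 0.1, False),
               IndependenceDecision("B", "D", ("C",), 0.0, 0.1, False)]
        pdag = orient(g, ind)
        assert ("C", "D") in pdag.directed

    def test_exogeneity_constraint_blocks_reverse_arrows(self):
        g = nx.Graph([("X", "Z"), ("Y", "Z")])
        ind = [IndependenceDecision("X", "Y", (), 0.0, 0.1, False)]
        pdag = orient(g, ind, exogenous={"Z"})
        assert pdag.directed == set() and len(pdag.undirected) == 2


class TestFactorization:
    def test_expected_network_reads_off_eq1_factors(self):
        pdag = PDAG(
            nodes=("S", "M", "XP", "XS", "XHAT", "T"),
            directed={("XP", "XHAT"), ("XS", "XHAT"), ("S", "XHAT"),
                      ("S", "T"), ("XS", "T")},
            undirected={frozenset(("M", "XS")), frozenset(("XP", "XS"))})
        factors = dict(factorization(pdag))
        assert factors["S"] == () and factors["M"] == () and factors["XP"] == ()
        assert factors["XS"] == ("M", "XP")
        assert factors["XHAT"] == ("S", "XP", "XS")
        assert factors["T"] == ("S", "XS")

    def test_empty_graph_gives_marginals(self):
        pdag = PDAG(nodes=("S", "M"), directed=set(), undirected=set())
        assert dict(factorization(pdag)) == {"S": (), "M": ()}

    def test_cycle_raises(self):
        pdag = PDAG(nodes=("S", "M", "XP"), directed={("S", "M"), ("M", "XP"),
                                                      ("XP", "S")},
                    undirected=set())
        with pytest.raises(ValueError):
            factorization(pdag)


class TestEndToEnd:
    def test_default_dataset_recovers_reference_network(self, default_table):
        pdag = elicit(default_table, ThresholdPolicy(seed=0))
        assert pdag.directed == {("XP", "XHAT"), ("XS", "XHAT"),
                                 ("S", "XHAT"), ("S", "T"), ("XS", "T")}
        assert pdag.undirected == {frozenset(("M", "XS")),
                                   frozenset(("XP", "XS"))}
        assert pdag.conflicts == []

    def test_export_formats(self, default_table, tmp_path):
        from avpercept.structure import export_dot, export_edge_list
        pdag = elicit(default_table, ThresholdPolicy(seed=0))
        export_edge_list(pdag, tmp_path / "edges.csv")
        export_dot(pdag, tmp_path / "net.dot")
        text = (tmp_path / "edges.csv").read_text()
        assert "XS,XHAT,->" in text or "XS,T,->" in text
        assert "dir=none" in (tmp_path / "net.dot").read_text()
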