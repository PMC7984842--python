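import numpy as np
import pandas as pd
import pytest

from protcov.io import DataError, ProteinMatrix
from protcov.network import (
    CovariationGraph,
    Partition,
    covariation_matrix,
    module_viz_threshold,
    network_enhancement,
    partition_surprise_leiden,
    surprise_quality,
)
from protcov.simulate import simulate_profile_matrix

from conftest import make_design


def clique_graph(blocks, weight=1.0):
    n = sum(blocks)
    W = np.zeros((n, n))
    start = 0
    for b in blocks:
        W[start:start + b, start:start + b] = weight
        start += b
    np.fill_diagonal(W, 0.0)
    nodes = [f"n{i}" for i in range(n)]
    return CovariationGraph(nodes, W, enhanced=True)


def adjusted_rand_index(labels_a, labels_b):
    """Contingency-table ARI, written out from the definition."""
    from math import comb

    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    ct = pd.crosstab(a, b).to_numpy()
    sum_comb = sum(comb(int(x), 2) for x in ct.ravel())
    sum_a = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestCovariation:
    def test_hand_computed_pearson(self):
        design = make_design(n_mixtures=1, fractions=2, spqc=0)
        cols = design.sample_ids  # 4 biological samples
        vals = pd.DataFrame(
            2.0 ** np.array([[1.0, 2, 3, 4], [2.0, 1, 4, 3]]),
            index=["A", "B"], columns=cols,
        )
        g = covariation_matrix(ProteinMatrix(vals, pd.Series(2, index=["A", "B"])), design)
        assert g.weights[0, 1] == pytest.approx(0.6)
        assert np.allclose(np.diag(g.weights), 1.0)

    def test_affine_copy_gives_unit_correlation(self):
        design = make_design(n_mixtures=1, fractions=2, spqc=0)
        rng = np.random.default_rng(0)
        a = rng.normal(18, 1, 4)
        vals = pd.DataFrame(2.0 ** np.vstack([a, 3 * a + 7]),
                            index=["A", "B"], columns=design.sample_ids)
        g = covariation_matrix(ProteinMatrix(vals, pd.Series(2, index=["A", "B"])), design)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_zero_variance_protein_named(self):
        design = make_design(n_mixtures=1, fractions=2, spqc=0)
        vals = pd.DataFrame([[2.0, 2, 2, 2], [1.0, 2, 4, 8]],
                            index=["FLAT", "B"], columns=design.sample_ids)
        with pytest.raises(DataError, match="FLAT"):
            covariation_matrix(ProteinMatrix(vals, pd.Series(2, index=vals.index)), design)

    def test_spqc_excluded_from_correlation(self):
        design = make_design(n_mixtures=1, fractions=2, spqc=2)
        cols = design.sample_ids
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(2.0 ** rng.normal(18, 1, (3, len(cols))),
                            index=list("ABC"), columns=cols)
        # poison SPQC columns: would crash log2 if used
        g = covariation_matrix(ProteinMatrix(vals, pd.Series(2, index=vals.index)), design)
        bio = [c for c in cols if "SPQC" not in c]
        expect = np.corrcoef(np.log2(vals[bio].to_numpy()))
        assert np.allclose(g.weights, (expect + expect.T) / 2, atol=1e-12)


def reference_enhancement(W_in, k, alpha, order):
    """Independent transcription of the diffusion re-weighting, solving the
    closed form as (1-a) P (I - a P^order)^-1 instead of via eigenvalues."""
    W_in = W_in.copy().astype(float)
    np.fill_diagonal(W_in, 0.0)
    n = len(W_in)
    deg_in = np.abs(W_in).sum(axis=1)
    active = deg_in > 0
    idx = np.flatnonzero(active)
    W0 = W_in[np.ix_(idx, idx)]
    DD = np.abs(W0).sum(axis=1)
    m = len(W0)

    def row_norm(w):
        out = np.zeros_like(w)
        for i in range(len(w)):
            s = np.abs(w[i]).sum() + np.finfo(float).eps
            out[i] = w[i] / s
        return out

    W = row_norm(W0)
    W = (W + W.T) / 2.0
    if len(np.unique(W)) > 2:
        P = np.zeros_like(W)
        kk = min(k, m - 1)
        for i in range(m):
            top = np.argsort(np.abs(W[i]), kind="stable")[::-1][:kk]
            P[i, top] = np.abs(W[i, top])
        P = (P + P.T) / 2.0 * np.sign(W)
    else:
        P = W.copy()
    P = P + np.eye(m) + np.diag(np.abs(P).sum(axis=1))
    # transition fields
    zero_rows = P.sum(axis=1) == 0
    T = row_norm(P * m)
    colw = np.sqrt(np.abs(T).sum(axis=0) + np.finfo(float).eps)
    T = T / colw[None, :]
    T = T @ T.T
    T[zero_rows, :] = 0.0
    T[:, zero_rows] = 0.0
    # closed-form diffusion without an eigendecomposition
    T = T - np.finfo(float).eps * np.eye(m)
    Wd = (1 - alpha) * T @ np.linalg.inv(np.eye(m) - alpha * np.linalg.matrix_power(T, order))
    diag = np.diag(Wd).copy()
    np.fill_diagonal(Wd, 0.0)
    Wd = Wd / np.maximum(1.0 - diag, np.finfo(float).eps)[:, None]
    Wd = DD[:, None] * Wd
    Wd[Wd < 0] = 0.0
    Wd = (Wd + Wd.T) / 2.0
    out = np.zeros_like(W_in)
    out[np.ix_(idx, idx)] = Wd
    return out


class TestEnhancement:
    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(3)
        W = rng.random((10, 10))
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        g = CovariationGraph([f"x{i}" for i in range(10)], W)
        out = network_enhancement(g, k_neighbors=4, alpha=0.9, diffusion_order=2)
        ref = reference_enhancement(W, 4, 0.9, 2)
        assert np.allclose(out.weights, ref, atol=1e-6)

    def test_block_structure_preserved(self):
        rng = np.random.default_rng(4)
        W = np.zeros((12, 12))
        for sl in (slice(0, 6), slice(6, 12)):
            B = rng.random((6, 6))
            W[sl, sl] = (B + B.T) / 2.0
        np.fill_diagonal(W, 0.0)
        g = CovariationGraph([f"x{i}" for i in range(12)], W)
        out = network_enhancement(g, k_neighbors=3)
        assert np.abs(out.weights[:6, 6:]).max() == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_nonnegative_output(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        W = rng.normal(0, 1, (n, n))
        W = (W + W.T) / 2.0
        g = CovariationGraph([f"x{i}" for i in range(n)], W)
        out = network_enhancement(g, k_neighbors=5)
        assert np.abs(out.weights - out.weights.T).max() <= 1e-9
        assert out.weights.min() >= 0.0

    def test_within_module_ordering_preserved(self):
        design = make_design()
        mat, truth = simulate_profile_matrix(n_modules=5, proteins_per_module=15,
                                             design=design, seed=5)
        vals = pd.DataFrame(2.0**mat, index=mat.index, columns=mat.columns)
        pm = ProteinMatrix(vals, pd.Series(2, index=vals.index))
        g = covariation_matrix(pm, design)
        out = network_enhancement(g)
        labels = np.array([truth[n] for n in g.nodes])
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        diff = ~same
        np.fill_diagonal(diff, False)
        for W in (np.clip(g.offdiag(), 0, None), out.weights):
            assert W[same].mean() > W[diff].mean()

    def test_asymmetric_input_rejected(self):
        W = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CovariationGraph(["a", "b"], W)


class TestSurprise:
    def test_two_cliques_closed_form(self):
        g = clique_graph([3, 3])
        part = Partition({n: ("A" if i < 3 else "B") for i, n in enumerate(g.nodes)},
                         0, 0, 0, g.nodes)
        assert surprise_quality(g, part) == pytest.approx(6 * np.log(15 / 6), abs=1e-12)

    def test_single_module_partition_is_zero(self):
        g = clique_graph([3, 3])
        part = Partition({n: "A" for n in g.nodes}, 0, 0, 0, g.nodes)
        assert surprise_quality(g, part) == 0.0

    def test_random_partition_below_planted(self):
        rng = np.random.default_rng(6)
        g = clique_graph([5, 5, 5], weight=1.0)
        truth = Partition({n: f"B{i // 5}" for i, n in enumerate(g.nodes)}, 0, 0, 0, g.nodes)
        s_true = surprise_quality(g, truth)
        s_rand = []
        for _ in range(50):
            labels = rng.permutation([f"B{i // 5}" for i in range(15)])
            s_rand.append(surprise_quality(
                g, Partition(dict(zip(g.nodes, labels)), 0, 0, 0, g.nodes)))
        assert max(s_rand) < s_true
        assert np.mean(s_rand) < 0.2 * s_true


class TestLeiden:
    def test_two_disjoint_5cliques_recovered_exactly(self):
        g = clique_graph([5, 5])
        part = partition_surprise_leiden(g, seed=0, n_restarts=5)
        assert part.n_modules == 2
        mods = [part.module_of[n] for n in g.nodes]
        assert len(set(mods[:5])) == 1 and len(set(mods[5:])) == 1
        assert mods[0] != mods[5]

    def test_determinism(self):
        g = clique_graph([4, 4, 4], weight=1.0)
        p1 = partition_surprise_leiden(g, seed=9, n_restarts=3)
        p2 = partition_surprise_leiden(g, seed=9, n_restarts=3)
        assert p1.module_of == p2.module_of and p1.quality == p2.quality

    def test_partition_quality_beats_degenerate_partitions(self):
        design = make_design()
        mat, truth = simulate_profile_matrix(n_modules=6, proteins_per_module=12,
                                             design=design, seed=10)
        pm = ProteinMatrix(2.0**mat, pd.Series(2, index=mat.index))
        g = covariation_matrix(pm, design)
        enh = network_enhancement(g)
        part = partition_surprise_leiden(enh, seed=0, n_restarts=5)
        singleton = Partition({n: n for n in enh.nodes}, 0, 0, 0, enh.nodes)
        one = Partition({n: "A" for n in enh.nodes}, 0, 0, 0, enh.nodes)
        assert part.quality >= surprise_quality(enh, singleton)
        assert part.quality >= surprise_quality(enh, one)

    def test_planted_modules_recovered(self):
        design = make_design()
        mat, truth = simulate_profile_matrix(n_modules=10, proteins_per_module=30,
                                             design=design, seed=11)
        pm = ProteinMatrix(2.0**mat, pd.Series(2, index=mat.index))
        g = covariation_matrix(pm, design)
        enh = network_enhancement(g)
        part = partition_surprise_leiden(enh, seed=1, n_restarts=10)
        ari = adjusted_rand_index([truth[n] for n in enh.nodes],
                                  [part.module_of[n] for n in enh.nodes])
        assert ari >= 0.9

    def test_module_ids_ordered_by_size(self):
        g = clique_graph([6, 3])
        part = partition_surprise_leiden(g, seed=0, n_restarts=3)
        sizes = {m: len(part.members(m)) for m in set(part.module_of.values())}
        assert sizes["M1"] >= sizes["M2"]


def brute_force_max_removal(nodes, edges):
    """Oracle: largest k such that deleting the k lightest edges keeps the
    graph connected (DFS connectivity, no networkx)."""

    def connected(edge_subset):
        adj = {n: [] for n in nodes}
        for u, v, _ in edge_subset:
            adj[u].append(v)
            adj[v].append(u)
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(nodes)

    ordered = sorted(edges, key=lambda e: (e[2], e[0], e[1]))
    best_k = 0
    for k in range(len(ordered) + 1):
        if connected(ordered[k:]):
            best_k = k
        else:
            break
    return best_k, ordered[best_k:]


class TestVizThreshold:
    def _graph(self, W, nodes=None):
        nodes = nodes or [f"n{i}" for i in range(len(W))]
        return (CovariationGraph(nodes, W, enhanced=True),
                Partition({n: "M1" for n in nodes}, 0, 0, 0, nodes))

    def test_spanning_tree_nothing_removable(self):
        W = np.zeros((4, 4))
        for i, j, w in [(0, 1, 0.5), (1, 2, 0.7), (2, 3, 0.9)]:
            W[i, j] = W[j, i] = w
        g, p = self._graph(W)
        thr, kept, _ = module_viz_threshold(g, p, "M1")
        assert len(kept) == 3
        assert thr == pytest.approx(0.5)  # first (lightest) edge is already a bridge

    def test_unit_triangle_one_edge_removed(self):
        W = np.ones((3, 3)) - np.eye(3)
        g, p = self._graph(W)
        thr, kept, deg = module_viz_threshold(g, p, "M1")
        assert len(kept) == 2
        assert thr == pytest.approx(1.0)
        assert np.allclose(deg.to_numpy(), 2.0)

    def test_heavy_chord_retained(self):
        # path n0-n1-n2-n3 with light edges and a heavy chord n0-n3
        W = np.zeros((4, 4))
        for i, j, w in [(0, 1, 0.2), (1, 2, 0.3), (2, 3, 0.4), (0, 3, 0.9)]:
            W[i, j] = W[j, i] = w
        g, p = self._graph(W)
        thr, kept, _ = module_viz_threshold(g, p, "M1")
        pairs = {frozenset((r.source, r.target)) for r in kept.itertuples()}
        assert frozenset(("n0", "n3")) in pairs
        # removing 0.2 keeps the cycle; 0.3's removal would disconnect n1
        assert thr == pytest.approx(0.3)
        assert len(kept) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_oracle_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        W = np.zeros((n, n))
        for i in range(n - 1):  # random spanning path keeps it connected
            W[i, i + 1] = W[i + 1, i] = rng.uniform(0.1, 1.0)
        extra = rng.integers(1, n)
        for _ in range(extra):
            i, j = rng.integers(0, n, 2)
            if i != j and W[i, j] == 0:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0)
        g, p = self._graph(W)
        thr, kept, _ = module_viz_threshold(g, p, "M1")
        nodes = g.nodes
        edges = [(nodes[i], nodes[j], W[i, j]) for i in range(n) for j in range(i + 1, n)
                 if W[i, j] > 0]
        k_star, retained = brute_force_max_removal(nodes, edges)
        assert len(kept) == len(edges) - k_star
        got = {frozenset((r.source, r.target)) for r in kept.itertuples()}
        want = {frozenset((u, v)) for u, v, _ in retained}
        assert got == want

    def test_disconnected_module_warns_and_returns_input(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        g, p = self._graph(W)
        with pytest.warns(UserWarning, match="disconnected"):
            thr, kept, _ = module_viz_threshold(g, p, "M1")
        assert len(kept) == 2
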