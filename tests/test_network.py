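"""Spearman thresholding, NetworkAnalyzer metrics, signaled positive fraction."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phycosignal.network import (
    Edge,
    EdgeSign,
    GenusNode,
    Kingdom,
    SignalingNetwork,
    build_network,
    closeness_centrality,
    information_centrality,
    metrics,
    signaled_positive_fraction,
    spearman,
)
from phycosignal.simulate import (
    SimulationConfig,
    make_abundance_series,
    planted_fraction_config,
)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5, 6]
        assert spearman(x, [10, 20, 30, 40, 50, 60])[0] == pytest.approx(1.0)
        assert spearman(x, [60, 50, 40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1)); d = (-1,1,-1,1,0),
        # sum(d^2) = 4 -> 1 - 24/120 = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(8), rng.random(8)
        assert spearman(x, y) == pytest.approx(spearman(y, x))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(12), rng.random(12)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(5 * x), y**3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_exact_permutation_p_matches_plain_enumeration(self):
        # independent oracle: direct python loop over all 5! orderings
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho_obs, p = spearman(x, y)
        count = total = 0
        for perm in itertools.permutations(y):
            r = stats.pearsonr(
                stats.rankdata(x), stats.rankdata(perm)
            ).statistic
            total += 1
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_large_n_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(20), rng.random(20)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_tie_correction(self):
        x = [1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
        y = [2, 1, 2, 4, 4, 6, 7, 8, 9, 10, 11, 12]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_series_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])


def _flags(**kw) -> dict[str, GenusNode]:
    out = {}
    for name, (kingdom, signaled) in kw.items():
        out[name] = GenusNode(name, kingdom, signaled)
    return out


class TestBuildNetwork:
    def test_planted_pair_yields_positive_edge(self):
        cfg = SimulationConfig(seed=8, n_samples=12)
        profiles, truth = make_abundance_series(cfg)
        net = build_network(profiles, cfg.genus_flags())
        edges = {(e.node_a, e.node_b): e for e in net.edges}
        assert ("Pseudomonas", "Chlorella") in edges
        assert edges[("Pseudomonas", "Chlorella")].sign is EdgeSign.POSITIVE

    def test_negative_loading_yields_negative_edge(self):
        cfg = SimulationConfig(seed=8, n_samples=12)
        profiles, _ = make_abundance_series(cfg)
        net = build_network(profiles, cfg.genus_flags())
        edges = {(e.node_a, e.node_b): e for e in net.edges}
        assert ("Bradyrhizobium", "Chlorella") in edges
        assert edges[("Bradyrhizobium", "Chlorella")].sign is EdgeSign.NEGATIVE

    def test_exact_null_false_edge_probability_is_controlled(self):
        # In the exact-permutation regime (n <= 9) the null distribution of
        # ranks is uniform over permutations, so the per-pair false-edge
        # probability can be computed exactly by enumeration and must respect
        # the nominal p < 0.01 bound.
        n = 8
        x = np.arange(1.0, n + 1)
        perms = np.array(list(itertools.permutations(range(n))), dtype=float) + 1.0
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = pc @ xc / np.sqrt((xc @ xc) * (pc * pc).sum(axis=1))
        abs_sorted = np.sort(np.abs(rhos))
        # exact two-sided p of each permutation's rho from the ECDF
        ranks = np.searchsorted(abs_sorted, np.abs(rhos) - 1e-12, side="left")
        pvals = 1.0 - ranks / len(rhos)
        false_rate = np.mean((np.abs(rhos) > 0.6) & (pvals < 0.01))
        assert false_rate <= 0.01
        # spot-check the ECDF p against the implementation's exact p
        y = x[list((2, 0, 1, 3, 4, 5, 6, 7))]
        assert spearman(x, y)[1] == pytest.approx(
            np.mean(np.abs(rhos) >= abs(spearman(x, y)[0]) - 1e-12)
        )

    def test_independent_noise_rarely_edges(self):
        # At n=12 the t-approximation is mildly anti-conservative; the
        # measured per-pair false-edge rate stays close to the nominal 1%.
        rng = np.random.default_rng(99)
        false_edges = trials = 0
        flags = _flags(B=(Kingdom.BACTERIA, False), P=(Kingdom.PHYTOPLANKTON, False))
        for _ in range(1000):
            profiles = pd.DataFrame(
                rng.random((2, 12)), index=["B", "P"],
                columns=[f"S{i}" for i in range(12)],
            )
            net = build_network(profiles, flags)
            trials += 1
            false_edges += len(net.edges)
        assert false_edges / trials < 0.025

    def test_intra_kingdom_pairs_never_tested(self):
        # two perfectly correlated bacteria: no edge by construction
        x = np.arange(12, dtype=float)
        profiles = pd.DataFrame(
            [x, x, x[::-1]], index=["B1", "B2", "P"],
            columns=[f"S{i}" for i in range(12)],
        )
        flags = _flags(
            B1=(Kingdom.BACTERIA, True), B2=(Kingdom.BACTERIA, False),
            P=(Kingdom.PHYTOPLANKTON, False),
        )
        net = build_network(profiles, flags)
        assert all(
            {net.nodes[e.node_a].kingdom, net.nodes[e.node_b].kingdom}
            == {Kingdom.BACTERIA, Kingdom.PHYTOPLANKTON}
            for e in net.edges
        )
        assert ("B1", "B2") not in {(e.node_a, e.node_b) for e in net.edges}

    def test_fewer_than_four_samples_is_an_error(self):
        profiles = pd.DataFrame(
            [[1, 2, 3], [3, 2, 1]], index=["B", "P"], columns=["a", "b", "c"]
        )
        flags = _flags(B=(Kingdom.BACTERIA, False), P=(Kingdom.PHYTOPLANKTON, False))
        with pytest.raises(ValueError, match="insufficient"):
            build_network(profiles, flags)


def _net_from_graph(g: nx.Graph) -> SignalingNetwork:
    nodes = {
        str(n): GenusNode(str(n), Kingdom.BACTERIA, False) for n in g.nodes
    }
    edges = [Edge(str(a), str(b), rho=0.9, p=1e-4) for a, b in g.edges]
    return SignalingNetwork(nodes=nodes, edges=edges)


def brute_force_metrics(g: nx.Graph) -> dict:
    """Independent oracle: exhaustive BFS shortest paths and direct
    linear-algebra information centrality."""
    n = g.number_of_nodes()
    nodes = sorted(g.nodes)
    degs = {v: sum(1 for _ in g.neighbors(v)) for v in nodes}
    dvals = np.array([degs[v] for v in nodes], dtype=float)
    m = sum(dvals) / 2
    density = 2 * m / (n * (n - 1))
    mean = dvals.mean()
    het = np.sqrt(((dvals - mean) ** 2).mean()) / mean if mean else 0.0
    central = (n / (n - 2)) * (dvals.max() / (n - 1) - density)

    def bfs(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    close = []
    for v in nodes:
        dist = bfs(v)
        del dist[v]
        close.append(len(dist) / sum(dist.values()) if dist else 0.0)

    info = {}
    for comp_nodes in nx.connected_components(g):
        comp = sorted(comp_nodes)
        k = len(comp)
        if k == 1:
            info[comp[0]] = 0.0
            continue
        a = np.zeros((k, k))
        for i, u in enumerate(comp):
            for j, v in enumerate(comp):
                if g.has_edge(u, v):
                    a[i, j] = 1.0
        b = np.diag(a.sum(axis=1)) - a + 1.0
        c = np.linalg.inv(b)
        for i, u in enumerate(comp):
            info[u] = 1.0 / (c[i, i] + (np.trace(c) - 2 * c[i].sum()) / k)
    ivals = np.array([info[v] for v in nodes])
    cvals = np.array(close)
    return {
        "density": density,
        "heterogeneity": het,
        "centralization": central,
        "information_centrality_mean": ivals.mean(),
        "information_centrality_sd": ivals.std(ddof=1),
        "closeness_centrality_mean": cvals.mean(),
        "closeness_centrality_sd": cvals.std(ddof=1),
    }


class TestMetrics:
    def test_complete_graph_k4(self):
        m = metrics(_net_from_graph(nx.complete_graph(4)))
        assert m.density == pytest.approx(1.0)
        assert m.heterogeneity == pytest.approx(0.0)
        assert m.centralization == pytest.approx(0.0)

    def test_star_graph(self):
        # hub degree 3, leaves degree 1: density 0.5, centralization 1.0,
        # heterogeneity = sqrt(var({3,1,1,1}))/mean = sqrt(0.75)/1.5
        m = metrics(_net_from_graph(nx.star_graph(3)))
        assert m.density == pytest.approx(0.5)
        assert m.centralization == pytest.approx(1.0)
        assert m.heterogeneity == pytest.approx(np.sqrt(0.75) / 1.5)
        assert m.heterogeneity == pytest.approx(0.577, abs=5e-4)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 50:
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.25, 0.9)), seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            checked += 1
            got = metrics(_net_from_graph(g)).to_dict()
            expected = brute_force_metrics(nx.relabel_nodes(g, str))
            for key, val in expected.items():
                assert got[key] == pytest.approx(val), key

    def test_adding_edge_never_decreases_density(self):
        g = nx.gnp_random_graph(7, 0.4, seed=4)
        before = metrics(_net_from_graph(g)).density
        comp = nx.complement(g)
        u, v = next(iter(comp.edges))
        g.add_edge(u, v)
        assert metrics(_net_from_graph(g)).density > before

    def test_removing_star_hub_decreases_centralization(self):
        g = nx.star_graph(5)
        g.add_edge(1, 2)  # keep the residue connected enough to measure
        before = metrics(_net_from_graph(g)).centralization
        g.remove_node(0)
        after = metrics(_net_from_graph(g)).centralization
        assert after < before

    def test_too_small_graph_is_an_error(self):
        g = nx.path_graph(2)
        with pytest.raises(ValueError, match="centralization"):
            metrics(_net_from_graph(g))


def _signaling_net(n_signaled_pos: int, n_nonsignaled_pos: int, n_neg: int = 0):
    nodes = {"P": GenusNode("P", Kingdom.PHYTOPLANKTON, True)}
    edges = []
    for i in range(n_signaled_pos):
        name = f"S{i}"
        nodes[name] = GenusNode(name, Kingdom.BACTERIA, True)
        edges.append(Edge(name, "P", rho=0.9, p=1e-4))
    for i in range(n_nonsignaled_pos):
        name = f"N{i}"
        nodes[name] = GenusNode(name, Kingdom.BACTERIA, False)
        edges.append(Edge(name, "P", rho=0.8, p=1e-3))
    for i in range(n_neg):
        name = f"X{i}"
        nodes[name] = GenusNode(name, Kingdom.BACTERIA, True)
        edges.append(Edge(name, "P", rho=-0.9, p=1e-4))
    return SignalingNetwork(nodes=nodes, edges=edges)


class TestSignaledPositiveFraction:
    def test_study_counts_give_70_27(self):
        n_sig, n_non, frac = signaled_positive_fraction(_signaling_net(26, 11, n_neg=3))
        assert (n_sig, n_non) == (26, 11)
        assert frac == 70.27

    def test_all_signaled_and_even_split(self):
        assert signaled_positive_fraction(_signaling_net(5, 0))[2] == 100.00
        assert signaled_positive_fraction(_signaling_net(4, 4))[2] == 50.00

    def test_invariant_under_edge_order(self):
        rng = np.random.default_rng(1)
        net = _signaling_net(7, 3, n_neg=2)
        shuffled = SignalingNetwork(nodes=net.nodes, edges=list(net.edges))
        rng.shuffle(shuffled.edges)
        assert signaled_positive_fraction(net) == signaled_positive_fraction(shuffled)

    def test_no_positive_edges_is_an_error(self):
        with pytest.raises(ValueError, match="no positive edges"):
            signaled_positive_fraction(_signaling_net(0, 0, n_neg=2))


class TestFractionRecovery:
    @pytest.mark.parametrize("fraction", [0.3, 0.5, 0.7])
    def test_planted_fraction_recovered(self, fraction):
        recovered = []
        for rep in range(50):
            cfg = planted_fraction_config(fraction, n_samples=24, seed=1000 + rep)
            profiles, _ = make_abundance_series(cfg)
            net = build_network(profiles, cfg.genus_flags())
            _, _, frac = signaled_positive_fraction(net)
            recovered.append(frac / 100.0)
        assert abs(np.mean(recovered) - fraction) <= 0.1
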