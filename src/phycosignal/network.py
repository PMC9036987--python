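"""Interkingdom co-occurrence networks and the signaled positive-edge fraction.

Genus abundance series are correlated across samples with Spearman's rank
correlation, restricted to bacteria-phytoplankton pairs.  A pair becomes an
edge when |rho| > 0.6 and p < 0.01 (both strict); negative correlations are
kept, carrying their sign.  Graph-level metrics follow the Cytoscape
NetworkAnalyzer definitions (density, degree heterogeneity, degree
centralization, closeness, and Stephenson-Zelen information centrality), so
no external tool is needed to reproduce them.  The headline statistic is the
share of positive edges whose bacterial endpoint is a "signaled" genus — one
whose reads carry an IAA-synthetase annotation.

p-values: for n <= 9 samples the exact permutation distribution of the rank
correlation is enumerated (the study's own regime is n = 6, where the
t-approximation is unreliable); for larger n the usual t-approximation with
n - 2 degrees of freedom is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RHO_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 0.01
EXACT_PERMUTATION_MAX_N = 9


class Kingdom(str, Enum):
    BACTERIA = "BACTERIA"
    PHYTOPLANKTON = "PHYTOPLANKTON"


class EdgeSign(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class GenusNode:
    name: str
    kingdom: Kingdom
    signaled: bool


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    rho: float
    p: float

    @property
    def sign(self) -> EdgeSign:
        return EdgeSign.POSITIVE if self.rho > 0 else EdgeSign.NEGATIVE


@dataclass
class SignalingNetwork:
    nodes: dict[str, GenusNode]
    edges: list[Edge]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for name, node in self.nodes.items():
            g.add_node(
                name, kingdom=node.kingdom.value, signaled=node.signaled
            )
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, rho=e.rho, p=e.p, sign=e.sign.value)
        return g

    def subgraph(self, signaled: bool) -> "SignalingNetwork":
        """Network restricted to edges whose bacterial endpoint has the given
        signaled status (plus all phytoplankton endpoints involved)."""
        keep_edges = []
        names: set[str] = set()
        for e in self.edges:
            bact = e.node_a if self.nodes[e.node_a].kingdom is Kingdom.BACTERIA else e.node_b
            if self.nodes[bact].signaled == signaled:
                keep_edges.append(e)
                names.update((e.node_a, e.node_b))
        return SignalingNetwork(
            nodes={n: self.nodes[n] for n in names}, edges=keep_edges
        )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided p-value.

    Exact permutation p for n <= 9; t-approximation (df = n - 2) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman: series must be 1-D and equal length")
    n = len(x)
    if n < 4:
        raise ValueError("spearman: need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman: constant series has undefined correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = _t_approximation_p(rho, n)
    return rho, p


def _t_approximation_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


from functools import lru_cache


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: fraction of permutations of one rank vector whose
    |rho| reaches |rho_obs| (observed permutation included by construction)."""
    n = len(rx)
    perms = _all_permutations(n)
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    denom = np.sqrt(
        np.sum(rx_c**2) * np.sum((permuted - permuted.mean(axis=1, keepdims=True)) ** 2, axis=1)
    )
    rhos = (permuted - permuted.mean(axis=1, keepdims=True)) @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def build_network(
    profiles: pd.DataFrame,
    flags: Mapping[str, GenusNode],
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> SignalingNetwork:
    """Threshold Spearman correlations into a bipartite signaling network.

    ``profiles`` is a genus-by-sample abundance table (rows: genus); every
    genus must appear in ``flags``.  Only bacteria-phytoplankton pairs are
    tested; an edge requires |rho| strictly above ``rho_threshold`` and p
    strictly below ``p_threshold``.
    """
    n_samples = profiles.shape[1]
    if n_samples < 4:
        raise ValueError(
            f"build_network: {n_samples} samples is insufficient; "
            "Spearman thresholding needs at least 4"
        )
    missing = set(profiles.index) - set(flags)
    if missing:
        raise KeyError(f"genera without kingdom/signaled flags: {sorted(missing)}")
    bacteria = [g for g in profiles.index if flags[g].kingdom is Kingdom.BACTERIA]
    phyto = [g for g in profiles.index if flags[g].kingdom is Kingdom.PHYTOPLANKTON]
    edges: list[Edge] = []
    for b in bacteria:
        xb = profiles.loc[b].to_numpy(dtype=float)
        for p_name in phyto:
            yp = profiles.loc[p_name].to_numpy(dtype=float)
            if np.all(xb == xb[0]) or np.all(yp == yp[0]):
                continue  # constant series: no defined correlation, no edge
            rho, p = spearman(xb, yp)
            if abs(rho) > rho_threshold and p < p_threshold:
                edges.append(Edge(node_a=b, node_b=p_name, rho=rho, p=p))
    nodes = {g: flags[g] for g in profiles.index}
    return SignalingNetwork(nodes=nodes, edges=edges)


@dataclass
class NetworkMetrics:
    density: float
    heterogeneity: float
    centralization: float
    information_centrality_mean_sd: tuple[float, float]
    closeness_centrality_mean_sd: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "heterogeneity": self.heterogeneity,
            "centralization": self.centralization,
            "information_centrality_mean": self.information_centrality_mean_sd[0],
            "information_centrality_sd": self.information_centrality_mean_sd[1],
            "closeness_centrality_mean": self.closeness_centrality_mean_sd[0],
            "closeness_centrality_sd": self.closeness_centrality_mean_sd[1],
        }


def information_centrality(g: nx.Graph) -> dict[str, float]:
    """Stephenson-Zelen current-flow centrality, computed per component.

    Within a component of size N with degree matrix D, adjacency A and
    all-ones J:  C = (D - A + J)^-1  and
    I_i = 1 / (C_ii + (trace(C) - 2 * rowsum_i(C)) / N).
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            out[nodes[0]] = 0.0
            continue
        a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
        d = np.diag(a.sum(axis=1))
        b = d - a + np.ones((n, n))
        c = np.linalg.inv(b)
        tr = np.trace(c)
        rowsums = c.sum(axis=1)
        for i, name in enumerate(nodes):
            out[name] = 1.0 / (c[i, i] + (tr - 2.0 * rowsums[i]) / n)
    return out


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Cytoscape-style closeness: (reachable nodes) / (sum of distances),
    within components; isolated nodes score 0."""
    out: dict[str, float] = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        del lengths[node]
        if not lengths:
            out[node] = 0.0
        else:
            out[node] = len(lengths) / sum(lengths.values())
    return out


def metrics(net: SignalingNetwork) -> NetworkMetrics:
    """Whole-network metric suite (NetworkAnalyzer formulas)."""
    g = net.to_networkx()
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("metrics: empty node set")
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = degrees.mean()
    heterogeneity = (
        float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    )
    if n < 3:
        raise ValueError("metrics: centralization undefined for fewer than 3 nodes")
    centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    info = np.array(list(information_centrality(g).values()))
    close = np.array(list(closeness_centrality(g).values()))
    return NetworkMetrics(
        density=float(density),
        heterogeneity=heterogeneity,
        centralization=float(centralization),
        information_centrality_mean_sd=(float(info.mean()), float(info.std(ddof=1)) if n > 1 else 0.0),
        closeness_centrality_mean_sd=(float(close.mean()), float(close.std(ddof=1)) if n > 1 else 0.0),
    )


def signaled_positive_fraction(net: SignalingNetwork) -> tuple[int, int, float]:
    """Share of positive bacteria-phytoplankton edges attributable to signaling.

    Positive edges are partitioned by the signaled status of their bacterial
    endpoint; the fraction is 100 * signaled / (signaled + non-signaled),
    reported to two decimals.
    """
    n_signaled = 0
    n_nonsignaled = 0
    for e in net.edges:
        if e.sign is not EdgeSign.POSITIVE:
            continue
        bact = e.node_a if net.nodes[e.node_a].kingdom is Kingdom.BACTERIA else e.node_b
        if net.nodes[bact].signaled:
            n_signaled += 1
        else:
            n_nonsignaled += 1
    total = n_signaled + n_nonsignaled
    if total == 0:
        raise ValueError("signaled_positive_fraction: no positive edges")
    fraction = round(100.0 * n_signaled / total, 2)
    return n_signaled, n_nonsignaled, fraction


def write_edge_tsv(net: SignalingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genus_a\tgenus_b\trho\tp\tsign\tsignaled_bacterium\n")
        for e in sorted(net.edges, key=lambda e: (e.node_a, e.node_b)):
            bact = e.node_a if net.nodes[e.node_a].kingdom is Kingdom.BACTERIA else e.node_b
            fh.write(
                f"{e.node_a}\t{e.node_b}\t{e.rho:.4f}\t{e.p:.3g}\t"
                f"{e.sign.value}\t{net.nodes[bact].signaled}\n"
            )


def write_node_tsv(net: SignalingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genus\tkingdom\tsignaled\n")
        for name in sorted(net.nodes):
            node = net.nodes[name]
            fh.write(f"{name}\t{node.kingdom.value}\t{node.signaled}\n")


def write_graphml(net: SignalingNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), path)
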