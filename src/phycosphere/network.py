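"""Spearman co-occurrence networks and their stability metrics.

Networks are built by thresholding pairwise Spearman correlations between
taxa across samples (|rho| >= r_threshold and p <= p_threshold; the sign is
kept as an edge attribute so reports can verify, rather than assume, claims
about positive-correlation dominance). Stability is summarized by

* robustness — mean fraction of surviving nodes left in the largest
  connected component after random removal of a fixed node fraction;
* vulnerability — the maximum over nodes of the relative drop in global
  efficiency (mean inverse shortest-path length) caused by removing that
  node.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .io import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceNetwork:
    """Undirected simple graph of taxa; edges carry ``rho`` and ``p``."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_edge_fraction(self) -> float | None:
        if self.n_edges == 0:
            return None
        pos = sum(1 for _, _, d in self.graph.edges(data=True) if d["rho"] > 0)
        return pos / self.n_edges


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n.

    Enumerates all n! orderings of one rank vector; honors ties because the
    observed rank vectors (average ranks) are permuted directly.
    """
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 1.0
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        r = (xc @ yc[list(perm)]) / denom
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def correlation_network(
    table: AbundanceTable,
    r_threshold: float = 0.75,
    p_threshold: float = 0.01,
    min_prevalence: float = 0.0,
    exact_p_below: int = 10,
) -> CooccurrenceNetwork:
    """Build the thresholded Spearman co-occurrence network of a table.

    Taxa detected in fewer than ``min_prevalence`` of samples are dropped
    before correlation; constant (zero-variance) taxa are excluded with a
    warning and can never form edges. p-values use the t-distribution
    approximation, or exact permutation when there are fewer than
    ``exact_p_below`` samples.
    """
    n = table.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to build a network")
    x = table.values
    prevalence = (x > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    taxa = np.asarray(table.taxon_ids)[keep]
    x = x[:, keep]
    variances = x.var(axis=0)
    constant = variances == 0
    if constant.any():
        logger.warning(
            "excluding %d constant taxa from correlation", int(constant.sum())
        )
    g = nx.Graph()
    taxonomy = table.taxonomy or {}
    for t in taxa[~constant]:
        g.add_node(str(t))
        if t in taxonomy:
            g.nodes[str(t)]["family"] = _family_of(taxonomy[t])
    idx = np.flatnonzero(~constant)
    if len(idx) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(idx) == 2:
                r, pv = spearmanr(x[:, idx[0]], x[:, idx[1]])
                rho_mat = np.array([[1.0, r], [r, 1.0]])
                p_mat = np.array([[0.0, pv], [pv, 0.0]])
            else:
                rho_mat, p_mat = spearmanr(x[:, idx])
        ranks = np.apply_along_axis(rankdata, 0, x[:, idx])
        for a, b in combinations(range(len(idx)), 2):
            rho = float(rho_mat[a, b])
            if np.isnan(rho) or abs(rho) < r_threshold:
                continue
            if n < exact_p_below:
                p = _exact_spearman_p(ranks[:, a], ranks[:, b], rho)
            else:
                p = float(p_mat[a, b])
            if p <= p_threshold:
                g.add_edge(str(taxa[idx[a]]), str(taxa[idx[b]]), rho=rho, p=p)
    return CooccurrenceNetwork(graph=g)


def _family_of(lineage: str) -> str:
    """Extract the family rank from a ;-separated lineage (f__ prefix or
    5th rank), falling back to the whole string."""
    parts = [p.strip() for p in lineage.split(";")]
    for p in parts:
        if p.startswith("f__"):
            return p[3:] or "unclassified"
    if len(parts) >= 5:
        return parts[4]
    return lineage


def network_metrics(net: CooccurrenceNetwork) -> dict:
    """Node/edge counts, average degree 2E/N, density 2E/(N(N-1)) and mean
    local clustering coefficient (0 for degree < 2 nodes)."""
    n, e = net.n_nodes, net.n_edges
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return {
        "n_nodes": n,
        "n_edges": e,
        "avg_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)),
        "avg_clustering": float(nx.average_clustering(net.graph)),
    }


def robustness(
    net: CooccurrenceNetwork,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = 0,
) -> float:
    """Mean largest-component fraction among survivors of random removal.

    Each repetition removes floor(removal_fraction * N) uniformly chosen
    nodes; the repetition's score is |largest connected component among
    survivors| / |survivors|. Isolated survivors count as singletons.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    n = net.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    n_remove = int(np.floor(removal_fraction * n))
    nodes = np.asarray(sorted(net.graph.nodes()), dtype=object)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_reps)
    for r in range(n_reps):
        removed = rng.choice(n, size=n_remove, replace=False)
        survivors = np.delete(nodes, removed)
        sub = net.graph.subgraph(survivors)
        if sub.number_of_nodes() == 0:
            scores[r] = 0.0
            continue
        largest = max((len(c) for c in nx.connected_components(sub)), default=0)
        scores[r] = largest / sub.number_of_nodes()
    return float(scores.mean())


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path length over unordered node pairs
    (disconnected pairs contribute 0)."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, hop in lengths.items():
            if dst != src:
                total += 1.0 / hop
    return total / (n * (n - 1))


def vulnerability(net: CooccurrenceNetwork) -> dict:
    """Global efficiency, per-node vulnerability and their maximum.

    V_i = (E_glob(G) - E_glob(G - i)) / E_glob(G); removing a structurally
    redundant node can make V_i negative. An edgeless graph has
    vulnerability 0 by convention (warned).
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes")
    e_glob = global_efficiency(net.graph)
    if e_glob == 0:
        logger.warning("edgeless graph: vulnerability defined as 0")
        return {
            "global_efficiency": 0.0,
            "per_node_vulnerability": {v: 0.0 for v in net.graph.nodes()},
            "vulnerability": 0.0,
        }
    per_node = {}
    for v in net.graph.nodes():
        sub = net.graph.subgraph([u for u in net.graph.nodes() if u != v])
        per_node[v] = (e_glob - global_efficiency(sub)) / e_glob
    return {
        "global_efficiency": e_glob,
        "per_node_vulnerability": per_node,
        "vulnerability": max(per_node.values()),
    }


def high_weight_edges(
    net: CooccurrenceNetwork, threshold: float = 0.9
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edges with rho > threshold, annotated with endpoint families.

    Returns the edge table and a per-family-pair count table (for heatmap
    export); counts sum to the number of high-weight edges.
    """
    rows = []
    for u, v, d in net.graph.edges(data=True):
        if d["rho"] > threshold:
            a, b = sorted((str(u), str(v)))
            fa = net.graph.nodes[a].get("family", "unknown")
            fb = net.graph.nodes[b].get("family", "unknown")
            f1, f2 = sorted((fa, fb))
            rows.append({"source": a, "target": b, "rho": d["rho"],
                         "p": d["p"], "family_source": fa, "family_target": fb,
                         "family_pair": f"{f1}|{f2}"})
    edges = pd.DataFrame(
        rows, columns=["source", "target", "rho", "p", "family_source",
                       "family_target", "family_pair"],
    ).sort_values(["source", "target"]) if rows else pd.DataFrame(
        columns=["source", "target", "rho", "p", "family_source",
                 "family_target", "family_pair"])
    counts = (
        edges.groupby("family_pair").size().rename("count").reset_index()
        if len(edges)
        else pd.DataFrame(columns=["family_pair", "count"])
    )
    return edges, counts
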