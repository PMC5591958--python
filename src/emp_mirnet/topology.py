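"""Centrality metrics and hub ranking for the inferred co-expression network.

Five classical unweighted-shortest-path centralities are computed within
each connected component:

* degree — number of incident edges;
* betweenness(v) = sum over ordered-free pairs s != t != v of
  sigma_st(v) / sigma_st (unnormalized);
* stress(v) = sum of sigma_st(v), the raw count of shortest paths through v;
* closeness(v) = (n_c - 1) / sum_t d(v, t) within the component;
* radiality(v) = sum_{t != v} (diam + 1 - d(v, t)) / (n_c - 1), with diam
  the component diameter.

Edge weights (partial correlations) are deliberately ignored for
distances; they stay available as edge attributes.  Hubs are ranked by the
sum of per-metric descending ranks (average rank on ties); the top hub of
each component is flagged, ties broken lexicographically by node ID.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import rankdata

__all__ = ["centralities", "rank_hubs"]

METRICS = ("degree", "betweenness", "stress", "closeness", "radiality")


def _bfs_counts(adj: list[list[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (unweighted BFS)."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[source] = 0
    sigma[source] = 1.0
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if dist[w] == -1:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        frontier = nxt
    return dist, sigma


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Compute the five centralities for every node, per connected component."""
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "component", *METRICS])

    rows = []
    for comp_idx, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)))
    ):
        nodes = sorted(comp)
        n = len(nodes)
        index = {v: i for i, v in enumerate(nodes)}
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in graph.subgraph(comp).edges():
            adj[index[u]].append(index[v])
            adj[index[v]].append(index[u])

        dist = np.zeros((n, n), dtype=np.int64)
        sigma = np.zeros((n, n), dtype=np.float64)
        for s in range(n):
            dist[s], sigma[s] = _bfs_counts(adj, s, n)
        diam = int(dist.max()) if n > 1 else 0

        betweenness = np.zeros(n)
        stress = np.zeros(n)
        for v in range(n):
            # pairs (s, t), s < t, both != v, with v on a shortest s-t path
            on_path = dist[:, v][:, None] + dist[v, :][None, :] == dist
            on_path[v, :] = False
            on_path[:, v] = False
            np.fill_diagonal(on_path, False)
            through = np.where(on_path, sigma[:, v][:, None] * sigma[v, :][None, :], 0.0)
            iu = np.triu_indices(n, 1)
            stress[v] = through[iu].sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(on_path, through / np.where(sigma > 0, sigma, 1.0), 0.0)
            betweenness[v] = frac[iu].sum()

        degree = np.array([len(adj[i]) for i in range(n)], dtype=float)
        if n > 1:
            dsum = dist.sum(axis=1)
            closeness = (n - 1) / dsum
            radiality = (diam + 1 - dist).sum(axis=1) - (diam + 1)  # drop t == v term
            radiality = radiality / (n - 1)
        else:
            closeness = np.array([0.0])
            radiality = np.array([0.0])

        for i, node in enumerate(nodes):
            rows.append(
                {
                    "node": node,
                    "component": comp_idx,
                    "degree": degree[i],
                    "betweenness": betweenness[i],
                    "stress": stress[i],
                    "closeness": closeness[i],
                    "radiality": radiality[i],
                }
            )
    return pd.DataFrame(rows, columns=["node", "component", *METRICS])


def rank_hubs(report: pd.DataFrame) -> pd.DataFrame:
    """Rank nodes by summed descending ranks over the five centralities.

    Returns the report sorted by ascending ``rank_sum`` (node ID as the
    tie-break), with one ``is_top_hub`` flag per connected component.
    """
    if report.empty:
        raise ValueError("empty topology report")
    out = report.copy()
    out["rank_sum"] = 0.0
    for comp, idx in out.groupby("component").groups.items():
        sub = out.loc[idx]
        total = np.zeros(len(sub))
        for metric in METRICS:
            # descending: largest value gets rank 1; average rank on ties
            total += rankdata(-sub[metric].to_numpy(), method="average")
        out.loc[idx, "rank_sum"] = total
    out = out.sort_values(["rank_sum", "node"], kind="mergesort").reset_index(drop=True)
    out["is_top_hub"] = False
    for comp, idx in out.groupby("component").groups.items():
        out.loc[idx.min(), "is_top_hub"] = True  # first row of each component
    return out
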