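"""Stepping-stone (multigenerational) connectivity on the site graph.

Direct connectivity probabilities define a weighted digraph with edge
weights w = -ln P. All-pairs shortest paths on w (Floyd–Warshall)
minimise the summed log-transformed probabilities, i.e. maximise the
product of probabilities along the path; re-exponentiating the path
length gives the stepping-stone probability SS_ij >= P_ij. All
computation stays in log space, so chains of hundreds of weak links
do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix


@dataclass
class SteppingStoneMatrix:
    """SS probabilities, their -log distances, reachability, and the
    next-hop matrix for path recovery. SS_ii = 1 by convention (the
    zero-length path); unreachable pairs have SS = 0 and empty path."""

    site_ids: np.ndarray
    ss: np.ndarray
    log_dist: np.ndarray
    reachable: np.ndarray
    next_hop: np.ndarray

    def path(self, i: int, j: int) -> list[int]:
        """Site-id sequence of the maximising path i -> j ([] if
        unreachable; [i] for i == j)."""
        pos = {int(s): k for k, s in enumerate(self.site_ids)}
        a, b = pos[int(i)], pos[int(j)]
        if a == b:
            return [int(i)]
        if not self.reachable[a, b]:
            return []
        out = [a]
        while out[-1] != b:
            out.append(int(self.next_hop[out[-1], b]))
        return [int(self.site_ids[k]) for k in out]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.ss, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def build_graph(mat: ConnectivityMatrix) -> nx.DiGraph:
    """Directed graph with one node per site and an edge (i, j) for
    every P_ij > 0, weighted w = -ln P_ij >= 0 (probability kept as an
    edge attribute)."""
    g = nx.DiGraph()
    g.add_nodes_from(int(s) for s in mat.site_ids)
    n = len(mat.site_ids)
    for i in range(n):
        for j in range(n):
            p = mat.P[i, j]
            if p > 0:
                g.add_edge(int(mat.site_ids[i]), int(mat.site_ids[j]),
                           weight=float(-np.log(p)), probability=float(p))
    return g


def stepping_stone(mat: ConnectivityMatrix) -> SteppingStoneMatrix:
    """Floyd–Warshall closure of the connectivity matrix in log space.

    The diagonal is fixed at SS_ii = 1 (zero-length path) regardless of
    retention. Ties between equal-weight paths are broken
    deterministically toward the lowest intermediate node id (strict
    ``<`` relaxation with ascending k keeps the first — lowest-k —
    minimiser, and keeps a direct edge over an equal-weight detour).
    """
    if np.any(mat.P < 0):
        raise ValueError("negative probabilities")
    n = len(mat.site_ids)
    with np.errstate(divide="ignore"):
        D = np.where(mat.P > 0, -np.log(mat.P), np.inf)
    np.fill_diagonal(D, 0.0)
    nxt = np.where(np.isfinite(D), np.arange(n)[None, :], -1)
    np.fill_diagonal(nxt, np.arange(n))
    for k in range(n):
        alt = D[:, k, None] + D[None, k, :]
        better = alt < D
        D = np.where(better, alt, D)
        nxt = np.where(better, nxt[:, k, None], nxt)
    reachable = np.isfinite(D)
    ss = np.where(reachable, np.exp(-D), 0.0)
    np.fill_diagonal(ss, 1.0)
    return SteppingStoneMatrix(site_ids=np.asarray(mat.site_ids, dtype=int),
                               ss=ss, log_dist=D, reachable=reachable, next_hop=nxt)


def export_graphml(mat: ConnectivityMatrix, path) -> None:
    nx.write_graphml(build_graph(mat), path)


def export_edgelist(mat: ConnectivityMatrix, path) -> None:
    g = build_graph(mat)
    rows = [(u, v, d["probability"], d["weight"]) for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "sink", "probability", "weight"]).to_csv(path, index=False)
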