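"""Independent brute-force oracles used only by the test suite.

Deliberately naive: Floyd-Warshall over an adjacency dict and explicit
double loops, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math


def floyd_warshall(nodes, edges):
    """Full all-pairs hop-distance matrix as a dict of dicts (inf = unreachable)."""
    nodes = list(nodes)
    dist = {u: {v: (0 if u == v else math.inf) for v in nodes} for u in nodes}
    for u, v in edges:
        dist[u][v] = min(dist[u][v], 1)
        dist[v][u] = min(dist[v][u], 1)
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == math.inf:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def brute_mu(nodes, edges, members_i, members_j, A=0.9, b=1.0, C=0):
    """mu by explicit enumeration of every ordered cross pair."""
    dist = floyd_warshall(nodes, edges)
    num = den = 0.0
    for n in members_i:
        for m in members_j:
            d = dist[n][m]
            s = 0.0 if d == math.inf else A * math.exp(-b * d)
            den += s
            if d <= C:
                num += s
    return num / den if den > 0 else 0.0


def brute_mean_path_length(nodes, edges):
    """Mean shortest-path length over finite unordered pairs (nan if none)."""
    dist = floyd_warshall(nodes, edges)
    nodes = list(nodes)
    total, count = 0.0, 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if dist[u][v] != math.inf:
                total += dist[u][v]
                count += 1
    return total / count if count else math.nan
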