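"""The ICod similarity mu between disease subnetworks, with a permutation null.

The score for subnetworks i and j is

    mu(i, j) = sum_{D(n,m) <= C} S(n, m)  /  sum_{n in i, m in j} S(n, m)

over all ordered cross pairs (n from i's members, m from j's members), where
D is the unweighted shortest-path distance on the GLOBAL integrated network
and S(n, m) = A * exp(-b * D(n, m)) is the distance-decay transform.  With
the default threshold C = 0 the numerator counts exactly the shared members,
so mu is the decay-normalized proportion of direct overlap.  Unreachable
pairs contribute S = 0 (the decay limit), which keeps mu defined on
fragmented networks.

Significance comes from a permutation null: random seed sets of matched
size are drawn, subnetworks are rebuilt from scratch, and mu is recomputed;
the p-value uses the add-one permutation estimator so it is never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from icod.subnetwork import DiseaseSubnetwork, SeedGeneSet, extract_subnetwork

#: Sentinel distance for node pairs in different components.  Using the IEEE
#: infinity makes the decay transform go to its limit 0 with no special case.
UNREACHABLE: float = math.inf

#: Above this node count the dense all-pairs matrix is not materialized and
#: per-source BFS with memoization is used instead (a real integrated PPI
#: network of ~11K nodes would need a ~1 GB dense matrix).
_DENSE_NODE_LIMIT = 4000


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the distance-decay transform S = A * exp(-b * D).

    A is the dimensionless amplitude (0 < A <= 1), b the per-hop decay rate,
    C the hop-distance threshold defining "directly overlapping" pairs for
    the numerator.  Defaults A=0.9, b=1, C=0.
    """

    A: float = 0.9
    b: float = 1.0
    C: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.A <= 1):
            raise ValueError("amplitude A must be in (0, 1]")
        if self.b <= 0:
            raise ValueError("decay rate b must be positive")
        if self.C < 0 or int(self.C) != self.C:
            raise ValueError("threshold C must be a non-negative integer")


@dataclass
class SimilarityResult:
    """mu for one subnetwork pair, optionally with its permutation null."""

    label_i: str
    label_j: str
    mu: float
    numerator: float
    denominator: float
    n_overlap_pairs: int
    n_members_i: int
    n_members_j: int
    p_value: float | None = None
    null_mus: np.ndarray | None = None
    n_permutations: int = 0
    scheme: str | None = None
    rng_seed: int | None = None


class DistanceProvider:
    """Shortest-path hop distances on one network, cached for reuse.

    Small networks get a dense all-pairs matrix (scipy csgraph BFS, C speed);
    large ones fall back to memoized per-source BFS so memory stays linear.
    """

    def __init__(self, net: nx.Graph, dense_limit: int = _DENSE_NODE_LIMIT):
        self.net = net
        self.nodes = sorted(net.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self._dense: np.ndarray | None = None
        self._decay_cache: dict[tuple[float, float], np.ndarray] = {}
        self._bfs_cache: dict[str, dict[str, int]] = {}
        if 0 < len(self.nodes) <= dense_limit:
            adj = nx.to_scipy_sparse_array(net, nodelist=self.nodes, format="csr")
            self._dense = _csgraph_shortest_path(adj, method="D", unweighted=True)

    @property
    def is_dense(self) -> bool:
        return self._dense is not None

    def distance(self, u: str, v: str) -> float:
        """D(u, v) in hops; UNREACHABLE (inf) across components."""
        if u not in self.index or v not in self.index:
            raise KeyError(f"node not in network: {u if u not in self.index else v!r}")
        if self._dense is not None:
            return float(self._dense[self.index[u], self.index[v]])
        if u not in self._bfs_cache:
            self._bfs_cache[u] = dict(nx.single_source_shortest_path_length(self.net, u))
        return float(self._bfs_cache[u].get(v, UNREACHABLE))

    def decay_matrix(self, params: DecayParams) -> np.ndarray:
        """Dense S = A*exp(-b*D) with unreachable pairs mapped to 0."""
        if self._dense is None:
            raise RuntimeError("decay matrix requires the dense backend")
        key = (params.A, params.b)
        if key not in self._decay_cache:
            with np.errstate(over="ignore"):
                s = params.A * np.exp(-params.b * self._dense)
            s[~np.isfinite(self._dense)] = 0.0
            self._decay_cache[key] = s
        return self._decay_cache[key]

    def indices(self, nodes: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.index[n] for n in sorted(nodes)), dtype=np.intp)


def shortest_path_distance(net: nx.Graph, u: str, v: str) -> float:
    """Unweighted shortest-path hop count between u and v on ``net``.

    Returns UNREACHABLE (inf) when no path exists; D(x, x) = 0.  Nodes
    absent from the network are a fatal argument error.
    """
    if u not in net or v not in net:
        missing = u if u not in net else v
        raise ValueError(f"node {missing!r} is not in the network")
    if u == v:
        return 0.0
    try:
        return float(nx.shortest_path_length(net, u, v))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def transform_distance(d: float, params: DecayParams = DecayParams()) -> float:
    """Distance-decay transform S(d) = A * exp(-b * d); S(UNREACHABLE) = 0."""
    if d != UNREACHABLE and d < 0:
        raise ValueError("distance must be non-negative")
    if d == UNREACHABLE:
        return 0.0
    return params.A * math.exp(-params.b * d)


def _pair_nodes(sub: DiseaseSubnetwork, pairs: str) -> frozenset[str]:
    if pairs == "members":
        return sub.members
    if pairs == "seeds":
        return sub.seed_genes_used
    raise ValueError(f"unknown pairs mode: {pairs!r}")


def compute_mu(
    global_net: nx.Graph,
    sub_i: DiseaseSubnetwork,
    sub_j: DiseaseSubnetwork,
    params: DecayParams = DecayParams(),
    distances: DistanceProvider | None = None,
    pairs: str = "members",
) -> SimilarityResult:
    """Compute mu for one subnetwork pair (no p-value).

    Distances for both numerator and denominator are measured on the global
    network, not on the induced subnetworks.  The denominator sums S over
    all ordered cross pairs; the numerator restricts to pairs with
    D <= C (with C = 0: shared members, giving A * |intersection|).
    If every cross pair is unreachable the denominator is 0 and mu = 0 by
    convention.
    """
    nodes_i = _pair_nodes(sub_i, pairs)
    nodes_j = _pair_nodes(sub_j, pairs)
    if not nodes_i or not nodes_j:
        raise ValueError("both member sets must be non-empty")
    missing = (nodes_i | nodes_j) - set(global_net.nodes)
    if missing:
        raise ValueError(f"members not in the global network: {sorted(missing)[:5]}")
    if distances is None:
        distances = DistanceProvider(global_net)

    if distances.is_dense:
        ii = distances.indices(nodes_i)
        jj = distances.indices(nodes_j)
        d_block = distances._dense[np.ix_(ii, jj)]
        s_block = distances.decay_matrix(params)[np.ix_(ii, jj)]
        denominator = float(s_block.sum())
        close = d_block <= params.C
        numerator = float(s_block[close].sum())
        n_overlap = int(close.sum())
    else:
        numerator = denominator = 0.0
        n_overlap = 0
        for n in nodes_i:
            for m in nodes_j:
                d = distances.distance(n, m)
                s = transform_distance(d, params)
                denominator += s
                if d <= params.C:
                    numerator += s
                    n_overlap += 1

    mu = numerator / denominator if denominator > 0 else 0.0
    return SimilarityResult(
        label_i=sub_i.label,
        label_j=sub_j.label,
        mu=mu,
        numerator=numerator,
        denominator=denominator,
        n_overlap_pairs=n_overlap,
        n_members_i=len(nodes_i),
        n_members_j=len(nodes_j),
    )


def _degree_bins(net: nx.Graph, n_bins: int = 10) -> tuple[np.ndarray, list[np.ndarray]]:
    """Decile bin assignment of all nodes by degree; returns (edges, pools)."""
    nodes = sorted(net.nodes)
    degrees = np.array([net.degree(n) for n in nodes], dtype=float)
    edges = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1  # right-inclusive top bin
    assignment = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, n_bins - 1)
    pools = [np.array([nodes[i] for i in np.flatnonzero(assignment == b)]) for b in range(n_bins)]
    return edges, pools


def _draw_null_seeds(
    net: nx.Graph,
    observed: frozenset[str],
    scheme: str,
    rng: np.random.Generator,
    bins: tuple[np.ndarray, list[np.ndarray]] | None,
    node_array: np.ndarray,
) -> frozenset[str]:
    size = len(observed)
    if size > len(node_array):
        raise ValueError("seed-set size exceeds the network's node count")
    if scheme == "uniform":
        return frozenset(rng.choice(node_array, size=size, replace=False))
    if scheme == "degree_binned":
        assert bins is not None
        edges, pools = bins
        drawn: list[str] = []
        counts = np.zeros(len(pools), dtype=int)
        for g in observed:
            deg = net.degree(g)
            b = int(np.clip(np.searchsorted(edges, deg, side="right") - 1, 0, len(pools) - 1))
            counts[b] += 1
        for b, k in enumerate(counts):
            if k == 0:
                continue
            pool = pools[b]
            if k > len(pool):  # degenerate bin; spill into uniform draw
                drawn.extend(pool.tolist())
                continue
            drawn.extend(rng.choice(pool, size=int(k), replace=False).tolist())
        while len(drawn) < size:  # top up after any spill, avoiding duplicates
            extra = rng.choice(node_array, size=1, replace=False)[0]
            if extra not in drawn:
                drawn.append(extra)
        return frozenset(drawn)
    raise ValueError(f"unknown permutation scheme: {scheme!r}")


def permutation_pvalue(
    global_net: nx.Graph,
    seeds_i: SeedGeneSet,
    seeds_j: SeedGeneSet,
    params: DecayParams = DecayParams(),
    n_permutations: int = 1000,
    scheme: str = "uniform",
    rng_seed: int = 0,
    distances: DistanceProvider | None = None,
    pairs: str = "members",
) -> SimilarityResult:
    """mu for the observed seed pair plus its permutation p-value.

    Each permutation draws two random seed sets of matched size
    (|seeds ∩ net| each) — uniformly from the network's nodes, or matched to
    the observed seeds' degree deciles (``degree_binned``) — rebuilds both
    subnetworks from scratch and recomputes mu.  The p-value is the add-one
    estimator (1 + #{null mu >= observed}) / (1 + n_permutations), so the
    smallest attainable p is 1/(n_permutations + 1).  A single integer seed
    makes the whole run bit-reproducible.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if distances is None:
        distances = DistanceProvider(global_net)

    sub_i = extract_subnetwork(global_net, seeds_i)
    sub_j = extract_subnetwork(global_net, seeds_j)
    observed = compute_mu(global_net, sub_i, sub_j, params, distances, pairs)

    rng = np.random.default_rng(rng_seed)
    node_array = np.array(distances.nodes)
    bins = _degree_bins(global_net) if scheme == "degree_binned" else None

    null_mus = np.empty(n_permutations)
    for k in range(n_permutations):
        rand_i = _draw_null_seeds(global_net, sub_i.seed_genes_used, scheme, rng, bins, node_array)
        rand_j = _draw_null_seeds(global_net, sub_j.seed_genes_used, scheme, rng, bins, node_array)
        perm_i = extract_subnetwork(global_net, SeedGeneSet("null_i", rand_i))
        perm_j = extract_subnetwork(global_net, SeedGeneSet("null_j", rand_j))
        null_mus[k] = compute_mu(global_net, perm_i, perm_j, params, distances, pairs).mu

    p = (1 + int(np.sum(null_mus >= observed.mu))) / (1 + n_permutations)
    observed.p_value = p
    observed.null_mus = null_mus
    observed.n_permutations = n_permutations
    observed.scheme = scheme
    observed.rng_seed = rng_seed
    return observed


@dataclass
class DiseaseSimilarityNetwork:
    """All-pairs similarity: mu and p matrices plus per-pair results."""

    labels: list[str]
    mu_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    results: dict[tuple[str, str], SimilarityResult] = field(default_factory=dict)

    def to_graph(self, p_cutoff: float | None = 0.05) -> nx.Graph:
        """Similarity network: one node per subnetwork label, one edge per
        unordered pair, carrying mu and p; optionally thresholded at p."""
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for (li, lj), res in self.results.items():
            if p_cutoff is None or (res.p_value is not None and res.p_value < p_cutoff):
                g.add_edge(li, lj, mu=res.mu, p_value=res.p_value)
        return g

    def long_form(self) -> pd.DataFrame:
        """One row per pair: labels, mu, p, and a Benjamini-Hochberg column
        (reported for convenience, never used for the default threshold)."""
        from scipy.stats import false_discovery_control

        rows = [
            {
                "label_i": li,
                "label_j": lj,
                "mu": r.mu,
                "p_value": r.p_value,
                "n_overlap_pairs": r.n_overlap_pairs,
                "n_members_i": r.n_members_i,
                "n_members_j": r.n_members_j,
            }
            for (li, lj), r in sorted(self.results.items())
        ]
        frame = pd.DataFrame(rows)
        if len(frame) and frame["p_value"].notna().all():
            frame["p_bh"] = false_discovery_control(frame["p_value"], method="bh")
        return frame


def build_similarity_network(
    subnets: Sequence[DiseaseSubnetwork],
    global_net: nx.Graph,
    params: DecayParams = DecayParams(),
    n_permutations: int = 1000,
    scheme: str = "uniform",
    rng_seed: int = 0,
    pairs: str = "members",
) -> DiseaseSimilarityNetwork:
    """Score every unordered subnetwork pair: mu matrix, p matrix, network.

    Permutation nulls redraw seed sets of size |seed_genes_used| for each
    pair; one distance provider is shared across all pairs.  Each pair gets
    its own child seed derived from ``rng_seed`` so results do not depend on
    pair enumeration order.
    """
    if len(subnets) < 2:
        raise ValueError("need at least two subnetworks")
    labels = [s.label for s in subnets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate subnetwork labels")
    distances = DistanceProvider(global_net)
    mu_mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    p_mat = pd.DataFrame(np.full((len(labels), len(labels)), np.nan), index=labels, columns=labels)
    results: dict[tuple[str, str], SimilarityResult] = {}
    child_seeds = np.random.SeedSequence(rng_seed).generate_state(
        len(labels) * (len(labels) - 1) // 2
    )
    for k, (a, b) in enumerate(combinations(range(len(subnets)), 2)):
        sub_a, sub_b = subnets[a], subnets[b]
        res = permutation_pvalue(
            global_net,
            SeedGeneSet(sub_a.label, sub_a.seed_genes_used),
            SeedGeneSet(sub_b.label, sub_b.seed_genes_used),
            params,
            n_permutations=n_permutations,
            scheme=scheme,
            rng_seed=int(child_seeds[k] % (2**31)),
            distances=distances,
            pairs=pairs,
        )
        results[(sub_a.label, sub_b.label)] = res
        mu_mat.loc[sub_a.label, sub_b.label] = mu_mat.loc[sub_b.label, sub_a.label] = res.mu
        p_mat.loc[sub_a.label, sub_b.label] = p_mat.loc[sub_b.label, sub_a.label] = res.p_value
    return DiseaseSimilarityNetwork(labels, mu_mat, p_mat, results)
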