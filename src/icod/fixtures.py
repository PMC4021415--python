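"""Synthetic networks, seed lists and MITAB files for fully offline testing.

The generator emulates the regime the method assumes: a scale-free PPI
universe (grown by preferential attachment) with planted, optionally
overlapping "disease" modules whose seeds sit either in the hub core or in
the periphery of the degree distribution.  Everything is deterministic
given an integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from icod.subnetwork import SeedGeneSet

#: Human-readable names for the MI codes a fixture commonly samples.
_MI_NAMES = {
    "MI:0218": "physical interaction",
    "MI:0407": "direct interaction",
    "MI:0915": "physical association",
    "MI:0403": "colocalization",
    "MI:0914": "association",
}


def _node_label(i: int) -> str:
    # Zero-padded labels keep lexicographic tie-breaks stable.
    return f"G{i:06d}"


def generate_scale_free(n: int, m: int, rng_seed: int = 0) -> nx.Graph:
    """Grow a connected scale-free network by preferential attachment.

    Starts from a clique on the first m+1 nodes; each subsequent node
    attaches to m distinct existing nodes chosen with probability
    proportional to current degree (no duplicate edges).  The edge count is
    therefore exactly m*(n-m-1) + m*(m+1)/2.
    """
    if m < 1 or n <= m:
        raise ValueError("require n > m >= 1")
    rng = np.random.default_rng(rng_seed)
    net = nx.Graph()
    labels = [_node_label(i) for i in range(n)]
    net.add_nodes_from(labels[: m + 1])
    # degree-weighted urn: node index appears once per incident edge end
    urn: list[int] = []
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            net.add_edge(labels[i], labels[j])
            urn.extend((i, j))
    for new in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(urn[rng.integers(len(urn))])
        for t in targets:
            net.add_edge(labels[new], labels[t])
            urn.extend((new, t))
    return net


@dataclass
class PlantedModuleSpec:
    """Recipe for a scale-free universe with planted overlapping modules.

    ``module_sizes`` maps each label to its seed count; ``overlap_fraction``
    is the pairwise shared-seed fraction (shared seeds form one common core
    across all modules).  ``core_degree_bias`` places seeds in the top
    (``hub_core``) or bottom (``peripheral``) degree quantile, either one
    value for all modules or a per-label mapping.
    """

    n_background: int = 500
    attachment_m: int = 2
    module_sizes: dict[str, int] = field(default_factory=lambda: {"disease_a": 20, "disease_b": 20})
    overlap_fraction: float = 0.5
    core_degree_bias: str | dict[str, str] = "hub_core"
    quantile: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_sizes:
            raise ValueError("at least one module is required")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        smallest = min(self.module_sizes.values())
        shared = self.overlap_fraction * smallest
        if abs(shared - round(shared)) > 1e-9:
            raise ValueError(
                f"overlap_fraction * min module size = {shared} is not an integer count"
            )
        if self.n_background < sum(self.module_sizes.values()):
            raise ValueError("n_background must be >= total seed count")

    def bias_of(self, label: str) -> str:
        bias = (
            self.core_degree_bias.get(label, "hub_core")
            if isinstance(self.core_degree_bias, dict)
            else self.core_degree_bias
        )
        if bias not in ("hub_core", "peripheral"):
            raise ValueError(f"unknown degree bias: {bias!r}")
        return bias

    @property
    def n_shared(self) -> int:
        return round(self.overlap_fraction * min(self.module_sizes.values()))


def generate_planted_modules(
    spec: PlantedModuleSpec,
) -> tuple[nx.Graph, list[SeedGeneSet], dict[str, list[str]]]:
    """Build the background network and plant module seed sets on it.

    Shared seeds (one common core of ``spec.n_shared`` nodes) are drawn
    first, then each module's private seeds, all without replacement from
    the degree-quantile pool its bias selects.  Returns the network, the
    seed sets, and a truth map label -> sorted seed list for assertions.
    """
    net = generate_scale_free(spec.n_background, spec.attachment_m, spec.rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed).generate_state(2)[1])
    by_degree = sorted(net.nodes, key=lambda v: (-net.degree(v), v))
    k = max(1, math.ceil(spec.quantile * len(by_degree)))
    pools = {"hub_core": by_degree[:k], "peripheral": by_degree[-k:]}

    labels = sorted(spec.module_sizes)
    biases = {lab: spec.bias_of(lab) for lab in labels}
    for lab in labels:
        need = spec.module_sizes[lab]
        if need > len(pools[biases[lab]]):
            raise ValueError(
                f"quantile {spec.quantile} holds only {k} nodes; module {lab!r} needs {need}"
            )

    used: set[str] = set()

    def draw(pool: list[str], size: int) -> list[str]:
        avail = [v for v in pool if v not in used]
        if size > len(avail):
            raise ValueError("degree-quantile pool exhausted; raise quantile or n_background")
        picked = rng.choice(np.array(avail), size=size, replace=False).tolist()
        used.update(picked)
        return picked

    module_biases = {biases[lab] for lab in labels}
    shared_pool = (
        pools[next(iter(module_biases))]
        if len(module_biases) == 1
        else pools["hub_core"] + pools["peripheral"]
    )
    shared = draw(shared_pool, spec.n_shared) if spec.n_shared else []

    seed_sets: list[SeedGeneSet] = []
    truth: dict[str, list[str]] = {}
    for lab in labels:
        private = draw(pools[biases[lab]], spec.module_sizes[lab] - len(shared))
        genes = sorted(set(shared) | set(private))
        seed_sets.append(SeedGeneSet(label=lab, genes=frozenset(genes)))
        truth[lab] = genes
    return net, seed_sets, truth


def write_fixture_mitab(
    net: nx.Graph,
    path: str | Path,
    mi_code_distribution: dict[str, float] | None = None,
    rng_seed: int = 0,
) -> None:
    """Write one MITAB 2.5 row per edge, sampling the interaction-type
    column from ``mi_code_distribution`` (default: all MI:0915)."""
    dist = mi_code_distribution or {"MI:0915": 1.0}
    codes = sorted(dist)
    probs = np.array([dist[c] for c in codes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mi_code_distribution probabilities must sum to 1")
    rng = np.random.default_rng(rng_seed)
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges)
    drawn = rng.choice(len(codes), size=len(edges), p=probs)
    lines = []
    for (a, b), ci in zip(edges, drawn):
        code = codes[ci]
        type_field = f'psi-mi:"{code}"({_MI_NAMES.get(code, "interaction")})'
        row = [a, b] + ["-"] * 9 + [type_field, "-", "-", "-"]
        lines.append("\t".join(row))
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def write_seed_file(seeds: SeedGeneSet, path: str | Path) -> None:
    """One symbol per line, sorted, with a comment header naming the set."""
    out = [f"# seed genes: {seeds.label}"] + sorted(seeds.genes)
    Path(path).write_text("".join(line + "\n" for line in out), encoding="utf-8")


def write_truth(truth: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
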