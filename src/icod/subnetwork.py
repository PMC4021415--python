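"""Disease subnetworks: seed genes plus first neighbors on the global network."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from icod.ppi_io import normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class SeedGeneSet:
    """A named set of seed genes annotated to one disease or condition."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"seed set {self.label!r} is empty")


@dataclass
class DiseaseSubnetwork:
    """Seeds found in the global network, their first neighbors, induced edges.

    ``members`` is the node set (seeds_used union their neighbors);
    ``graph`` is the full induced subgraph of the global network on members,
    so edges between two neighbor-only members are retained.
    ``seeds_missing`` lists seeds absent from the global network.
    """

    label: str
    seed_genes_used: frozenset[str]
    members: frozenset[str]
    graph: nx.Graph
    seeds_missing: frozenset[str] = field(default_factory=frozenset)


def load_seeds(path: str | Path, label: str | None = None) -> SeedGeneSet:
    """Load a seed-gene list: one symbol per line, ``#`` comments allowed.

    Symbols are normalized (strip, uppercase) and deduplicated.  The label
    defaults to the file name stem.  An empty list is fatal.
    """
    path = Path(path)
    genes = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(normalize_symbol(line))
    genes.discard("")
    if not genes:
        raise ValueError(f"no seeds found in {path}")
    return SeedGeneSet(label=label or path.stem, genes=frozenset(genes))


def extract_subnetwork(
    net: nx.Graph,
    seeds: SeedGeneSet,
    neighbor_edges: bool = True,
) -> DiseaseSubnetwork:
    """Expand a seed set to its subnetwork: seeds present in ``net`` plus
    their first neighbors (exactly one hop), with induced edges.

    Seeds absent from the network are dropped and reported on the result
    (and logged), not imputed.  Zero mapped seeds is fatal, since the
    subnetwork would be empty.

    Parameters
    ----------
    neighbor_edges
        If True (default) the full induced subgraph on the members is kept,
        including edges between two neighbor-only members.  If False, only
        edges incident to a seed are retained (sensitivity analysis).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("global network is empty")
    seeds_used = frozenset(g for g in seeds.genes if g in net)
    seeds_missing = frozenset(seeds.genes - seeds_used)
    if seeds_missing:
        logger.info(
            "seed set %r: %d of %d seeds absent from the network: %s",
            seeds.label,
            len(seeds_missing),
            len(seeds.genes),
            sorted(seeds_missing),
        )
    if not seeds_used:
        raise ValueError(
            f"none of the {len(seeds.genes)} seeds of {seeds.label!r} map to the network"
        )
    members = set(seeds_used)
    for s in seeds_used:
        members.update(net.neighbors(s))
    sub = net.subgraph(members).copy()
    if not neighbor_edges:
        sub.remove_edges_from(
            [(u, v) for u, v in sub.edges if u not in seeds_used and v not in seeds_used]
        )
    return DiseaseSubnetwork(
        label=seeds.label,
        seed_genes_used=seeds_used,
        members=frozenset(members),
        graph=sub,
        seeds_missing=seeds_missing,
    )
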