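"""Parsing, filtering, integration and serialization of protein-interaction data.

Interaction records arrive either as PSI-MI TAB (MITAB 2.5; later versions
append columns that are ignored here) or as a simple 2-3 column tab-separated
edge list.  Records are filtered to physical-evidence interaction types and
integrated into one undirected simple graph whose nodes are normalized gene
symbols.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

#: PSI-MI controlled-vocabulary codes accepted as physical evidence:
#: physical interaction (MI:0218), direct interaction (MI:0407),
#: physical association (MI:0915).
PHYSICAL_EVIDENCE_CODES: frozenset[str] = frozenset({"MI:0218", "MI:0407", "MI:0915"})

_MI_CODE_RE = re.compile(r"MI:\d{4}")

# MITAB 2.5 layout, 1-based: interactor ids in columns 1-2, interaction type
# in column 12.  Stored 0-based.
_MITAB_MIN_COLUMNS = 15
_MITAB_TYPE_COLUMN = 11


@dataclass(frozen=True)
class InteractionRecord:
    """One parsed interaction row: two interactors plus evidence-type codes."""

    interactor_a: str
    interactor_b: str
    interaction_type_codes: frozenset[str] = frozenset()
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.interactor_a or not self.interactor_b:
            raise ValueError("interactor symbols must be non-empty")


@dataclass
class ParseReport:
    """Records parsed from one file plus skip bookkeeping."""

    records: list[InteractionRecord] = field(default_factory=list)
    n_rows: int = 0
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def normalize_symbol(raw: str) -> str:
    """Canonical symbol form: surrounding whitespace stripped, uppercased."""
    return raw.strip().upper()


def _strip_db_prefix(identifier: str) -> str:
    # MITAB identifiers are "db:accession"; keep the accession. Bare symbols
    # carry no colon and pass through unchanged.
    return identifier.rsplit(":", 1)[-1]


def parse_mitab(
    path: str | Path,
    dialect: str = "mitab",
    source_db: str | None = None,
) -> ParseReport:
    """Parse an interaction file into :class:`InteractionRecord` objects.

    Parameters
    ----------
    path
        Tab-separated input file.
    dialect
        ``"mitab"`` for MITAB 2.5+ (>= 15 columns; interactor ids in columns
        1-2, interaction type in column 12), or ``"simple_edgelist"`` for
        ``symbol_a<TAB>symbol_b[<TAB>comma-separated MI codes]``.
    source_db
        Label recorded on every record; defaults to the file name stem.

    Rows with too few columns or missing interactors are skipped and counted
    in the report, never fatal.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    if dialect not in ("mitab", "simple_edgelist"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    label = source_db if source_db is not None else path.stem
    report = ParseReport()
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            report.n_rows += 1
            cols = line.split("\t")
            if dialect == "mitab":
                if len(cols) < _MITAB_MIN_COLUMNS:
                    report.n_skipped += 1
                    continue
                a = normalize_symbol(_strip_db_prefix(cols[0]))
                b = normalize_symbol(_strip_db_prefix(cols[1]))
                codes = frozenset(_MI_CODE_RE.findall(cols[_MITAB_TYPE_COLUMN]))
            else:
                if len(cols) < 2:
                    report.n_skipped += 1
                    continue
                a = normalize_symbol(cols[0])
                b = normalize_symbol(cols[1])
                codes = frozenset()
                if len(cols) >= 3:
                    codes = frozenset(_MI_CODE_RE.findall(cols[2]))
            if not a or a == "-" or not b or b == "-":
                report.n_skipped += 1
                continue
            report.records.append(
                InteractionRecord(a, b, interaction_type_codes=codes, source_db=label)
            )
    return report


def filter_physical(
    records: Iterable[InteractionRecord],
    allowed_codes: Iterable[str] = PHYSICAL_EVIDENCE_CODES,
) -> list[InteractionRecord]:
    """Keep records whose type codes intersect ``allowed_codes``.

    Records without any MI code are removed: absence of evidence annotation
    is not physical evidence.
    """
    allowed = frozenset(allowed_codes)
    return [r for r in records if r.interaction_type_codes & allowed]


def integrate(*record_collections: Iterable[InteractionRecord]) -> nx.Graph:
    """Union one or more record collections into an undirected simple graph.

    Duplicate pairs (within or across sources) collapse to a single edge;
    self-pairs are dropped entirely (they never affect shortest-path
    distances between distinct nodes and would bias degree rankings).
    Each edge carries a ``sources`` attribute: the set of contributing
    ``source_db`` labels.
    """
    net = nx.Graph()
    for collection in record_collections:
        for rec in collection:
            a, b = rec.interactor_a, rec.interactor_b
            if a == b:
                continue
            if net.has_edge(a, b):
                net.edges[a, b]["sources"].add(rec.source_db)
            else:
                net.add_edge(a, b, sources={rec.source_db})
    return net


def write_network(net: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Serialize a network.

    ``edgelist`` writes one edge per line as two tab-separated symbols,
    lexicographically sorted within and across lines (byte-stable output);
    isolated nodes are written as single-column lines so the round trip
    reproduces the node set exactly.  ``graphml`` preserves edge provenance
    as a pipe-joined ``sources`` attribute.
    """
    path = Path(path)
    if format == "edgelist":
        lines = sorted(
            "\t".join(sorted((str(u), str(v)))) for u, v in net.edges
        )
        lines.extend(sorted(str(n) for n in net.nodes if net.degree(n) == 0))
        lines.sort()
        path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    elif format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(net.nodes)
        for u, v, data in net.edges(data=True):
            attrs = {}
            if "sources" in data:
                attrs["sources"] = "|".join(sorted(data["sources"]))
            out.add_edge(u, v, **attrs)
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path, format: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "edgelist":
        net = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                net.add_node(parts[0])
            else:
                net.add_edge(parts[0], parts[1])
        return net
    if format == "graphml":
        net = nx.read_graphml(path)
        for _, _, data in net.edges(data=True):
            if "sources" in data and isinstance(data["sources"], str):
                data["sources"] = set(data["sources"].split("|")) if data["sources"] else set()
        return net
    raise ValueError(f"unknown network format: {format!r}")


def apply_symbol_map(
    records: Iterable[InteractionRecord], mapping: dict[str, str]
) -> list[InteractionRecord]:
    """Re-map interactor identifiers through a user-supplied two-column table.

    Cross-namespace reconciliation (e.g. Entrez id to gene symbol) is the
    caller's responsibility; unmapped identifiers pass through unchanged.
    """
    norm_map = {normalize_symbol(k): normalize_symbol(v) for k, v in mapping.items()}
    out = []
    for rec in records:
        out.append(
            InteractionRecord(
                norm_map.get(rec.interactor_a, rec.interactor_a),
                norm_map.get(rec.interactor_b, rec.interactor_b),
                rec.interaction_type_codes,
                rec.source_db,
            )
        )
    return out


def read_symbol_map(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated identifier mapping file."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 2:
            mapping[cols[0]] = cols[1]
    return mapping
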