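"""Drug–gene interaction network construction.

Loads a seed list of drug-interacting gene symbols and a PSI-MITAB
protein–protein interaction file (iRefIndex-style, tolerant of extra
columns), then expands the seeds one hop: the result is the subgraph of the
interactome *induced* on the seeds plus their direct interactors, so
neighbor–neighbor edges are retained. Graphs are simple and undirected;
repeated interaction records for the same pair are collapsed into one edge
whose ``n_records`` attribute counts the supporting records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "SeedSet",
    "ExpansionResult",
    "read_seed_genes",
    "read_mitab",
    "expand_seed",
    "write_edge_list",
    "read_edge_list",
    "write_node_list",
    "packaged_seed_path",
]

_DATA_DIR = Path(__file__).parent / "data"


def packaged_seed_path() -> Path:
    """Path of the packaged montelukast seed-gene fixture."""
    return _DATA_DIR / "montelukast_seed_genes.txt"


@dataclass(frozen=True)
class SeedSet:
    genes: frozenset[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("seed set must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)


def read_seed_genes(path: str | Path, source_tag: str | None = None) -> SeedSet:
    """Read seed gene symbols, one per line or comma-separated.

    ``#`` starts a comment; symbols are uppercased and deduplicated.
    """
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for tok in line.split(","):
            sym = tok.strip().upper()
            if sym:
                symbols.add(sym)
    if not symbols:
        raise ValueError(f"no gene symbols found in {path}")
    return SeedSet(genes=frozenset(symbols), source_tag=source_tag or str(path))


# ---------------------------------------------------------------------------
# PSI-MITAB


def _resolve_symbol(*fields: str) -> str | None:
    # Try each field in turn; take the first '|'-separated token, strip any
    # "db:" prefix and a trailing "(description)".
    for f in fields:
        f = f.strip()
        if not f or f == "-":
            continue
        tok = f.split("|", 1)[0]
        if ":" in tok:
            tok = tok.split(":", 1)[1]
        tok = tok.split("(", 1)[0].strip().upper()
        if tok:
            return tok
    return None


def _taxon_of(f: str) -> str:
    # "taxid:9606(Homo sapiens)" -> "taxid:9606"
    return f.split("|", 1)[0].split("(", 1)[0].strip()


def read_mitab(path: str | Path, taxon: str | None = None) -> nx.Graph:
    """Parse a PSI-MITAB interaction file into a simple undirected graph.

    Gene symbols are resolved from the alias columns (5/6) with fallback to
    the alternative-ID (3/4) and unique-ID (1/2) columns; the taxon filter,
    when given (e.g. ``"taxid:9606"``), is applied to columns 10/11. Self
    interactions, rows failing the taxon filter and rows with no resolvable
    symbol are dropped and counted; duplicate pairs are collapsed with their
    record count accumulated on the edge. Parse statistics live in
    ``graph.graph["provenance"]``.
    """
    g = nx.Graph()
    n_rows = n_short = n_taxon = n_self = n_unresolved = 0
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            cols = line.split("\t")
            if len(cols) < 15:
                n_short += 1
                continue
            if taxon is not None:
                if _taxon_of(cols[9]) != taxon or _taxon_of(cols[10]) != taxon:
                    n_taxon += 1
                    continue
            a = _resolve_symbol(cols[4], cols[2], cols[0])
            b = _resolve_symbol(cols[5], cols[3], cols[1])
            if a is None or b is None:
                n_unresolved += 1
                continue
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                g[a][b]["n_records"] += 1
            else:
                g.add_edge(a, b, n_records=1)
    if n_rows > 0 and n_short == n_rows:
        raise ValueError(f"{path}: no PSI-MITAB row with >= 15 columns")
    g.graph["provenance"] = {
        "source": str(path),
        "rows": n_rows,
        "dropped_short": n_short,
        "dropped_taxon": n_taxon,
        "dropped_self": n_self,
        "dropped_unresolved": n_unresolved,
    }
    return g


def write_mitab_minimal(g: nx.Graph, path: str | Path, taxon: str = "taxid:9606") -> None:
    """Write edges as minimal 15-column PSI-MITAB (one row per record)."""
    rows = []
    for a, b, data in sorted(g.edges(data=True)):
        for _ in range(int(data.get("n_records", 1))):
            rows.append(
                "\t".join(
                    [
                        f"entrez gene/locuslink:{a}",
                        f"entrez gene/locuslink:{b}",
                        "-",
                        "-",
                        f"hgnc:{a}",
                        f"hgnc:{b}",
                        "psi-mi:\"MI:0004\"(affinity chromatography technology)",
                        "-",
                        "-",
                        f"{taxon}(Homo sapiens)",
                        f"{taxon}(Homo sapiens)",
                        "psi-mi:\"MI:0915\"(physical association)",
                        "psi-mi:\"MI:0000\"(synthetic)",
                        f"{a}-{b}",
                        "-",
                    ]
                )
            )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# one-hop expansion


@dataclass
class ExpansionResult:
    network: nx.Graph
    seeds_present: frozenset[str]
    seeds_missing: frozenset[str]


def expand_seed(network: nx.Graph, seeds: SeedSet) -> ExpansionResult:
    """Induced subgraph on the seeds plus their direct interactors.

    All interactome edges with both endpoints inside the expansion set are
    kept (including neighbor–neighbor edges). Seeds present in the
    interactome but isolated within the expansion are retained as nodes;
    seeds absent from the interactome are reported, not added.
    """
    present = frozenset(s for s in seeds.genes if s in network)
    missing = frozenset(seeds.genes) - present
    members: set[str] = set(present)
    for s in present:
        members.update(network.neighbors(s))
    sub = network.subgraph(members).copy()
    sub.graph["provenance"] = {
        "seeds_present": sorted(present),
        "seeds_missing": sorted(missing),
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
    }
    return ExpansionResult(network=sub, seeds_present=present, seeds_missing=missing)


# ---------------------------------------------------------------------------
# plain-text graph I/O


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tn_records"]
    for a, b, data in sorted((min(a, b), max(a, b), d) for a, b, d in g.edges(data=True)):
        lines.append(f"{a}\t{b}\t{int(data.get('n_records', 1))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, n = line.split("\t")
        g.add_edge(a, b, n_records=int(n))
    return g


def write_node_list(g: nx.Graph, seeds: Iterable[str], path: str | Path) -> None:
    seedset = set(seeds)
    lines = ["gene\tis_seed\tdegree"]
    for n in sorted(g.nodes):
        lines.append(f"{n}\t{str(n in seedset).lower()}\t{g.degree[n]}")
    Path(path).write_text("\n".join(lines) + "\n")
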