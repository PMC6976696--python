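"""Assembly of a deduplicated undirected protein-protein interactome.

Heterogeneous edge-list sources (each a TSV of gene-symbol pairs with
optional database/evidence tags) are merged into a single simple undirected
:class:`networkx.Graph`: symbols are canonicalized, self-loops dropped,
duplicate pairs collapsed with their source tags unioned, and whole evidence
classes (by default computationally inferred interactions) excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Recognised interaction-evidence classes.  ``inferred`` covers
#: computational predictions (co-expression, evolutionary or metabolic
#: associations) that are excluded from the high-confidence interactome.
EVIDENCE_CLASSES = frozenset(
    {
        "binary_Y2H",
        "kinase_substrate",
        "literature_curated",
        "signaling",
        "inferred",
        "other",
    }
)

#: Evidence classes dropped at assembly unless the caller overrides.
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"inferred"})


class InteractomeError(ValueError):
    """Raised for malformed interaction input."""


def canonical_symbol(symbol: str) -> str:
    """Canonical gene identifier: uppercased, surrounding whitespace stripped.

    Canonicalization is idempotent; two symbols denote the same gene iff
    their canonical forms are equal.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction as read from a source database dump.

    Self-loops and duplicates are permitted here; they are resolved by
    :func:`assemble_interactome`.
    """

    gene_a: str
    gene_b: str
    source: str = "unknown"
    evidence: str = "other"

    def canonical(self) -> "InteractionRecord":
        return InteractionRecord(
            canonical_symbol(self.gene_a),
            canonical_symbol(self.gene_b),
            self.source,
            self.evidence,
        )


def assemble_interactome(
    records: Iterable[InteractionRecord],
    excluded_evidence: Iterable[str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Merge raw interaction records into a simple undirected graph.

    Parameters
    ----------
    records
        Raw interactions; duplicated pairs are removed (their source tags
        are unioned onto the surviving edge) and self-loops are dropped.
    excluded_evidence
        Evidence classes to exclude entirely (default: ``{"inferred"}``).
    alias_map
        Optional symbol -> official-symbol map applied after
        canonicalization (both sides of the map are canonicalized too).

    Returns
    -------
    networkx.Graph
        Nodes are canonical gene symbols; each edge carries a ``sources``
        attribute holding the set of database tags that reported it.
    """
    records = list(records)
    if not records:
        raise InteractomeError("no interactions")
    excluded = (
        DEFAULT_EXCLUDED_EVIDENCE if excluded_evidence is None else set(excluded_evidence)
    )
    alias = (
        {canonical_symbol(k): canonical_symbol(v) for k, v in alias_map.items()}
        if alias_map
        else {}
    )

    g = nx.Graph()
    n_excluded = n_self = n_dup = 0
    for lineno, rec in enumerate(records, start=1):
        a, b = canonical_symbol(rec.gene_a), canonical_symbol(rec.gene_b)
        if not a or not b:
            raise InteractomeError(f"empty gene symbol in record {lineno}: {rec}")
        a, b = alias.get(a, a), alias.get(b, b)
        if rec.evidence in excluded:
            n_excluded += 1
            continue
        if a == b:
            n_self += 1
            continue
        # ";" joins multiple tags (the writer emits merged edges that way)
        tags = set(rec.source.split(";"))
        if g.has_edge(a, b):
            n_dup += 1
            g.edges[a, b]["sources"].update(tags)
        else:
            g.add_edge(a, b, sources=tags)
    logger.info(
        "assembled interactome: %d nodes, %d edges "
        "(%d excluded by evidence, %d self-loops dropped, %d duplicates merged)",
        g.number_of_nodes(),
        g.number_of_edges(),
        n_excluded,
        n_self,
        n_dup,
    )
    return g


def induced_subgraph(g: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subgraph of ``g`` induced by ``genes`` (unknown genes are ignored).

    Gene symbols are canonicalized before lookup; the number of genes
    absent from the graph is logged.
    """
    wanted = {canonical_symbol(x) for x in genes}
    present = wanted & set(g.nodes)
    if len(present) < len(wanted):
        logger.info("induced_subgraph: %d/%d genes not on graph", len(wanted) - len(present), len(wanted))
    return nx.Graph(g.subgraph(present))


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, dialect: str = "tsv") -> list[InteractionRecord]:
    """Read interaction records from a TSV edge list or a SIF file.

    TSV columns: gene_a, gene_b[, source[, evidence]]; lines starting with
    ``#`` are comments.  SIF lines are ``node relation node [node ...]``;
    the relation becomes the source tag.
    """
    path = Path(path)
    if dialect not in {"tsv", "sif"}:
        raise InteractomeError(f"unknown edge-list dialect: {dialect!r}")
    records: list[InteractionRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if dialect == "tsv" else line.split()
            if dialect == "sif":
                if len(fields) < 3:
                    raise InteractomeError(f"{path}:{lineno}: SIF line needs >=3 fields")
                relation = fields[1]
                records.extend(
                    InteractionRecord(fields[0], tgt, source=relation) for tgt in fields[2:]
                )
                continue
            if len(fields) < 2:
                raise InteractomeError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            source = fields[2] if len(fields) > 2 and fields[2] else "unknown"
            evidence = fields[3] if len(fields) > 3 and fields[3] else "other"
            if evidence not in EVIDENCE_CLASSES:
                evidence = "other"
            records.append(InteractionRecord(fields[0], fields[1], source, evidence))
    return records


def write_edge_list(g_or_records: nx.Graph | Sequence[InteractionRecord], path: str | Path) -> None:
    """Write a canonical, sorted TSV edge list (reproducible diffs).

    Accepts either an assembled graph (sources joined with ``;``) or raw
    records (canonicalized, one line each).
    """
    path = Path(path)
    lines = ["#gene_a\tgene_b\tsource\tevidence"]
    if isinstance(g_or_records, nx.Graph):
        for a, b in sorted(tuple(sorted(e)) for e in g_or_records.edges):
            sources = ";".join(sorted(g_or_records.edges[a, b].get("sources", {"unknown"})))
            lines.append(f"{a}\t{b}\t{sources}\tother")
    else:
        recs = sorted(
            (r.canonical() for r in g_or_records),
            key=lambda r: (r.gene_a, r.gene_b, r.source, r.evidence),
        )
        lines.extend(f"{r.gene_a}\t{r.gene_b}\t{r.source}\t{r.evidence}" for r in recs)
    path.write_text("\n".join(lines) + "\n")
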