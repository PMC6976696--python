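"""Fisher exact over-representation analysis with Bonferroni correction.

A query gene set is tested against each pathway of a GMT collection with
the one-sided hypergeometric (Fisher exact) upper-tail probability of the
observed overlap, then Bonferroni-adjusted over the number of sets tested.
The same flat machinery serves pathway and GO cellular-component
collections.  Reports are ranked by adjusted p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .interactome import canonical_symbol

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Raised for malformed gene-set input or empty queries."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway collection over a gene universe.

    The universe defaults to the union of all set members; a restricted
    universe (e.g. the genes actually measured) may be supplied, in which
    case sets are intersected down to it.
    """

    name: str
    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        name: str = "collection",
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        canon = {
            str(pname): frozenset(canonical_symbol(g) for g in members)
            for pname, members in sets.items()
        }
        if universe is None:
            uni = frozenset().union(*canon.values()) if canon else frozenset()
        else:
            uni = frozenset(canonical_symbol(g) for g in universe)
            canon = {p: members & uni for p, members in canon.items()}
        canon = {p: members for p, members in canon.items() if members}
        if not canon:
            raise EnrichmentError("empty gene-set collection")
        return cls(name=name, sets=canon, universe=uni)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection.from_sets(self.sets, name=self.name, universe=universe)


def hypergeom_tail(q: int, k: int, m: int, n_universe: int) -> float:
    """P(X >= q) for X ~ Hypergeometric(N, m, k): overlap of a size-k draw
    with a size-m set in a universe of N genes."""
    if q <= 0:
        return 1.0
    return float(hypergeom.sf(q - 1, n_universe, m, k))


def bonferroni(p_values: Sequence[float], m_tests: int) -> list[float]:
    """Bonferroni adjustment: p * m_tests capped at 1."""
    if m_tests < len(p_values):
        raise EnrichmentError(
            f"m_tests ({m_tests}) smaller than number of p-values ({len(p_values)})"
        )
    return [min(1.0, p * m_tests) for p in p_values]


def fisher_exact_enrichment(
    query: Iterable[str], coll: GeneSetCollection
) -> pd.DataFrame:
    """One-sided over-representation test of ``query`` against every set.

    The query is intersected with the collection universe first (loss is
    logged).  Returns a DataFrame sorted by (p_adj, pathway) with columns
    pathway, q (overlap), k (query size), m (set size), N (universe size),
    p_raw, p_adj and the overlapping genes.
    """
    if not coll.sets:
        raise EnrichmentError("empty gene-set collection")
    q_raw = {canonical_symbol(g) for g in query}
    q_eff = q_raw & coll.universe
    if len(q_eff) < len(q_raw):
        logger.info(
            "enrichment query: %d/%d genes outside universe dropped",
            len(q_raw) - len(q_eff), len(q_raw),
        )
    if not q_eff:
        raise EnrichmentError("empty effective query (no query genes in universe)")
    n_universe = len(coll.universe)
    k = len(q_eff)
    rows = []
    for pathway, members in coll.sets.items():
        overlap = q_eff & members
        rows.append(
            {
                "pathway": pathway,
                "q": len(overlap),
                "k": k,
                "m": len(members),
                "N": n_universe,
                "p_raw": hypergeom_tail(len(overlap), k, len(members), n_universe),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    report = pd.DataFrame(rows)
    report["p_adj"] = bonferroni(report["p_raw"].tolist(), len(coll.sets))
    report = report.sort_values(["p_adj", "pathway"], kind="mergesort").reset_index(drop=True)
    report.insert(0, "rank", report.index + 1)
    return report[["rank", "pathway", "p_adj", "p_raw", "q", "k", "m", "N", "overlap_genes"]]


def enrich_direction_split(
    de: pd.DataFrame, coll: GeneSetCollection, mode: str = "all_de",
    fc_cutoff: float | None = None, p_cutoff: float | None = None,
) -> pd.DataFrame:
    """Enrichment of the up-regulated or all significant DE genes.

    ``mode`` is ``up_only`` (Fig.-2b-style: enrichment of induced genes) or
    ``all_de``.  Optional cut-offs pre-filter the DE table; otherwise every
    record with direction up/down enters.  The report carries the mode as a
    DataFrame attribute.
    """
    if mode not in {"up_only", "all_de"}:
        raise EnrichmentError(f"unknown enrichment mode: {mode!r}")
    if de.empty:
        raise EnrichmentError("empty DE table")
    table = de
    if p_cutoff is not None:
        table = table[table["p"] <= p_cutoff]
    if fc_cutoff is not None:
        up = table["fc"] >= fc_cutoff
        down = table["fc"] <= 1.0 / fc_cutoff
        table = table[up | down] if mode == "all_de" else table[up]
    elif mode == "up_only":
        table = table[table["direction"] == "up"]
    if table.empty:
        raise EnrichmentError("empty effective query (no genes pass the filters)")
    report = fisher_exact_enrichment(table.index, coll)
    report.attrs["mode"] = mode
    return report


# ---------------------------------------------------------------------------
# GMT and report I/O
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path, name: str | None = None, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets[fields[0]] = fields[2:]
    if not sets:
        raise EnrichmentError(f"{path}: no gene sets")
    return GeneSetCollection.from_sets(sets, name=name or path.stem, universe=universe)


def write_gmt(coll: GeneSetCollection, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for pname in sorted(coll.sets):
        desc = (descriptions or {}).get(pname, "na")
        lines.append("\t".join([pname, desc, *sorted(coll.sets[pname])]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_universe(path: str | Path) -> frozenset[str]:
    """One gene symbol per line; '#' comments allowed."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(canonical_symbol(line))
    return frozenset(genes)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Ranked enrichment TSV (rank, pathway, adjusted p, raw p, overlap)."""
    report.to_csv(path, sep="\t", index=False, float_format="%.6E")
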