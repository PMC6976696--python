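"""Overlap statistics between gene signatures (module-vs-module comparisons).

Quantifies how strongly two gene sets (e.g. a disease module and a
compression module, or an external published signature) overlap: raw and
percentage overlap, Jaccard index, and a hypergeometric upper-tail p-value
for observing at least the seen intersection when one set is drawn at
random from the universe.  A two/three-set exclusive-region (Venn) tally is
included for reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

from .enrichment import hypergeom_tail
from .interactome import canonical_symbol

logger = logging.getLogger(__name__)


class SetComparisonError(ValueError):
    """Raised for invalid overlap-test input."""


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap summary; symmetric in a and b up to the percent fields."""

    name_a: str
    name_b: str
    size_a: int
    size_b: int
    intersection: int
    percent_of_a: float
    percent_of_b: float
    jaccard: float
    universe_size: int
    p_hyper: float

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        header = "\t".join(d)
        row = "\t".join(
            f"{v:.6E}" if isinstance(v, float) else str(v) for v in d.values()
        )
        Path(path).write_text(header + "\n" + row + "\n")


def overlap_test(
    a: Iterable[str],
    b: Iterable[str],
    universe: Iterable[str],
    name_a: str = "a",
    name_b: str = "b",
) -> OverlapResult:
    """Hypergeometric significance of the overlap between sets a and b.

    Genes outside the universe are intersected away (and logged).  The
    p-value is P(X >= |a&b|) for X ~ Hypergeometric(N, |b|, |a|), which is
    symmetric under swapping a and b.  Percent overlap is reported relative
    to each set; ``percent_of_a`` treats a as the reference signature.
    """
    uni = {canonical_symbol(g) for g in universe}
    if not uni:
        raise SetComparisonError("empty universe")
    set_a = {canonical_symbol(g) for g in a}
    set_b = {canonical_symbol(g) for g in b}
    lost = (len(set_a - uni), len(set_b - uni))
    if any(lost):
        logger.info("overlap_test: dropped %d/%d genes outside universe (a/b)", *lost)
    set_a &= uni
    set_b &= uni
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return OverlapResult(
        name_a=name_a,
        name_b=name_b,
        size_a=len(set_a),
        size_b=len(set_b),
        intersection=inter,
        percent_of_a=100.0 * inter / len(set_a) if set_a else 0.0,
        percent_of_b=100.0 * inter / len(set_b) if set_b else 0.0,
        jaccard=inter / union if union else 0.0,
        universe_size=len(uni),
        p_hyper=hypergeom_tail(inter, len(set_a), len(set_b), len(uni)),
    )


def three_way_venn(sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Exclusive-region counts for 2 or 3 named sets.

    Region keys are '&'-joined sorted member names (e.g. ``"a&b"`` for
    genes in exactly a and b); counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise SetComparisonError("three_way_venn takes exactly 2 or 3 sets")
    canon = {
        str(name): {canonical_symbol(g) for g in members} for name, members in sets.items()
    }
    names = sorted(canon)
    regions: dict[str, int] = {}
    for mask in product([False, True], repeat=len(names)):
        if not any(mask):
            continue
        inside = [n for n, bit in zip(names, mask) if bit]
        outside = [n for n, bit in zip(names, mask) if not bit]
        region = set.intersection(*(canon[n] for n in inside))
        for n in outside:
            region -= canon[n]
        regions["&".join(inside)] = len(region)
    return regions


def read_gene_list(path: str | Path) -> frozenset[str]:
    """External signature file: one gene symbol per line, '#' comments allowed."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(canonical_symbol(line))
    if not genes:
        raise SetComparisonError(f"{path}: empty gene list")
    return frozenset(genes)
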