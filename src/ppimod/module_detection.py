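"""Disease-module detection: seed-induced LCC and its randomization null.

The module statistic is the size of the largest connected component (LCC)
of the interactome subgraph induced by the seed genes.  Significance comes
from a null that randomizes both the network (degree-preserving double-edge
swaps, so every node keeps its interaction count) and the seed placement
(uniform node sets of the mapped seed count); a configuration switch
restricts the null to random seeds on the fixed network.  Reported are the
z-score of the observed LCC against the null samples and the add-one
empirical p-value (r + 1) / (n + 1).

The swap chain is a standard symmetric-proposal Markov chain whose
stationary distribution is uniform over simple graphs with the observed
degree sequence: two edges (a,b), (c,d) and an orientation are drawn
uniformly and rewired to (a,d), (c,b) unless that would create a self-loop
or a duplicate edge.  The chain runs hot in a jit-compiled kernel
(edge-endpoint arrays plus an integer-keyed hash set); each null sample is
taken after ``swaps_per_edge * |edges|`` further attempted swaps, with an
equally long initial burn-in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from numba import njit

from .diffexpr import SeedSet
from .interactome import canonical_symbol, induced_subgraph

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 1000
DEFAULT_SWAPS_PER_EDGE = 10


class ModuleError(ValueError):
    """Raised for degenerate module-detection input."""


def _seed_genes(seeds: SeedSet | Iterable[str]) -> set[str]:
    genes = seeds.genes if isinstance(seeds, SeedSet) else seeds
    return {canonical_symbol(g) for g in genes}


def largest_connected_component(g: nx.Graph, seeds: SeedSet | Iterable[str]) -> set[str]:
    """Node set of the largest component of the seed-induced subgraph.

    Unmapped seeds are ignored (their count is logged).  Ties between
    equal-size components break deterministically toward the component
    containing the lexicographically smallest gene.
    """
    genes = _seed_genes(seeds)
    sub = induced_subgraph(g, genes)
    if sub.number_of_nodes() == 0:
        raise ModuleError("no seeds on interactome")
    components = [set(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return components[0]


@dataclass(frozen=True)
class NullDistribution:
    """LCC sizes of random seed sets on (rewired) copies of the interactome."""

    samples: np.ndarray
    n_samples: int
    swaps_per_sample: int
    rng_seed: int
    randomize_network: bool = True

    def __post_init__(self) -> None:
        if self.n_samples != len(self.samples) or self.n_samples < 1:
            raise ModuleError("null distribution needs >=1 sample")

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if self.n_samples > 1 else 0.0


# ---------------------------------------------------------------------------
# jit kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _bit_test(bits, key):
    return (bits[key >> 6] >> np.uint64(key & 63)) & np.uint64(1)


@njit(cache=True)
def _null_lcc_kernel(u, v, n_nodes, seed_size, n_samples, swaps_per_sample, burn_in, seed):
    """Run the swap chain and record induced-LCC sizes of random seed sets.

    u, v are edge-endpoint arrays (mutated in place).  Edge membership sits
    in a packed adjacency bitset (upper-triangle key a * n + b, a < b) for
    O(1) duplicate checks.  All randomness from numba's RNG, seeded once.
    """
    np.random.seed(seed)
    m = u.shape[0]
    bits = np.zeros((n_nodes * n_nodes + 63) // 64, dtype=np.uint64)
    for i in range(m):
        a, b = u[i], v[i]
        if a > b:
            a, b = b, a
        key = a * n_nodes + b
        bits[key >> 6] |= np.uint64(1) << np.uint64(key & 63)

    def _attempt_swaps(n_attempts):
        for _ in range(n_attempts):
            i = np.random.randint(0, m)
            j = np.random.randint(0, m)
            if i == j:
                continue
            a, b = u[i], v[i]
            c, d = u[j], v[j]
            if np.random.randint(0, 2) == 1:
                c, d = d, c
            # propose (a,d) and (c,b)
            if a == d or c == b:
                continue
            ka = a * n_nodes + d if a < d else d * n_nodes + a
            kb = c * n_nodes + b if c < b else b * n_nodes + c
            if ka == kb or _bit_test(bits, ka) or _bit_test(bits, kb):
                continue
            old_i = (a * n_nodes + b) if a < b else (b * n_nodes + a)
            old_j = (c * n_nodes + d) if c < d else (d * n_nodes + c)
            bits[old_i >> 6] &= ~(np.uint64(1) << np.uint64(old_i & 63))
            bits[old_j >> 6] &= ~(np.uint64(1) << np.uint64(old_j & 63))
            bits[ka >> 6] |= np.uint64(1) << np.uint64(ka & 63)
            bits[kb >> 6] |= np.uint64(1) << np.uint64(kb & 63)
            u[i], v[i] = a, d
            u[j], v[j] = c, b

    sizes = np.empty(n_samples, dtype=np.int64)
    chosen = np.empty(seed_size, dtype=np.int64)
    pool = np.arange(n_nodes)
    parent = np.empty(seed_size, dtype=np.int64)
    comp_size = np.empty(seed_size, dtype=np.int64)

    _attempt_swaps(burn_in)
    for s in range(n_samples):
        _attempt_swaps(swaps_per_sample)
        # partial Fisher-Yates draw of seed_size distinct nodes
        for t in range(seed_size):
            r = t + np.random.randint(0, n_nodes - t)
            pool[t], pool[r] = pool[r], pool[t]
            chosen[t] = pool[t]
        # union-find over induced edges
        for t in range(seed_size):
            parent[t] = t
            comp_size[t] = 1
        best = 1
        for p in range(seed_size):
            for q in range(p + 1, seed_size):
                a, b = chosen[p], chosen[q]
                key = a * n_nodes + b if a < b else b * n_nodes + a
                if _bit_test(bits, key):
                    ra = p
                    while parent[ra] != ra:
                        ra = parent[ra]
                    rb = q
                    while parent[rb] != rb:
                        rb = parent[rb]
                    if ra != rb:
                        if comp_size[ra] < comp_size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        comp_size[ra] += comp_size[rb]
                        if comp_size[ra] > best:
                            best = comp_size[ra]
        sizes[s] = best
    return sizes


def degree_preserving_null(
    g: nx.Graph,
    seed_size: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    rng_seed: int = 0,
    randomize_network: bool = True,
) -> NullDistribution:
    """Null LCC-size distribution for random seed sets of ``seed_size``.

    Each sample rewires the graph by ``swaps_per_edge * |edges|`` attempted
    double-edge swaps (continuing a single chain with an equal burn-in) and
    draws a uniform node set; with ``randomize_network=False`` the graph
    stays fixed and only the seeds are random.  Degree sequence and edge
    count are verified after sampling.
    """
    n_nodes = g.number_of_nodes()
    m = g.number_of_edges()
    if seed_size > n_nodes:
        raise ModuleError(f"seed_size {seed_size} exceeds {n_nodes} nodes")
    if seed_size < 1:
        raise ModuleError("seed_size must be >= 1")
    if n_samples < 1:
        raise ModuleError("n_samples must be >= 1")

    nodes = sorted(g.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    u = np.empty(m, dtype=np.int64)
    v = np.empty(m, dtype=np.int64)
    for i, (a, b) in enumerate(sorted(tuple(sorted(e)) for e in g.edges)):
        u[i], v[i] = index[a], index[b]
    degrees_before = np.bincount(np.concatenate([u, v]), minlength=n_nodes)

    swaps_per_sample = swaps_per_edge * m if randomize_network else 0
    burn_in = swaps_per_sample
    sizes = _null_lcc_kernel(
        u, v, n_nodes, seed_size, n_samples, swaps_per_sample, burn_in,
        int(rng_seed) % (2**32),
    )

    degrees_after = np.bincount(np.concatenate([u, v]), minlength=n_nodes)
    if not np.array_equal(degrees_before, degrees_after):
        raise AssertionError("double-edge swap chain altered the degree sequence")
    return NullDistribution(
        samples=sizes,
        n_samples=n_samples,
        swaps_per_sample=swaps_per_sample,
        rng_seed=int(rng_seed),
        randomize_network=randomize_network,
    )


@dataclass(frozen=True)
class DiseaseModule:
    """Seed-induced LCC with its null-model statistics and provenance."""

    members: frozenset[str]
    seeds_mapped: int
    seeds_unmapped: int
    lcc_size: int
    null: NullDistribution
    z_score: float | None
    empirical_p: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "members": sorted(self.members),
            "seeds_mapped": self.seeds_mapped,
            "seeds_unmapped": self.seeds_unmapped,
            "lcc_size": self.lcc_size,
            "null": {
                "n_samples": self.null.n_samples,
                "mean": round(self.null.mean, 6),
                "sd": round(self.null.sd, 6),
                "swaps_per_sample": self.null.swaps_per_sample,
                "rng_seed": self.null.rng_seed,
                "randomize_network": self.null.randomize_network,
            },
            "z_score": None if self.z_score is None else round(self.z_score, 6),
            "empirical_p": round(self.empirical_p, 8),
            "provenance": self.provenance,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def write_gene_list(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.members)) + "\n")


def empirical_p_value(null_samples: np.ndarray, observed: float) -> float:
    """Add-one empirical p: (#{null >= observed} + 1) / (n + 1)."""
    r = int(np.sum(np.asarray(null_samples) >= observed))
    return (r + 1) / (len(null_samples) + 1)


def module_significance(
    g: nx.Graph,
    seeds: SeedSet | Iterable[str],
    n_samples: int = DEFAULT_N_SAMPLES,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    rng_seed: int = 0,
    randomize_network: bool = True,
    provenance: dict | None = None,
) -> DiseaseModule:
    """Observed module plus null statistics in one call.

    The null uses the mapped seed count, so observed and null statistics
    are comparable; the z-score is flagged ``None`` when the null is
    degenerate (sd = 0), in which case only the empirical p is meaningful.
    """
    genes = _seed_genes(seeds)
    mapped = genes & set(g.nodes)
    if not mapped:
        raise ModuleError("no seeds on interactome")
    members = largest_connected_component(g, mapped)
    lcc_size = len(members)
    null = degree_preserving_null(
        g, len(mapped), n_samples=n_samples, swaps_per_edge=swaps_per_edge,
        rng_seed=rng_seed, randomize_network=randomize_network,
    )
    sd = null.sd
    z = (lcc_size - null.mean) / sd if sd > 0 else None
    p_emp = empirical_p_value(null.samples, lcc_size)
    prov = {
        "n_samples": n_samples,
        "swaps_per_edge": swaps_per_edge,
        "rng_seed": int(rng_seed),
        "randomize_network": randomize_network,
    }
    if isinstance(seeds, SeedSet):
        prov.update(
            fc_cutoff=seeds.fc_cutoff,
            p_cutoff=seeds.p_cutoff,
            direction_filter=seeds.direction_filter,
        )
    if provenance:
        prov.update(provenance)
    logger.info(
        "module: %d/%d seeds mapped, LCC %d, null %.2f+/-%.2f, z=%s, p=%.3g",
        len(mapped), len(genes), lcc_size, null.mean, sd,
        "NA" if z is None else f"{z:.2f}", p_emp,
    )
    return DiseaseModule(
        members=frozenset(members),
        seeds_mapped=len(mapped),
        seeds_unmapped=len(genes) - len(mapped),
        lcc_size=lcc_size,
        null=null,
        z_score=z,
        empirical_p=p_emp,
        provenance=prov,
    )
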