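"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three coupled generators emulate a small paired mechanobiology RNA-seq
study on a protein interaction network:

* a scale-free background interactome (preferential attachment, or a
  configuration model for degree-sequence control) with a planted connected
  module — a random spanning tree over the module genes plus extra
  intra-module edges, so the module is connected by construction;
* paired control/treated negative-binomial counts per donor, with
  log-uniform base means, lognormal donor-level multipliers, per-sample
  sequencing-depth multipliers, and a multiplicative fold-change effect on
  the planted genes in treated samples;
* a pathway collection of random gene sets containing one planted set
  stuffed with module genes.

Defaults mirror the emulated study design: 2000 genes, attachment m = 3, a
30-gene module at log2 fold change 2, NB dispersion 0.1, 4 + 4 donors with
paired control/compressed samples and 2 replicates each.  Truth labels are
always written next to the fixtures; the pipeline never reads them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import write_counts, write_sample_meta
from .enrichment import GeneSetCollection, write_gmt
from .interactome import write_edge_list
from .seeding import stage_rng


class SyntheticError(ValueError):
    """Raised for invalid synthetic-study configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the emulated study; serialized verbatim for provenance."""

    n_genes: int = 2000
    interactome_model: str = "barabasi_albert"  # or "configuration"
    attachment_m: int = 3
    degree_sequence: Sequence[int] | None = None
    planted_module_size: int = 30
    extra_module_edges: int = 30  # intra-module edges beyond the spanning tree
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    base_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 of NB mean
    n_donors: int = 8  # half non-asthmatic, half asthmatic
    replicates_per_condition: int = 2
    depth_multipliers: Sequence[float] | None = None  # default: log-uniform in [0.5, 2]
    donor_sigma: float = 0.2  # lognormal sigma of the donor multiplier
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 60)
    planted_pathway_fraction: float = 0.8
    timepoint: str = "t3h"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_genes:
            raise SyntheticError("planted module larger than gene universe")
        if min(self.n_genes, self.planted_module_size, self.n_donors,
               self.replicates_per_condition, self.n_pathways) < 1:
            raise SyntheticError("all sizes must be positive")
        if self.nb_dispersion < 0:
            raise SyntheticError("nb_dispersion must be >= 0")
        if not 0 <= self.planted_pathway_fraction <= 1:
            raise SyntheticError("planted_pathway_fraction must be in [0, 1]")
        if self.interactome_model not in {"barabasi_albert", "configuration"}:
            raise SyntheticError(f"unknown interactome model {self.interactome_model!r}")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degree_sequence"] = None if self.degree_sequence is None else list(self.degree_sequence)
        d["depth_multipliers"] = None if self.depth_multipliers is None else list(self.depth_multipliers)
        d["base_mean_log_range"] = list(self.base_mean_log_range)
        d["pathway_size_range"] = list(self.pathway_size_range)
        return d


def generate_interactome(cfg: SyntheticConfig) -> tuple[nx.Graph, frozenset[str]]:
    """Scale-free background graph with a planted connected module.

    Returns the graph (gene-symbol nodes, each edge tagged with source
    ``synthetic``) and the planted gene set, whose induced subgraph is
    connected by construction.
    """
    rng = stage_rng(cfg.rng_seed, "interactome")
    if cfg.interactome_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(
            cfg.n_genes, cfg.attachment_m, seed=int(rng.integers(2**31))
        )
    else:
        if cfg.degree_sequence is None:
            raise SyntheticError("configuration model needs degree_sequence")
        g = nx.configuration_model(
            list(cfg.degree_sequence), seed=int(rng.integers(2**31))
        )
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))

    names = cfg.gene_names()
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    planted = [names[i] for i in rng.choice(cfg.n_genes, cfg.planted_module_size, replace=False)]

    # random spanning tree over the planted genes: attach each to a random
    # earlier one (random recursive tree), then sprinkle extra intra edges
    order = list(rng.permutation(planted))
    for i in range(1, len(order)):
        g.add_edge(order[i], order[int(rng.integers(i))])
    for _ in range(cfg.extra_module_edges):
        if len(planted) < 2:
            break
        a, b = rng.choice(planted, 2, replace=False)
        if a != b:
            g.add_edge(a, b)

    nx.set_edge_attributes(g, {e: {"synthetic"} for e in g.edges}, "sources")
    return g, frozenset(planted)


def sample_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Sample metadata for the paired design (one row per sequencing sample)."""
    rows = []
    half = cfg.n_donors // 2
    for di in range(cfg.n_donors):
        donor = f"D{di + 1}"
        phenotype = "non_asthmatic" if di < half else "asthmatic"
        for treatment in ("control", "compressed"):
            for rep in range(1, cfg.replicates_per_condition + 1):
                rows.append(
                    {
                        "sample_id": f"{donor}_{treatment}_r{rep}",
                        "donor": donor,
                        "phenotype": phenotype,
                        "treatment": treatment,
                        "timepoint": cfg.timepoint,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Draw NB counts with variance ``mean + dispersion * mean**2``.

    ``dispersion = 0`` degenerates to Poisson.  Uses the (r, p)
    parametrization r = 1/dispersion, p = r / (r + mean).
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def generate_counts(
    cfg: SyntheticConfig, planted_genes: frozenset[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for the paired design.

    Per gene g the NB mean of sample j is ``depth_j * donor_d * effect *
    mu_g`` with mu_g log-uniform over ``base_mean_log_range`` (log10),
    donor multipliers lognormal(0, donor_sigma), and effect
    ``2**planted_log2fc`` for planted genes in compressed samples.
    Dispersion alpha gives variance ``mu + alpha * mu**2``; alpha = 0 is
    Poisson.

    Returns (counts, metadata, truth) where truth lists each gene's true
    fold change and planted flag.
    """
    rng = stage_rng(cfg.rng_seed, "counts")
    meta = sample_table(cfg)
    genes = cfg.gene_names()
    n_samples = len(meta)

    lo, hi = cfg.base_mean_log_range
    mu = 10.0 ** rng.uniform(lo, hi, size=cfg.n_genes)
    donor_mult = {
        d: float(rng.lognormal(0.0, cfg.donor_sigma)) for d in meta["donor"].unique()
    }
    if cfg.depth_multipliers is not None:
        if len(cfg.depth_multipliers) != n_samples:
            raise SyntheticError(
                f"depth_multipliers needs {n_samples} values, got {len(cfg.depth_multipliers)}"
            )
        depth = np.asarray(cfg.depth_multipliers, dtype=float)
    else:
        depth = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))

    planted_mask = np.array([g in planted_genes for g in genes])
    effect = 2.0**cfg.planted_log2fc
    counts = np.empty((cfg.n_genes, n_samples), dtype=np.int64)
    for j, (sid, row) in enumerate(meta.iterrows()):
        mean_j = mu * depth[j] * donor_mult[row["donor"]]
        if row["treatment"] == "compressed":
            mean_j = np.where(planted_mask, mean_j * effect, mean_j)
        counts[:, j] = nb_sample(rng, mean_j, cfg.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=meta.index)
    truth = pd.DataFrame(
        {
            "true_log2fc": np.where(planted_mask, cfg.planted_log2fc, 0.0),
            "is_planted": planted_mask,
        },
        index=pd.Index(genes, name="gene"),
    )
    return counts_df, meta, truth


def generate_pathways(
    cfg: SyntheticConfig, planted_genes: frozenset[str], all_genes: Sequence[str] | None = None
) -> tuple[GeneSetCollection, str]:
    """Random pathway collection with one planted enriched set.

    The planted set has ``planted_pathway_fraction`` of its members drawn
    from the planted module and the rest at random.  Returns the collection
    and the planted set's name.
    """
    rng = stage_rng(cfg.rng_seed, "pathways")
    genes = list(all_genes) if all_genes is not None else cfg.gene_names()
    planted = sorted(planted_genes)
    background = [g for g in genes if g not in planted_genes]
    lo, hi = cfg.pathway_size_range

    sets: dict[str, list[str]] = {}
    width = len(str(cfg.n_pathways))
    for i in range(1, cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        sets[f"PW{i:0{width}d}_RANDOM"] = list(rng.choice(genes, size, replace=False))

    planted_name = "PW_PLANTED"
    size = min(cfg.planted_module_size, len(genes))
    n_from_module = min(int(round(cfg.planted_pathway_fraction * size)), len(planted))
    members = list(rng.choice(planted, n_from_module, replace=False))
    fill = size - len(members)
    if fill > 0 and background:
        members += list(rng.choice(background, min(fill, len(background)), replace=False))
    sets[planted_name] = members

    coll = GeneSetCollection.from_sets(sets, name="synthetic_pathways", universe=genes)
    return coll, planted_name


def write_fixtures(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate everything and write the files the pipeline consumes.

    Emits edge-list TSV, counts TSV, sample-metadata TSV, pathway GMT and a
    truth JSON (planted genes, planted pathway, per-gene fold changes,
    config echo).  Identical configs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, planted = generate_interactome(cfg)
    counts, meta, truth = generate_counts(cfg, planted)
    coll, planted_pathway = generate_pathways(cfg, planted)

    paths = {
        "edges": out / "interactome_edges.tsv",
        "counts": out / "counts.tsv",
        "meta": out / "sample_meta.tsv",
        "gmt": out / "pathways.gmt",
        "truth": out / "truth.json",
    }
    write_edge_list(g, paths["edges"])
    write_counts(counts, paths["counts"])
    write_sample_meta(meta, paths["meta"])
    write_gmt(coll, paths["gmt"])
    truth_payload = {
        "config": cfg.to_dict(),
        "planted_genes": sorted(planted),
        "planted_pathway": planted_pathway,
        "true_log2fc": {g_: float(v) for g_, v in truth["true_log2fc"].items() if v != 0.0},
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    return paths
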