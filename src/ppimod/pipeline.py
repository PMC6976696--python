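"""End-to-end orchestration: counts -> DE -> module -> enrichment -> overlaps.

A single YAML config drives the whole workflow: for every configured
contrast the pipeline computes (or loads) a DE table, thresholds it into a
seed set, detects the seed-induced disease module with its randomization
null, and runs pathway enrichment; configured module pairs are then
compared with the hypergeometric overlap test.  Every output lands in one
directory together with a manifest of SHA-256 checksums, so a rerun with
the same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    DiffExprError,
    differential_expression,
    read_counts,
    read_de_table,
    read_sample_meta,
    select_seeds,
    write_de_table,
)
from .enrichment import enrich_direction_split, read_gmt, read_universe, write_report
from .interactome import assemble_interactome, read_edge_list
from .module_detection import module_significance
from .seeding import derive_seed
from .set_comparison import overlap_test

logger = logging.getLogger(__name__)

DEFAULT_FC_CUTOFF_3H = 1.87
DEFAULT_FC_CUTOFF_24H = 1.67
DEFAULT_P_CUTOFF = 0.05


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class Contrast:
    name: str
    group_a: Mapping[str, str]
    group_b: Mapping[str, str]
    paired: bool = True
    fc_cutoff: float = DEFAULT_FC_CUTOFF_3H
    p_cutoff: float = DEFAULT_P_CUTOFF
    direction_filter: str = "both"
    enrichment_mode: str = "all_de"
    de_table: str | None = None  # optional precomputed DE TSV (e.g. DESeq2 output)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    counts: Path
    metadata: Path
    edge_lists: list[Path]
    gmt: Path
    contrasts: list[Contrast]
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    universe: Path | None = None
    null_n_samples: int = 1000
    null_swaps_per_edge: int = 10
    null_randomize_network: bool = True
    rng_seed: int = 0
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def _p(rel: str | None) -> Path | None:
            return None if rel is None else (base / rel)

        paths = raw.get("paths", {})
        null = raw.get("module_null", {})
        contrasts = [Contrast(**c) for c in raw.get("contrasts", [])]
        for c in contrasts:
            if c.de_table is not None:
                c.de_table = str(base / c.de_table)
        cfg = cls(
            counts=_p(paths.get("counts")),
            metadata=_p(paths.get("metadata")),
            edge_lists=[base / e for e in paths.get("edge_lists", [])],
            gmt=_p(paths.get("gmt")),
            universe=_p(paths.get("universe")),
            contrasts=contrasts,
            comparisons=[tuple(pair) for pair in raw.get("comparisons", [])],
            null_n_samples=int(null.get("n_samples", 1000)),
            null_swaps_per_edge=int(null.get("swaps_per_edge", 10)),
            null_randomize_network=bool(null.get("randomize_network", True)),
            rng_seed=int(raw.get("rng_seed", 0)),
            schema_version=int(raw.get("schema_version", 1)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, p in [("counts", self.counts), ("metadata", self.metadata), ("gmt", self.gmt)]:
            if p is None:
                raise PipelineError(f"config: missing required path {label!r}")
            if not Path(p).exists():
                raise PipelineError(f"config: {label} file not found: {p}")
        if not self.edge_lists:
            raise PipelineError("config: at least one edge list required")
        for e in self.edge_lists:
            if not Path(e).exists():
                raise PipelineError(f"config: edge list not found: {e}")
        if self.universe is not None and not Path(self.universe).exists():
            raise PipelineError(f"config: universe file not found: {self.universe}")
        if not self.contrasts:
            raise PipelineError("config: at least one contrast required")
        names = [c.name for c in self.contrasts]
        if len(set(names)) != len(names):
            raise PipelineError("config: contrast names must be unique")
        for a, b in self.comparisons:
            for side in (a, b):
                if side not in names:
                    raise PipelineError(f"config: comparison references unknown contrast {side!r}")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "rng_seed": self.rng_seed,
            "paths": {
                "counts": str(self.counts),
                "metadata": str(self.metadata),
                "edge_lists": [str(e) for e in self.edge_lists],
                "gmt": str(self.gmt),
                "universe": None if self.universe is None else str(self.universe),
            },
            "module_null": {
                "n_samples": self.null_n_samples,
                "swaps_per_edge": self.null_swaps_per_edge,
                "randomize_network": self.null_randomize_network,
            },
            "contrasts": [
                {
                    "name": c.name,
                    "group_a": dict(c.group_a),
                    "group_b": dict(c.group_b),
                    "paired": c.paired,
                    "fc_cutoff": c.fc_cutoff,
                    "p_cutoff": c.p_cutoff,
                    "direction_filter": c.direction_filter,
                    "enrichment_mode": c.enrichment_mode,
                    "de_table": c.de_table,
                }
                for c in self.contrasts
            ],
            "comparisons": [list(pair) for pair in self.comparisons],
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_groups(cfg: PipelineConfig, meta: pd.DataFrame) -> None:
    """Fail before any compute when a contrast group matches zero samples."""
    for c in cfg.contrasts:
        for label, query in (("group_a", c.group_a), ("group_b", c.group_b)):
            mask = pd.Series(True, index=meta.index)
            for col, val in query.items():
                if col not in meta.columns:
                    raise PipelineError(
                        f"contrast {c.name!r}: unknown metadata column {col!r} in {label}"
                    )
                mask &= meta[col].astype(str) == str(val)
            if not mask.any():
                raise PipelineError(
                    f"contrast {c.name!r}: {label} matches zero samples: {dict(query)}"
                )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured workflow; returns the run manifest (also
    written to ``manifest.json``).

    Per contrast the outputs are ``de_<name>.tsv``, ``module_<name>.json``
    + ``.tsv`` and ``enrichment_<name>.tsv``; per comparison
    ``overlap_<a>_<b>.tsv``/``.json``.  A stage failure aborts the run,
    preserving partial outputs and a manifest marked failed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("ppimod").addHandler(log_handler)

    manifest: dict[str, Any] = {
        "software": {"name": "ppimod", "version": __version__},
        "config": cfg.to_dict(),
        "stages": {},
        "checksums": {},
    }
    stage = "setup"
    try:
        records = []
        for edge_path in cfg.edge_lists:
            records.extend(read_edge_list(edge_path))
        interactome = assemble_interactome(records)
        counts = read_counts(cfg.counts)
        meta = read_sample_meta(cfg.metadata)
        _validate_groups(cfg, meta)
        collection = read_gmt(cfg.gmt)
        if cfg.universe is not None:
            collection = collection.restrict(read_universe(cfg.universe))
        else:
            # default universe: measured genes that the collection annotates
            collection = collection.restrict(set(counts.index) & collection.universe)
        manifest["stages"]["setup"] = "ok"

        modules: dict[str, frozenset[str]] = {}
        for contrast in cfg.contrasts:
            stage = f"de:{contrast.name}"
            if contrast.de_table:
                de = read_de_table(contrast.de_table)
            else:
                de = differential_expression(
                    counts, meta, contrast.group_a, contrast.group_b, paired=contrast.paired
                )
            de_path = out / f"de_{contrast.name}.tsv"
            write_de_table(de, de_path)
            manifest["stages"][stage] = "ok"

            stage = f"module:{contrast.name}"
            seeds = select_seeds(
                de, contrast.fc_cutoff, contrast.p_cutoff, contrast.direction_filter
            )
            module = module_significance(
                interactome,
                seeds,
                n_samples=cfg.null_n_samples,
                swaps_per_edge=cfg.null_swaps_per_edge,
                rng_seed=derive_seed(cfg.rng_seed, f"module:{contrast.name}"),
                randomize_network=cfg.null_randomize_network,
                provenance={"contrast": contrast.name},
            )
            module.write_json(out / f"module_{contrast.name}.json")
            module.write_gene_list(out / f"module_{contrast.name}.tsv")
            modules[contrast.name] = module.members
            manifest["stages"][stage] = "ok"

            stage = f"enrichment:{contrast.name}"
            sig = de[de["p"] <= contrast.p_cutoff]
            report = enrich_direction_split(
                sig, collection, mode=contrast.enrichment_mode, fc_cutoff=contrast.fc_cutoff
            )
            write_report(report, out / f"enrichment_{contrast.name}.tsv")
            manifest["stages"][stage] = "ok"

        universe = set(interactome.nodes)
        for a, b in cfg.comparisons:
            stage = f"overlap:{a}:{b}"
            result = overlap_test(modules[a], modules[b], universe, name_a=a, name_b=b)
            result.write_tsv(out / f"overlap_{a}_{b}.tsv")
            result.write_json(out / f"overlap_{a}_{b}.json")
            manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        manifest["failed"] = stage
        _finalize_manifest(manifest, out)
        logging.getLogger("ppimod").removeHandler(log_handler)
        log_handler.close()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _finalize_manifest(manifest, out)
    logging.getLogger("ppimod").removeHandler(log_handler)
    log_handler.close()
    return manifest


def _finalize_manifest(manifest: dict, out: Path) -> None:
    for path in sorted(out.iterdir()):
        if path.name in {"manifest.json", "run.log"} or path.is_dir():
            continue
        manifest["checksums"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
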