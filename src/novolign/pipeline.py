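"""Full-pipeline orchestration: prepare -> align -> LCA -> compose -> QC.

A single :class:`RunConfig` carries every stage's parameter block; each run
writes its resolved configuration, a manifest with per-stage counts, and
all stage outputs into one directory, so results are reproducible from the
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aligner import (
    AlignParams,
    align_all,
    build_reference_db,
    filter_hits,
    parse_hits,
    run_diamond,
    write_hits_tsv,
)
from .composition import CompositionParams, compose, write_composition_tsv
from .denovo_io import FilterConfig, filter_denovo, make_decoys, read_denovo, write_query_fasta
from .qc import spectral_qc
from .taxonomy import LcaParams, assign_lca, load_taxdump, write_lca_tsv

logger = logging.getLogger(__name__)

DEFAULT_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serializable to YAML)."""

    denovo_path: str = ""
    reference_fasta: str = ""
    taxdump: str = ""
    out_dir: str = "novolign_out"
    engine: str = "internal"  # or "diamond"
    dialect: str = "auto"
    seed: int = 1
    ranks: tuple[str, ...] = DEFAULT_RANKS
    filters: FilterConfig = field(default_factory=FilterConfig)
    align: AlignParams = field(default_factory=AlignParams)
    lca: LcaParams = field(default_factory=LcaParams)
    composition: CompositionParams = field(default_factory=CompositionParams)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("filters", FilterConfig),
            ("align", AlignParams),
            ("lca", LcaParams),
            ("composition", CompositionParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; outputs and a manifest land in ``config.out_dir``.

    A stage failure aborts with the stage name; outputs of completed stages
    are preserved in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "engine": config.engine,
        "counts": {},
        "timings_s": {},
    }
    rng = np.random.default_rng(config.seed)

    def _stage(name):
        def deco(fn):
            t0 = time.monotonic()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                _write_manifest(out, manifest)
                raise StageError(name, exc) from exc
            manifest["timings_s"][name] = round(time.monotonic() - t0, 3)
            return result

        return deco

    # --- prepare ---------------------------------------------------------
    def prepare():
        records = read_denovo(config.denovo_path, dialect=config.dialect)
        manifest["counts"]["parsed"] = len(records)
        kept = filter_denovo(records, config.filters)
        manifest["counts"]["filtered"] = len(kept)
        if not kept:
            raise ValueError("no records pass the de novo filters")
        decoys = make_decoys(kept, rng)
        write_query_fasta(kept, decoys, out / "queries.fasta")
        return kept, decoys

    records, decoys = _stage("prepare")(prepare)

    # --- align -----------------------------------------------------------
    def align():
        db = build_reference_db(config.reference_fasta)
        if config.engine == "diamond":
            run_diamond(out / "queries.fasta", config.reference_fasta, out / "hits.tsv", config.align)
            hits = parse_hits(out / "hits.tsv", db.taxid_map)
        else:
            queries = [(r.query_id, r.peptide) for r in records + decoys]
            hits = align_all(queries, db, config.align)
            write_hits_tsv(hits, out / "hits.tsv")
        manifest["counts"]["hits"] = len(hits)
        manifest["counts"]["aligned_queries"] = len(
            {h.query_id for h in hits if not h.is_decoy_query}
        )
        return db, hits

    db, hits = _stage("align")(align)

    # --- lca -------------------------------------------------------------
    def lca():
        if not config.taxdump:
            raise FileNotFoundError(
                "no taxdump configured; supply nodes.dmp/names.dmp or a lineage table"
            )
        tree = load_taxdump(config.taxdump)
        kept = filter_hits(hits, config.lca.min_bitscore)
        manifest["counts"]["hits_after_bitscore"] = len(kept)
        results = {}
        for method in ("CON", "W", "BIT"):
            params = dataclasses.replace(config.lca, method=method)
            res = assign_lca(kept, params, tree)
            write_lca_tsv(res, out / f"lca_{method}.tsv")
            results[method] = res
        chosen = results[config.lca.method]
        manifest["counts"]["classified_queries"] = sum(
            1
            for r in chosen
            if not r.is_decoy_query and not r.lineage.is_empty()
        )
        return tree, results

    tree, lca_results = _stage("lca")(lca)

    # --- compose ---------------------------------------------------------
    def compose_stage():
        tables = {}
        for method, res in lca_results.items():
            for rank in config.ranks:
                params = dataclasses.replace(config.composition, rank=rank)
                table = compose(
                    res,
                    params,
                    n_target_queries=len(records),
                    n_decoy_queries=len(decoys),
                )
                write_composition_tsv(table, out / f"composition_{method}_{rank}.tsv")
                tables[(method, rank)] = table
        chosen = tables[(config.lca.method, config.composition.rank)]
        manifest["counts"]["reported_taxa"] = int(
            (chosen.rows["taxon"] != "other").sum()
        )
        manifest["decoy_match_rate"] = chosen.decoy_match_rate
        return tables

    tables = _stage("compose")(compose_stage)

    # --- qc --------------------------------------------------------------
    def qc_stage():
        qc_records = spectral_qc(records, filter_hits(hits, config.lca.min_bitscore))
        import pandas as pd

        pd.DataFrame(
            {
                "query_id": [r.query_id for r in qc_records],
                "category": [r.category for r in qc_records],
                "score": [r.score for r in qc_records],
                "db_status": [r.db_status for r in qc_records],
            }
        ).to_csv(out / "spectral_qc.tsv", sep="\t", index=False)
        return qc_records

    _stage("qc")(qc_stage)

    _write_manifest(out, manifest)
    logger.info("pipeline complete: %s", out)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
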