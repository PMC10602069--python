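"""End-to-end orchestration: preprocess -> pseudobulk -> screen -> enrich.

Every stage writes its CSV outputs into the run directory as it completes,
so a failed run keeps its partial results; a JSON manifest records package
and library versions, the seed, the full configuration, and the filter log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, io
from .config import PipelineConfig
from .enrich import run_enrichment
from .exceptions import BfhdeError, PipelineError
from .priors import gene_prior_source
from .pseudobulk import aggregate_weighted, filter_cells, filter_genes
from .screen import screen_genes

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _load_counts(cfg: PipelineConfig):
    p = Path(cfg.counts_path)
    if p.is_dir():
        return io.read_counts_mtx(p)
    return io.read_counts_csv(p)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "preprocess"
    try:
        if not cfg.counts_path or not cfg.metadata_path or not cfg.phenotype_path:
            raise BfhdeError("counts_path, metadata_path and phenotype_path are required")
        counts, gene_ids, cell_ids = _load_counts(cfg)
        meta = io.read_cell_metadata(cfg.metadata_path)
        pheno = io.read_phenotypes(cfg.phenotype_path)
        ds = io.build_cell_dataset(counts, gene_ids, cell_ids, meta, mito_prefix=cfg.mito_prefix)
        steps = (
            (filter_genes, dict(threshold=cfg.gene_mean_min)),
            (filter_cells, dict(mito_max=cfg.mito_max, detected_pct=cfg.detected_pct)),
        )
        for fn, kw in steps if cfg.gene_filter_first else reversed(steps):
            ds = fn(ds, **kw)
        logger.info("preprocess: %d genes x %d cells retained", ds.n_genes, ds.n_cells)

        stage = "pseudobulk"
        pb = aggregate_weighted(ds).attach_groups(pheno)
        io.write_pseudobulk(pb, out / "pseudobulk_Y.csv", out / "pseudobulk_donors.csv")

        stage = "screen"
        priors = None
        if cfg.bulk_prior_path:
            bulk = io.read_bulk_prior_table(cfg.bulk_prior_path)
            priors = gene_prior_source(bulk, p=3 if pb.x2 is not None else 2, bayes_index=1)
        result = screen_genes(
            pb,
            method=cfg.method,
            priors=priors,
            alpha=cfg.alpha,
            effect_min=cfg.effect_min,
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
        )
        io.write_screen_result(result, out / "screen.csv")
        logger.info("screen: %d/%d genes selected", len(result.selected_genes), result.n_genes)

        stage = "enrich"
        if cfg.gene_sets_path:
            gene_sets = io.read_gmt(cfg.gene_sets_path)
            enr = run_enrichment(
                result.selected_genes, gene_sets, result.tested_genes, q_max=cfg.q_max
            )
            io.write_enrichment(enr, out / "enrichment.csv")
            logger.info("enrich: %d pathway(s) below q=%g", len(enr), cfg.q_max)

        stage = "manifest"
        manifest = {
            "bfhde_version": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "filter_log": pb.filter_log,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    return out
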