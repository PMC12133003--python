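"""End-to-end orchestration: simulate/ingest → select → stats → validate → structure.

A run writes every module's tabular outputs plus a ``run_report.json``
capturing versions, the exact configuration applied, per-stage wall-clock
and a file manifest — enough to re-run deterministic stages bit-identically.

One global seed fans out to per-stage seeds (stage name hashed with
CRC-32), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_selection import ConsensusMatrix, CoreSelection, FilterParams, select_core
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    VarietyAssignment,
    read_variety_map,
    read_vcf,
    write_vcf,
)
from .popgen_stats import locus_stats_table, snp_density, summarize_panel
from .similarity import pairwise_similarity, similarity_correlation
from .structure import bootstrap_support, cv_choose_k, newick_with_support, pca
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger("corepanel")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "heatmap_export",
           "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed: global seed folded with a CRC-32 of the stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one input source: either ``vcf``+``varieties`` paths or a
    ``simulation`` config (the bundled generator).
    """

    outdir: Path
    vcf: Path | None = None
    varieties: Path | None = None
    simulation: SimulationConfig | None = None
    filter_params: FilterParams = dataclasses.field(default_factory=FilterParams)
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    cv_folds: int = 5
    bootstrap: int = 200
    n_restarts: int = 8
    max_structure_loci: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        has_files = self.vcf is not None or self.varieties is not None
        if has_files and self.simulation is not None:
            raise ValueError("give input paths or a simulation config, not both")
        if not has_files and self.simulation is None:
            raise ValueError("either input paths or a simulation config is required")
        if has_files and (self.vcf is None or self.varieties is None):
            raise ValueError("both a VCF and a cultivar map are required")

    def echo(self) -> dict:
        d: dict = {
            "outdir": str(self.outdir),
            "vcf": str(self.vcf) if self.vcf else None,
            "varieties": str(self.varieties) if self.varieties else None,
            "simulation": dataclasses.asdict(self.simulation) if self.simulation else None,
            "filter_params": self.filter_params.to_dict(),
            "k_range": list(self.k_range),
            "cv_folds": self.cv_folds,
            "bootstrap": self.bootstrap,
            "n_restarts": self.n_restarts,
            "max_structure_loci": self.max_structure_loci,
            "seed": self.seed,
        }
        return d


@dataclasses.dataclass
class RunReport:
    """Machine-readable record of a completed run."""

    version: str
    config: dict
    filter_stages: list[dict]
    panel_summary: dict
    correlation: dict | None
    best_k: int | None
    cv_errors: dict | None
    manifest: dict[str, str]
    timings: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


_HET_EXPORT = True


def heatmap_export(panel: ConsensusMatrix | GenotypeMatrix, path: str | Path | None = None
                   ) -> pd.DataFrame:
    """Loci × samples genotype-character table (the data behind a panel heatmap).

    Alphabet: homozygotes as the doubled base (``AA``/``CC``/``GG``/``TT``),
    heterozygotes flagged as the ref+alt pair (two distinct bases), missing
    as an empty cell.
    """
    if isinstance(panel, GenotypeMatrix):
        geno, cols, loci = panel.genotypes, panel.samples, panel.loci
    else:
        geno, cols, loci = panel.genotypes, panel.varieties, panel.loci
    if geno.shape[1] == 0:
        raise ValueError("cannot export an empty panel")
    rows = []
    for j, loc in enumerate(loci):
        ref, alt = loc.ref, loc.alt[0]
        text = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: ""}
        rows.append([text[int(c)] for c in geno[:, j]])
    df = pd.DataFrame(rows, columns=list(cols),
                      index=[loc.id for loc in loci])
    df.index.name = "locus"
    if path is not None:
        df.to_csv(path, sep="\t")
    return df


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order, writing all outputs under ``cfg.outdir``."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    timings: dict[str, float] = {}

    def note(key: str, path: Path) -> None:
        manifest[key] = str(path)

    # ---- input -----------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.simulation is not None:
        sim_cfg = dataclasses.replace(
            cfg.simulation, seed=derive_seed(cfg.seed, "simulate")
        ) if cfg.simulation.seed == 0 else cfg.simulation
        gm, varieties, truth = simulate(sim_cfg)
        note("input_vcf", write_vcf(gm, out / "genotypes.vcf"))
        note("truth", truth.to_json(out / "truth.json"))
        from .genotype_io import write_variety_map
        note("varieties", write_variety_map(varieties, out / "varieties.tsv"))
    else:
        gm = read_vcf(cfg.vcf)
        varieties = read_variety_map(cfg.varieties)
        varieties.require_complete(gm.samples)
    timings["input"] = time.perf_counter() - t0
    logger.info("input: %d samples x %d loci", gm.n_samples, gm.n_loci)

    # ---- core selection --------------------------------------------------
    t0 = time.perf_counter()
    logger.info("filter thresholds: %s", cfg.filter_params.to_dict())
    sel = select_core(gm, varieties, cfg.filter_params)
    note("core_vcf", write_vcf(sel.core_genotypes, out / "core.vcf"))
    note("consensus", _write_tsv(sel.consensus.to_frame(), out / "consensus.tsv"))
    note("filter_report", _write_tsv(sel.report.to_frame(), out / "filter_report.tsv"))
    sel.report.to_json(out / "filter_report.json")
    note("filter_report_json", out / "filter_report.json")
    heatmap_path = None
    if sel.consensus.n_loci:
        heatmap_export(sel.core_genotypes, out / "core_heatmap.tsv")
        note("core_heatmap", out / "core_heatmap.tsv")
    timings["select"] = time.perf_counter() - t0
    if not sel.core_indices:
        logger.warning("empty core panel after the cascade")

    # ---- summary statistics ---------------------------------------------
    t0 = time.perf_counter()
    total_stats = locus_stats_table(sel.total.genotypes, sel.total.loci)
    note("total_stats", _write_tsv(total_stats, out / "total_locus_stats.tsv"))
    note("total_summary", _write_tsv(
        summarize_panel(total_stats).round(3), out / "total_summary.tsv", index=True))
    note("total_density", _write_tsv(
        snp_density(sel.total.loci), out / "total_density.tsv"))
    panel_summary: dict = {}
    if sel.consensus.n_loci:
        core_stats = locus_stats_table(sel.consensus.genotypes, sel.consensus.loci)
        note("core_stats", _write_tsv(core_stats, out / "core_locus_stats.tsv"))
        core_sum = summarize_panel(core_stats)
        note("core_summary", _write_tsv(core_sum.round(3), out / "core_summary.tsv",
                                        index=True))
        note("core_density", _write_tsv(
            snp_density([sel.total.loci[i] for i in sel.core_indices]),
            out / "core_density.tsv"))
        panel_summary = {
            stat: {k: round(float(v), 3) for k, v in row.items()}
            for stat, row in core_sum.iterrows()
        }
    timings["stats"] = time.perf_counter() - t0

    # ---- similarity validation ------------------------------------------
    t0 = time.perf_counter()
    correlation = None
    if sel.core_indices and sel.total.n_loci:
        total_sim = pairwise_similarity(sel.total)
        core_sim = pairwise_similarity(sel.total, sel.core_indices)
        note("pair_table", _write_tsv(
            total_sim.pair_table().rename(columns={"similarity": "total_sim"})
            .assign(core_sim=core_sim.pair_table()["similarity"]),
            out / "similarity_pairs.tsv"))
        note("total_similarity", _write_tsv(total_sim.to_frame(),
                                            out / "total_similarity.tsv", index=True))
        note("core_similarity", _write_tsv(core_sim.to_frame(),
                                           out / "core_similarity.tsv", index=True))
        corr = similarity_correlation(total_sim, core_sim)
        corr.to_json(out / "similarity_correlation.json")
        note("correlation", out / "similarity_correlation.json")
        correlation = dataclasses.asdict(corr)
    timings["validate"] = time.perf_counter() - t0

    # ---- structure -------------------------------------------------------
    t0 = time.perf_counter()
    best_k = None
    cv_errors = None
    if cfg.k_range and sel.core_indices:
        core_gm = sel.core_genotypes
        if core_gm.n_loci > cfg.max_structure_loci:
            rng = np.random.default_rng(derive_seed(cfg.seed, "structure_subset"))
            pick = np.sort(rng.choice(core_gm.n_loci, cfg.max_structure_loci,
                                      replace=False))
            core_gm = core_gm.subset_loci(pick)
        tree, _ = bootstrap_support(core_gm, b=cfg.bootstrap,
                                    seed=derive_seed(cfg.seed, "bootstrap"))
        (out / "core_nj.nwk").write_text(newick_with_support(tree) + "\n")
        note("nj_tree", out / "core_nj.nwk")
        pca_res = pca(core_gm)
        note("pca", _write_tsv(pca_res.to_frame().round(6), out / "core_pca.tsv"))
        cv = cv_choose_k(core_gm, cfg.k_range, folds=cfg.cv_folds,
                         seed=derive_seed(cfg.seed, "cv"),
                         n_restarts=cfg.n_restarts)
        note("cv_errors", _write_tsv(cv.to_frame(), out / "cv_errors.tsv"))
        best_k, cv_errors = cv.best_k, {str(k): v for k, v in cv.errors.items()}
        from .structure import AdmixtureModel
        fit = AdmixtureModel(core_gm, best_k).fit(
            seed=derive_seed(cfg.seed, "admixture"), n_restarts=cfg.n_restarts)
        note("q_matrix", _write_tsv(fit.q_frame().round(6), out / "admixture_Q.tsv"))
    else:
        logger.info("structure stage skipped (empty k_range or empty panel)")
    timings["structure"] = time.perf_counter() - t0

    report = RunReport(
        version=__version__,
        config=cfg.echo(),
        filter_stages=[
            {"stage": s, "loci_in": a, "loci_removed": b, "loci_out": c}
            for s, a, b, c in sel.report.stages
        ],
        panel_summary=panel_summary,
        correlation=correlation,
        best_k=best_k,
        cv_errors=cv_errors,
        manifest=manifest,
        timings={k: round(v, 3) for k, v in timings.items()},
    )
    report.to_json(out / "run_report.json")
    return report
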