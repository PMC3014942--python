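"""End-to-end orchestration: simulate/ingest -> map -> score -> survival.

Each stage reads and writes the package's standard formats, so a run
leaves a fully re-parseable report bundle plus a provenance file
(package and library versions, seed, config echo) sufficient to
reproduce every report byte-for-byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, genome_coords, io, simulate, survival, targeting
from .intervals import ValidationError
from .targeting import GeneUniverse

logger = logging.getLogger(__name__)


def _provenance(config: io.RunConfig) -> dict:
    import lifelines
    import pandas
    import scipy

    return {
        "cnapath": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "lifelines": lifelines.__version__,
        "seed": config.seed,
        "config": __import__("dataclasses").asdict(config),
    }


def map_coordinates(
    bacs, genes, segments, mode: str = "extended"
):
    """Resolve overlaps, expand, extend, associate, and overlay segments."""
    genome_coords.resolve_bac_overlaps(bacs)
    genome_coords.expand_bacs(bacs)
    genome_coords.extend_bacs(bacs)
    gene_bac = genome_coords.assign_genes_to_bacs(genes, bacs, mode=mode)
    return genome_coords.genes_in_altered_segments(
        segments, genes, gene_bac_map=gene_bac, bacs=bacs, mode=mode
    )


def run_pipeline(config: io.RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns paths of written reports.

    Any stage failure aborts with the stage named in the raised error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        sim_cfg = None
        if config.simulate or not (config.matrix or config.segments):
            stage = "simulate"
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim_cfg = simulate.SimulationConfig(**sim_kwargs)
            rng = sim_cfg.rng()
            pathways = simulate.make_pathways(sim_cfg, rng)
            matrix, pathways = simulate.make_cna_cohort(sim_cfg, pathways, rng)
            io.write_gmt(pathways, out / "pathways.gmt")
            io.write_alteration_matrix(matrix, out / "matrix.tsv")
            written["pathways"] = out / "pathways.gmt"
            written["matrix"] = out / "matrix.tsv"
        else:
            stage = "ingest"
            pathways = io.read_gmt(config.gmt)
            if config.matrix:
                matrix = io.read_alteration_matrix(config.matrix)
            else:
                stage = "map-coords"
                bacs = io.read_bacs_bed(config.bacs)
                genes = io.read_genes_bed(config.genes)
                segments = io.read_segments(config.segments)
                matrix = map_coordinates(bacs, genes, segments, mode=config.coord_mode)
                io.write_alteration_matrix(matrix, out / "matrix.tsv")
                written["matrix"] = out / "matrix.tsv"

        stage = "score"
        if config.universe:
            with open(config.universe, encoding="utf-8") as fh:
                universe = GeneUniverse(frozenset(line.strip() for line in fh if line.strip()))
        else:
            universe = GeneUniverse(frozenset(matrix.index))
        results = targeting.score_all_pathways(
            matrix,
            pathways,
            universe=universe,
            hit_definition=config.hit_definition,
            tail=config.tail,
            df_mode=config.df_mode,
            alpha=config.alpha,
        )
        io.write_targeting_report(results, out / "targeting_report.tsv")
        io.write_per_sample_report(results, out / "per_sample_pvalues.tsv")
        written["targeting_report"] = out / "targeting_report.tsv"
        written["per_sample_pvalues"] = out / "per_sample_pvalues.tsv"

        if config.run_survival:
            stage = "survival"
            if config.scores and config.clinical:
                scores = io.read_score_matrix(config.scores)
                clinical = io.read_survival_table(config.clinical)
            elif sim_cfg is not None:
                # synthetic survival driven by the top-ranked pathway's state
                top = targeting.results_to_frame(results).iloc[0]["pathway_id"]
                pw = next(p for p in pathways if p.pathway_id == top)
                labels = simulate.planted_sample_labels(matrix, pw)
                rng2 = np.random.default_rng(sim_cfg.seed + 1)
                clinical = simulate.make_survival(
                    labels, sim_cfg, rng2, sample_ids=list(matrix.columns)
                )
                scores = simulate.make_score_matrix(
                    pathways[: min(10, len(pathways))],
                    {top: labels},
                    sim_cfg.n_samples,
                    rng=rng2,
                )
                clinical.to_csv(out / "clinical.tsv", sep="\t", index=False,
                                lineterminator="\n")
                written["clinical"] = out / "clinical.tsv"
            else:
                scores = clinical = None
            if scores is not None:
                report = survival.survival_screen(
                    scores,
                    clinical,
                    method=config.stratify_method,
                    alpha=config.alpha,
                    seed=config.seed,
                )
                io.write_survival_report(report, out / "survival_report.tsv")
                written["survival_report"] = out / "survival_report.tsv"

        stage = "provenance"
        with open(out / "provenance.yaml", "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(_provenance(config), fh, sort_keys=True)
        written["provenance"] = out / "provenance.yaml"
    except ValidationError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return written
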