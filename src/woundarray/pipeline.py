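"""End-to-end orchestration: simulate/load → preprocess → DE → sets →
templates → positional clusters → GO enrichment, with a run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as wio
from . import ontology as onto
from .config import PipelineConfig
from .core import DesignTable, ExpressionMatrix
from .differential import (
    CONTRASTS,
    estimate_prior,
    fit_gene_models,
    log_odds,
    moderated_t,
    select_genes,
)
from .positional import (
    assign_coordinates,
    characterize_clusters,
    chromosome_enrichment,
    expected_clusters,
    find_positional_clusters,
)
from .preprocess import nonspecific_filter, quantile_normalize
from .set_logic import build_membership, classify_subsets, extract_sets, sign_patterns
from .synthetic import generate_annotation, generate_expression, generate_ontology
from .templates import assign_clusters, prefilter_for_templates

log = logging.getLogger("woundarray")

ALL_STAGES = ("simulate", "preprocess", "de", "sets", "templates", "clusters", "go")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict:
    """Run the requested stages and return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _parameters(config), "counts": {}, "stages": []}
    counts = manifest["counts"]

    truth = None
    annotation = None
    graph = None
    annot_map = None

    # ---- inputs -----------------------------------------------------------
    try:
        if config.expression:
            matrix, design = wio.read_expression_table(
                config.expression, config.design, scale="linear"
            )
        else:
            syn = config.synthetic
            syn.seed = config.seed
            matrix, design, truth = generate_expression(syn)
            annotation, truth = generate_annotation(syn, truth)
            graph, annot_map = generate_ontology(syn, truth)
            if "simulate" in stages:
                wio.write_expression(matrix, outdir / "expression.tsv")
                wio.write_design(design, outdir / "design.tsv")
                wio.write_bed(annotation, outdir / "annotation.bed")
                onto.write_obo(graph, outdir / "ontology.obo")
                onto.write_gaf(annot_map.table, outdir / "annotations.gaf.tsv")
                truth.to_csv(outdir / "truth.tsv", sep="\t")
                manifest["stages"].append("simulate")
        if config.annotation:
            annotation = wio.read_gene_annotation(
                config.annotation, config.annotation_format
            )
        if config.obo:
            graph = onto.read_obo(config.obo)
        if config.gaf:
            from .synthetic import AnnotationMap

            annot_map = AnnotationMap(table=onto.read_gaf(config.gaf))
        counts["input_genes"] = matrix.shape[0]
        counts["input_samples"] = matrix.shape[1]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("input", exc) from exc

    # ---- preprocess -------------------------------------------------------
    try:
        filtered = nonspecific_filter(
            matrix, config.min_intensity, config.min_frac, config.iqr_percentile
        )
        log.info(
            "%d probe sets, out of %d passed the non-specific filter",
            filtered.n_kept,
            matrix.shape[0],
        )
        normalized = quantile_normalize(filtered.matrix.to_log2(pseudo=0.0))
        counts["filtered_genes"] = filtered.n_kept
        counts["removed_genes"] = filtered.n_removed
        if "preprocess" in stages:
            wio.write_expression(normalized, outdir / "normalized.tsv")
            manifest["stages"].append("preprocess")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", exc) from exc

    # ---- differential -----------------------------------------------------
    try:
        fits = fit_gene_models(normalized, design)
        params = estimate_prior(fits)
        tables = {name: moderated_t(fits, params, name) for name in CONTRASTS}
        for name in ("W", "NW", "D"):
            tables[name]["B"] = log_odds(fits, params, name)
        counts["prior_df"] = params.d0
        counts["prior_var"] = params.s0_sq
        for name in ("W", "NW", "D"):
            sel = select_genes(
                tables[name], config.fc_cut, config.alpha, config.use_adjusted
            )
            counts[f"selected_{name}"] = len(sel)
        if "de" in stages:
            for name, table in tables.items():
                safe = name.replace("+", "pos").replace("-", "neg")
                table.to_csv(outdir / f"contrast_{safe}.tsv", sep="\t")
            manifest["stages"].append("de")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", exc) from exc

    # ---- set logic --------------------------------------------------------
    try:
        membership = build_membership(
            tables, config.fc_cut, config.alpha, config.use_adjusted
        )
        signs = sign_patterns(
            tables, config.fc_cut, config.alpha, config.use_adjusted
        )
        wo, wnwd = extract_sets(membership)
        subsets = classify_subsets(membership, signs)
        counts["WO"] = len(wo)
        counts["WNWD"] = len(wnwd)
        counts["venn_regions"] = (
            membership[membership["venn_region"] != "none"]["venn_region"]
            .nunique()
        )
        if "sets" in stages:
            out = membership.join(subsets, how="left")
            out.to_csv(outdir / "membership.tsv", sep="\t")
            manifest["stages"].append("sets")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sets", exc) from exc

    # ---- template clustering ---------------------------------------------
    try:
        candidates = prefilter_for_templates(
            {k: tables[k] for k in ("W", "NW", "D")}, config.template_alpha
        )
        assignments = assign_clusters(
            fits.means,
            genes=candidates,
            r2_threshold=config.r2_threshold,
            flat_eps=config.flat_eps,
        )
        assigned = assignments[assignments["template"] != ""]
        counts["template_candidates"] = len(candidates)
        counts["template_assigned"] = len(assigned)
        counts["template_clusters"] = assigned["template"].nunique()
        if "templates" in stages:
            assignments.to_csv(outdir / "templates.tsv", sep="\t")
            manifest["stages"].append("templates")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("templates", exc) from exc

    # ---- positional clustering -------------------------------------------
    if annotation is None:
        log.info("positional stage skipped: no gene annotation available")
        counts["positional_skipped"] = "no annotation"
    else:
        try:
            directed = select_genes(
                tables["W"], config.cluster_fc, config.alpha, config.use_adjusted
            )
            loci, unmapped = assign_coordinates(directed.index, annotation)
            counts["unmapped_genes"] = len(unmapped)
            mapped = directed.loc[[g for g in directed.index if g not in set(unmapped)]]
            arm_stats = chromosome_enrichment(
                set(mapped.index),
                loci,
                n_rand=config.n_rand_chromosome,
                seed=config.seed,
            )
            clusters = find_positional_clusters(
                mapped, loci, config.min_de, config.window_genes
            )
            null = expected_clusters(
                mapped,
                loci,
                config.min_de,
                config.window_genes,
                n_rand=config.n_rand_clusters,
                seed=config.seed,
            )
            counts["positional_clusters"] = len(clusters)
            counts["positional_null_mean"] = null["null_mean"]
            counts["positional_p"] = null["p_empirical"]
            if "clusters" in stages:
                arm_stats.to_csv(outdir / "arm_enrichment.tsv", sep="\t")
                rows = [
                    {
                        "arm": c.arm,
                        "direction": c.direction,
                        "n_genes": len(c.genes),
                        "span_start": c.span[0],
                        "span_end": c.span[1],
                        "window_gene_count": c.window_gene_count,
                        "genes": ",".join(c.genes),
                    }
                    for c in clusters
                ]
                pd.DataFrame(
                    rows,
                    columns=[
                        "arm", "direction", "n_genes", "span_start",
                        "span_end", "window_gene_count", "genes",
                    ],
                ).to_csv(outdir / "positional_clusters.tsv", sep="\t", index=False)
                pd.DataFrame({"null_count": null["null"]}).to_csv(
                    outdir / "positional_null.tsv", sep="\t", index=False
                )
                if clusters:
                    characterize_clusters(clusters, loci).to_csv(
                        outdir / "cluster_characteristics.tsv", sep="\t"
                    )
                manifest["stages"].append("clusters")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("clusters", exc) from exc

    # ---- GO enrichment ----------------------------------------------------
    if graph is None or annot_map is None:
        log.info("GO stage skipped: no ontology/annotations available")
        counts["go_skipped"] = "no ontology"
    else:
        try:
            term_genes = onto.project_annotations(
                annot_map.table, graph,
                namespace=config.go_namespace, level=config.go_level,
            )
            universe = set().union(*term_genes.values()) if term_genes else set()
            results = {}
            for name, gene_set in (("WO", set(wo)), ("WNWD", set(wnwd))):
                subset = gene_set & universe
                res = onto.hypergeometric_enrichment(
                    subset, universe, term_genes, graph, alpha=config.go_alpha
                ) if subset else pd.DataFrame()
                results[name] = res
                counts[f"go_enriched_{name}"] = len(res)
            counts["go_universe"] = len(universe)
            if "go" in stages:
                for name, res in results.items():
                    res.to_csv(outdir / f"go_{name}.tsv", sep="\t", index=False)
                manifest["stages"].append("go")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("go", exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _parameters(config: PipelineConfig) -> dict:
    params = asdict(config)
    params["synthetic"]["conditions"] = list(params["synthetic"]["conditions"])
    params["synthetic"]["fc_range"] = list(params["synthetic"]["fc_range"])
    return params
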