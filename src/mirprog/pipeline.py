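"""End-to-end orchestration: quantify -> dynamics -> network -> enrichment -> FRP.

Every stage writes its artifact into a run directory stamped with the
config digest and seed; a rerun with the same config and inputs is
bit-identical.  Stages only append to the run directory, never rewrite
another stage's output.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import dynamics, frp, io, network, quantify
from .config import PipelineConfig
from .enrichment import singular_enrichment
from .quantify import CountMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    outdir: Path
    de_mirna: pd.DataFrame
    de_mrna: pd.DataFrame
    mirna_profiles: pd.DataFrame
    mrna_profiles: pd.DataFrame
    filtered: pd.DataFrame
    stage_edges: dict
    trend_edges: pd.DataFrame
    enrichment: dict
    frps: dict


def _correlation_matrices(config, mirna_counts, mrna_counts, mirna_norm, mrna_norm):
    if config.correlation_source == "normalized":
        return mirna_norm, mrna_norm
    if config.correlation_source == "rpkm":
        return quantify.rpkm(mirna_counts), quantify.rpkm(mrna_counts)
    # mixed: normalized counts for miRNAs, RPKM for mRNAs
    if mrna_counts.feature_lengths is None:
        logger.warning("no mRNA lengths; using normalized counts instead of RPKM")
        return mirna_norm, mrna_norm
    return mirna_norm, quantify.rpkm(mrna_counts)


def run_pipeline(
    config: PipelineConfig,
    outdir,
    mirna_counts: CountMatrix | None = None,
    mrna_counts: CountMatrix | None = None,
    candidates: pd.DataFrame | None = None,
    annotations: dict | None = None,
    background: set | None = None,
) -> PipelineResult:
    """Run the full inference chain and write its artifacts.

    Inputs may be passed in memory or read from the paths in
    ``config.inputs`` (keys: mirna_counts, mirna_meta, mrna_counts,
    mrna_meta, interactions, annotations, background).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = config.inputs

    def _need(key):
        if key not in paths:
            raise FileNotFoundError(f"missing required input path: {key}")
        p = Path(paths[key])
        if not p.exists():
            raise FileNotFoundError(f"input does not exist: {p}")
        return p

    if mirna_counts is None:
        mirna_counts = io.read_counts(_need("mirna_counts"), _need("mirna_meta"))
    if mrna_counts is None:
        mrna_counts = io.read_counts(_need("mrna_counts"), _need("mrna_meta"))
    if candidates is None:
        candidates = io.read_interactions(_need("interactions"))
    if annotations is None:
        annotations = io.read_gmt(_need("annotations"))
    if background is None:
        if "background" in paths:
            background = set(Path(paths["background"]).read_text().split())
        else:
            background = set(mrna_counts.feature_ids)

    stamp = {"config_digest": config.digest(), "seed": config.seed}
    timepoints = list(dict.fromkeys(mirna_counts.samples["timepoint"]))

    # --- quantify ---
    mirna_norm = quantify.quantile_normalize(mirna_counts.values)
    mrna_norm = quantify.quantile_normalize(mrna_counts.values)
    de_mirna = quantify.differential_expression_all(
        mirna_counts, timepoints, normalized=mirna_norm,
        pseudocount=config.pseudocount, fdr_cutoff=config.de_fdr_cutoff)
    de_mrna = quantify.differential_expression_all(
        mrna_counts, timepoints, normalized=mrna_norm,
        pseudocount=config.pseudocount, fdr_cutoff=config.de_fdr_cutoff)
    de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t", index=False)
    de_mrna.to_csv(outdir / "de_mrna.tsv", sep="\t", index=False)

    # --- dynamics ---
    def _logfc_table(de):
        return de.pivot(index="feature", columns="timepoint", values="logFC")[timepoints]

    mirna_profiles = dynamics.build_profiles(
        _logfc_table(de_mirna), k=config.discretization_k, scope=config.discretization_scope)
    mrna_profiles = dynamics.build_profiles(
        _logfc_table(de_mrna), k=config.discretization_k, scope=config.discretization_scope)
    mirna_profiles.rename_axis("feature").to_csv(outdir / "profiles_mirna.tsv", sep="\t")
    mrna_profiles.rename_axis("feature").to_csv(outdir / "profiles_mrna.tsv", sep="\t")
    dynamics.pattern_summary(mirna_profiles).to_csv(
        outdir / "pattern_summary_mirna.tsv", sep="\t", index=False)

    # --- network ---
    mi_expr, mr_expr = _correlation_matrices(
        config, mirna_counts, mrna_counts, mirna_norm, mrna_norm)
    filtered = network.filter_by_correlation(candidates, mi_expr, mr_expr)
    logger.info("correlation filter: %d of %d candidates retained",
                len(filtered), len(candidates))
    stage_edges = {}
    for tp in timepoints:
        edges = network.stage_network(filtered, de_mirna, de_mrna, tp)
        stage_edges[tp] = edges
        logger.info("stage %s network: %d edges", tp, len(edges))
    trend_edges = network.trend_network(filtered, mirna_profiles, mrna_profiles)
    logger.info("trend network: %d edges", len(trend_edges))
    all_edges = pd.concat(
        [*stage_edges.values(), trend_edges], ignore_index=True)
    all_edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    summary = {tp: network.degree_stats(e) for tp, e in stage_edges.items()}
    summary["trend"] = network.degree_stats(trend_edges)
    io.write_json({**stamp, "networks": summary}, outdir / "network_summary.json")

    # --- enrichment ---
    enrichment_by_net = {}
    for tp, edges in stage_edges.items():
        res = singular_enrichment(set(edges["gene"]), annotations, background)
        enrichment_by_net[tp] = res
        res.to_csv(outdir / f"enrichment_{tp}.tsv", sep="\t", index=False)

    # --- FRP ---
    frps_by_net = {}
    networks = {tp: stage_edges[tp] for tp in timepoints}
    supports = dict(zip(timepoints, config.min_supports))
    networks["trend"] = trend_edges
    supports["trend"] = config.trend_min_support
    for name, edges in networks.items():
        frps_by_net[name] = mine_frps(
            edges, annotations, background,
            min_support=supports[name],
            min_itemset_size=config.min_itemset_size,
            mb_fdr_cutoff=config.mb_fdr_cutoff,
        )
        frp.frp_table(frps_by_net[name]).to_csv(
            outdir / f"frps_{name}.tsv", sep="\t", index=False)

    io.write_json(stamp, outdir / "run_stamp.json")
    return PipelineResult(
        outdir=outdir, de_mirna=de_mirna, de_mrna=de_mrna,
        mirna_profiles=mirna_profiles, mrna_profiles=mrna_profiles,
        filtered=filtered, stage_edges=stage_edges, trend_edges=trend_edges,
        enrichment=enrichment_by_net, frps=frps_by_net,
    )


def mine_frps(
    edges: pd.DataFrame,
    annotations: dict,
    background: set,
    min_support: int,
    min_itemset_size: int = 1,
    mb_fdr_cutoff: float = 0.05,
    positive_silhouette_only: bool = True,
) -> list:
    """Mine one network's FRPs: bicliques -> significance -> silhouette.

    Bicliques are mined from the network's annotated genes at
    ``min_support``, kept when significant against the background, scored
    by silhouette (only positive scores survive, undefined retained), and
    assembled into FRPs by attaching regulator miRNAs.
    """
    genes = set(edges["gene"])
    incidence = frp.build_incidence(genes, annotations)
    mbs = frp.mine_closed_itemsets(incidence, min_support, min_itemset_size)
    if not mbs:
        return []
    mbs = frp.mb_significance(mbs, genes, annotations, background,
                              fdr_cutoff=mb_fdr_cutoff)
    mbs = frp.silhouette_scores(mbs, incidence)
    if positive_silhouette_only:
        mbs = [mb for mb in mbs if mb.silhouette is None or mb.silhouette > 0]
    return frp.assemble_frps(mbs, edges)
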