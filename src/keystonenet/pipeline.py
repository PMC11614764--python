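"""End-to-end pipelines tying the stages together.

``run_network_pipeline``: abundance table -> per-rank consensus network,
node features, keystone calls, clusters and correlation-pattern
summaries, all written as TSV/GraphML/JSON artifacts with a provenance
record.

``run_transcription_pipeline``: stratified functional table -> per-taxon
transcriptional-state models and feature-importance tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .consensus import (
    ConsensusNetwork,
    build_consensus,
    run_subsamples,
    write_edge_list,
    write_graphml,
)
from .metrics import (
    call_keystones,
    cluster_positive_network,
    keystone_potential,
    network_summary,
    node_features,
    write_node_features,
)
from .patterns import sign_fractions, within_between_genus
from .profiles import (
    AbundanceTable,
    aggregate_to_rank,
    filter_prevalence,
    read_sample_metadata,
    read_taxonomic_profile,
    select_one_sample_per_participant,
    site_similarity,
    write_abundance_tsv,
)
from .transcription import (
    fit_states,
    normalize_cpm,
    permutation_importance,
    read_functional_profile,
    sorensen_similarity,
)

logger = logging.getLogger("keystonenet")


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "keystonenet_version": __version__,
        "numpy_version": np.__version__,
    }


def _rank_artifacts(
    table: AbundanceTable, config: PipelineConfig, rank_dir: Path, seed: int
) -> dict:
    runs = run_subsamples(
        table,
        n_runs=config.consensus.n_runs,
        subsample_size=min(config.consensus.subsample_size, table.n_samples),
        params=config.sparcc,
        seed=seed,
    )
    net = build_consensus(
        runs,
        alpha=config.consensus.alpha,
        min_support_fraction=config.consensus.min_support_fraction,
    )
    feats = node_features(net)
    kps = keystone_potential(feats)
    calls = call_keystones(kps, mad_factor=config.keystone.mad_factor)
    clusters = cluster_positive_network(net)
    summary = network_summary(net, clusters)

    write_edge_list(net, rank_dir / "consensus_edges.tsv")
    write_graphml(net, rank_dir / "consensus.graphml")
    write_node_features(feats, calls, clusters, rank_dir / "node_features.tsv")

    result: dict = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "modularity": summary.modularity,
        "cohesion": summary.cohesion,
        "kp_cutoff": calls.cutoff,
        "keystones": calls.keystones,
        "n_clusters": clusters.n_clusters,
    }
    if net.n_edges > 0:
        signs = sign_fractions(net)
        result["fraction_positive"] = signs.fraction_positive
        result["fraction_negative"] = signs.fraction_negative
        if table.rank == "species":
            part = within_between_genus(net)
            result["within_genus"] = asdict(part.within)
            result["between_genus"] = asdict(part.between)
    (rank_dir / "network_summary.json").write_text(json.dumps(result, indent=2))
    return result


def run_network_pipeline(config: PipelineConfig) -> dict:
    """Execute profiles -> sparcc/consensus -> metrics -> patterns per rank."""
    if config.abundance_path is None:
        raise PipelineStageError("profiles_io", "no abundance table configured")
    path = Path(config.abundance_path)
    if not path.exists():
        raise PipelineStageError("profiles_io", f"input not found: {path}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    results: dict = {"ranks": {}}
    base_rank = "species"
    try:
        table = read_taxonomic_profile(path, rank=base_rank)
    except Exception as e:
        raise PipelineStageError("profiles_io", str(e)) from e
    if config.metadata_path:
        meta = read_sample_metadata(config.metadata_path)
        table = select_one_sample_per_participant(table, meta, seed=config.seed)
    if table.n_samples >= 2:
        mean_jaccard, _ = site_similarity(table)
        results["mean_jaccard_similarity"] = mean_jaccard

    root_ss = np.random.SeedSequence(config.seed)
    rank_seeds = root_ss.spawn(len(config.ranks))
    for rank, rank_ss in zip(config.ranks, rank_seeds):
        logger.info("rank %s: aggregating and filtering", rank)
        try:
            at_rank = aggregate_to_rank(table, rank)
            prevalent = filter_prevalence(at_rank, config.min_prevalence)
        except Exception as e:
            raise PipelineStageError("profiles_io", f"rank {rank}: {e}") from e
        rank_dir = out / rank
        rank_dir.mkdir(parents=True, exist_ok=True)
        write_abundance_tsv(prevalent, rank_dir / "prevalent_counts.tsv")
        try:
            seed = int(rank_ss.generate_state(1)[0] % 2**31)
            results["ranks"][rank] = _rank_artifacts(prevalent, config, rank_dir, seed)
        except Exception as e:
            raise PipelineStageError("consensus_network", f"rank {rank}: {e}") from e

    results["provenance"] = _provenance(config)
    (out / "provenance.json").write_text(json.dumps(results["provenance"], indent=2))
    (out / "results.json").write_text(json.dumps(results, indent=2, default=str))
    return results


def run_transcription_pipeline(
    config: PipelineConfig, taxa: list[str] | None = None
) -> dict:
    """Per-taxon transcriptional-state models and feature importances."""
    if config.functional_path is None:
        raise PipelineStageError("transcription_states", "no functional profile configured")
    path = Path(config.functional_path)
    if not path.exists():
        raise PipelineStageError("transcription_states", f"input not found: {path}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        profiles = read_functional_profile(path)
    except Exception as e:
        raise PipelineStageError("transcription_states", str(e)) from e
    if taxa:
        profiles = {t: p for t, p in profiles.items() if t in set(taxa)}
        if not profiles:
            raise PipelineStageError("transcription_states", f"no profiles for taxa {taxa}")

    tcfg = config.transcription
    root_ss = np.random.SeedSequence(config.seed)
    results: dict = {"taxa": {}}
    assignment_rows = []
    for (taxon, profile), taxon_ss in zip(sorted(profiles.items()), root_ss.spawn(len(profiles))):
        norm = normalize_cpm(profile)
        record: dict = {"n_samples": len(norm.sample_ids) - len(norm.zero_samples)}
        if record["n_samples"] >= 2:
            mean_sor, _ = sorensen_similarity(norm)
            record["mean_sorensen"] = mean_sor
        seeds = taxon_ss.spawn(2)
        model = None
        if record["n_samples"] >= 2 * tcfg.min_cluster_size:
            model = fit_states(
                norm,
                k_max=tcfg.k_max,
                min_cluster_size=tcfg.min_cluster_size,
                seed=int(seeds[0].generate_state(1)[0] % 2**31),
            )
        if model is None:
            record["state_model"] = "no stable state model"
        else:
            record["k"] = model.k
            record["mean_silhouette"] = model.mean_silhouette
            record["n_excluded"] = len(model.excluded_samples)
            for s, st in model.assignments.items():
                assignment_rows.append({"taxon": taxon, "sample": s, "state": st})
            imp = permutation_importance(
                norm,
                model.assignments,
                n_trees=tcfg.n_trees,
                n_perm=tcfg.n_perm,
                seed=int(seeds[1].generate_state(1)[0] % 2**31),
            )
            safe = taxon.replace("|", "_").replace(".", "_")
            imp.to_frame().to_csv(out / f"importance_{safe}.tsv", sep="\t", index=False)
            pd.DataFrame(model.silhouette_curve, columns=["k", "mean_silhouette"]).to_csv(
                out / f"silhouette_{safe}.tsv", sep="\t", index=False
            )
        results["taxa"][taxon] = record
    pd.DataFrame(assignment_rows, columns=["taxon", "sample", "state"]).to_csv(
        out / "state_assignments.tsv", sep="\t", index=False
    )
    results["provenance"] = _provenance(config)
    (out / "transcription_results.json").write_text(json.dumps(results, indent=2, default=str))
    return results
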