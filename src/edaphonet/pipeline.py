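"""End-to-end orchestration: preprocess -> network -> modules -> ordination.

Chains the per-module building blocks in the order the analysis prescribes:
per-domain table hygiene and rare-ASV filtering on raw counts, the relative
transform, the cross-domain merge, Spearman network construction with
Louvain module detection (label propagation and walktrap as convergence
checks), module abundance profiles with substrate tests and environmental
consensus, and CSS-based constrained ordination with forward selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edaphonet import env_spatial, module_env, network, ordination, preprocess
from edaphonet.tables import AsvTable, TaxonomyTable, merge_domains, write_network

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    merged: AsvTable
    graph: object
    network_summary: dict
    partition: network.ModulePartition
    convergence: pd.DataFrame
    metrics: pd.DataFrame
    keystones: pd.DataFrame
    profile: pd.DataFrame
    module_report: module_env.ModuleEnvReport
    env: env_spatial.EnvMatrix
    ordinations: dict = field(default_factory=dict)


def preprocess_domain(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    metadata: pd.DataFrame,
    min_rel: float = 0.001,
    min_total: int = 5,
    min_prev: int = 3,
) -> AsvTable:
    """Hygiene filters and the rare-ASV filter for one domain's raw table."""
    t = preprocess.drop_controls_and_dedup(table, metadata)
    t = preprocess.remove_singletons(t)
    t = preprocess.remove_organelles_and_contaminants(t, taxonomy)
    return preprocess.filter_rare(t, min_rel, min_total, min_prev)


def run_pipeline(
    bacteria: AsvTable,
    eukaryotes: AsvTable,
    taxonomy: TaxonomyTable,
    metadata: pd.DataFrame,
    rho_min: float = 0.7,
    alpha: float = 0.01,
    seed: int = 0,
    n_perm: int = 199,
    rf_trees: int = 500,
    with_ordination: bool = True,
) -> PipelineResult:
    """Run the full downstream analysis on a paired cross-domain dataset."""
    rng = np.random.default_rng(seed)
    bac = preprocess_domain(bacteria, taxonomy, metadata)
    euk = preprocess_domain(eukaryotes, taxonomy, metadata)
    merged = merge_domains(
        preprocess.to_relative(bac), preprocess.to_relative(euk)
    )
    log.info(
        "pipeline: merged table %d samples x %d ASVs",
        merged.n_samples, merged.n_asvs,
    )

    graph, summary = network.build_network(merged, rho_min=rho_min,
                                           taxonomy=taxonomy)
    part = network.louvain(graph, seed=int(rng.integers(2**31 - 1)))
    others = [
        network.label_propagation(graph, seed=int(rng.integers(2**31 - 1))),
        network.walktrap(graph),
    ]
    convergence = network.partition_convergence([part] + others)
    metrics = network.node_metrics(graph)
    keystones = network.keystone_candidates(graph, part, metrics)

    profile = module_env.module_profile(merged, part)
    env = env_spatial.transform_env(metadata.loc[merged.sample_ids])
    report = module_env.consensus_predictors(
        profile,
        env,
        metadata=metadata,
        alpha=alpha,
        n_trees=rf_trees,
        seed=int(rng.integers(2**31 - 1)),
    )

    ordinations = {}
    if with_ordination:
        sample_meta = metadata.loc[merged.sample_ids]
        css = preprocess.css_normalize(
            _restrict_raw(bacteria, eukaryotes, merged)
        )
        dist = ordination.community_distance(css.table)
        ordinations["pcoa"] = ordination.pcoa(dist)
        predictor_sets = {
            "environment": env.values,
            "bedrock": env_spatial.substrate_dummies(sample_meta),
        }
        coords = sample_meta[["latitude", "longitude"]]
        geo = env_spatial.geodesic_distance_matrix(coords)
        try:
            basis = env_spatial.pcnm(geo)
            predictor_sets["pcnm"] = basis.eigenvectors
        except ValueError as exc:
            log.warning("pipeline: PCNM skipped (%s)", exc)
        for name, x in predictor_sets.items():
            ordinations[name] = ordination.forward_select(
                dist,
                pd.DataFrame(x, index=merged.sample_ids),
                alpha=0.05,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )

    return PipelineResult(
        merged=merged,
        graph=graph,
        network_summary=summary,
        partition=part,
        convergence=convergence,
        metrics=metrics,
        keystones=keystones,
        profile=profile,
        module_report=report,
        env=env,
        ordinations=ordinations,
    )


def _restrict_raw(bacteria, eukaryotes, merged) -> AsvTable:
    """Raw-count table restricted to the merged table's samples and ASVs."""
    counts = pd.concat(
        [bacteria.counts, eukaryotes.counts], axis=1
    ).loc[merged.sample_ids, merged.asv_ids]
    domain = pd.concat([bacteria.domain_of_asv, eukaryotes.domain_of_asv])
    return AsvTable(counts, domain.loc[merged.asv_ids], "raw_counts")


def write_reports(result: PipelineResult, outdir) -> dict:
    """Write the pipeline's declared report files to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["network_graphml"] = outdir / "network.graphml"
    write_network(result.graph, paths["network_graphml"], "graphml",
                  partition=result.partition, metrics=result.metrics)
    paths["edges_csv"] = outdir / "edges.csv"
    write_network(result.graph, paths["edges_csv"], "edge_list")

    paths["module_profile"] = outdir / "module_profile.tsv"
    result.profile.to_csv(paths["module_profile"], sep="\t",
                          index_label="module")
    paths["keystones"] = outdir / "keystones.tsv"
    result.keystones.to_csv(paths["keystones"], sep="\t", index=False)

    report = {
        "network": _jsonable(result.network_summary),
        "modularity_q": result.partition.modularity_q,
        "n_modules": result.partition.n_modules,
        "module_sizes": result.partition.module_sizes(),
        "algorithm_convergence_ari": result.convergence.to_dict(),
        "substrate_kw": result.module_report.substrate_kw.to_dict(),
        "consensus_predictors": result.module_report.consensus.to_dict(
            orient="records"
        ),
        "major_explanatory_variable": {
            str(m): (None if v is None else {"variable": v[0], "sign": v[1]})
            for m, v in result.module_report.major_of_module.items()
        },
        "ordination": {
            name: {
                "r2": res.r2,
                "adj_r2": res.adj_r2,
                "permutation_p": res.permutation_p,
                "selected_terms": _jsonable(res.selected_terms),
            }
            for name, res in result.ordinations.items()
            if isinstance(res, ordination.DbRdaResult)
        },
    }
    paths["report"] = outdir / "report.json"
    Path(paths["report"]).write_text(json.dumps(_jsonable(report), indent=1))
    return {k: str(v) for k, v in paths.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
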