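"""End-to-end orchestration of the tissue-microbiome network analysis.

Stages (each consumes the outputs of the previous ones and records its
seed and null count in the report):

1. filter: contaminant removal on negative controls, singleton and
   5%-prevalence filtering of the ASV table;
2. the environmentally-acquired branch (*Wolbachia* excluded): three
   aggregated bipartite constructions (environment unmerged + tissues,
   environment merged + tissues, tissues only), per-column rarefaction,
   nestedness temperature with connectance-preserving nulls, and the
   tissue-by-substrate / substrate-by-substrate sharing tables;
3. the tissue-partition branch (*Wolbachia* retained): weighted modularity
   with annealing + nulls, network specialization H2' with fixed-margin
   nulls, the zero-inflated GLMM comparison of all tissue groupings, and
   NMDS on Bray-Curtis dissimilarities;
4. per-sample diversity summaries on the rarefied table.

The report is a plain dict, serializable to deterministic JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import community as comm
from .community import (
    BipartiteNetwork, CountMatrix, SampleMetadata, TaxonAnnotation,
    TISSUES, ENV_SUBSTRATES,
)
from .grouping import compare_partitions, long_counts
from .modularity import modularity_test
from .nestedness import nestedness_test
from .ordination import bray_curtis, nmds
from .specialization import h2prime

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings; depths and null counts default to the study's."""

    depth_env_mosquito: int = 2176     # env + mosquito matrices
    depth_mosquito: int = 2000         # mosquito-only matrix
    n_null_nestedness: int = 1000
    n_null_h2: int = 1000
    n_null_modularity: int = 100
    anneal_steps: int = 10_000
    anneal_restarts: int = 5
    min_total: int = 2
    min_prevalence: float = 0.05
    glmm_family: str = "nbinom2"
    glmm_maxiter: int = 200
    nmds_starts: int = 20
    seed: int = 0

    def seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = [
            "rarefy_unmerged", "rarefy_merged", "rarefy_tissue",
            "rarefy_samples", "nest_unmerged", "nest_merged", "nest_tissue",
            "modularity", "h2", "nmds",
        ]
        children = ss.spawn(len(names))
        return {
            n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for n, c in zip(names, children)
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name, fn, report, outdir):
    t0 = time.perf_counter()
    logger.info("stage %s ...", name)
    try:
        result = fn()
    except Exception as exc:
        if outdir is not None:
            _write_report(report, outdir)  # retain partial outputs
        raise StageError(name, exc) from exc
    logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
    return result


def _write_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, sort_keys=True, indent=1,
                               default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(
    counts: CountMatrix,
    metadata: SampleMetadata,
    taxonomy: TaxonAnnotation,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis graph; returns (and optionally writes) the report."""
    cfg = config if config is not None else PipelineConfig()
    seeds = cfg.seeds()
    report: dict = {"config": asdict(cfg), "seeds": seeds}

    # ---- stage: filter ---------------------------------------------------
    def do_filter():
        cm = comm.remove_control_taxa(counts, metadata)
        cm = comm.filter_rare(cm, cfg.min_total, cfg.min_prevalence)
        return cm
    filtered = _stage("filter", do_filter, report, outdir)
    meta = metadata.subset(filtered.sample_ids)
    report["filtered"] = {
        "n_taxa": filtered.shape[0],
        "n_samples": filtered.shape[1],
        "n_taxa_input": counts.shape[0],
    }

    # ---- environmentally-acquired branch (Wolbachia excluded) -----------
    def do_branch_env():
        return comm.exclude_wolbachia(filtered, taxonomy)
    no_wolb = _stage("wolbachia_exclusion", do_branch_env, report, outdir)

    def do_networks():
        nets = {}
        for name, scheme, depth, seed_key in [
            ("env_unmerged", comm.scheme_env_unmerged(),
             cfg.depth_env_mosquito, "rarefy_unmerged"),
            ("env_merged", comm.scheme_env_merged(),
             cfg.depth_env_mosquito, "rarefy_merged"),
            ("tissues_only", comm.scheme_tissues_only(),
             cfg.depth_mosquito, "rarefy_tissue"),
        ]:
            net = comm.aggregate(no_wolb, meta, scheme)
            nets[name] = comm.rarefy_network(net, depth, seeds[seed_key])
        return nets
    networks = _stage("aggregate_rarefy", do_networks, report, outdir)

    def do_nestedness():
        out = {}
        for name, seed_key in [("env_unmerged", "nest_unmerged"),
                               ("env_merged", "nest_merged"),
                               ("tissues_only", "nest_tissue")]:
            res = nestedness_test(networks[name], n=cfg.n_null_nestedness,
                                  seed=seeds[seed_key])
            out[name] = res.to_dict()
        return out
    report["nestedness"] = _stage("nestedness", do_nestedness, report, outdir)

    def do_sharing():
        t2 = comm.sharing_table(no_wolb, meta, cols=TISSUES, rows=ENV_SUBSTRATES)
        t3 = comm.sharing_table(no_wolb, meta, cols=ENV_SUBSTRATES,
                                rows=ENV_SUBSTRATES)
        return {
            "tissue_by_substrate": {
                "shared": t2.shared.to_dict(),
                "totals": t2.col_totals.to_dict(),
                "proportion": t2.rounded().to_dict(),
            },
            "substrate_by_substrate": {
                "shared": t3.shared.to_dict(),
                "totals": t3.col_totals.to_dict(),
                "proportion": t3.rounded().to_dict(),
            },
        }
    report["sharing"] = _stage("sharing", do_sharing, report, outdir)

    # ---- tissue-partition branch (Wolbachia retained) --------------------
    def do_tissue_net():
        net = comm.aggregate(filtered, meta, comm.scheme_tissues_only())
        return comm.rarefy_network(net, cfg.depth_mosquito, seeds["rarefy_tissue"])
    tissue_net = _stage("tissue_network", do_tissue_net, report, outdir)

    def do_modularity():
        res = modularity_test(
            tissue_net, n=cfg.n_null_modularity, seed=seeds["modularity"],
            steps=cfg.anneal_steps, restarts=cfg.anneal_restarts,
        )
        d = res.to_dict()
        d["modules"] = {
            "columns": {
                cid: int(lab) for cid, lab in
                zip(tissue_net.col_ids, res.partition.col_labels)
            },
        }
        d["seed"] = seeds["modularity"]
        d["n_null"] = cfg.n_null_modularity
        return d
    report["modularity"] = _stage("modularity", do_modularity, report, outdir)

    def do_h2():
        res = h2prime(tissue_net, n_null=cfg.n_null_h2, seed=seeds["h2"])
        d = res.to_dict()
        d["seed"] = seeds["h2"]
        return d
    report["specialization"] = _stage("h2", do_h2, report, outdir)

    def do_glmm():
        tissue_samples = [s for s in filtered.sample_ids
                          if meta.substrate_of(s) in TISSUES]
        tissue_cm = filtered.select_samples(tissue_samples).drop_empty_taxa()
        data = long_counts(tissue_cm, meta.subset(tissue_samples))
        cmp_ = compare_partitions(data, family=cfg.glmm_family,
                                  maxiter=cfg.glmm_maxiter)
        return cmp_.to_dict()
    report["grouping_models"] = _stage("glmm", do_glmm, report, outdir)

    def do_diversity():
        tissue_samples = [s for s in filtered.sample_ids
                          if meta.substrate_of(s) in TISSUES]
        env_samples = [s for s in filtered.sample_ids
                       if meta.substrate_of(s) in ENV_SUBSTRATES]
        rare = comm.rarefy(filtered, cfg.depth_mosquito, seeds["rarefy_samples"])
        simp = comm.simpson(rare)
        rich = comm.richness(rare)
        def summarize(samples):
            keep = [s for s in samples if s in rare.sample_ids]
            return {
                "n": len(keep),
                "simpson_mean": float(simp[keep].mean()) if keep else None,
                "richness_mean": float(rich[keep].mean()) if keep else None,
            }
        return {"tissue": summarize(tissue_samples),
                "environment": summarize(env_samples)}
    report["diversity"] = _stage("diversity", do_diversity, report, outdir)

    def do_nmds():
        tissue_samples = [s for s in filtered.sample_ids
                          if meta.substrate_of(s) in TISSUES]
        sub = filtered.select_samples(tissue_samples).drop_empty_taxa()
        d = bray_curtis(sub)
        res = nmds(d, k=2, n_starts=cfg.nmds_starts, seed=seeds["nmds"])
        return {
            "stress": res.stress,
            "converged": res.converged,
            "seed": seeds["nmds"],
            "n_samples": len(d.sample_ids),
        }
    report["ordination"] = _stage("nmds", do_nmds, report, outdir)

    if outdir is not None:
        _write_report(report, outdir)
    return report
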