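"""Synthetic community generator emulating the field study's design.

The generator produces datasets with the statistical structure the
analysis assumes, so every stage of the pipeline is testable without any
sequence data:

* a heavy-tailed (log-normal) regional pool of environmental taxa,
  perturbed per site, sampled as triplicate soil / water / plant-nectar
  communities per site with substrate-specific tilts (so cross-substrate
  taxon sharing is high but imperfect);
* tissue communities drawn as *filtered subsets* of the local
  environmental pool: selection weight proportional to pool abundance
  times an exponential tissue-affinity term, with a planted module
  structure (taxa assigned to a module are up-weighted in that module's
  tissues) implementing a known tissue partition;
* vertically transmitted, *Wolbachia*-like taxa injected only into the
  Malpighian-tubule and ovary samples;
* per-(taxon, sample) structural zeros before multinomial depth sampling,
  mirroring the zero-inflation component of the mixed model.

The default design matches the field study's layout: 20 sites, one pooled
sample per tissue per site (80 tissue samples) and triplicate samples of
three environmental substrates per site (180 environmental samples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .community import (
    CountMatrix,
    SampleMetadata,
    TaxonAnnotation,
    TISSUES,
    ENV_SUBSTRATES,
    write_count_table,
    write_metadata,
    write_taxonomy,
)
from .grouping import TissuePartition


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the generative scenario (defaults = the study design)."""

    n_sites: int = 20
    n_env_taxa: int = 1000
    env_replicates: int = 3              # soil / water / nectar per site
    depth_env: int = 6000                # reads per environmental sample
    depth_tissue: int = 4000             # reads per pooled tissue sample
    pool_mu: float = 0.0                 # log-normal regional pool
    pool_sigma: float = 1.2
    site_sigma: float = 0.8              # per-site pool perturbation
    substrate_sigma: float = 1.8         # substrate-specific tilt
    substrate_exclusion: float = 0.25    # taxa absent from a given substrate
    alpha: float = 3.0                   # tissue filter strength (>= 0)
    affinity_jitter: float = 0.05        # per-tissue deviation inside a block
    colonizer_fraction: float = 0.2      # taxa able to colonize tissues at all
    planted_partition: str | None = "cg-mo"
    module_effect: float = 8.0           # within-module abundance multiplier
    module_fraction: float = 0.3         # fraction of colonizers in modules
    n_vertical_taxa: int = 2
    vertical_tissues: tuple[str, ...] = ("malpighian_tubule", "ovary")
    vertical_load: float = 0.35          # expected read share of vertical taxa
    zero_inflation: float = 0.25         # structural-zero probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_env_taxa <= 0:
            raise ValueError("counts must be positive")
        if self.module_effect < 1:
            raise ValueError("module effect multiplier must be >= 1")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero-inflation probability must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("tissue filter strength must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted parameters that recovery tests assert against."""

    pool: np.ndarray                     # (n_taxa,) regional abundances
    site_pools: np.ndarray               # (n_sites, n_taxa)
    substrate_tilts: dict = field(default_factory=dict)
    tissue_weights: dict = field(default_factory=dict)  # (site, tissue) -> weights
    module_of_taxon: np.ndarray | None = None   # -1 = none, else block index
    module_of_tissue: dict = field(default_factory=dict)
    colonizer: np.ndarray | None = None         # taxa able to enter tissues
    vertical_taxa: list = field(default_factory=list)
    zero_draws: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "n_taxa": int(self.pool.size),
            "vertical_taxa": list(self.vertical_taxa),
            "module_of_tissue": {k: int(v) for k, v in self.module_of_tissue.items()},
            "module_counts": (
                {} if self.module_of_taxon is None else
                {str(int(m)): int((self.module_of_taxon == m).sum())
                 for m in np.unique(self.module_of_taxon)}
            ),
        }
        return json.dumps(payload, sort_keys=True)


def _env_taxon_ids(n: int) -> list[str]:
    return [f"ASV{i+1:04d}" for i in range(n)]


def simulate_environment(cfg: ScenarioConfig):
    """Simulate the environmental samples; returns (CountMatrix, meta, truth)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n = cfg.n_env_taxa
    pool = rng.lognormal(cfg.pool_mu, cfg.pool_sigma, size=n)
    site_pools = pool[None, :] * rng.lognormal(
        0.0, cfg.site_sigma, size=(cfg.n_sites, n)
    )
    tilts = {
        sub: rng.lognormal(0.0, cfg.substrate_sigma, size=n)
        * (rng.random(n) >= cfg.substrate_exclusion)
        for sub in ENV_SUBSTRATES
    }
    truth = SyntheticTruth(pool=pool, site_pools=site_pools,
                           substrate_tilts=tilts)
    cols, meta_rows = {}, []
    for s in range(cfg.n_sites):
        for sub in ENV_SUBSTRATES:
            w = site_pools[s] * tilts[sub]
            p = w / w.sum()
            for rep in range(cfg.env_replicates):
                sid = f"S{s+1:02d}_{sub}_{rep+1}"
                cols[sid] = rng.multinomial(cfg.depth_env, p)
                meta_rows.append((sid, f"site{s+1:02d}", sub))
    cm = CountMatrix(pd.DataFrame(cols, index=_env_taxon_ids(n), dtype=np.int64))
    meta = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "site_id", "substrate"])
        .set_index("sample_id")
    )
    return cm, meta, truth


def simulate_tissues(truth: SyntheticTruth, cfg: ScenarioConfig):
    """Simulate tissue communities as filtered subsets of the site pools."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    n = cfg.n_env_taxa
    tissues = list(TISSUES)

    # Only a subset of environmental taxa can colonize tissues at all.
    colonizer = rng.random(n) < cfg.colonizer_fraction
    if not colonizer.any():
        colonizer[rng.integers(n)] = True

    # Planted partition: tissue -> block, and module taxa assigned to blocks.
    if cfg.planted_partition is not None:
        part = TissuePartition.from_name(cfg.planted_partition)
        tissue_block = {t: part.mapping[t] for t in tissues}
        n_blocks = part.n_groups
        module_of_taxon = np.full(n, -1, dtype=np.int64)
        candidates = np.flatnonzero(colonizer)
        n_module_taxa = int(round(cfg.module_fraction * candidates.size))
        chosen = rng.choice(candidates, size=n_module_taxa, replace=False)
        module_of_taxon[chosen] = rng.integers(0, n_blocks, size=n_module_taxa)
        # Block-level affinities shared within a block, plus per-tissue jitter.
        block_aff = rng.normal(0.0, 1.0, size=(n, n_blocks))
        affinity = np.column_stack([
            block_aff[:, tissue_block[t]]
            + cfg.affinity_jitter * rng.normal(0.0, 1.0, size=n)
            for t in tissues
        ])
    else:
        tissue_block = {}
        module_of_taxon = None
        affinity = rng.normal(0.0, 1.0, size=(n, len(tissues)))

    truth.module_of_taxon = module_of_taxon
    truth.module_of_tissue = dict(tissue_block)
    truth.colonizer = colonizer

    vertical_ids = [f"WOLB{i+1}" for i in range(cfg.n_vertical_taxa)]
    truth.vertical_taxa = vertical_ids
    taxon_ids = _env_taxon_ids(n) + vertical_ids

    cols, meta_rows = {}, []
    for s in range(truth.site_pools.shape[0]):
        for ti, t in enumerate(tissues):
            w = truth.site_pools[s] * colonizer * np.exp(cfg.alpha * affinity[:, ti])
            if module_of_taxon is not None:
                match = module_of_taxon == tissue_block[t]
                w = w * np.where(match, cfg.module_effect, 1.0)
            # structural zeros before depth sampling
            zeros = rng.random(n) < cfg.zero_inflation
            w = np.where(zeros, 0.0, w)
            if w.sum() == 0:
                w = truth.site_pools[s] * colonizer
            full_w = np.concatenate([w, np.zeros(cfg.n_vertical_taxa)])
            if cfg.n_vertical_taxa and t in cfg.vertical_tissues:
                share = cfg.vertical_load / max(cfg.n_vertical_taxa, 1)
                vert = w.sum() * share / max(1 - cfg.vertical_load, 1e-9) \
                    * rng.lognormal(0.0, 0.3, size=cfg.n_vertical_taxa)
                full_w[n:] = vert
            p = full_w / full_w.sum()
            sid = f"S{s+1:02d}_{t}"
            cols[sid] = rng.multinomial(cfg.depth_tissue, p)
            meta_rows.append((sid, f"site{s+1:02d}", t))
            truth.tissue_weights[(s, t)] = full_w
    cm = CountMatrix(pd.DataFrame(cols, index=taxon_ids, dtype=np.int64))
    meta = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "site_id", "substrate"])
        .set_index("sample_id")
    )
    return cm, meta, truth


@dataclass(frozen=True)
class Bundle:
    """A complete synthetic dataset: counts + metadata + taxonomy + truth."""

    counts: CountMatrix
    metadata: SampleMetadata
    taxonomy: TaxonAnnotation
    truth: SyntheticTruth
    config: ScenarioConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "truth": outdir / "truth.json",
            "config": outdir / "config.tsv",
        }
        write_count_table(self.counts, paths["counts"])
        write_metadata(self.metadata, paths["metadata"])
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        lines = [f"{k}\t{v}" for k, v in sorted(asdict(self.config).items())]
        paths["config"].write_text("\n".join(lines) + "\n")
        return paths


def scenario_paper_like(seed: int = 0, config: ScenarioConfig | None = None,
                        outdir: str | Path | None = None) -> Bundle:
    """Full default scenario: 80 tissue + 180 environmental samples.

    Returns the combined count table (environmental + tissue samples over
    the union of taxa), metadata, and a taxonomy flagging the vertical
    *Wolbachia*-like taxa. Optionally writes the standard TSV bundle.
    """
    cfg = config if config is not None else ScenarioConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = ScenarioConfig(**{**asdict(config), "seed": seed})
    env_cm, env_meta, truth = simulate_environment(cfg)
    tis_cm, tis_meta, truth = simulate_tissues(truth, cfg)

    combined = env_cm.data.reindex(tis_cm.data.index).fillna(0).astype(np.int64)
    counts = CountMatrix(pd.concat([combined, tis_cm.data], axis=1))
    meta = SampleMetadata(pd.concat([env_meta.data, tis_meta.data]))

    lineage = {tid: "Bacteria;EnvLineage" for tid in counts.taxon_ids}
    flags = {tid: False for tid in counts.taxon_ids}
    for i, tid in enumerate(truth.vertical_taxa):
        lineage[tid] = f"Bacteria;Proteobacteria;Wolbachia;wAlb{'AB'[i % 2]}"
        flags[tid] = True
    taxonomy = TaxonAnnotation(pd.DataFrame({
        "lineage": pd.Series(lineage),
        "is_wolbachia": pd.Series(flags),
    }).rename_axis("taxon_id"))
    bundle = Bundle(counts, meta, taxonomy, truth, cfg)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
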