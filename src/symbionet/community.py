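"""Count-matrix containers, filtering, rarefaction, and bipartite aggregation.

The universal input of the package is a taxa x samples table of non-negative
integer read counts (ASV abundances), accompanied by sample metadata that
assigns each sample to a collection site and a substrate category (four
mosquito tissues, three environmental substrates, or negative control), and
a taxonomy table flagging vertically transmitted *Wolbachia* lineages.

This module provides:

* :class:`CountMatrix`, :class:`SampleMetadata`, :class:`TaxonAnnotation` --
  validated containers over pandas DataFrames, with TSV readers/writers;
* the filtering steps applied to ASV tables before analysis (control-taxon
  removal, singleton removal, prevalence filtering, *Wolbachia* exclusion);
* rarefaction (subsampling reads without replacement to a common depth);
* aggregation of samples into a weighted taxa x category
  :class:`BipartiteNetwork`, the input of every network statistic;
* per-sample diversity summaries (Gini-Simpson index, richness) and the
  tissue-by-substrate taxon sharing tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed substrate vocabulary.
TISSUES = ("crop", "midgut", "malpighian_tubule", "ovary")
ENV_SUBSTRATES = ("soil", "water", "plant_nectar")
NEGATIVE_CONTROL = "negative_control"
SUBSTRATES = TISSUES + ENV_SUBSTRATES + (NEGATIVE_CONTROL,)

#: Category label used when the environmental substrates are merged.
MERGED_ENVIRONMENT = "environment"
EXCLUDE = "exclude"


class CountTableError(ValueError):
    """Malformed count table (non-integer cells, duplicates, bad dims)."""


@dataclass(frozen=True)
class CountMatrix:
    """Taxa x samples table of non-negative integer counts.

    Parameters
    ----------
    data
        DataFrame indexed by taxon id with sample ids as columns. Values
        must be non-negative integers; identifiers must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(values.astype(float))):
                i, j = np.argwhere(frac != 0)[0]
                raise CountTableError(
                    f"non-integer count at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}: {df.iat[i, j]!r}"
                )
            object.__setattr__(self, "data", df.astype(np.int64))
        if values.size and (values.astype(np.int64) < 0).any():
            i, j = np.argwhere(values.astype(np.int64) < 0)[0]
            raise CountTableError(
                f"negative count at taxon {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {df.iat[i, j]}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def taxon_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(sample_ids)])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(taxon_ids), :])

    def drop_empty_taxa(self) -> "CountMatrix":
        keep = self.data.sum(axis=1) > 0
        return CountMatrix(self.data.loc[keep])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample site and substrate assignments (closed vocabulary)."""

    data: pd.DataFrame  # indexed by sample_id; columns: site_id, substrate

    def __post_init__(self) -> None:
        df = self.data
        missing = {"site_id", "substrate"} - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        bad = sorted(set(df["substrate"]) - set(SUBSTRATES))
        if bad:
            raise ValueError(
                f"unknown substrate values {bad}; allowed: {list(SUBSTRATES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def substrate_of(self, sample_id: str) -> str:
        return str(self.data.at[sample_id, "substrate"])

    def samples_with(self, *substrates: str) -> list[str]:
        mask = self.data["substrate"].isin(substrates)
        return list(self.data.index[mask])

    def require_cover(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.data.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class TaxonAnnotation:
    """Taxonomic lineages with a boolean *Wolbachia* flag per taxon."""

    data: pd.DataFrame  # indexed by taxon_id; columns: lineage, is_wolbachia

    def __post_init__(self) -> None:
        df = self.data
        missing = {"lineage", "is_wolbachia"} - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValueError("duplicate taxon ids in taxonomy")

    def wolbachia_taxa(self) -> list[str]:
        flags = self.data["is_wolbachia"].astype(bool)
        return list(self.data.index[flags])


@dataclass(frozen=True)
class BipartiteNetwork:
    """Weighted taxa x category interaction matrix.

    Zero rows and columns are dropped at construction so that every node of
    the network participates in at least one interaction.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("weights shape does not match id lists")
        if (w < 0).any():
            raise ValueError("negative weights in bipartite network")
        if w.size and ((w.sum(axis=1) == 0).any() or (w.sum(axis=0) == 0).any()):
            raise ValueError(
                "all-zero row or column in bipartite network; "
                "construct via from_weights() to drop them"
            )
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_weights(
        cls,
        weights: np.ndarray,
        row_ids: Sequence[str],
        col_ids: Sequence[str],
    ) -> "BipartiteNetwork":
        """Build a network, silently dropping all-zero rows/columns."""
        w = np.asarray(weights)
        rkeep = w.sum(axis=1) > 0
        ckeep = w.sum(axis=0) > 0
        return cls(
            tuple(np.asarray(row_ids, dtype=object)[rkeep]),
            tuple(np.asarray(col_ids, dtype=object)[ckeep]),
            w[np.ix_(rkeep, ckeep)],
        )

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights))

    def is_integer(self) -> bool:
        w = self.weights
        return bool(np.all(np.mod(w, 1) == 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.row_ids), columns=list(self.col_ids)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> CountMatrix:
    """Read a tab-delimited count table (first column taxon ids).

    Raises :class:`CountTableError` naming the offending cell for negative
    or non-integer counts, and for duplicate identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        if num.isna().any():
            taxon = df.index[num.isna().to_numpy().nonzero()[0][0]]
            raise CountTableError(
                f"non-numeric count at taxon {taxon!r}, sample {col!r}: "
                f"{raw.loc[taxon]!r}"
            )
        if np.any(np.mod(num.to_numpy(dtype=float), 1) != 0):
            taxon = df.index[(np.mod(num.to_numpy(dtype=float), 1) != 0).nonzero()[0][0]]
            raise CountTableError(
                f"non-integer count at taxon {taxon!r}, sample {col!r}: "
                f"{raw.loc[taxon]!r}"
            )
        if (num < 0).any():
            taxon = df.index[(num < 0).to_numpy().nonzero()[0][0]]
            raise CountTableError(
                f"negative count at taxon {taxon!r}, sample {col!r}: "
                f"{raw.loc[taxon]!r}"
            )
        parsed[col] = num.astype(np.int64)
    return CountMatrix(parsed)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    """Write the canonical TSV form (header ``taxon_id`` + sample ids)."""
    cm.data.to_csv(path, sep="\t", index_label="taxon_id", lineterminator="\n")


def read_biom_json(path: str | Path) -> CountMatrix:
    """Adapter for BIOM-style JSON tables (format 1.0, dense or sparse)."""
    import json

    doc = json.loads(Path(path).read_text())
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = int(v)
    else:
        counts[:] = np.asarray(doc["data"])
    return CountMatrix(pd.DataFrame(counts, index=taxa, columns=samples))


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "site_id", "substrate"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_taxonomy(path: str | Path) -> TaxonAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "lineage": str})
    required = {"taxon_id", "lineage", "is_wolbachia"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxonomy must have columns {sorted(required)}")
    df = df.set_index("taxon_id")
    df["is_wolbachia"] = df["is_wolbachia"].astype(int).astype(bool)
    return TaxonAnnotation(df)


def write_taxonomy(ann: TaxonAnnotation, path: str | Path) -> None:
    out = ann.data.copy()
    out["is_wolbachia"] = out["is_wolbachia"].astype(int)
    out.to_csv(path, sep="\t", index_label="taxon_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def remove_control_taxa(cm: CountMatrix, meta: SampleMetadata) -> CountMatrix:
    """Drop taxa detected in any negative control, and the controls themselves.

    Taxa with nonzero counts in reagent/no-template control samples are
    treated as contaminants of the molecular pipeline. With zero control
    samples the taxon set is unchanged.
    """
    meta.require_cover(cm)
    controls = [s for s in cm.sample_ids if meta.substrate_of(s) == NEGATIVE_CONTROL]
    keep_samples = [s for s in cm.sample_ids if s not in set(controls)]
    if not controls:
        return cm.select_samples(keep_samples)
    contaminated = cm.data[controls].sum(axis=1) > 0
    keep_taxa = cm.data.index[~contaminated]
    logger.info(
        "remove_control_taxa: dropped %d contaminant taxa, %d control samples",
        int(contaminated.sum()), len(controls),
    )
    return CountMatrix(cm.data.loc[keep_taxa, keep_samples])


def filter_rare(
    cm: CountMatrix,
    min_total: int = 2,
    min_prevalence: float = 0.05,
) -> CountMatrix:
    """Remove singleton-like and low-prevalence taxa.

    A taxon is kept when its total count is at least ``min_total`` *and* it
    is detected (count > 0) in at least ``ceil(min_prevalence * n_samples)``
    samples. Order of the remaining taxa is preserved.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    totals = cm.taxon_totals()
    detected = (cm.data > 0).sum(axis=1)
    n_needed = int(np.ceil(min_prevalence * cm.shape[1]))
    keep = (totals >= min_total) & (detected >= n_needed)
    if not keep.any():
        logger.warning("filter_rare: no taxa left after filtering")
    return CountMatrix(cm.data.loc[keep])


def exclude_wolbachia(cm: CountMatrix, ann: TaxonAnnotation) -> CountMatrix:
    """Remove flagged *Wolbachia* lineages (wAlbA/wAlbB-like taxa).

    Used on the nestedness/sharing branch of the analysis, which asks
    whether environmentally acquired symbionts source tissue microbiomes;
    vertically transmitted endosymbionts are uninformative for that question.
    """
    missing = sorted(set(cm.taxon_ids) - set(ann.data.index))
    if missing:
        raise ValueError(f"taxa without annotation: {missing}")
    flagged = set(ann.wolbachia_taxa())
    keep = [t for t in cm.taxon_ids if t not in flagged]
    return cm.select_taxa(keep)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(cm: CountMatrix, depth: int, seed: int | np.random.Generator) -> CountMatrix:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (with a
    logged warning) rather than raising, mirroring tolerant rarefaction of
    unevenly sequenced designs. The draw per sample is multivariate
    hypergeometric, so identical seeds give identical output.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = cm.sample_totals()
    kept, dropped = [], []
    out = {}
    for s in cm.sample_ids:
        total = int(totals[s])
        if total < depth:
            dropped.append(s)
            continue
        col = cm.data[s].to_numpy(dtype=np.int64)
        if total == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
        kept.append(s)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not kept:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    df = pd.DataFrame(out, index=cm.data.index, columns=kept, dtype=np.int64)
    return CountMatrix(df)


def rarefy_network(
    net: BipartiteNetwork, depth: int, seed: int | np.random.Generator
) -> BipartiteNetwork:
    """Rarefy each column of an aggregated network to ``depth`` units."""
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    if not net.is_integer():
        raise ValueError("rarefaction requires integer weights")
    rng = np.random.default_rng(seed)
    w = net.weights.astype(np.int64)
    cols, keep = [], []
    for j, cid in enumerate(net.col_ids):
        total = int(w[:, j].sum())
        if total < depth:
            logger.warning("rarefy_network: dropped column %r (total %d < %d)",
                           cid, total, depth)
            continue
        col = w[:, j] if total == depth else rng.multivariate_hypergeometric(w[:, j], depth)
        cols.append(col)
        keep.append(cid)
    if not cols:
        raise ValueError("no column reaches rarefaction depth")
    return BipartiteNetwork.from_weights(np.column_stack(cols), list(net.row_ids), keep)


# ---------------------------------------------------------------------------
# Aggregation to bipartite networks
# ---------------------------------------------------------------------------

def scheme_env_unmerged() -> dict[str, str]:
    """Categories: soil, water, plant_nectar + the four tissues."""
    scheme = {s: s for s in TISSUES + ENV_SUBSTRATES}
    return scheme


def scheme_env_merged() -> dict[str, str]:
    """Environmental substrates collapsed into one 'environment' column."""
    scheme = {s: s for s in TISSUES}
    scheme.update({s: MERGED_ENVIRONMENT for s in ENV_SUBSTRATES})
    return scheme


def scheme_tissues_only() -> dict[str, str]:
    """Mosquito tissues only; environmental substrates excluded."""
    scheme = {s: s for s in TISSUES}
    scheme.update({s: EXCLUDE for s in ENV_SUBSTRATES})
    return scheme


def aggregate(
    cm: CountMatrix,
    meta: SampleMetadata,
    scheme: Mapping[str, str],
) -> BipartiteNetwork:
    """Sum counts over samples into taxa x category interaction weights.

    ``scheme`` maps every non-control substrate present in the data to a
    category label, to :data:`MERGED_ENVIRONMENT`, or to :data:`EXCLUDE`.
    All-zero rows/columns are dropped; the total weight equals the total
    reads of the included samples.
    """
    meta.require_cover(cm)
    categories: dict[str, list[str]] = {}
    for s in cm.sample_ids:
        substrate = meta.substrate_of(s)
        if substrate == NEGATIVE_CONTROL:
            continue
        if substrate not in scheme:
            raise ValueError(f"substrate {substrate!r} not mapped by scheme")
        cat = scheme[substrate]
        if cat == EXCLUDE:
            continue
        if cat == "merged-environment":
            cat = MERGED_ENVIRONMENT
        categories.setdefault(cat, []).append(s)
    if not categories:
        raise ValueError("aggregation scheme excluded every sample")
    order = list(dict.fromkeys(
        scheme[meta.substrate_of(s)]
        if scheme.get(meta.substrate_of(s)) != "merged-environment"
        else MERGED_ENVIRONMENT
        for s in cm.sample_ids
        if meta.substrate_of(s) != NEGATIVE_CONTROL
        and scheme.get(meta.substrate_of(s)) != EXCLUDE
    ))
    weights = np.column_stack(
        [cm.data[categories[cat]].sum(axis=1).to_numpy() for cat in order]
    )
    return BipartiteNetwork.from_weights(weights, cm.taxon_ids, order)


# ---------------------------------------------------------------------------
# Diversity and sharing summaries
# ---------------------------------------------------------------------------

def simpson(cm: CountMatrix) -> pd.Series:
    """Gini-Simpson diversity, ``1 - sum(p_i^2)``, per sample.

    Empty samples yield NaN (undefined diversity, reported as missing).
    """
    counts = cm.counts.astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
        vals = 1.0 - np.nansum(p * p, axis=0)
    vals = np.where(totals > 0, vals, np.nan)
    return pd.Series(vals, index=cm.sample_ids, name="simpson")


def richness(cm: CountMatrix) -> pd.Series:
    """Number of taxa detected (count > 0) per sample."""
    return pd.Series(
        (cm.counts > 0).sum(axis=0), index=cm.sample_ids, name="richness"
    )


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SharingTable:
    """Taxon co-occurrence between tissue and environmental categories.

    ``shared`` holds, per (column category, row category) pair, the number
    of taxa detected in both; ``col_totals`` the number of taxa detected in
    each column category. Proportions are shared / column total.
    """

    shared: pd.DataFrame        # rows: env substrates; cols: tissue categories
    col_totals: pd.Series       # taxa detected per tissue (column) category

    @property
    def proportions(self) -> pd.DataFrame:
        return self.shared.div(self.col_totals, axis=1)

    def rounded(self) -> pd.DataFrame:
        """Proportions rounded half-up to 2 decimals for reporting."""
        return self.proportions.map(
            lambda v: np.nan if pd.isna(v) else _round2(v)
        )

    def formatted(self) -> pd.DataFrame:
        """Cells formatted like a printed co-occurrence table: 'n (p)'."""
        out = self.shared.astype(object).copy()
        props = self.rounded()
        for r in out.index:
            for c in out.columns:
                p = props.at[r, c]
                cell = f"{int(self.shared.at[r, c])}"
                out.at[r, c] = cell + ("" if pd.isna(p) else f" ({p:.2f})")
        return out


def _detected_sets(
    cm: CountMatrix, meta: SampleMetadata, categories: Iterable[str]
) -> dict[str, set[str]]:
    sets = {}
    for cat in categories:
        samples = [s for s in cm.sample_ids if meta.substrate_of(s) == cat]
        sub = cm.data[samples]
        sets[cat] = set(sub.index[(sub > 0).any(axis=1)])
    return sets


def sharing_table(
    cm: CountMatrix,
    meta: SampleMetadata,
    cols: Sequence[str] = TISSUES,
    rows: Sequence[str] = ENV_SUBSTRATES,
) -> SharingTable:
    """Count taxa shared between each column category and each row category.

    For the tissue-by-substrate table the proportion is the fraction of the
    tissue-specific microbiome that is shared with the environmental
    substrate. *Wolbachia* lineages should already be excluded upstream.
    Empty column categories give NaN proportions (undefined, missing).
    """
    meta.require_cover(cm)
    col_sets = _detected_sets(cm, meta, cols)
    row_sets = _detected_sets(cm, meta, rows)
    shared = pd.DataFrame(
        [[len(col_sets[c] & row_sets[r]) for c in cols] for r in rows],
        index=list(rows), columns=list(cols), dtype=np.int64,
    )
    totals = pd.Series({c: len(col_sets[c]) for c in cols})
    return SharingTable(shared, totals)


def prevalence_table(cm: CountMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Distribute each taxon's detections across substrate categories.

    Cell (taxon, category) is the number of samples of that category in
    which the taxon is detected, normalized so rows sum to 1. Taxa absent
    everywhere yield all-zero rows and are logged.
    """
    meta.require_cover(cm)
    categories = list(dict.fromkeys(meta.substrate_of(s) for s in cm.sample_ids))
    det = pd.DataFrame(0, index=cm.data.index, columns=categories, dtype=float)
    for cat in categories:
        samples = [s for s in cm.sample_ids if meta.substrate_of(s) == cat]
        det[cat] = (cm.data[samples] > 0).sum(axis=1)
    totals = det.sum(axis=1)
    absent = totals == 0
    if absent.any():
        logger.warning(
            "prevalence_table: %d taxa undetected everywhere", int(absent.sum())
        )
    with np.errstate(invalid="ignore"):
        out = det.div(totals.where(totals > 0), axis=0).fillna(0.0)
    return out
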