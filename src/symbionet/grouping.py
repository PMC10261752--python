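"""Tissue-grouping inference: partition enumeration, ZINB mixed-model fits,
and AICc-based model comparison.

The question: does the tissue-specific microbiome partition the four
mosquito tissues (crop, midgut, Malpighian tubule, ovary) into modules?
Every set partition of the tissues (14 for four tissues, excluding the
single-block partition) defines a candidate grouping; each grouping is fit
as a zero-inflated count mixed model in which taxa respond to tissue
*groups* rather than individual tissues, plus a null model with no
grouping at all. Models are ranked by small-sample-corrected AIC, with
Akaike weights, evidence ratios, and likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .community import CountMatrix, SampleMetadata, TISSUES
from .zinb import Family, GlmmFit, fit_zinb_glmm_arrays

logger = logging.getLogger(__name__)

#: Single-letter codes used in grouping-model names.
TISSUE_CODES = {
    "crop": "c",
    "midgut": "g",
    "malpighian_tubule": "m",
    "ovary": "o",
}

#: AICc interpretation bands.
BAND_INDISTINGUISHABLE = "indistinguishable"   # delta <= 2
BAND_WORSE = "worse"                           # 2 < delta <= 7
BAND_REJECTED = "poor fit, rejected"           # delta > 7


@dataclass(frozen=True)
class TissuePartition:
    """A set partition of tissues into non-empty disjoint groups."""

    groups: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        seen: set = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty group in tissue partition")
            if seen & g:
                raise ValueError("overlapping groups in tissue partition")
            seen |= g
        ordered = tuple(sorted(
            (frozenset(g) for g in self.groups),
            key=lambda g: min(self._code(t) for t in g),
        ))
        object.__setattr__(self, "groups", ordered)

    @staticmethod
    def _code(tissue: str) -> str:
        # single letters for the four standard tissues; full labels otherwise
        return TISSUE_CODES.get(tissue, tissue)

    @property
    def name(self) -> str:
        """Canonical name: letters sorted within groups, groups hyphenated."""
        blocks = []
        for g in self.groups:
            codes = sorted(self._code(t) for t in g)
            sep = "" if all(len(c) == 1 for c in codes) else "+"
            blocks.append(sep.join(codes))
        return "-".join(blocks)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def mapping(self) -> dict[str, int]:
        """tissue -> 0-based group index."""
        return {t: i for i, g in enumerate(self.groups) for t in g}

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(
            "".join(sorted(self._code(t) for t in g)) for g in self.groups
        )

    @classmethod
    def from_name(cls, name: str, tissues=TISSUES) -> "TissuePartition":
        """Parse a canonical-style name such as ``"cg-mo"``."""
        code_to_tissue = {cls._code(t): t for t in tissues}
        groups = []
        for block in name.split("-"):
            try:
                groups.append(frozenset(code_to_tissue[ch] for ch in block))
            except KeyError as exc:
                raise ValueError(f"unknown tissue code in {name!r}") from exc
        return cls(tuple(groups))


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


def enumerate_partitions(tissues=TISSUES) -> list[TissuePartition]:
    """All set partitions with >= 2 blocks (the 1-block case is the null).

    Four tissues give the 14 grouping models; counts follow the Bell
    numbers minus one.
    """
    tissues = list(tissues)
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue labels")
    parts = [
        TissuePartition(tuple(frozenset(b) for b in blocks))
        for blocks in _set_partitions(tissues)
        if len(blocks) >= 2
    ]
    return sorted(parts, key=lambda p: (p.n_groups, p.name))


# ---------------------------------------------------------------------------
# Long counts and fitting
# ---------------------------------------------------------------------------

def long_counts(cm: CountMatrix, meta: SampleMetadata,
                tissues=TISSUES) -> pd.DataFrame:
    """Reshape a tissue count matrix to one row per (sample, taxon).

    Columns: sample_id, site_id, tissue, taxon_id, count, offset
    (log of the sample's total reads). Only tissue samples are kept.
    """
    meta.require_cover(cm)
    keep = [s for s in cm.sample_ids if meta.substrate_of(s) in tissues]
    if not keep:
        raise ValueError("no tissue samples in count matrix")
    sub = cm.select_samples(keep)
    totals = sub.sample_totals()
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"tissue sample(s) with zero reads: {empty}")
    rows = sub.data.stack().rename("count").reset_index()
    rows.columns = ["taxon_id", "sample_id", "count"]
    rows["tissue"] = rows["sample_id"].map(
        lambda s: meta.substrate_of(s))
    rows["site_id"] = rows["sample_id"].map(
        lambda s: meta.data.at[s, "site_id"])
    rows["offset"] = rows["sample_id"].map(np.log(totals.astype(float)))
    return rows[["sample_id", "site_id", "tissue", "taxon_id", "count", "offset"]]


def _pivot(data: pd.DataFrame):
    """LongCounts -> (Y, offset, tissue-per-sample, sample ids, taxon ids)."""
    wide = data.pivot(index="taxon_id", columns="sample_id", values="count")
    if wide.isna().any().any():
        raise ValueError("long counts must contain one row per (sample, taxon)")
    sample_ids = list(wide.columns)
    per_sample = data.drop_duplicates("sample_id").set_index("sample_id")
    offset = per_sample.loc[sample_ids, "offset"].to_numpy(dtype=float)
    tissue = per_sample.loc[sample_ids, "tissue"].to_numpy()
    return (wide.to_numpy(dtype=np.int64), offset, tissue,
            sample_ids, list(wide.index))


def fit_zi_glmm(
    data: pd.DataFrame,
    part: TissuePartition | None,
    family: Family = "nbinom2",
    start: np.ndarray | None = None,
    mode_start: np.ndarray | None = None,
    maxiter: int = 200,
) -> GlmmFit:
    """Fit the zero-inflated count mixed model for one tissue grouping.

    ``part=None`` fits the null model (intercept + taxon intercept + zero
    inflation only). Raises if any tissue group has fewer than 2 samples.
    """
    Y, offset, tissue, sample_ids, taxon_ids = _pivot(data)
    if part is None:
        return fit_zinb_glmm_arrays(
            Y, offset, None, 0, (), taxon_ids, family=family, start=start,
            mode_start=mode_start, maxiter=maxiter,
        )
    mapping = part.mapping
    missing = sorted(set(tissue) - set(mapping))
    if missing:
        raise ValueError(f"tissues not covered by partition: {missing}")
    gidx = np.array([mapping[t] for t in tissue], dtype=np.int64)
    counts = np.bincount(gidx, minlength=part.n_groups)
    if (counts < 2).any():
        raise ValueError("every tissue group needs at least 2 samples")
    return fit_zinb_glmm_arrays(
        Y, offset, gidx, part.n_groups, part.group_names, taxon_ids,
        family=family, start=start, mode_start=mode_start, maxiter=maxiter,
    )


# ---------------------------------------------------------------------------
# Information-criterion arithmetic
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta_aicc) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    delta = np.asarray(list(delta_aicc), dtype=float)
    if delta.size == 0:
        raise ValueError("empty delta-AICc list")
    if delta.min() < -1e-9 or abs(delta.min()) > 1e-9:
        raise ValueError("delta-AICc values must be >= 0 with minimum 0")
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


def evidence_ratio(w_top: float, w_second: float) -> float:
    """Relative likelihood of the top model over the runner-up."""
    if w_top <= 0 or w_second < 0:
        raise ValueError("weights must be positive")
    if w_second == 0:
        return float("inf")
    return w_top / w_second


def likelihood_ratio_test(full: GlmmFit, nested: GlmmFit) -> tuple[float, int, float]:
    """LRT statistic 2(l_full - l_nested), df, and chi-square p-value."""
    if nested.k >= full.k:
        raise ValueError("nested model must have fewer parameters")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    df = full.k - nested.k
    return stat, df, float(chi2.sf(stat, df))


def conditional_modes(fit: GlmmFit) -> pd.DataFrame:
    """Per-(taxon, group) random interaction modes of a converged fit.

    Positive values mean the taxon is more abundant in that tissue group
    than its own across-tissue average.
    """
    if not fit.converged:
        raise ValueError("conditional modes require a converged fit")
    if fit.modes_v is None:
        raise ValueError("null model has no taxon-by-group interaction")
    return pd.DataFrame(
        fit.modes_v, index=list(fit.taxon_ids), columns=list(fit.group_names)
    )


def _band(delta: float) -> str:
    if delta <= 2.0:
        return BAND_INDISTINGUISHABLE
    if delta <= 7.0:
        return BAND_WORSE
    return BAND_REJECTED


@dataclass(frozen=True)
class ModelComparison:
    """Ranked tissue-grouping models with AICc, weights and bands."""

    table: pd.DataFrame            # sorted by AICc
    fits: dict                     # name -> GlmmFit

    @property
    def best_name(self) -> str:
        return str(self.table.index[0])

    def delta_of(self, name: str) -> float:
        return float(self.table.at[name, "delta_aicc"])

    def to_dict(self) -> dict:
        return {
            "ranking": [
                {
                    "model": name,
                    "loglik": float(row["loglik"]),
                    "k": int(row["k"]),
                    "aicc": float(row["aicc"]),
                    "delta_aicc": float(row["delta_aicc"]),
                    "weight": float(row["weight"]),
                    "band": str(row["band"]),
                }
                for name, row in self.table.iterrows()
            ]
        }


def compare_partitions(
    data: pd.DataFrame,
    partitions: list[TissuePartition] | None = None,
    include_null: bool = True,
    family: Family = "nbinom2",
    maxiter: int = 200,
) -> ModelComparison:
    """Fit all grouping models plus the null, rank by AICc.

    Interpretation bands follow the conventional thresholds: models within
    2 AICc units of the best are indistinguishable from it; above 7 they
    are rejected as poor fits. Non-converged fits are excluded with a
    warning. Fits are warm-started from the finest partition's estimates.
    """
    if partitions is None:
        tissues = sorted(set(data["tissue"]))
        partitions = enumerate_partitions(tissues)
    fits: dict[str, GlmmFit] = {}

    # Fit the finest partition first; its parameters and inner modes
    # warm-start every coarser model.
    order = sorted(partitions, key=lambda p: -p.n_groups)
    finest = order[0] if order else None
    shared_start: dict[str, float] = {}
    v_of_tissue: dict[str, np.ndarray] = {}
    uz: tuple[np.ndarray, np.ndarray] | None = None
    for part in order:
        start = mode_start = None
        if shared_start and part is not finest:
            mode_start = _mode_start(part, uz, v_of_tissue)
            summary = dict(shared_start)
            if mode_start is not None:
                # coarser/misgrouped models need room for the residual
                # block structure their grouping cannot absorb
                summary["sv2"] = max(summary["sv2"],
                                     float(mode_start[:, 1:-1].var()))
            start = _warm_start(part, summary, family)
        try:
            fit = fit_zi_glmm(data, part, family=family, start=start,
                              mode_start=mode_start, maxiter=maxiter)
        except Exception as exc:   # pragma: no cover - defensive
            logger.warning("fit failed for %s: %s", part.name, exc)
            continue
        if not fit.converged:
            logger.warning("fit for %s did not converge; excluded", part.name)
            continue
        fits[part.name] = fit
        if part is finest:
            shared_start = _finest_summary(part, fit)
            uz = (fit.modes_u, fit.modes_z)
            if fit.modes_v is not None:
                for tissue, g in part.mapping.items():
                    v_of_tissue[tissue] = fit.modes_v[:, g]
    if include_null:
        mode0 = None
        if uz is not None:
            mode0 = np.column_stack(uz)
        fit0 = fit_zi_glmm(data, None, family=family, mode_start=mode0,
                           maxiter=maxiter)
        if fit0.converged:
            fits["null"] = fit0
        else:
            logger.warning("null-model fit did not converge; excluded")
    if not fits:
        raise RuntimeError("all grouping-model fits failed")

    n = next(iter(fits.values())).n_obs
    rows = {
        name: {"loglik": f.loglik, "k": f.k, "aicc": aicc(f.loglik, f.k, n)}
        for name, f in fits.items()
    }
    table = pd.DataFrame(rows).T.sort_values("aicc", kind="stable")
    table["k"] = table["k"].astype(int)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["weight"] = akaike_weights(table["delta_aicc"])
    table["band"] = [_band(d) for d in table["delta_aicc"]]
    return ModelComparison(table=table, fits=fits)


def _finest_summary(part: TissuePartition, fit: GlmmFit) -> dict:
    """Per-tissue fixed effects and shared components from the finest fit."""
    out = {"theta": fit.theta, "su2": fit.sigma_u2,
           "sv2": fit.sigma_v2 or 0.5, "zeta0": fit.zeta0, "sz2": fit.sigma_z2}
    for g, name in enumerate(fit.group_names):
        for tissue, idx in part.mapping.items():
            if idx == g:
                out[f"beta:{tissue}"] = float(fit.beta[g])
    return out


def _mode_start(part: TissuePartition, uz, v_of_tissue) -> np.ndarray | None:
    """Inner-mode warm start: group modes = mean of member-tissue modes."""
    if uz is None or not v_of_tissue:
        return None
    u, z = uz
    cols = [u]
    for g in part.groups:
        cols.append(np.mean([v_of_tissue[t] for t in sorted(g)], axis=0))
    cols.append(z)
    return np.column_stack(cols)


def _warm_start(part: TissuePartition, summary: dict,
                family: Family = "nbinom2") -> np.ndarray | None:
    try:
        beta = np.array([
            np.mean([summary[f"beta:{t}"] for t in sorted(g)])
            for g in part.groups
        ])
    except KeyError:
        return None
    from .zinb import _pack  # packing layout lives with the fitter
    return _pack(
        {"beta": beta, "theta": summary["theta"] if np.isfinite(summary["theta"]) else 1.0,
         "su2": max(summary["su2"], 1e-3), "sv2": max(summary["sv2"], 1e-3),
         "zeta0": summary["zeta0"], "sz2": max(summary["sz2"], 1e-3)},
        part.n_groups, family,
    )
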