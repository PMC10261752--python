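"""Constrained randomizations of bipartite networks and significance tests.

Two null-model schemes are provided, matching the two used throughout the
analysis:

* :func:`vaznull` -- keeps the observed dimensions, connectance (number of
  links), total weight, and coverage of every row and column, while only
  approximately preserving the marginal totals. Links are placed cell by
  cell with probability proportional to the product of the marginal
  probabilities, then the remaining integer weight is spread over the
  filled cells, again proportionally to the marginal products.
* :func:`r2dtable_null` -- Patefield's algorithm: integer tables with
  *exactly* the observed row and column sums, drawn from the
  margin-conditional (multivariate hypergeometric) distribution. Delegates
  to :func:`scipy.stats.random_table`.

:func:`significance` converts an observed statistic plus its null
distribution into a z-score, an add-one empirical p-value, and the central
95% interval of the nulls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .community import BipartiteNetwork

Tail = Literal["lower", "upper", "two-sided"]


@dataclass(frozen=True)
class NullEnsemble:
    """A set of randomized matrices generated under one constraint scheme."""

    method: str
    n: int
    seed: int
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    matrices: tuple[np.ndarray, ...]

    def networks(self):
        for m in self.matrices:
            yield BipartiteNetwork(self.row_ids, self.col_ids, m)

    def to_dir(self, path: str | Path) -> None:
        """Serialize to a directory of TSV matrices plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.matrices):
            header = "taxon_id\t" + "\t".join(map(str, self.col_ids))
            lines = [header] + [
                str(r) + "\t" + "\t".join(str(int(v)) for v in row)
                for r, row in zip(self.row_ids, m)
            ]
            (path / f"null_{i:04d}.tsv").write_text("\n".join(lines) + "\n")
        manifest = {
            "method": self.method,
            "n": self.n,
            "seed": self.seed,
            "shape": [len(self.row_ids), len(self.col_ids)],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))


@dataclass(frozen=True)
class SignificanceResult:
    """Observed statistic versus its null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    z: float            # NaN when the nulls have no spread
    p: float
    ci95: tuple[float, float]
    tail: Tail
    n_null: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "p": self.p,
            "ci95": list(self.ci95),
            "tail": self.tail,
            "n_null": self.n_null,
        }


def _require_integer(net: BipartiteNetwork, method: str) -> np.ndarray:
    if not net.is_integer():
        raise ValueError(
            f"{method} requires integer weights; rarefy the matrix first"
        )
    return net.weights.astype(np.int64)


def _vaznull_once(
    w: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    nr, nc = w.shape
    r = w.sum(axis=1).astype(float)
    c = w.sum(axis=0).astype(float)
    F = int(w.sum())
    L = int(np.count_nonzero(w))
    if L < max(nr, nc):
        raise ValueError(
            f"link count {L} cannot cover all {nr} rows and {nc} columns"
        )
    filled = np.zeros((nr, nc), dtype=bool)
    # Coverage phase: a minimal skeleton of max(nr, nc) links covering every
    # row and column. On the longer side each node gets exactly one link;
    # nodes of the shorter side are matched one-to-one to a weighted random
    # subset of the longer side, the rest attach proportionally to margins.
    pc = c / c.sum()
    pr = r / r.sum()
    if nr >= nc:
        anchors = rng.choice(nr, size=nc, replace=False, p=pr)
        filled[anchors, rng.permutation(nc)] = True
        rest_rows = np.setdiff1d(np.arange(nr), anchors)
        filled[rest_rows, rng.choice(nc, size=rest_rows.size, p=pc)] = True
    else:
        anchors = rng.choice(nc, size=nr, replace=False, p=pc)
        filled[rng.permutation(nr), anchors] = True
        rest_cols = np.setdiff1d(np.arange(nc), anchors)
        filled[rng.choice(nr, size=rest_cols.size, p=pr), rest_cols] = True
    # Fill phase: remaining links among empty cells, p ~ r_i * c_j.
    n_more = L - int(filled.sum())
    if n_more > 0:
        empty = np.flatnonzero(~filled.ravel())
        probs = np.outer(r, c).ravel()[empty]
        pick = rng.choice(empty, size=n_more, replace=False, p=probs / probs.sum())
        filled.ravel()[pick] = True
    # Weight phase: each link gets 1 unit; distribute the remaining
    # F - L units over the links with p ~ r_i * c_j.
    out = filled.astype(np.int64)
    rest = F - L
    if rest > 0:
        idx = np.flatnonzero(filled.ravel())
        probs = np.outer(r, c).ravel()[idx]
        extra = rng.multinomial(rest, probs / probs.sum())
        out.ravel()[idx] += extra
    return out


def vaznull(net: BipartiteNetwork, n: int, seed: int) -> NullEnsemble:
    """Connectance-, coverage- and total-weight-preserving null ensemble.

    Every null matrix has the observed dimensions, exactly the observed
    number of non-zero cells, at least one link in every row and column,
    and the observed total weight; marginal totals are preserved only in
    expectation.
    """
    w = _require_integer(net, "vaznull")
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(n):
        m = _vaznull_once(w, rng)
        assert m.sum() == w.sum()
        assert np.count_nonzero(m) == np.count_nonzero(w)
        assert (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all()
        mats.append(m)
    return NullEnsemble("vaznull", n, seed, net.row_ids, net.col_ids, tuple(mats))


def r2dtable_null(net: BipartiteNetwork, n: int, seed: int) -> NullEnsemble:
    """Patefield ensemble: exact observed row and column marginal totals."""
    w = _require_integer(net, "r2dtable")
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    rng = np.random.default_rng(seed)
    draws = stats.random_table(r, c).rvs(n, random_state=rng)
    draws = np.asarray(draws, dtype=np.int64).reshape(n, *w.shape)
    for m in draws:
        assert (m.sum(axis=1) == r).all() and (m.sum(axis=0) == c).all()
    return NullEnsemble(
        "r2dtable", n, seed, net.row_ids, net.col_ids, tuple(draws)
    )


def significance(
    observed: float, nulls: Sequence[float], tail: Tail = "two-sided"
) -> SignificanceResult:
    """Empirical significance of an observed statistic against nulls.

    The p-value uses the add-one permutation convention,
    ``p = (1 + #extreme) / (1 + n)``, so it is never exactly zero. The
    z-score is reported as NaN when fewer than two distinct null values
    exist.
    """
    nulls = np.asarray(list(nulls), dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if nulls.size > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    n = nulls.size
    p_lower = (1 + int((nulls <= observed).sum())) / (1 + n)
    p_upper = (1 + int((nulls >= observed).sum())) / (1 + n)
    if tail == "lower":
        p = p_lower
    elif tail == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    lo, hi = np.percentile(nulls, [2.5, 97.5])
    return SignificanceResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        p=float(p),
        ci95=(float(lo), float(hi)),
        tail=tail,
        n_null=int(n),
    )
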