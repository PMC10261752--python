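"""Matrix packing and the nestedness temperature of presence/absence matrices.

Nestedness asks whether species-poor communities are taxonomic subsets of
species-rich ones. The temperature statistic maps a packed binary matrix
onto the unit square, draws the isocline of perfect nestedness for the
observed fill, and scores every cell in the "wrong" region (a presence in
the expected-absence region, or an absence in the expected-presence
region) by its squared relative distance from the isocline along the
cell's corner-to-corner diagonal. A perfectly nested packed matrix scores
0; a fully random one scores near 100.

The isocline family follows the smooth-boundary parameterization: in unit
square coordinates (x right, y down, presences packed toward the top-left)
the boundary is ``(1-x)^p + (1-y)^p = 1``, with the exponent ``p`` solved
numerically so that the area of the expected-presence region equals the
observed fill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .community import BipartiteNetwork
from .nulls import NullEnsemble, SignificanceResult, significance, vaznull

#: Scaling constant: the maximum attainable mean unexpectedness is 0.04145,
#: so temperatures live on a 0-100 scale.
_K = 100.0 / 0.04145


@dataclass(frozen=True)
class PackedMatrix:
    """A binary matrix with packing permutations applied."""

    matrix: np.ndarray            # packed presence/absence (0/1)
    row_order: np.ndarray         # packed row r came from input row row_order[r]
    col_order: np.ndarray

    @property
    def fill(self) -> float:
        return float(self.matrix.mean())


@dataclass(frozen=True)
class NestednessResult:
    temperature: float
    packed: PackedMatrix
    significance: SignificanceResult | None
    n_null: int
    seed: int | None

    def to_dict(self) -> dict:
        out = {
            "temperature": self.temperature,
            "fill": self.packed.fill,
            "matrix_shape": list(self.packed.matrix.shape),
            "n_null": self.n_null,
            "seed": self.seed,
        }
        if self.significance is not None:
            sig = self.significance.to_dict()
            out.update(
                {"p": sig["p"], "z": sig["z"], "null_ci": sig["ci95"],
                 "null_mean": sig["null_mean"]}
            )
        return out


def binarize(net: BipartiteNetwork | np.ndarray) -> np.ndarray:
    """Presence/absence matrix: cell > 0 becomes 1."""
    w = net.weights if isinstance(net, BipartiteNetwork) else np.asarray(net)
    return (w > 0).astype(np.int8)


def _drop_empty(binary: np.ndarray) -> np.ndarray:
    rkeep = binary.sum(axis=1) > 0
    ckeep = binary.sum(axis=0) > 0
    if not rkeep.all() or not ckeep.all():
        warnings.warn(
            "dropping all-zero rows/columns before packing", stacklevel=3
        )
    return binary[np.ix_(rkeep, ckeep)], rkeep, ckeep


def _isocline_exponent(fill: float) -> float:
    """Solve for p such that area{(1-x)^p + (1-y)^p >= 1} equals fill.

    The complementary region is the superellipse quadrant a^p + b^p <= 1
    with volume Gamma(1+1/p)^2 / Gamma(1+2/p).
    """
    def area(logp: float) -> float:
        p = np.exp(logp)
        vol = np.exp(2 * gammaln(1 + 1 / p) - gammaln(1 + 2 / p))
        return (1.0 - vol) - fill

    return float(np.exp(brentq(area, -7.0, 7.0, xtol=1e-12, rtol=1e-15)))


def _unexpectedness(binary: np.ndarray) -> np.ndarray:
    """Per-cell squared relative diagonal distance from the isocline.

    Expected cells score 0. Fully empty or full matrices return all zeros.
    """
    m, n = binary.shape
    fill = binary.mean()
    u = np.zeros((m, n), dtype=float)
    if fill <= 0 or fill >= 1:
        return u
    p = _isocline_exponent(fill)
    x = (np.arange(n) + 0.5) / n
    y = (np.arange(m) + 0.5) / m
    X, Y = np.meshgrid(x, y)          # shape (m, n); Y increases downward

    s = (1 - X) ** p + (1 - Y) ** p - 1.0
    present = binary > 0
    unexpected = (present & (s < 0)) | (~present & (s > 0))
    if not unexpected.any():
        return u

    x0 = X[unexpected]
    y0 = Y[unexpected]
    t_lo = -np.minimum(x0, y0)
    t_hi = np.minimum(1 - x0, 1 - y0)
    # s(t) = (1-x0-t)^p + (1-y0-t)^p - 1 is decreasing in t; bisect for root.
    lo, hi = t_lo.copy(), t_hi.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = (1 - x0 - mid) ** p + (1 - y0 - mid) ** p - 1.0
        above = val > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    t_root = 0.5 * (lo + hi)
    d = np.abs(t_root)
    D = t_hi - t_lo
    u[unexpected] = (d / D) ** 2
    return u


def temperature(pm: PackedMatrix | np.ndarray) -> float:
    """Nestedness temperature of a packed binary matrix, in [0, 100]."""
    binary = pm.matrix if isinstance(pm, PackedMatrix) else np.asarray(pm)
    fill = binary.mean()
    if fill <= 0 or fill >= 1:
        warnings.warn("degenerate (empty or full) matrix; temperature = 0")
        return 0.0
    return float(min(100.0, _K * _unexpectedness(binary).mean()))


def _order_by(keys, n: int) -> np.ndarray:
    """Stable argsort over tuple keys (ascending)."""
    return np.array(sorted(range(n), key=lambda i: keys[i]))


def pack(binary: np.ndarray, max_iter: int = 20) -> PackedMatrix:
    """Reorder rows and columns to concentrate presences toward the top-left.

    Starts from marginal-total ordering (richest rows on top, most-filled
    columns on the left) and refines by alternately re-ranking rows and
    columns by the mean position of their presences, keeping the ordering
    with the lowest temperature seen. Ties break by input order, so packing
    is deterministic.
    """
    binary = np.asarray(binary)
    binary, rkeep, ckeep = _drop_empty(binary)
    m, n = binary.shape
    rows0 = np.flatnonzero(rkeep)
    cols0 = np.flatnonzero(ckeep)

    row_sum = binary.sum(axis=1)
    col_sum = binary.sum(axis=0)
    r_ord = _order_by([(-row_sum[i], i) for i in range(m)], m)
    c_ord = _order_by([(-col_sum[j], j) for j in range(n)], n)

    best = (temperature(binary[np.ix_(r_ord, c_ord)]), r_ord, c_ord)
    cur_r, cur_c = r_ord, c_ord
    for _ in range(max_iter):
        packed = binary[np.ix_(cur_r, cur_c)]
        # mean packed-column position of each row's presences, and vice versa
        colpos = np.arange(n) + 0.5
        rowpos = np.arange(m) + 0.5
        rkey = (packed * colpos).sum(axis=1) / packed.sum(axis=1)
        ckey = (packed * rowpos[:, None]).sum(axis=0) / packed.sum(axis=0)
        new_r = cur_r[_order_by([(rkey[i], -packed[i].sum(), i) for i in range(m)], m)]
        new_c = cur_c[_order_by([(ckey[j], -packed[:, j].sum(), j) for j in range(n)], n)]
        if np.array_equal(new_r, cur_r) and np.array_equal(new_c, cur_c):
            break
        cur_r, cur_c = new_r, new_c
        t = temperature(binary[np.ix_(cur_r, cur_c)])
        if t < best[0] - 1e-12:
            best = (t, cur_r, cur_c)
        else:
            break
    _, r_ord, c_ord = best
    return PackedMatrix(
        matrix=binary[np.ix_(r_ord, c_ord)],
        row_order=rows0[r_ord],
        col_order=cols0[c_ord],
    )


def nestedness_statistic(net: BipartiteNetwork | np.ndarray) -> float:
    """Temperature of a (weighted or binary) matrix after binarize + pack."""
    return temperature(pack(binarize(net)))


def nestedness_test(
    net: BipartiteNetwork,
    n: int = 1000,
    seed: int = 0,
    null_ensemble: NullEnsemble | None = None,
) -> NestednessResult:
    """Observed temperature versus connectance-preserving nulls, lower tail.

    Low temperature means nested; the test asks whether the observed
    matrix is *more* nested (cooler) than random matrices with the same
    dimensions, connectance, and total weight.
    """
    packed = pack(binarize(net))
    obs = temperature(packed)
    ensemble = null_ensemble if null_ensemble is not None else vaznull(net, n, seed)
    null_t = [temperature(pack(binarize(m))) for m in ensemble.matrices]
    sig = significance(obs, null_t, tail="lower")
    return NestednessResult(
        temperature=obs,
        packed=packed,
        significance=sig,
        n_null=ensemble.n,
        seed=seed,
    )
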