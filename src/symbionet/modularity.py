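"""Weighted bipartite modularity and a simulated-annealing maximizer.

Modularity of a weighted bipartite network measures the excess of
interaction weight inside modules (groups containing both taxa and
categories) over the expectation from the marginal totals:

    Q = sum_ij [ A_ij / F - r_i c_j / F^2 ] * 1{module(row i) = module(col j)}

The maximizer is a flat-partition simulated annealing over joint
(row, column) module labels, in the spirit of the simulated-annealing
maximizers used for quantitative bipartite modularity, validated against
an exact oracle that enumerates column partitions (rows then attach
optimally, which is exact because row-row pairs never contribute to Q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .community import BipartiteNetwork
from .nulls import SignificanceResult, significance, vaznull

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every row and column node to a module label (1-based)."""

    row_labels: np.ndarray
    col_labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.concatenate([self.row_labels, self.col_labels])
        uniq = np.unique(labels)
        if uniq.size and not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("module labels must be contiguous from 1")

    @property
    def n_modules(self) -> int:
        return int(max(self.row_labels.max(initial=0), self.col_labels.max(initial=0)))

    @classmethod
    def from_raw(cls, row_labels, col_labels) -> "ModulePartition":
        """Relabel arbitrary labels to contiguous 1..k (order of appearance)."""
        row_labels = np.asarray(row_labels)
        col_labels = np.asarray(col_labels)
        seen: dict = {}
        def remap(a):
            out = np.empty(a.size, dtype=np.int64)
            for i, v in enumerate(a):
                if v not in seen:
                    seen[v] = len(seen) + 1
                out[i] = seen[v]
            return out
        return cls(remap(row_labels), remap(col_labels))

    @classmethod
    def single_module(cls, nr: int, nc: int) -> "ModulePartition":
        return cls(np.ones(nr, dtype=np.int64), np.ones(nc, dtype=np.int64))

    def to_frame(self, row_ids, col_ids):
        """Tidy node table: node_id, node_side (taxon/category), module_id."""
        import pandas as pd

        return pd.DataFrame({
            "node_id": list(row_ids) + list(col_ids),
            "node_side": ["taxon"] * len(row_ids) + ["category"] * len(col_ids),
            "module_id": np.concatenate([self.row_labels, self.col_labels]),
        })


@dataclass(frozen=True)
class ModularityResult:
    Q: float
    partition: ModulePartition
    n_modules: int
    significance: SignificanceResult | None = None
    trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"Q": self.Q, "n_modules": self.n_modules, "trace": self.trace}
        if self.significance is not None:
            sig = self.significance.to_dict()
            out.update({"p": sig["p"], "z": sig["z"], "null_mean": sig["null_mean"]})
        return out


def _B(net: BipartiteNetwork) -> np.ndarray:
    w = net.weights.astype(float)
    F = w.sum()
    return w / F - np.outer(net.row_totals, net.col_totals) / F**2


def modularity_Q(net: BipartiteNetwork, part: ModulePartition) -> float:
    """Barber-style modularity of a given partition."""
    if part.row_labels.size != len(net.row_ids) or part.col_labels.size != len(net.col_ids):
        raise ValueError("partition does not cover all nodes")
    B = _B(net)
    same = part.row_labels[:, None] == part.col_labels[None, :]
    return float(B[same].sum())


def _set_partitions(items: list) -> "list[list[list]]":
    """All set partitions of ``items`` (recursive, first-element anchored)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


def exhaustive_best_partition(net: BipartiteNetwork) -> ModularityResult:
    """Exact maximizer by enumeration, for small networks.

    Enumerates all set partitions of the *columns*; given a column
    partition, each row attaches independently to its best column module
    (Q has no row-row terms, and a row's module sums over all columns add
    to zero, so the best attachment is always >= 0). This is an exact
    search over the quotient of the full partition lattice.
    """
    nr, nc = len(net.row_ids), len(net.col_ids)
    if nr + nc > 12:
        raise ValueError(
            "exhaustive search limited to <= 12 nodes; use quanbimo() instead"
        )
    B = _B(net)
    best_q = -np.inf
    best = None
    for blocks in _set_partitions(list(range(nc))):
        S = np.column_stack([B[:, blk].sum(axis=1) for blk in blocks])
        row_best = S.max(axis=1)
        q = float(np.maximum(row_best, 0.0).sum())
        if q > best_q + 1e-15:
            best_q = q
            best = (blocks, S)
    blocks, S = best
    col_labels = np.empty(nc, dtype=np.int64)
    for lab, blk in enumerate(blocks, start=1):
        col_labels[blk] = lab
    row_labels = S.argmax(axis=1) + 1
    part = ModulePartition.from_raw(row_labels, col_labels)
    q = modularity_Q(net, part)
    return ModularityResult(Q=max(best_q, q), partition=part,
                            n_modules=part.n_modules,
                            trace={"method": "exhaustive"})


def _polish_partition(B: np.ndarray, cl: np.ndarray, max_passes: int = 50):
    """Deterministic local search: optimal row attachment + column moves.

    Given column labels, each row's best attachment is computable exactly
    (row-row pairs never enter Q), so the search reduces to single-column
    moves with rows re-attached optimally after every candidate move.
    """
    nr, nc = B.shape
    cl = cl.copy()

    def score(col_labels):
        mods = np.unique(col_labels)
        S = np.column_stack([B[:, col_labels == m].sum(axis=1) for m in mods])
        return float(np.maximum(S.max(axis=1), 0.0).sum())

    best = score(cl)
    for _ in range(max_passes):
        improved = False
        for j in range(nc):
            old = cl[j]
            candidates = set(cl) | {cl.max() + 1}
            candidates.discard(old)
            for m in candidates:
                cl[j] = m
                q = score(cl)
                if q > best + 1e-12:
                    best = q
                    old = m
                    improved = True
                else:
                    cl[j] = old
        if not improved:
            break
    mods = np.unique(cl)
    S = np.column_stack([B[:, cl == m].sum(axis=1) for m in mods])
    rl = mods[S.argmax(axis=1)]
    return best, rl, cl


def _anneal_once(
    B: np.ndarray,
    rng: np.random.Generator,
    steps: int,
    cooling: float,
    t0: float | None,
) -> tuple[float, np.ndarray, np.ndarray]:
    nr, nc = B.shape
    n_nodes = nr + nc
    # labels: 0-based module indices over rows then cols
    labels = np.concatenate([
        rng.integers(0, min(nc, 4), size=nr),
        np.arange(nc) % min(nc, 4),
    ])

    def q_of(lab: np.ndarray) -> float:
        rl, cl = lab[:nr], lab[nr:]
        same = rl[:, None] == cl[None, :]
        return float(B[same].sum())

    def delta_move(lab, node, new_mod):
        old = lab[node]
        if node < nr:
            cl = lab[nr:]
            return B[node, cl == new_mod].sum() - B[node, cl == old].sum()
        j = node - nr
        rl = lab[:nr]
        return B[rl == new_mod, j].sum() - B[rl == old, j].sum()

    def propose_module(lab, node):
        used = np.unique(lab)
        fresh = used.max() + 1
        choices = np.append(used[used != lab[node]], fresh)
        return int(choices[rng.integers(choices.size)])

    # Calibrate the initial temperature so roughly half the worsening
    # warm-up moves would be accepted.
    if t0 is None:
        worsens = []
        for _ in range(100):
            node = rng.integers(n_nodes)
            d = delta_move(labels, node, propose_module(labels, node))
            if d < 0:
                worsens.append(-d)
        t0 = (np.median(worsens) / np.log(2.0)) if worsens else 1e-3
        t0 = max(t0, 1e-9)

    q = q_of(labels)
    best_q, best_lab = q, labels.copy()
    T = t0
    for step in range(steps):
        if nc > 1 and rng.random() < 0.05:
            # merge move: relabel one module into another
            used = np.unique(labels)
            if used.size > 1:
                a, b = rng.choice(used, size=2, replace=False)
                old_labels = labels.copy()
                old_q = q
                labels[labels == a] = b
                q = q_of(labels)
                d = q - old_q
                if d >= 0 or rng.random() < np.exp(d / T):
                    if q > best_q:
                        best_q, best_lab = q, labels.copy()
                else:
                    labels, q = old_labels, old_q
            T *= cooling
            continue
        node = rng.integers(n_nodes)
        new_mod = propose_module(labels, node)
        d = delta_move(labels, node, new_mod)
        if d >= 0 or rng.random() < np.exp(d / T):
            labels[node] = new_mod
            q += d
            if q > best_q:
                best_q, best_lab = q, labels.copy()
        T *= cooling
    # deterministic polish from the best annealed state
    best_q, rl, cl = _polish_partition(B, best_lab[nr:])
    return best_q, rl, cl


def quanbimo(
    net: BipartiteNetwork,
    steps: int = 10_000,
    initial_temperature: float | None = None,
    cooling_rate: float = 0.995,
    restarts: int = 5,
    seed: int = 0,
) -> ModularityResult:
    """Simulated-annealing maximization of weighted bipartite modularity.

    Single-node reassignments with Metropolis acceptance under geometric
    cooling; best state over ``restarts`` independent runs is returned.
    Modules containing only row nodes are merged into their best column
    module on output (this never lowers Q, because each row's best column
    module is always >= 0). Deterministic under ``seed``.
    """
    if steps <= 0 or restarts <= 0 or not (0 < cooling_rate <= 1):
        raise ValueError("invalid annealing schedule")
    B = _B(net)
    nr, nc = B.shape
    rng = np.random.default_rng(seed)
    best = (-np.inf, None, None)
    restart_qs = []
    for _ in range(restarts):
        q, rl, cl = _anneal_once(B, rng, steps, cooling_rate, initial_temperature)
        restart_qs.append(q)
        if q > best[0]:
            best = (q, rl, cl)
    _, rl, cl = best
    # Presentation: every row joins its best column module.
    col_mods = np.unique(cl)
    S = np.column_stack([B[:, cl == m].sum(axis=1) for m in col_mods])
    rl = col_mods[S.argmax(axis=1)]
    part = ModulePartition.from_raw(rl, cl)
    q = modularity_Q(net, part)
    if q < 0.0:  # the single-module partition (Q = 0) is always available
        part = ModulePartition.single_module(nr, nc)
        q = 0.0
    return ModularityResult(
        Q=q, partition=part, n_modules=part.n_modules,
        trace={"restart_Q": [float(v) for v in restart_qs],
               "steps": steps, "cooling": cooling_rate, "restarts": restarts,
               "seed": seed},
    )


def modularity_test(
    net: BipartiteNetwork,
    n: int = 100,
    seed: int = 0,
    steps: int = 10_000,
    restarts: int = 5,
    cooling_rate: float = 0.995,
) -> ModularityResult:
    """Annealed Q of the observed network versus vaznull nulls, upper tail."""
    obs = quanbimo(net, steps=steps, restarts=restarts,
                   cooling_rate=cooling_rate, seed=seed)
    ensemble = vaznull(net, n, seed + 1)
    null_q = []
    for i, m in enumerate(ensemble.matrices):
        null_net = BipartiteNetwork(net.row_ids, net.col_ids, m)
        res = quanbimo(null_net, steps=steps, restarts=max(1, restarts // 2),
                       cooling_rate=cooling_rate, seed=seed + 2 + i)
        null_q.append(res.Q)
    sig = significance(obs.Q, null_q, tail="upper")
    return ModularityResult(
        Q=obs.Q, partition=obs.partition, n_modules=obs.n_modules,
        significance=sig, trace=obs.trace,
    )
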