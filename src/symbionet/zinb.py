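"""Zero-inflated count mixed models with per-taxon Laplace approximation.

The model for read count ``y_ts`` of taxon ``t`` in sample ``s`` (whose
tissue belongs to group ``g(s)`` under a tissue partition):

    count component   log mu_ts = beta_{g(s)} + offset_s + u_t + v_{t,g(s)}
    random effects    u_t ~ N(0, sigma_u^2),  v_{t,g} ~ N(0, sigma_v^2)
    zero inflation    logit pi_t = z_t,  z_t ~ N(zeta_0, sigma_z^2)
    observation       y_ts ~ pi_t * delta_0 + (1 - pi_t) * NB2(mu_ts, theta)

The null model drops the grouping: a single fixed intercept, no ``v``.
Zero inflation varies across taxa through the random intercept ``z_t``.

Random effects are independent across taxa given the variance components,
so the marginal likelihood factorizes into per-taxon blocks. Each block is
integrated by a Laplace approximation at the joint mode of
``(u_t, v_t., z_t)``, found by a damped Newton iteration vectorized across
taxa; the outer parameters are maximized by L-BFGS-B with finite-difference
gradients and warm-started inner modes.

Parameter count (used for AICc): ``G`` fixed group means + dispersion +
sigma_u^2 + sigma_v^2 + zeta_0 + sigma_z^2 = G + 5 for a grouping model,
and 5 for the null model (no sigma_v^2, single intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

Family = Literal["nbinom2", "poisson"]

_ETA_CLIP = 30.0
_Z_CLIP = 30.0

try:  # compiled kernels for the per-cell likelihood chains
    from ._zinb_kernels import nb_obj as _nb_obj, nb_gradhess as _nb_gradhess
    _HAVE_KERNELS = True
except Exception:  # pragma: no cover - numba unavailable
    _HAVE_KERNELS = False


@dataclass(frozen=True)
class GlmmFit:
    """A fitted zero-inflated count mixed model."""

    group_names: tuple[str, ...]        # () for the null model
    family: str
    beta: np.ndarray                    # (G,) group means, or (1,) intercept
    theta: float                        # NB dispersion (inf for poisson)
    sigma_u2: float
    sigma_v2: float | None              # None for the null model
    zeta0: float
    sigma_z2: float
    loglik: float
    k: int
    n_obs: int
    converged: bool
    taxon_ids: tuple[str, ...]
    modes_u: np.ndarray                 # (T,)
    modes_v: np.ndarray | None          # (T, G)
    modes_z: np.ndarray                 # (T,)
    message: str = ""

    @property
    def zero_inflation_mean(self) -> float:
        """Average structural-zero probability across taxa (at the modes)."""
        return float(expit(self.modes_z).mean())

    def to_dict(self) -> dict:
        return {
            "group_names": list(self.group_names),
            "family": self.family,
            "beta": [float(b) for b in self.beta],
            "theta": self.theta,
            "sigma_u2": self.sigma_u2,
            "sigma_v2": self.sigma_v2,
            "zeta0": self.zeta0,
            "sigma_z2": self.sigma_z2,
            "loglik": self.loglik,
            "k": self.k,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


@dataclass
class _Block:
    """Preprocessed arrays shared by every likelihood evaluation."""

    Y: np.ndarray          # (T, S) counts
    offset: np.ndarray     # (S,)
    gidx: np.ndarray | None  # (S,) group index, None for the null model
    G: int                 # number of groups (0 for null)
    pos: np.ndarray        # boolean (T, S), y > 0
    lgamma_y1: np.ndarray  # (T, S) lgamma(y + 1)
    group_masks: list[np.ndarray] = field(default_factory=list)
    ridx: np.ndarray | None = None    # rows of the root block (sub-blocks)
    _root: "object" = None
    _gl_cache: dict = field(default_factory=dict)

    @classmethod
    def build(cls, Y, offset, gidx, G):
        Y = np.asarray(Y, dtype=np.int64)
        blk = cls(
            Y=Y,
            offset=np.asarray(offset, dtype=float),
            gidx=None if gidx is None else np.asarray(gidx, dtype=np.int64),
            G=G,
            pos=Y > 0,
            lgamma_y1=gammaln(Y + 1.0),
        )
        if gidx is not None:
            blk.group_masks = [blk.gidx == g for g in range(G)]
            blk.onehot = np.column_stack(
                [m.astype(float) for m in blk.group_masks])   # (S, G)
        return blk

    def rows(self, idx):
        """A view-block restricted to the taxa in ``idx``."""
        sub = _Block(
            Y=self.Y[idx], offset=self.offset, gidx=self.gidx, G=self.G,
            pos=self.pos[idx], lgamma_y1=self.lgamma_y1[idx],
            ridx=idx, _root=self if self._root is None else self._root,
        )
        sub.group_masks = self.group_masks
        sub.onehot = getattr(self, "onehot", None)
        return sub

    def lgamma_yth(self, theta):
        """Dense lgamma(Y + theta), memoized per theta on the root block."""
        root = self._root if self._root is not None else self
        cached = root._gl_cache.get(theta)
        if cached is None:
            root._gl_cache.clear()   # one-slot memo: theta fixed per eval
            cached = gammaln(root.Y + theta)
            root._gl_cache[theta] = cached
        return cached if self.ridx is None else cached[self.ridx]

    def count_tables(self, theta):
        """(lgamma(y + theta), lgamma(y + 1)) tables over count values."""
        root = self._root if self._root is not None else self
        ymax = getattr(root, "_ymax", None)
        if ymax is None:
            ymax = int(root.Y.max(initial=0))
            root._ymax = ymax
            root._gl1_table = gammaln(np.arange(ymax + 1) + 1.0)
        key = ("tab", theta)
        tab = root._gl_cache.get(key)
        if tab is None:
            for k in [k for k in root._gl_cache if isinstance(k, tuple)]:
                del root._gl_cache[k]
            tab = gammaln(np.arange(ymax + 1) + theta)
            root._gl_cache[key] = tab
        return tab, root._gl1_table


def _linpred(blk, B, beta):
    u = B[:, 0]
    if blk.G:
        v = B[:, 1:1 + blk.G]
        eta = beta[blk.gidx][None, :] + blk.offset[None, :] + u[:, None] + v[:, blk.gidx]
    else:
        eta = beta[0] + blk.offset[None, :] + u[:, None]
    pi = expit(np.clip(B[:, -1], -_Z_CLIP, _Z_CLIP))[:, None]
    return eta, pi


def _obs_loglik(blk, eta, pi, theta, family):
    """Per-observation zero-inflated log-likelihood (no derivatives)."""
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    if family == "nbinom2":
        th = theta
        log_p0 = th * (np.log(th) - np.log(mu + th))
    else:
        log_p0 = -mu
    L0 = pi + (1.0 - pi) * np.exp(log_p0)
    ll = np.log(np.maximum(L0, 1e-300))
    pos = blk.pos
    yp = blk.Y[pos].astype(float)
    mup = mu[pos]
    pip = np.broadcast_to(pi, blk.Y.shape)[pos]
    if family == "nbinom2":
        th = theta
        denp = mup + th
        llp = (
            blk.lgamma_yth(theta)[pos] - gammaln(th) - blk.lgamma_y1[pos]
            + th * np.log(th / denp) + yp * np.log(mup / denp)
        )
    else:
        llp = yp * np.log(mup) - mup - blk.lgamma_y1[pos]
    ll[pos] = np.log1p(-pip) + llp
    return ll


def _obs_derivs(Y, pos, eta, pi_col, theta, family):
    """Per-observation first/second derivatives of the log-likelihood.

    Returns (gE, hE, gZ, hZ, hC): derivatives with respect to the linear
    predictor eta and the zero-inflation logit z. ``pi_col`` is the
    per-taxon inflation probability broadcast over samples.
    """
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    pi = pi_col
    w = pi * (1.0 - pi)                       # d pi / d z

    if family == "nbinom2":
        th = theta
        denom = mu + th
        log_p0 = th * (np.log(th) - np.log(denom))
        s0 = -th * mu / denom
        ds0 = -mu * th**2 / denom**2
    else:  # poisson
        log_p0 = -mu
        s0 = -mu
        ds0 = -mu

    p0 = np.exp(log_p0)
    # zero observations: mixture mass pi + (1-pi) p0
    L0 = pi + (1.0 - pi) * p0
    L0 = np.maximum(L0, 1e-300)
    c = (1.0 - pi) * p0 / L0                  # P(count zero | observed zero)
    out_gE = c * s0
    out_hE = c * (1.0 - c) * s0**2 + c * ds0
    gZ0 = w * (1.0 - p0) / L0
    out_gZ = gZ0.copy()
    out_hZ = (1.0 - 2.0 * pi) * w * (1.0 - p0) / L0 - gZ0**2
    out_hC = -w * p0 * s0 / L0 - gZ0 * out_gE

    # positive observations
    mup = mu[pos]
    pip = np.broadcast_to(pi, Y.shape)[pos]
    yp = Y[pos].astype(float)
    if family == "nbinom2":
        th = theta
        denp = mup + th
        out_gE[pos] = th * (yp - mup) / denp
        out_hE[pos] = -mup * th * (yp + th) / denp**2
    else:
        out_gE[pos] = yp - mup
        out_hE[pos] = -mup
    out_gZ[pos] = -pip
    out_hZ[pos] = -pip * (1.0 - pip)
    out_hC[pos] = 0.0
    return out_gE, out_hE, out_gZ, out_hZ, out_hC


def _penalized_obj(blk, B, beta, theta, su2, sv2, zeta0, sz2, family):
    """Negative penalized log joint per taxon: -(loglik + log prior)."""
    u = B[:, 0]
    z = B[:, -1]
    eta, pi = _linpred(blk, B, beta)
    if _HAVE_KERNELS:
        poisson = family == "poisson"
        th = 1.0 if poisson else theta
        gl_yth, gl_y1 = blk.count_tables(th)
        llsum = _nb_obj(blk.Y, eta, B[:, -1], th, gl_yth, gl_y1,
                        float(gammaln(th)), poisson)
        obj = -llsum
    else:
        ll = _obs_loglik(blk, eta, pi, theta, family)
        obj = -ll.sum(axis=1)
    obj += 0.5 * u**2 / su2 + 0.5 * np.log(2 * np.pi * su2)
    if blk.G:
        v = B[:, 1:1 + blk.G]
        obj += 0.5 * (v**2).sum(axis=1) / sv2 + 0.5 * blk.G * np.log(2 * np.pi * sv2)
    obj += 0.5 * (z - zeta0)**2 / sz2 + 0.5 * np.log(2 * np.pi * sz2)
    return obj


def _grad_hess(blk, B, beta, theta, su2, sv2, zeta0, sz2, family):
    """Batched gradient (T, d) and Hessian (T, d, d) of the penalized obj."""
    T = blk.Y.shape[0]
    G = blk.G
    d = 2 + G
    u = B[:, 0]
    z = B[:, -1]
    if G:
        v = B[:, 1:1 + G]
        eta = beta[blk.gidx][None, :] + blk.offset[None, :] + u[:, None] + v[:, blk.gidx]
    else:
        eta = beta[0] + blk.offset[None, :] + u[:, None]
    if _HAVE_KERNELS:
        poisson = family == "poisson"
        th = 1.0 if poisson else theta
        gidx = blk.gidx if G else np.zeros(0, dtype=np.int64)
        sums, gsums = _nb_gradhess(blk.Y, eta, z, th, gidx, G, poisson)
        sum_gE, sum_hE, sum_gZ, sum_hZ, sum_hC = sums.T
        if G:
            gE_g, hE_g, hC_g = gsums[..., 0], gsums[..., 1], gsums[..., 2]
    else:
        pi = expit(np.clip(z, -_Z_CLIP, _Z_CLIP))[:, None]
        gE, hE, gZ, hZ, hC = _obs_derivs(blk.Y, blk.pos, eta, pi, theta, family)
        sum_gE = gE.sum(axis=1)
        sum_hE = hE.sum(axis=1)
        sum_gZ = gZ.sum(axis=1)
        sum_hZ = hZ.sum(axis=1)
        sum_hC = hC.sum(axis=1)
        if G:
            gE_g = gE @ blk.onehot      # (T, G) per-group sums
            hE_g = hE @ blk.onehot
            hC_g = hC @ blk.onehot

    grad = np.zeros((T, d))
    hess = np.zeros((T, d, d))
    grad[:, 0] = -sum_gE + u / su2
    grad[:, -1] = -sum_gZ + (z - zeta0) / sz2
    hess[:, 0, 0] = -sum_hE + 1.0 / su2
    hess[:, -1, -1] = -sum_hZ + 1.0 / sz2
    hess[:, 0, -1] = hess[:, -1, 0] = -sum_hC
    if G:
        cols = np.arange(1, 1 + G)
        grad[:, 1:1 + G] = -gE_g + v / sv2
        hess[:, cols, cols] = -hE_g + 1.0 / sv2
        hess[:, 0, 1:1 + G] = hess[:, 1:1 + G, 0] = -hE_g
        hess[:, cols, -1] = hess[:, -1, cols] = -hC_g
    return grad, hess


def _laplace_loglik(blk, params_dict, B0, family, inner_tol=1e-8, max_newton=40):
    """Laplace-approximate marginal log-likelihood and the inner modes.

    Damped Newton per taxon; converged taxa are frozen so the line search
    only ever re-evaluates the still-active rows.
    """
    beta = params_dict["beta"]
    theta = params_dict["theta"]
    su2 = params_dict["su2"]
    sv2 = params_dict["sv2"]
    zeta0 = params_dict["zeta0"]
    sz2 = params_dict["sz2"]
    args = (beta, theta, su2, sv2, zeta0, sz2, family)
    T = blk.Y.shape[0]
    d = 2 + blk.G
    eye = np.eye(d)[None]
    B = B0.copy()
    f = _penalized_obj(blk, B, *args)
    lam = np.zeros(T)

    def newton():
        nonlocal B, f
        hess_fresh = None
        for _ in range(max_newton):
            grad, hess = _grad_hess(blk, B, *args)
            hess_fresh = hess
            active = np.abs(grad).max(axis=1) > inner_tol
            if not active.any():
                break
            idx = np.flatnonzero(active)
            sub = blk.rows(idx)
            H = hess[idx] + (lam[idx, None, None] + 1e-10) * eye
            try:
                step = np.linalg.solve(H, grad[idx, :, None])[..., 0]
            except np.linalg.LinAlgError:
                lam[idx] = np.maximum(lam[idx] * 10, 1e-4)
                continue
            # trust region: cap the per-taxon step so a far-from-mode start
            # cannot fling the state into the saturated tails
            norms = np.linalg.norm(step, axis=1)
            cap = np.minimum(1.0, 3.0 / np.maximum(norms, 1e-12))
            step = step * cap[:, None]
            # backtracking line search over the active taxa only; later
            # trials re-evaluate just the rows that are still worse
            Ba, fa = B[idx], f[idx]
            scale = np.ones(idx.size)
            tol_f = 1e-10 * (1.0 + np.abs(fa))
            Bn = Ba - step
            fn = _penalized_obj(sub, Bn, *args)
            worse = fn > fa + tol_f
            for _ in range(11):
                if not worse.any():
                    break
                w = np.flatnonzero(worse)
                scale[w] *= 0.5
                Bn[w] = Ba[w] - scale[w, None] * step[w]
                fn_w = _penalized_obj(blk.rows(idx[w]), Bn[w], *args)
                fn[w] = fn_w
                worse[w] = fn_w > fa[w] + tol_f[w]
            ok = fn <= fa + tol_f
            Ba = np.where(ok[:, None], Bn, Ba)
            fa = np.where(ok, fn, fa)
            B[idx], f[idx] = Ba, fa
            lam[idx[ok]] *= 0.1
            lam[idx[~ok]] = np.maximum(lam[idx[~ok]] * 10, 1e-4)
            hess_fresh = None
        if hess_fresh is None:
            _, hess_fresh = _grad_hess(blk, B, *args)
        return hess_fresh

    # Newton with saddle escape: a zero-gradient point can be a saddle of
    # the joint (e.g. perfectly separated zero patterns make the count and
    # inflation components trade off); kick such taxa along their negative
    # curvature direction, downhill, and re-converge. The PD check is a
    # batched Cholesky (the common, all-PD case costs one factorization,
    # which also yields the log-determinants).
    for _ in range(4):
        hess = newton()
        try:
            chol = np.linalg.cholesky(hess + 1e-10 * eye)
            break
        except np.linalg.LinAlgError:
            pass
        eigval, eigvec = np.linalg.eigh(hess + 1e-10 * eye)
        saddle = eigval[:, 0] <= 0
        if not saddle.any():   # pragma: no cover - cholesky/eigh disagree
            chol = None
            break
        idx = np.flatnonzero(saddle)
        direction = eigvec[idx, :, 0]
        kick = 0.5 * np.maximum(1.0, np.abs(B[idx]).max(axis=1))[:, None]
        sub = blk.rows(idx)
        f_plus = _penalized_obj(sub, B[idx] + kick * direction, *args)
        f_minus = _penalized_obj(sub, B[idx] - kick * direction, *args)
        sgn = np.where(f_plus <= f_minus, 1.0, -1.0)[:, None]
        B[idx] = B[idx] + sgn * kick * direction
        f[idx] = np.minimum(f_plus, f_minus)
        lam[idx] = 1e-2
        chol = None
    if chol is not None:
        diag = np.diagonal(chol, axis1=1, axis2=2)
        logdet = 2.0 * np.log(diag).sum(axis=1)
    else:
        logger.warning("Laplace: non-PD curvature persists; eigenvalues floored")
        eigval = np.linalg.eigvalsh(hess + 1e-10 * eye)
        logdet = np.log(np.maximum(eigval, 1e-10)).sum(axis=1)
    ll = (-f + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet).sum()
    return float(ll), B


def _pack(params_dict, G, family):
    parts = [params_dict["beta"]]
    if family == "nbinom2":
        parts.append([np.log(params_dict["theta"])])
    parts.append([np.log(params_dict["su2"])])
    if G:
        parts.append([np.log(params_dict["sv2"])])
    parts.append([params_dict["zeta0"], np.log(params_dict["sz2"])])
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _unpack(x, G, family):
    nb = G if G else 1
    i = nb
    beta = np.asarray(x[:nb], dtype=float)
    if family == "nbinom2":
        theta = float(np.exp(x[i])); i += 1
    else:
        theta = np.inf
    su2 = float(np.exp(x[i])); i += 1
    if G:
        sv2 = float(np.exp(x[i])); i += 1
    else:
        sv2 = None
    zeta0 = float(x[i]); i += 1
    sz2 = float(np.exp(x[i]))
    return {"beta": beta, "theta": theta, "su2": su2,
            "sv2": sv2 if G else 1.0, "zeta0": zeta0, "sz2": sz2}


def fit_zinb_glmm_arrays(
    Y: np.ndarray,
    offset: np.ndarray,
    gidx: np.ndarray | None,
    G: int,
    group_names: Sequence[str] = (),
    taxon_ids: Sequence[str] | None = None,
    family: Family = "nbinom2",
    start: np.ndarray | None = None,
    mode_start: np.ndarray | None = None,
    maxiter: int = 200,
    ftol: float = 1e-8,
) -> GlmmFit:
    """Fit the model on pivoted arrays (taxa x samples).

    ``gidx=None`` (with ``G=0``) fits the null model: intercept only, no
    taxon-by-group interaction. ``start`` warm-starts the outer parameters
    and ``mode_start`` (T x (G+2)) the inner random-effect modes.
    """
    Y = np.asarray(Y, dtype=np.int64)
    T, S = Y.shape
    if T < 2 or S < 2:
        raise ValueError("need at least 2 taxa and 2 samples")
    blk = _Block.build(Y, offset, gidx, G)
    d = 2 + G

    # starting values
    if start is None:
        off = np.exp(np.asarray(offset, dtype=float))
        if G:
            beta0 = np.array([
                np.log(max(Y[:, m].sum(), 1) / (T * off[m].sum()))
                for m in blk.group_masks
            ])
        else:
            beta0 = np.array([np.log(max(Y.sum(), 1) / (T * off.sum()))])
        x0 = _pack(
            {"beta": beta0, "theta": 1.0, "su2": 1.0, "sv2": 0.5,
             "zeta0": -1.0, "sz2": 0.5},
            G, family,
        )
    else:
        x0 = np.asarray(start, dtype=float)

    nb = G if G else 1
    bounds = [(-30, 30)] * nb
    if family == "nbinom2":
        bounds += [(-4, 8)]
    bounds += [(-8, 4)]          # log sigma_u^2
    if G:
        bounds += [(-8, 4)]      # log sigma_v^2
    bounds += [(-8, 8), (-8, 4)]  # zeta0, log sigma_z^2

    if mode_start is not None and mode_start.shape == (T, d):
        mode_cache = {"B": np.asarray(mode_start, dtype=float).copy()}
    else:
        mode_cache = {"B": np.zeros((T, d))}

    def nll(x):
        pd_ = _unpack(x, G, family)
        ll, B = _laplace_loglik(blk, pd_, mode_cache["B"], family)
        mode_cache["B"] = B
        return -ll

    # FD step must sit well above the inner-Laplace noise floor (~1e-8)
    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": ftol, "maxcor": 25, "eps": 1e-5},
    )
    pd_ = _unpack(res.x, G, family)
    ll, B = _laplace_loglik(blk, pd_, mode_cache["B"], family, inner_tol=1e-9)

    k = nb + (1 if family == "nbinom2" else 0) + 1 + (1 if G else 0) + 2
    if taxon_ids is None:
        taxon_ids = [f"t{i}" for i in range(T)]
    return GlmmFit(
        group_names=tuple(group_names),
        family=family,
        beta=pd_["beta"],
        theta=pd_["theta"],
        sigma_u2=pd_["su2"],
        sigma_v2=pd_["sv2"] if G else None,
        zeta0=pd_["zeta0"],
        sigma_z2=pd_["sz2"],
        loglik=float(ll),
        k=k,
        n_obs=int(T * S),
        converged=bool(res.success),
        taxon_ids=tuple(taxon_ids),
        modes_u=B[:, 0].copy(),
        modes_v=B[:, 1:1 + G].copy() if G else None,
        modes_z=B[:, -1].copy(),
        message=str(res.message),
    )


def simulate_zinb_dataset(
    n_taxa: int,
    groups: Sequence[str],
    samples_per_group: int,
    beta: Sequence[float],
    sigma_u: float,
    sigma_v: float,
    theta: float,
    zeta0: float,
    sigma_z: float,
    offset: float = 0.0,
    seed: int = 0,
):
    """Draw (Y, gidx, offset, truth) exactly from the generative model.

    Used by parameter-recovery experiments: the returned ``truth`` dict
    holds the sampled random effects so conditional-mode recovery can be
    asserted against them.
    """
    rng = np.random.default_rng(seed)
    G = len(groups)
    S = G * samples_per_group
    gidx = np.repeat(np.arange(G), samples_per_group)
    u = rng.normal(0, sigma_u, size=n_taxa)
    v = rng.normal(0, sigma_v, size=(n_taxa, G))
    z = rng.normal(zeta0, sigma_z, size=n_taxa)
    pi = expit(z)
    beta = np.asarray(beta, dtype=float)
    eta = beta[gidx][None, :] + offset + u[:, None] + v[:, gidx]
    mu = np.exp(eta)
    if np.isfinite(theta):
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    structural = rng.random((n_taxa, S)) < pi[:, None]
    Y = np.where(structural, 0, counts)
    truth = {"u": u, "v": v, "z": z, "pi": pi, "gidx": gidx}
    return Y, gidx, np.full(S, float(offset)), truth
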