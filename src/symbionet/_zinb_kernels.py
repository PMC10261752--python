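"""Numba kernels for the zero-inflated count likelihood.

These fuse the per-observation likelihood/derivative chains of the mixed
model into single passes over the (taxa x samples) array. They are exact
re-implementations of the numpy reference path in ``zinb.py`` (no fastmath,
so results agree to floating-point rounding); the reference path remains
the fallback when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_ETA_CLIP = 30.0
_Z_CLIP = 30.0


@njit(cache=True)
def nb_obj(Y, eta, z, theta, gl_yth, gl_y1, lgam_th, poisson):
    """Per-taxon observation log-likelihood sums.

    ``gl_yth[y]`` holds lgamma(y + theta) and ``gl_y1[y]`` lgamma(y + 1)
    for every count value ``y`` present in ``Y``.
    """
    T, S = Y.shape
    out = np.zeros(T)
    log_theta = math.log(theta) if not poisson else 0.0
    for t in range(T):
        zt = z[t]
        if zt > _Z_CLIP:
            zt = _Z_CLIP
        elif zt < -_Z_CLIP:
            zt = -_Z_CLIP
        pi = 1.0 / (1.0 + math.exp(-zt))
        log1mpi = math.log1p(-pi)
        acc = 0.0
        for s in range(S):
            e = eta[t, s]
            if e > _ETA_CLIP:
                e = _ETA_CLIP
            elif e < -_ETA_CLIP:
                e = -_ETA_CLIP
            mu = math.exp(e)
            y = Y[t, s]
            if poisson:
                lp0 = -mu
            else:
                lp0 = theta * (log_theta - math.log(mu + theta))
            if y == 0:
                L0 = pi + (1.0 - pi) * math.exp(lp0)
                if L0 < 1e-300:
                    L0 = 1e-300
                acc += math.log(L0)
            else:
                if poisson:
                    acc += log1mpi + y * e - mu - gl_y1[y]
                else:
                    logden = math.log(mu + theta)
                    acc += (log1mpi + gl_yth[y] - lgam_th - gl_y1[y]
                            + theta * (log_theta - logden) + y * (e - logden))
        out[t] = acc
    return out


@njit(cache=True)
def nb_gradhess(Y, eta, z, theta, gidx, G, poisson):
    """Per-taxon sums of first/second derivatives of the observation loglik.

    Returns (sums, gsums) where ``sums[t] = (sum_gE, sum_hE, sum_gZ,
    sum_hZ, sum_hC)`` and ``gsums[t, g] = (gE, hE, hC)`` per tissue group
    (empty when ``G == 0``).
    """
    T, S = Y.shape
    sums = np.zeros((T, 5))
    gsums = np.zeros((T, max(G, 1), 3))
    for t in range(T):
        zt = z[t]
        if zt > _Z_CLIP:
            zt = _Z_CLIP
        elif zt < -_Z_CLIP:
            zt = -_Z_CLIP
        pi = 1.0 / (1.0 + math.exp(-zt))
        w = pi * (1.0 - pi)
        for s in range(S):
            e = eta[t, s]
            if e > _ETA_CLIP:
                e = _ETA_CLIP
            elif e < -_ETA_CLIP:
                e = -_ETA_CLIP
            mu = math.exp(e)
            y = Y[t, s]
            if y == 0:
                if poisson:
                    lp0 = -mu
                    s0 = -mu
                    ds0 = -mu
                else:
                    den = mu + theta
                    lp0 = theta * (math.log(theta) - math.log(den))
                    s0 = -theta * mu / den
                    ds0 = -mu * theta * theta / (den * den)
                p0 = math.exp(lp0)
                L0 = pi + (1.0 - pi) * p0
                if L0 < 1e-300:
                    L0 = 1e-300
                c = (1.0 - pi) * p0 / L0
                gE = c * s0
                hE = c * (1.0 - c) * s0 * s0 + c * ds0
                gZ = w * (1.0 - p0) / L0
                hZ = (1.0 - 2.0 * pi) * w * (1.0 - p0) / L0 - gZ * gZ
                hC = -w * p0 * s0 / L0 - gZ * gE
            else:
                if poisson:
                    gE = y - mu
                    hE = -mu
                else:
                    den = mu + theta
                    gE = theta * (y - mu) / den
                    hE = -mu * theta * (y + theta) / (den * den)
                gZ = -pi
                hZ = -w
                hC = 0.0
            sums[t, 0] += gE
            sums[t, 1] += hE
            sums[t, 2] += gZ
            sums[t, 3] += hZ
            sums[t, 4] += hC
            if G > 0:
                g = gidx[s]
                gsums[t, g, 0] += gE
                gsums[t, g, 1] += hE
                gsums[t, g, 2] += hC
    return sums, gsums
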