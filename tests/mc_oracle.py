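"""Independent layered (non-voxel) Monte Carlo oracle for engine tests.

A deliberately separate, vectorized implementation of photon transport in an
infinite plane-parallel slab of matched-index layers.  Because all layer
interfaces are index-matched, the exponential free path can be resampled at
every boundary crossing (memorylessness), which keeps the implementation
free of the dimensionless-pathlength bookkeeping the voxel engine uses —
the two codes share no transport logic beyond the physics.
"""

from __future__ import annotations

import numpy as np


def hg_cos(rng, g, n):
    xi = rng.random(n)
    if g == 0.0:
        return 1.0 - 2.0 * xi
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return np.clip((1.0 + g * g - frac * frac) / (2.0 * g), -1.0, 1.0)


def spin(rng, ux, uy, uz, cost):
    sint = np.sqrt(np.clip(1.0 - cost ** 2, 0.0, None))
    phi = 2.0 * np.pi * rng.random(len(ux))
    cosp, sinp = np.cos(phi), np.sin(phi)
    near_axis = np.abs(uz) > 1.0 - 1e-12
    tmp = np.sqrt(np.clip(1.0 - uz ** 2, 1e-30, None))
    nux = np.where(
        near_axis, sint * cosp,
        sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost)
    nuy = np.where(
        near_axis, np.sign(uz) * sint * sinp,
        sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost)
    nuz = np.where(near_axis, np.sign(uz) * cost, -sint * cosp * tmp + uz * cost)
    norm = np.sqrt(nux ** 2 + nuy ** 2 + nuz ** 2)
    return nux / norm, nuy / norm, nuz / norm


def layered_mc(layers, n_photons, seed, w_min=1e-4, p_surv=0.1,
               max_iter=100_000):
    """Diffuse reflectance/transmittance of a matched-index layered slab.

    ``layers``: sequence of (mu_a, mu_s, g, thickness_mm).  Photons enter at
    z = 0 along +z.  Returns a dict with mean reflectance/transmittance per
    photon, their standard errors, and the absorbed fraction.
    """
    rng = np.random.default_rng(seed)
    mu_a = np.array([l[0] for l in layers])
    mu_s = np.array([l[1] for l in layers])
    g = np.array([l[2] for l in layers])
    mu_t = mu_a + mu_s
    edges = np.concatenate([[0.0], np.cumsum([l[3] for l in layers])])
    n_layers = len(layers)

    z = np.zeros(n_photons)
    ux = np.zeros(n_photons)
    uy = np.zeros(n_photons)
    uz = np.ones(n_photons)
    w = np.ones(n_photons)
    lay = np.zeros(n_photons, dtype=int)
    alive = np.ones(n_photons, dtype=bool)
    refl = np.zeros(n_photons)
    trans = np.zeros(n_photons)
    absorbed = np.zeros(n_photons)

    for _ in range(max_iter):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        mt = mu_t[lay[idx]]
        step = -np.log(rng.random(len(idx))) / mt
        z_new = z[idx] + uz[idx] * step
        lo = edges[lay[idx]]
        hi = edges[lay[idx] + 1]
        cross_up = (uz[idx] < 0) & (z_new < lo)
        cross_down = (uz[idx] > 0) & (z_new > hi)
        interact = ~(cross_up | cross_down)

        # boundary crossings: move to the boundary, switch layer or exit
        up = idx[cross_up]
        z[up] = edges[lay[up]]
        lay[up] -= 1
        out = up[lay[up] < 0]
        refl[out] += w[out]
        alive[out] = False
        down = idx[cross_down]
        z[down] = edges[lay[down] + 1]
        lay[down] += 1
        out = down[lay[down] >= n_layers]
        trans[out] += w[out]
        alive[out] = False

        # interactions: drop, roulette, spin
        it = idx[interact]
        z[it] = z_new[interact]
        dep = w[it] * mu_a[lay[it]] / mu_t[lay[it]]
        absorbed[it] += dep
        w[it] -= dep
        low = it[w[it] < w_min]
        if len(low):
            survive = rng.random(len(low)) < p_surv
            killed = low[~survive]
            absorbed[killed] += w[killed]
            w[killed] = 0.0
            alive[killed] = False
            boosted = low[survive]
            absorbed[boosted] -= w[boosted] * (1.0 / p_surv - 1.0)
            w[boosted] /= p_surv
        it = it[alive[it]]
        for li in np.unique(lay[it]):
            sel = it[lay[it] == li]
            cost = hg_cos(rng, g[li], len(sel))
            ux[sel], uy[sel], uz[sel] = spin(rng, ux[sel], uy[sel], uz[sel], cost)
    else:
        raise RuntimeError("oracle failed to terminate")

    def mean_se(x):
        m = x.mean()
        return m, np.sqrt(max(x.var() / n_photons, 0.0))

    r_mean, r_se = mean_se(refl)
    t_mean, t_se = mean_se(trans)
    return {"R": r_mean, "R_se": r_se, "T": t_mean, "T_se": t_se,
            "A": absorbed.mean()}
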