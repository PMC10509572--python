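"""Numba core for the coalescent MCMC sampler.

Genealogy state is an array-encoded rooted binary tree (tips 0..n-1 at time
0, internals n..2n-2).  The STR likelihood uses Felsenstein pruning over a
bounded integer allele lattice with the closed-form symmetric single-step
(Skellam/Bessel) branch transition kernel; partial likelihoods are updated
incrementally along the path from a modified node to the root.  The
coalescent prior allows exponential growth: backwards in time the population
shrinks as N(t) = N exp(-alpha t), with alpha = beta / N for scaled growth
beta.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# SMM transition kernel


@njit(cache=True)
def _smm_kernel(theta: float, kmax: int, out: np.ndarray) -> None:
    """out[k] = P(|displacement| component k) = exp(-theta) I_k(theta).

    Computed by Miller's downward recurrence with the normalisation
    I_0 + 2 sum_{k>=1} I_k = exp(theta), which avoids overflow for the
    branch scales met here.
    """
    if theta < 1e-12:
        out[0] = 1.0
        for k in range(1, kmax + 1):
            out[k] = 0.0
        return
    start = kmax + int(theta) + 30
    u_hi = 0.0
    u_cur = 1e-280
    norm = 0.0
    for k in range(start, -1, -1):
        u_lo = u_hi + (2.0 * (k + 1) / theta) * u_cur
        if u_lo > 1e270:  # rescale to avoid overflow
            u_lo *= 1e-270
            u_cur *= 1e-270
            norm *= 1e-270
            for i in range(kmax + 1):
                out[i] *= 1e-270
        if k <= kmax:
            out[k] = u_lo
        norm += 2.0 * u_lo
        u_hi = u_cur
        u_cur = u_lo
    norm -= u_cur  # I_0 counted once
    for k in range(kmax + 1):
        out[k] /= norm


# ---------------------------------------------------------------------------
# Pruning likelihood


@njit(cache=True)
def _node_partial(
    u: int,
    left: np.ndarray,
    right: np.ndarray,
    times: np.ndarray,
    states: np.ndarray,  # (n_tips, L) lattice indices
    mus: np.ndarray,
    sizes: np.ndarray,  # lattice size per locus
    partials: np.ndarray,  # (m, L, smax)
    nodescale: np.ndarray,  # (m, L) log scale factors
    kern: np.ndarray,  # scratch (smax,)
    n_tips: int,
) -> None:
    L = mus.shape[0]
    smax = partials.shape[2]
    for l in range(L):
        S = sizes[l]
        acc_new = True
        for side in range(2):
            c = left[u] if side == 0 else right[u]
            theta = mus[l] * (times[u] - times[c])
            _smm_kernel(theta, S - 1, kern)
            if c < n_tips:
                st = states[c, l]
                if acc_new:
                    for j in range(S):
                        partials[u, l, j] = kern[abs(st - j)]
                    acc_new = False
                else:
                    for j in range(S):
                        partials[u, l, j] *= kern[abs(st - j)]
            else:
                if acc_new:
                    for j in range(S):
                        s = 0.0
                        for i in range(S):
                            s += kern[abs(i - j)] * partials[c, l, i]
                        partials[u, l, j] = s
                    acc_new = False
                else:
                    for j in range(S):
                        s = 0.0
                        for i in range(S):
                            s += kern[abs(i - j)] * partials[c, l, i]
                        partials[u, l, j] *= s
        mx = 0.0
        for j in range(S):
            if partials[u, l, j] > mx:
                mx = partials[u, l, j]
        if mx <= 0.0:
            mx = 1e-300
        for j in range(S):
            partials[u, l, j] /= mx
        nodescale[u, l] = math.log(mx)


@njit(cache=True)
def _loglik_from_arrays(
    root: int,
    partials: np.ndarray,
    nodescale: np.ndarray,
    sizes: np.ndarray,
    n_tips: int,
) -> float:
    m = partials.shape[0]
    L = partials.shape[1]
    total = 0.0
    for u in range(n_tips, m):
        for l in range(L):
            total += nodescale[u, l]
    for l in range(L):
        s = 0.0
        for i in range(sizes[l]):
            s += partials[root, l, i]
        total += math.log(s / sizes[l]) if s > 0 else -1e30
    return total


@njit(cache=True)
def _recompute_chain(
    u: int,
    parent: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    times: np.ndarray,
    states: np.ndarray,
    mus: np.ndarray,
    sizes: np.ndarray,
    partials: np.ndarray,
    nodescale: np.ndarray,
    kern: np.ndarray,
    n_tips: int,
) -> None:
    while u >= 0:
        _node_partial(u, left, right, times, states, mus, sizes, partials, nodescale, kern, n_tips)
        u = parent[u]


@njit(cache=True)
def _full_recompute(
    root: int,
    parent: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    times: np.ndarray,
    states: np.ndarray,
    mus: np.ndarray,
    sizes: np.ndarray,
    partials: np.ndarray,
    nodescale: np.ndarray,
    kern: np.ndarray,
    n_tips: int,
) -> None:
    m = parent.shape[0]
    order = np.argsort(times[n_tips:m]) + n_tips  # children precede parents
    for idx in range(order.shape[0]):
        _node_partial(order[idx], left, right, times, states, mus, sizes,
                      partials, nodescale, kern, n_tips)


# ---------------------------------------------------------------------------
# Coalescent prior


@njit(cache=True)
def _log_coalescent_prior(
    times: np.ndarray, n_tips: int, N: float, alpha: float
) -> float:
    """Log density of a labeled genealogy's event times under growth.

    Backwards-time intensity per pair is exp(alpha*t)/N.
    """
    m = times.shape[0]
    ev = np.sort(times[n_tips:m])
    logp = 0.0
    k = float(n_tips)
    t_prev = 0.0
    for j in range(ev.shape[0]):
        t = ev[j]
        if t < t_prev:
            return -1e30
        pairs = k * (k - 1.0) / 2.0
        if alpha > 1e-12:
            integral = (math.exp(alpha * t) - math.exp(alpha * t_prev)) / (alpha * N)
        else:
            integral = (t - t_prev) / N
        logp += -pairs * integral + alpha * t - math.log(N)
        t_prev = t
        k -= 1.0
    return logp


# ---------------------------------------------------------------------------
# Main sampler


@njit(cache=True)
def run_mcmc(
    states: np.ndarray,  # (n_tips, L) int64 lattice indices
    mus: np.ndarray,
    sizes: np.ndarray,
    parent: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    times: np.ndarray,
    n_iter: int,
    thin: int,
    seed: int,
    prior_only: int,
    n_init: float,
    fix_n: int,
    logn_mean: float,
    logn_sigma: float,
    beta_init: float,
    fix_growth: int,
    growth_scale: float,
):
    np.random.seed(seed)
    n_tips = states.shape[0]
    m = parent.shape[0]
    L = mus.shape[0]
    smax = int(np.max(sizes))
    root = -1
    for u in range(m):
        if parent[u] < 0:
            root = u

    partials = np.zeros((m, L, smax))
    nodescale = np.zeros((m, L))
    kern = np.zeros(smax + 1)
    use_lik = prior_only == 0
    if use_lik:
        _full_recompute(root, parent, left, right, times, states, mus, sizes,
                        partials, nodescale, kern, n_tips)
        loglik = _loglik_from_arrays(root, partials, nodescale, sizes, n_tips)
    else:
        loglik = 0.0

    N = n_init
    beta = beta_init
    alpha = beta / N
    logprior = _log_coalescent_prior(times, n_tips, N, alpha)

    n_rec = n_iter // thin
    rec_height = np.zeros(n_rec)
    rec_loglik = np.zeros(n_rec)
    rec_n = np.zeros(n_rec)
    rec_beta = np.zeros(n_rec)
    n_accept = 0
    n_props = 0

    saved_part = np.zeros((m, L, smax))
    saved_scale = np.zeros((m, L))
    chain = np.zeros(m, dtype=np.int64)

    internals = np.arange(n_tips, m)

    # move schedule; probability of fixed-parameter moves is redistributed
    p_slide = 0.40
    p_exch = 0.25
    p_scale = 0.15
    p_n = 0.10 if fix_n == 0 else 0.0
    p_beta = 0.10 if fix_growth == 0 else 0.0
    tot = p_slide + p_exch + p_scale + p_n + p_beta
    c_slide = p_slide / tot
    c_exch = c_slide + p_exch / tot
    c_scale = c_exch + p_scale / tot
    c_n = c_scale + p_n / tot

    for it in range(n_iter):
        move = np.random.random()
        n_props += 1
        clen = 0
        if move < c_slide:
            # --- node time slide ---
            u = internals[np.random.randint(0, internals.shape[0])]
            lo = max(times[left[u]], times[right[u]])
            old_t = times[u]
            log_hastings = 0.0
            if u == root:
                gap = old_t - lo
                fac = math.exp(1.0 * (np.random.random() - 0.5))
                new_t = lo + gap * fac
                log_hastings = math.log(fac)
            else:
                hi = times[parent[u]]
                new_t = lo + np.random.random() * (hi - lo)
            times[u] = new_t
            new_prior = _log_coalescent_prior(times, n_tips, N, alpha)
            if use_lik:
                # save chain u..root
                clen = 0
                v = u
                while v >= 0:
                    chain[clen] = v
                    saved_part[v, :, :] = partials[v, :, :]
                    saved_scale[v, :] = nodescale[v, :]
                    clen += 1
                    v = parent[v]
                _recompute_chain(u, parent, left, right, times, states, mus,
                                 sizes, partials, nodescale, kern, n_tips)
                new_lik = _loglik_from_arrays(root, partials, nodescale, sizes, n_tips)
            else:
                new_lik = 0.0
            log_ratio = (new_prior - logprior) + (new_lik - loglik) + log_hastings
            if math.log(np.random.random() + 1e-300) < log_ratio:
                logprior = new_prior
                loglik = new_lik
                n_accept += 1
            else:
                times[u] = old_t
                if use_lik:
                    for ci in range(clen):
                        v = chain[ci]
                        partials[v, :, :] = saved_part[v, :, :]
                        nodescale[v, :] = saved_scale[v, :]
        elif move < c_exch:
            # --- narrow exchange (swap node with its uncle) ---
            i = np.random.randint(0, m - 1)
            if i >= root:
                i += 1  # any non-root node
            p = parent[i]
            g = parent[p] if p >= 0 else -1
            if g >= 0:
                j = left[g] if right[g] == p else right[g]
                if times[p] > times[j]:
                    # swap i and j
                    if left[p] == i:
                        left[p] = j
                    else:
                        right[p] = j
                    if left[g] == j:
                        left[g] = i
                    else:
                        right[g] = i
                    parent[i] = g
                    parent[j] = p
                    new_prior = logprior  # times unchanged
                    if use_lik:
                        clen = 0
                        v = p
                        while v >= 0:
                            chain[clen] = v
                            saved_part[v, :, :] = partials[v, :, :]
                            saved_scale[v, :] = nodescale[v, :]
                            clen += 1
                            v = parent[v]
                        _recompute_chain(p, parent, left, right, times, states,
                                         mus, sizes, partials, nodescale, kern, n_tips)
                        new_lik = _loglik_from_arrays(root, partials, nodescale, sizes, n_tips)
                    else:
                        new_lik = 0.0
                    if math.log(np.random.random() + 1e-300) < (new_lik - loglik):
                        loglik = new_lik
                        n_accept += 1
                    else:
                        if left[p] == j:
                            left[p] = i
                        else:
                            right[p] = i
                        if left[g] == i:
                            left[g] = j
                        else:
                            right[g] = j
                        parent[i] = p
                        parent[j] = g
                        if use_lik:
                            for ci in range(clen):
                                v = chain[ci]
                                partials[v, :, :] = saved_part[v, :, :]
                                nodescale[v, :] = saved_scale[v, :]
        elif move < c_scale:
            # --- scale all internal times ---
            fac = math.exp(0.8 * (np.random.random() - 0.5))
            old_times = times.copy()
            for u in range(n_tips, m):
                times[u] *= fac
            log_hastings = (m - n_tips) * math.log(fac)
            new_prior = _log_coalescent_prior(times, n_tips, N, alpha)
            if use_lik:
                saved_part[:, :, :] = partials
                saved_scale[:, :] = nodescale
                _full_recompute(root, parent, left, right, times, states, mus,
                                sizes, partials, nodescale, kern, n_tips)
                new_lik = _loglik_from_arrays(root, partials, nodescale, sizes, n_tips)
            else:
                new_lik = 0.0
            log_ratio = (new_prior - logprior) + (new_lik - loglik) + log_hastings
            if math.log(np.random.random() + 1e-300) < log_ratio:
                logprior = new_prior
                loglik = new_lik
                n_accept += 1
            else:
                times[:] = old_times
                if use_lik:
                    partials[:, :, :] = saved_part
                    nodescale[:, :] = saved_scale
        elif move < c_n:
            # --- effective size update (prior-only term) ---
            if fix_n == 0:
                fac = math.exp(0.6 * (np.random.random() - 0.5))
                new_N = N * fac
                new_alpha = beta / new_N
                new_prior = _log_coalescent_prior(times, n_tips, new_N, new_alpha)
                lp_old = -0.5 * ((math.log(N) - logn_mean) / logn_sigma) ** 2 - math.log(N)
                lp_new = -0.5 * ((math.log(new_N) - logn_mean) / logn_sigma) ** 2 - math.log(new_N)
                log_ratio = (new_prior - logprior) + (lp_new - lp_old) + math.log(fac)
                if math.log(np.random.random() + 1e-300) < log_ratio:
                    N = new_N
                    alpha = new_alpha
                    logprior = new_prior
                    n_accept += 1
        else:
            # --- scaled growth update ---
            if fix_growth == 0:
                fac = math.exp(0.6 * (np.random.random() - 0.5))
                new_beta = beta * fac
                new_alpha = new_beta / N
                new_prior = _log_coalescent_prior(times, n_tips, N, new_alpha)
                lp_old = -beta / growth_scale
                lp_new = -new_beta / growth_scale
                log_ratio = (new_prior - logprior) + (lp_new - lp_old) + math.log(fac)
                if math.log(np.random.random() + 1e-300) < log_ratio:
                    beta = new_beta
                    alpha = new_alpha
                    logprior = new_prior
                    n_accept += 1

        if (it + 1) % thin == 0:
            r = (it + 1) // thin - 1
            rec_height[r] = times[root]
            rec_loglik[r] = loglik
            rec_n[r] = N
            rec_beta[r] = beta
    return rec_height, rec_loglik, rec_n, rec_beta, n_accept, n_props
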