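"""Numba-accelerated kernels for the slice sampler and step likelihood.

Pure-Python fallbacks with the same algorithm are provided so the package
stays importable without numba; the JIT path uses the MT19937 generator
seeded per chain (numba's ``np.random`` mirrors NumPy's legacy RandomState),
so chains are reproducible for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def step_loglik(a, log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr, n_total):
    """Normalized step-approximation log-likelihood at activity ``a``."""
    if n_total == 0:
        return 0.0
    if a >= 0.0:
        data = const + a * sum_nlr
        v = log_l + a * log_r
    else:
        data = const + (-a) * sum_nl1mr
        v = log_l + (-a) * log_1mr
    m = v[0]
    for i in range(v.shape[0]):
        if v[i] > m:
            m = v[i]
    s = 0.0
    for i in range(v.shape[0]):
        s += math.exp(v[i] - m)
    return data - n_total * (m + math.log(s))


@njit(cache=True)
def _kernel1(a, log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr, n_total,
             prior_mean, prior_sd):
    z = (a - prior_mean) / prior_sd
    return step_loglik(a, log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr,
                       n_total) - 0.5 * z * z


@njit(cache=True)
def slice_chain_1p(seed, iterations, w, max_stepout,
                   log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr, n_total,
                   prior_mean, prior_sd):
    """One slice-sampling chain for the one-parameter activity model."""
    np.random.seed(seed)
    x = np.random.normal() * 2.0  # overdispersed init
    lp = _kernel1(x, log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr,
                  n_total, prior_mean, prior_sd)
    if not np.isfinite(lp):
        x = 0.0
        lp = _kernel1(x, log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr,
                      n_total, prior_mean, prior_sd)
    out = np.empty(iterations)
    for it in range(iterations):
        log_y = lp + math.log(np.random.random())
        u = np.random.random()
        left = x - w * u
        right = left + w
        j = 0
        while j < max_stepout and _kernel1(left, log_l, log_r, log_1mr, const,
                                           sum_nlr, sum_nl1mr, n_total,
                                           prior_mean, prior_sd) > log_y:
            left -= w
            j += 1
        j = 0
        while j < max_stepout and _kernel1(right, log_l, log_r, log_1mr, const,
                                           sum_nlr, sum_nl1mr, n_total,
                                           prior_mean, prior_sd) > log_y:
            right += w
            j += 1
        while True:
            x_new = left + np.random.random() * (right - left)
            lp_new = _kernel1(x_new, log_l, log_r, log_1mr, const, sum_nlr,
                              sum_nl1mr, n_total, prior_mean, prior_sd)
            if lp_new > log_y:
                x = x_new
                lp = lp_new
                break
            if x_new < x:
                left = x_new
            else:
                right = x_new
        out[it] = x
    return out


@njit(cache=True)
def _kernel2(la, lb, log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr, n_total):
    """Two-parameter kernel in (log alpha, log beta) with N(0,1) priors."""
    prior = -0.5 * (la * la + lb * lb)
    if n_total == 0:
        return prior
    alpha = math.exp(la)
    beta = math.exp(lb)
    data = const + (alpha - 1.0) * sum_nlr + (beta - 1.0) * sum_nl1mr
    m = -1e308
    for i in range(log_l.shape[0]):
        v = log_l[i] + (alpha - 1.0) * log_r[i] + (beta - 1.0) * log_1mr[i]
        if v > m:
            m = v
    s = 0.0
    for i in range(log_l.shape[0]):
        v = log_l[i] + (alpha - 1.0) * log_r[i] + (beta - 1.0) * log_1mr[i]
        s += math.exp(v - m)
    return data - n_total * (m + math.log(s)) + prior


@njit(cache=True)
def _slice_coord2(which, x, other, w, max_stepout,
                  log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr, n_total):
    if which == 0:
        lp = _kernel2(x, other, log_l, log_r, log_1mr, const, sum_nlr,
                      sum_nl1mr, n_total)
    else:
        lp = _kernel2(other, x, log_l, log_r, log_1mr, const, sum_nlr,
                      sum_nl1mr, n_total)
    log_y = lp + math.log(np.random.random())
    u = np.random.random()
    left = x - w * u
    right = left + w
    j = 0
    while j < max_stepout:
        if which == 0:
            v = _kernel2(left, other, log_l, log_r, log_1mr, const, sum_nlr,
                         sum_nl1mr, n_total)
        else:
            v = _kernel2(other, left, log_l, log_r, log_1mr, const, sum_nlr,
                         sum_nl1mr, n_total)
        if v <= log_y:
            break
        left -= w
        j += 1
    j = 0
    while j < max_stepout:
        if which == 0:
            v = _kernel2(right, other, log_l, log_r, log_1mr, const, sum_nlr,
                         sum_nl1mr, n_total)
        else:
            v = _kernel2(other, right, log_l, log_r, log_1mr, const, sum_nlr,
                         sum_nl1mr, n_total)
        if v <= log_y:
            break
        right += w
        j += 1
    while True:
        x_new = left + np.random.random() * (right - left)
        if which == 0:
            v = _kernel2(x_new, other, log_l, log_r, log_1mr, const, sum_nlr,
                         sum_nl1mr, n_total)
        else:
            v = _kernel2(other, x_new, log_l, log_r, log_1mr, const, sum_nlr,
                         sum_nl1mr, n_total)
        if v > log_y:
            return x_new
        if x_new < x:
            left = x_new
        else:
            right = x_new


@njit(cache=True)
def slice_chain_2p(seed, iterations, warmup, w, max_stepout,
                   log_l, log_r, log_1mr, const, sum_nlr, sum_nl1mr, n_total):
    """Slice-within-Gibbs chain over (log alpha, log beta)."""
    np.random.seed(seed)
    la = np.random.normal() * 0.5
    lb = np.random.normal() * 0.5
    n_keep = iterations - warmup
    out_a = np.empty(n_keep)
    out_b = np.empty(n_keep)
    k = 0
    for it in range(iterations):
        la = _slice_coord2(0, la, lb, w, max_stepout, log_l, log_r, log_1mr,
                           const, sum_nlr, sum_nl1mr, n_total)
        lb = _slice_coord2(1, lb, la, w, max_stepout, log_l, log_r, log_1mr,
                           const, sum_nlr, sum_nl1mr, n_total)
        if it >= warmup:
            out_a[k] = la
            out_b[k] = lb
            k += 1
    return out_a, out_b
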