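"""Compiled inner loops for batched sequence log-likelihoods and gradients.

The trial recursions are scalar per block, so the vectorized numpy
implementation in :mod:`revlearn.models` pays substantial per-trial dispatch
overhead inside the sampler. These numba kernels run the same recursions
(value update, stable log-sigmoid choice term, analytic parameter
derivatives carried alongside) as tight loops. ``models.evaluate_blocks``
falls back to the numpy path when numba is unavailable, and the two paths
are asserted equal in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _logsigmoid_pair(z):
    """(log sigmoid(z), 1 - sigmoid(z)) without overflow."""
    if z >= 0.0:
        ez = np.exp(-z)
        return -np.log1p(ez), ez / (1.0 + ez)
    ez = np.exp(z)
    return z - np.log1p(ez), 1.0 / (1.0 + ez)


@njit(cache=True)
def ll_grad_rw_fict(ch, oc, er, en, beta, fict):
    """Reward/punishment and fictitious-update family.

    Returns (ll (B,), pointwise (B,T), grad (B,3)) with gradient columns
    ordered (eta_rew, eta_nrew, beta).
    """
    B, T = ch.shape
    ll = np.zeros(B)
    pt = np.zeros((B, T))
    grad = np.zeros((B, 3))
    for b in range(B):
        V = np.zeros(2)
        dVr = np.zeros(2)
        dVn = np.zeros(2)
        e_r = er[b]
        e_n = en[b]
        bb = beta[b]
        for t in range(T):
            c = ch[b, t]
            if c < 0:
                continue
            u = 1 - c
            o = oc[b, t]
            dv = V[c] - V[u]
            lp, q = _logsigmoid_pair(bb * dv)
            ll[b] += lp
            pt[b, t] = lp
            grad[b, 2] += q * dv
            grad[b, 0] += q * bb * (dVr[c] - dVr[u])
            grad[b, 1] += q * bb * (dVn[c] - dVn[u])
            pos = o > 0.0
            rate_c = e_r if pos else e_n
            pe_c = o - V[c]
            dVr[c] = dVr[c] * (1.0 - rate_c) + (pe_c if pos else 0.0)
            dVn[c] = dVn[c] * (1.0 - rate_c) + (0.0 if pos else pe_c)
            V[c] = V[c] + rate_c * pe_c
            if fict:
                rate_u = e_n if pos else e_r
                pe_u = -o - V[u]
                dVr[u] = dVr[u] * (1.0 - rate_u) + (0.0 if pos else pe_u)
                dVn[u] = dVn[u] * (1.0 - rate_u) + (pe_u if pos else 0.0)
                V[u] = V[u] + rate_u * pe_u
    return ll, pt, grad


@njit(cache=True)
def ll_grad_ewa(ch, oc, rho, phir, phin, beta):
    """Experience-weighted attraction family (shared or split payoff decay).

    Returns (ll, pointwise, grad (B,4)) with gradient columns ordered
    (rho, phi_rew, phi_nrew, beta); for the single-decay model the caller
    passes phir == phin and sums the two phi columns.
    """
    B, T = ch.shape
    ll = np.zeros(B)
    pt = np.zeros((B, T))
    grad = np.zeros((B, 4))
    for b in range(B):
        V = np.zeros(2)
        n = np.ones(2)
        dVrho = np.zeros(2)
        dVpr = np.zeros(2)
        dVpn = np.zeros(2)
        dnrho = np.zeros(2)
        rh = rho[b]
        pr = phir[b]
        pn = phin[b]
        bb = beta[b]
        for t in range(T):
            c = ch[b, t]
            if c < 0:
                continue
            u = 1 - c
            o = oc[b, t]
            dv = V[c] - V[u]
            lp, q = _logsigmoid_pair(bb * dv)
            ll[b] += lp
            pt[b, t] = lp
            grad[b, 3] += q * dv
            grad[b, 0] += q * bb * (dVrho[c] - dVrho[u])
            grad[b, 1] += q * bb * (dVpr[c] - dVpr[u])
            grad[b, 2] += q * bb * (dVpn[c] - dVpn[u])
            pos = o > 0.0
            phi = pr if pos else pn
            n_prev = n[c]
            n_new = n_prev * rh + 1.0
            newV = (V[c] * phi * n_prev + o) / n_new
            dnp = dnrho[c]
            dnn = dnp * rh + n_prev
            base = phi * n_prev / n_new
            dVrho[c] = (
                dVrho[c] * base + V[c] * phi * dnp / n_new - newV * dnn / n_new
            )
            common = V[c] * n_prev / n_new
            dVpr[c] = dVpr[c] * base + (common if pos else 0.0)
            dVpn[c] = dVpn[c] * base + (0.0 if pos else common)
            dnrho[c] = dnn
            V[c] = newV
            n[c] = n_new
    return ll, pt, grad
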