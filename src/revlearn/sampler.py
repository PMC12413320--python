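"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC kernel: slice-variable tree doubling
(the classic NUTS recursion), Stan-style warmup windows for estimating a
diagonal metric, and dual averaging of the step size toward a target
acceptance statistic. The target density is supplied as a callable
returning ``(log_density, gradient)`` on the unconstrained scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplerConfig", "nuts_chain"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings: chain count, warmup/sampling lengths, adaptation targets."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10


@dataclass
class ChainStats:
    divergences: int = 0
    step_size: float = float("nan")
    mean_accept: float = float("nan")
    inv_mass: np.ndarray = field(default_factory=lambda: np.array([]))


class _Nuts:
    def __init__(self, logp_grad, inv_mass, rng, max_treedepth):
        self.f = logp_grad
        self.inv_mass = inv_mass
        self.rng = rng
        self.max_treedepth = max_treedepth
        self.divergent = False

    def kinetic(self, p):
        return 0.5 * np.dot(p * p, self.inv_mass)

    def leapfrog(self, x, p, g, eps):
        p1 = p + 0.5 * eps * g
        x1 = x + eps * self.inv_mass * p1
        lp1, g1 = self.f(x1)
        p1 = p1 + 0.5 * eps * g1
        return x1, p1, lp1, g1

    def _no_uturn(self, xm, pm, xp, pp):
        d = xp - xm
        return (
            np.dot(d, self.inv_mass * pm) >= 0
            and np.dot(d, self.inv_mass * pp) >= 0
        )

    def _build(self, x, p, lp, g, logu, v, j, eps, h0):
        """Recursively double the trajectory; returns the subtree summary."""
        if j == 0:
            x1, p1, lp1, g1 = self.leapfrog(x, p, g, v * eps)
            h1 = lp1 - self.kinetic(p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(logu <= h1)
            diverged = logu >= h1 + _DELTA_MAX
            if diverged:
                self.divergent = True
            alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
            return (x1, p1, lp1, g1) * 2 + (x1, lp1, g1, n1, not diverged, alpha, 1)
        (
            xm, pm, lpm, gm, xp, pp, lpp, gp,
            x1, lp1, g1, n1, s1, a1, na1,
        ) = self._build(x, p, lp, g, logu, v, j - 1, eps, h0)
        if s1:
            if v < 0:
                (xm, pm, lpm, gm, _, _, _, _, x2, lp2, g2, n2, s2, a2, na2) = self._build(
                    xm, pm, lpm, gm, logu, v, j - 1, eps, h0
                )
            else:
                (_, _, _, _, xp, pp, lpp, gp, x2, lp2, g2, n2, s2, a2, na2) = self._build(
                    xp, pp, lpp, gp, logu, v, j - 1, eps, h0
                )
            if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
                x1, lp1, g1 = x2, lp2, g2
            n1 += n2
            s1 = s2 and self._no_uturn(xm, pm, xp, pp)
            a1 += a2
            na1 += na2
        return (xm, pm, lpm, gm, xp, pp, lpp, gp, x1, lp1, g1, n1, s1, a1, na1)

    def step(self, x, lp, g, eps):
        """One NUTS transition; returns (x, lp, g, accept_stat, divergent)."""
        self.divergent = False
        p0 = self.rng.standard_normal(x.size) / np.sqrt(self.inv_mass)
        h0 = lp - self.kinetic(p0)
        logu = h0 + np.log(self.rng.random())
        xm = xp = x
        pm = pp = p0
        lpm = lpp = lp
        gm = gp = g
        xc, lpc, gc = x, lp, g
        n, s, depth = 1, True, 0
        asum, nalpha = 0.0, 0
        while s and depth < self.max_treedepth:
            v = 1 if self.rng.random() < 0.5 else -1
            if v < 0:
                (xm, pm, lpm, gm, _, _, _, _, x1, lp1, g1, n1, s1, a1, na1) = self._build(
                    xm, pm, lpm, gm, logu, v, depth, eps, h0
                )
            else:
                (_, _, _, _, xp, pp, lpp, gp, x1, lp1, g1, n1, s1, a1, na1) = self._build(
                    xp, pp, lpp, gp, logu, v, depth, eps, h0
                )
            if s1 and n1 > 0 and self.rng.random() < min(1.0, n1 / n):
                xc, lpc, gc = x1, lp1, g1
            n += n1
            asum += a1
            nalpha += na1
            s = s1 and self._no_uturn(xm, pm, xp, pp)
            depth += 1
        accept = asum / max(nalpha, 1)
        return xc, lpc, gc, accept, self.divergent


def _find_reasonable_eps(kernel: _Nuts, x, lp, g, rng):
    eps = 1.0
    p = rng.standard_normal(x.size) / np.sqrt(kernel.inv_mass)
    h0 = lp - kernel.kinetic(p)
    _, p1, lp1, _ = kernel.leapfrog(x, p, g, eps)
    h1 = lp1 - kernel.kinetic(p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _ = kernel.leapfrog(x, p, g, eps)
        h1 = lp1 - kernel.kinetic(p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _DualAverage:
    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.m = 0
        self.hbar = 0.0
        self.log_eps_bar = np.log(eps0)
        self.log_eps = np.log(eps0)

    def update(self, accept):
        self.m += 1
        w = 1.0 / (self.m + self.t0)
        self.hbar = (1 - w) * self.hbar + w * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.hbar
        wb = self.m ** (-self.kappa)
        self.log_eps_bar = wb * self.log_eps + (1 - wb) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def _adaptation_windows(warmup):
    """Stan-style schedule: fast start, expanding slow windows, fast tail."""
    init_buf, term_buf, base = 75, 50, 25
    if warmup < init_buf + term_buf + base:
        init_buf = max(1, int(0.15 * warmup))
        term_buf = max(1, int(0.1 * warmup))
        base = max(1, warmup - init_buf - term_buf)
    boundaries = []
    start = init_buf
    size = base
    while start + size < warmup - term_buf:
        boundaries.append((start, start + size))
        start += size
        size *= 2
    boundaries.append((start, warmup - term_buf))
    return boundaries


def nuts_chain(
    logp_grad,
    x0: np.ndarray,
    cfg: SamplerConfig,
    seed,
) -> tuple[np.ndarray, ChainStats]:
    """Run one NUTS chain; returns post-warmup draws ``(cfg.draws, dim)``."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    lp, g = logp_grad(x)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log density at the initial point")
    dim = x.size
    inv_mass = np.ones(dim)
    kernel = _Nuts(logp_grad, inv_mass, rng, cfg.max_treedepth)
    eps0 = _find_reasonable_eps(kernel, x, lp, g, rng)
    da = _DualAverage(eps0, cfg.target_accept)

    windows = _adaptation_windows(cfg.warmup)
    win_iter = iter(windows)
    current = next(win_iter, None)
    wsum = np.zeros(dim)
    wsum2 = np.zeros(dim)
    wn = 0
    stats = ChainStats()
    accepts = []

    for m in range(cfg.warmup):
        x, lp, g, accept, div = kernel.step(x, lp, g, da.eps)
        da.update(accept)
        if current is not None and current[0] <= m < current[1]:
            wsum += x
            wsum2 += x * x
            wn += 1
        if current is not None and m == current[1] - 1:
            if wn > 1:
                var = wsum2 / wn - (wsum / wn) ** 2
                var = np.maximum(var, 0.0)
                shrunk = (wn / (wn + 5.0)) * var + 1e-3 * (5.0 / (wn + 5.0))
                kernel.inv_mass = shrunk
                lp, g = logp_grad(x)
                eps0 = _find_reasonable_eps(kernel, x, lp, g, rng)
                da = _DualAverage(eps0, cfg.target_accept)
            wsum[:] = 0.0
            wsum2[:] = 0.0
            wn = 0
            current = next(win_iter, None)

    eps = da.eps_final
    draws = np.empty((cfg.draws, dim))
    for m in range(cfg.draws):
        x, lp, g, accept, div = kernel.step(x, lp, g, eps)
        draws[m] = x
        accepts.append(accept)
        if div:
            stats.divergences += 1
    stats.step_size = eps
    stats.mean_accept = float(np.mean(accepts)) if accepts else float("nan")
    stats.inv_mass = kernel.inv_mass
    return draws, stats
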