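"""Hierarchical Bayesian estimation of model parameters across condition cells.

One joint fit covers all six session x feedback cells through the
effect-coding design matrix: for every model parameter there is a
group-level mean and a subject-level SD per design column, plus non-centered
standard-normal subject deviations per subject per column. A subject's
unconstrained cell value is the design-matrix row sum of
``mu_k + sigma_k * z_{s,k}``; inverse-probit links map it to the constrained
scale (learning rates and decay factors to (0, 1), the inverse temperature
to (0, beta_upper)).

Hyperpriors on the unconstrained scale: group means ~ Normal(0, 1), subject
SDs ~ half-Normal(0, 0.5) (configurable through :class:`GroupPrior`).
Sampling uses the in-package NUTS kernel with analytic likelihood gradients;
convergence is assessed with rank-normalized split R-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import design as dz
from .models import ModelSpec, evaluate_blocks, get_model
from .sampler import ChainStats, SamplerConfig, nuts_chain

__all__ = [
    "GroupPrior",
    "SamplerConfig",
    "PosteriorDraws",
    "HierarchicalModel",
    "fit_hierarchical",
    "rhat",
    "max_rhat",
]

_NORM_PDF = norm.pdf


@dataclass(frozen=True)
class GroupPrior:
    """Hyperpriors (unconstrained scale) and the inverse-temperature upper bound."""

    mu_mean: float = 0.0
    mu_sd: float = 1.0
    sigma_scale: float = 0.5
    beta_upper: float = 10.0

    def __post_init__(self):
        if self.mu_sd <= 0 or self.sigma_scale <= 0 or self.beta_upper <= 0:
            raise ValueError("prior scales and beta_upper must be positive")


class HierarchicalModel:
    """Data container and differentiable log joint density for one model fit."""

    def __init__(
        self,
        dataset: pd.DataFrame,
        model: str | ModelSpec,
        prior: GroupPrior | None = None,
    ):
        self.spec = get_model(model)
        self.prior = prior or GroupPrior()
        self.X = dz.design_array()
        self.subjects = sorted(dataset["subject_id"].unique())
        self.S = len(self.subjects)
        self.P = self.spec.n_params

        counts = dataset.groupby(["subject_id", "session", "feedback"]).size()
        if len(counts) != self.S * 6:
            raise ValueError(
                "dataset must cover all six session x feedback cells for every subject"
            )
        if counts.nunique() != 1:
            raise ValueError("every subject-cell must have the same trial count")
        self.T = int(counts.iloc[0])

        ch = np.full((self.S, 6, self.T), -1, dtype=int)
        oc = np.ones((self.S, 6, self.T))
        sidx = {s: i for i, s in enumerate(self.subjects)}
        for (subj, session, feedback), grp in dataset.groupby(
            ["subject_id", "session", "feedback"]
        ):
            r = dz.cell_index(session, feedback)
            grp = grp.sort_values("trial")
            c = grp["choice"].to_numpy(dtype=float)
            c = np.where(np.isnan(c), -1, c).astype(int)
            o = grp["outcome"].to_numpy(dtype=float)
            if np.any((o[c >= 0] != 1) & (o[c >= 0] != -1)):
                raise ValueError("outcomes must be coded +1 (win) / -1 (no win)")
            ch[sidx[subj], r] = c
            oc[sidx[subj], r] = o
        self.choices = ch.reshape(self.S * 6, self.T)
        self.outcomes = oc.reshape(self.S * 6, self.T)

        self.dim = 2 * 6 * self.P + self.S * 6 * self.P
        self.names = (
            [f"mu[{col},{p}]" for col in dz.COLUMNS for p in self.spec.params]
            + [f"sigma[{col},{p}]" for col in dz.COLUMNS for p in self.spec.params]
            + [
                f"z[{s},{col},{p}]"
                for s in self.subjects
                for col in dz.COLUMNS
                for p in self.spec.params
            ]
        )

    # --- packing -----------------------------------------------------------
    def unpack(self, x: np.ndarray):
        kp = 6 * self.P
        mu = x[:kp].reshape(6, self.P)
        ls = x[kp : 2 * kp].reshape(6, self.P)
        z = x[2 * kp :].reshape(self.S, 6, self.P)
        return mu, ls, z

    def _cell_theta(self, mu, sigma, z):
        a = mu[None] + sigma[None] * z  # (S, col, P)
        return np.einsum("rk,skp->srp", self.X, a)

    def constrain(self, theta):
        """Map unconstrained cell values (..., P) to constrained parameters."""
        out = np.empty_like(theta)
        for j, p in enumerate(self.spec.params):
            if p == "beta":
                out[..., j] = dz.scaled_probit_link(theta[..., j], self.prior.beta_upper)
            else:
                out[..., j] = dz.probit_link(theta[..., j])
        return out

    # --- log density -------------------------------------------------------
    def logp_grad(self, x: np.ndarray):
        pr = self.prior
        mu, ls, z = self.unpack(x)
        sigma = np.exp(ls)
        theta = self._cell_theta(mu, sigma, z)  # (S, cell, P)
        cons = self.constrain(theta)
        params = {
            p: cons[..., j].reshape(self.S * 6) for j, p in enumerate(self.spec.params)
        }
        out = evaluate_blocks(self.spec, params, self.choices, self.outcomes, grad=True)
        ll = float(out["loglik"].sum())

        dcons = _NORM_PDF(theta)
        scale = np.array(
            [pr.beta_upper if p == "beta" else 1.0 for p in self.spec.params]
        )
        g_theta = out["grad"].reshape(self.S, 6, self.P) * dcons * scale
        g_a = np.einsum("rk,srp->skp", self.X, g_theta)

        logp = (
            ll
            - 0.5 * np.sum(((mu - pr.mu_mean) / pr.mu_sd) ** 2)
            - 0.5 * np.sum(z**2)
            - 0.5 * np.sum((sigma / pr.sigma_scale) ** 2)
            + np.sum(ls)  # Jacobian of sigma = exp(ls)
        )
        g_mu = g_a.sum(axis=0) - (mu - pr.mu_mean) / pr.mu_sd**2
        g_z = g_a * sigma[None] - z
        g_ls = (g_a * z).sum(axis=0) * sigma - (sigma / pr.sigma_scale) ** 2 + 1.0
        grad = np.concatenate([g_mu.ravel(), g_ls.ravel(), g_z.ravel()])
        return logp, grad


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws with chain structure and fit metadata.

    ``samples`` holds unconstrained draws of shape ``(chains, draws, dim)``;
    sigma accessors return the positive scale.
    """

    samples: np.ndarray
    names: list[str]
    model: str
    subjects: list[str]
    prior: GroupPrior
    sampler: SamplerConfig
    seed: int
    chain_stats: list[ChainStats] = field(default_factory=list)

    @property
    def spec(self) -> ModelSpec:
        return get_model(self.model)

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_draws(self) -> int:
        return self.samples.shape[1]

    def _block(self, kind: str) -> np.ndarray:
        P = self.spec.n_params
        kp = 6 * P
        if kind == "mu":
            arr = self.samples[..., :kp]
        elif kind == "sigma":
            arr = np.exp(self.samples[..., kp : 2 * kp])
        else:
            arr = self.samples[..., 2 * kp :]
        return arr

    def mu(self, param: str) -> np.ndarray:
        """Group means per design column, shape (chains, draws, 6)."""
        j = self.spec.params.index(param)
        return self._block("mu").reshape(self.n_chains, self.n_draws, 6, -1)[..., j]

    def sigma(self, param: str) -> np.ndarray:
        """Subject-level SDs per design column, shape (chains, draws, 6)."""
        j = self.spec.params.index(param)
        return self._block("sigma").reshape(self.n_chains, self.n_draws, 6, -1)[..., j]

    def z(self, param: str) -> np.ndarray:
        """Subject deviations, shape (chains, draws, S, 6)."""
        j = self.spec.params.index(param)
        S = len(self.subjects)
        return self._block("z").reshape(self.n_chains, self.n_draws, S, 6, -1)[..., j]

    def group_cell_theta(self, param: str) -> np.ndarray:
        """Group-level unconstrained cell values (row sums), (chains, draws, 6)."""
        return self.mu(param) @ dz.design_array().T

    def group_cell_values(self, param: str, prior: GroupPrior | None = None) -> np.ndarray:
        """Group-level cell values on the constrained scale."""
        pr = prior or self.prior
        th = self.group_cell_theta(param)
        if param == "beta":
            return dz.scaled_probit_link(th, pr.beta_upper)
        return dz.probit_link(th)

    def subject_cell_values(self, param: str) -> np.ndarray:
        """Constrained per-subject cell values, (chains, draws, S, 6)."""
        j = self.spec.params.index(param)
        mu = self._block("mu").reshape(self.n_chains, self.n_draws, 6, -1)[..., j]
        sg = self._block("sigma").reshape(self.n_chains, self.n_draws, 6, -1)[..., j]
        z = self.z(param)
        a = mu[:, :, None, :] + sg[:, :, None, :] * z
        th = np.einsum("rk,cdsk->cdsr", dz.design_array(), a)
        if param == "beta":
            return dz.scaled_probit_link(th, self.prior.beta_upper)
        return dz.probit_link(th)

    def subject_modes(self, param: str) -> pd.DataFrame:
        """Posterior-mode point summary per subject and cell (constrained scale)."""
        from scipy.stats import gaussian_kde

        vals = self.subject_cell_values(param).reshape(-1, len(self.subjects), 6)
        rows = []
        for si, subj in enumerate(self.subjects):
            for r, (session, feedback) in enumerate(dz.CELLS):
                v = vals[:, si, r]
                lo, hi = v.min(), v.max()
                if hi - lo < 1e-12:
                    mode = float(v[0])
                else:
                    grid = np.linspace(lo, hi, 512)
                    mode = float(grid[np.argmax(gaussian_kde(v)(grid))])
                rows.append(
                    {
                        "subject_id": subj,
                        "session": session,
                        "feedback": feedback,
                        "param": param,
                        "mode": mode,
                    }
                )
        return pd.DataFrame(rows)

    def to_inference_data(self):
        """Package draws as an arviz InferenceData (mu/sigma/z per parameter)."""
        import arviz as az

        data = {}
        for p in self.spec.params:
            data[f"mu_{p}"] = self.mu(p)
            data[f"sigma_{p}"] = self.sigma(p)
            data[f"z_{p}"] = self.z(p)
        coords = {"column": list(dz.COLUMNS), "subject": self.subjects}
        dims = {}
        for p in self.spec.params:
            dims[f"mu_{p}"] = ["column"]
            dims[f"sigma_{p}"] = ["column"]
            dims[f"z_{p}"] = ["subject", "column"]
        return az.from_dict(posterior=data, coords=coords, dims=dims)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iter, parameter, value) frame; sigma on the positive scale."""
        C, D, K = self.samples.shape
        vals = self.samples.copy()
        P = self.spec.n_params
        kp = 6 * P
        vals[..., kp : 2 * kp] = np.exp(vals[..., kp : 2 * kp])
        chain = np.repeat(np.arange(C), D * K)
        it = np.tile(np.repeat(np.arange(D), K), C)
        name = np.tile(np.asarray(self.names, dtype=object), C * D)
        return pd.DataFrame(
            {"chain": chain, "iter": it, "parameter": name, "value": vals.ravel()}
        )


def fit_hierarchical(
    dataset: pd.DataFrame,
    model: str | ModelSpec = "fictitious",
    prior: GroupPrior | None = None,
    sampler_cfg: SamplerConfig | None = None,
    seed: int = 0,
    *,
    init_jitter: float = 0.2,
    max_init_retries: int = 5,
) -> PosteriorDraws:
    """Fit the hierarchical model to all condition cells jointly.

    Chains are initialized near the prior center (jittered; subject SDs
    start small) and re-seeded on a non-finite initial density before a
    hard failure. Draw count = chains x post-warmup iterations.
    """
    prior = prior or GroupPrior()
    cfg = sampler_cfg or SamplerConfig()
    hm = HierarchicalModel(dataset, model, prior)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(cfg.chains)
    chains = []
    stats = []
    for c in range(cfg.chains):
        rng = np.random.default_rng(chain_seeds[c])
        for attempt in range(max_init_retries):
            x0 = rng.normal(0.0, init_jitter, hm.dim)
            kp = 6 * hm.P
            x0[kp : 2 * kp] = np.log(0.2) + rng.normal(0.0, 0.1, kp)
            lp, _ = hm.logp_grad(x0)
            if np.isfinite(lp):
                break
        else:
            raise FloatingPointError(
                f"chain {c}: non-finite log density at initialization after "
                f"{max_init_retries} reseeded attempts"
            )
        draws, st = nuts_chain(
            hm.logp_grad, x0, cfg, seed=chain_seeds[c].spawn(1)[0]
        )
        chains.append(draws)
        stats.append(st)
    return PosteriorDraws(
        samples=np.stack(chains),
        names=hm.names,
        model=hm.spec.name,
        subjects=hm.subjects,
        prior=prior,
        sampler=cfg,
        seed=seed,
        chain_stats=stats,
    )


def rhat(draws: PosteriorDraws | np.ndarray, names=None) -> pd.Series:
    """Rank-normalized split R-hat per parameter.

    Accepts a :class:`PosteriorDraws` or a raw ``(chains, draws, dim)``
    array. Zero-variance parameters yield NaN (flagged, not an error).
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        arr = draws.samples
        names = draws.names
    else:
        arr = np.asarray(draws)
        if arr.ndim == 2:
            arr = arr[:, :, None]
    if arr.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    ds = az.convert_to_dataset(arr)
    rhat_vals = az.rhat(ds)["x"].values
    index = names if names is not None else [f"p{i}" for i in range(arr.shape[2])]
    return pd.Series(rhat_vals, index=index, name="rhat")


def max_rhat(draws: PosteriorDraws) -> float:
    return float(np.nanmax(rhat(draws).to_numpy()))
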