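"""Model comparison via pointwise predictive log-likelihoods.

For each candidate model the per-draw, per-trial log-likelihood of the
observed choices is evaluated over its posterior draws; expected log
pointwise predictive densities (elpd) are computed with Pareto-smoothed
importance sampling (leave-one-out), and models are combined with two
weighting schemes: Bayesian stacking of predictive means (simplex-
constrained optimization of the pointwise mixture score) and pseudo-BMA+
(Bayesian-bootstrap-regularized softmax of elpd sums). The pointwise unit
is one observed subject x trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .hier import HierarchicalModel, PosteriorDraws
from .models import evaluate_blocks

__all__ = [
    "PointwiseLogLik",
    "ModelWeights",
    "pointwise_loglik",
    "psis_elpd",
    "stacking_weights",
    "pseudo_bma_weights",
    "compare_models",
]


@dataclass(frozen=True)
class PointwiseLogLik:
    """Draws x units matrix of log-likelihoods for one fitted model."""

    model: str
    matrix: np.ndarray  # (n_total_draws, n_units)
    unit_labels: pd.DataFrame  # subject_id, session, feedback, trial per unit

    @property
    def n_units(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ModelWeights:
    """Per-model weights under each combination metric; each sums to 1."""

    weights: pd.DataFrame  # columns: model, metric, weight

    def of(self, model: str, metric: str) -> float:
        w = self.weights
        row = w[(w["model"] == model) & (w["metric"] == metric)]
        if row.empty:
            raise KeyError((model, metric))
        return float(row["weight"].iloc[0])


def pointwise_loglik(
    draws: PosteriorDraws,
    dataset: pd.DataFrame,
    model: str | None = None,
    *,
    thin: int = 1,
) -> PointwiseLogLik:
    """Per-draw per-trial log-likelihood of the observed choices.

    Missing trials are dropped from the unit set. ``thin`` keeps every
    ``thin``-th draw to bound memory on long chains.
    """
    model = model or draws.model
    if model != draws.model:
        raise ValueError(
            f"draws were fitted with {draws.model!r}, not {model!r}"
        )
    hm = HierarchicalModel(dataset, model, draws.prior)
    if hm.subjects != list(draws.subjects):
        raise ValueError("dataset subjects do not match the fitted draws")
    C, D, _ = draws.samples.shape
    sel = np.arange(0, D, thin)
    nd = C * sel.size
    # constrained per-draw block parameters, flattened draws x blocks
    vals = {
        p: draws.subject_cell_values(p)[:, sel].reshape(nd, hm.S * 6)
        for p in hm.spec.params
    }
    B = hm.S * 6
    params = {p: v.reshape(nd * B) for p, v in vals.items()}
    ch = np.broadcast_to(hm.choices, (nd, B, hm.T)).reshape(nd * B, hm.T)
    oc = np.broadcast_to(hm.outcomes, (nd, B, hm.T)).reshape(nd * B, hm.T)
    out = evaluate_blocks(hm.spec, params, ch, oc, per_trial=True)
    pt = out["pointwise"].reshape(nd, B * hm.T)
    observed = (hm.choices.reshape(-1) >= 0)
    labels = []
    from . import design as dz

    for si, subj in enumerate(hm.subjects):
        for session, feedback in dz.CELLS:
            for t in range(hm.T):
                labels.append((subj, session, feedback, t + 1))
    unit_labels = pd.DataFrame(
        labels, columns=["subject_id", "session", "feedback", "trial"]
    )[observed].reset_index(drop=True)
    return PointwiseLogLik(
        model=model, matrix=pt[:, observed], unit_labels=unit_labels
    )


def psis_elpd(pw: PointwiseLogLik) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out elpd per unit via Pareto-smoothed importance sampling.

    Returns ``(elpd_i, pareto_k)`` arrays of length ``n_units``.
    """
    import arviz as az

    ll = pw.matrix
    lw, k = az.psislw(-ll.T)  # expects (n_obs, n_draws)
    lw = np.asarray(lw)
    elpd = logsumexp(ll.T + lw, axis=1)
    return elpd, np.asarray(k)


def _check_aligned(models: list[PointwiseLogLik]) -> None:
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    n = models[0].n_units
    for m in models[1:]:
        if m.n_units != n:
            raise ValueError("pointwise matrices must share the same units")


def _elpd_matrix(models: list[PointwiseLogLik]) -> np.ndarray:
    _check_aligned(models)
    return np.stack([psis_elpd(m)[0] for m in models], axis=1)  # (N, M)


def stacking_weights(
    models: list[PointwiseLogLik], *, elpd_points: np.ndarray | None = None
) -> ModelWeights:
    """Bayesian stacking: maximize the summed log mixture predictive density.

    The objective sum_i log sum_m w_m exp(elpd_im) is concave in ``w`` and is
    optimized over the probability simplex (SLSQP from the uniform start, so
    exact ties resolve to uniform weights).
    """
    lpd = _elpd_matrix(models) if elpd_points is None else np.asarray(elpd_points)
    n, m = lpd.shape
    rowmax = lpd.max(axis=1, keepdims=True)
    e = np.exp(lpd - rowmax)  # (N, M), stabilized

    def neg(w):
        mix = e @ w
        return -np.sum(np.log(np.maximum(mix, 1e-300)))

    def grad(w):
        mix = np.maximum(e @ w, 1e-300)
        return -(e / mix[:, None]).sum(axis=0)

    w0 = np.full(m, 1.0 / m)
    res = minimize(
        neg,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"stacking optimization did not converge: {res.message}")
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    rows = [
        {"model": mod.model, "metric": "stacking", "weight": float(wi)}
        for mod, wi in zip(models, w)
    ]
    return ModelWeights(weights=pd.DataFrame(rows))


def pseudo_bma_weights(
    models: list[PointwiseLogLik],
    n_boot: int = 1000,
    seed: int = 0,
    *,
    elpd_points: np.ndarray | None = None,
) -> ModelWeights:
    """Pseudo-BMA+ weights: Bayesian-bootstrap softmax of elpd sums.

    Each bootstrap replicate draws Dirichlet(1) unit weights, forms the
    weighted elpd total per model, applies a softmax across models, and the
    replicates are averaged; deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    lpd = _elpd_matrix(models) if elpd_points is None else np.asarray(elpd_points)
    n, m = lpd.shape
    rng = np.random.default_rng(seed)
    wb = rng.dirichlet(np.ones(n), size=n_boot)  # (n_boot, N)
    totals = n * (wb @ lpd)  # (n_boot, M)
    totals -= totals.max(axis=1, keepdims=True)
    sm = np.exp(totals)
    sm /= sm.sum(axis=1, keepdims=True)
    w = sm.mean(axis=0)
    rows = [
        {"model": mod.model, "metric": "pseudo_bma", "weight": float(wi)}
        for mod, wi in zip(models, w)
    ]
    return ModelWeights(weights=pd.DataFrame(rows))


def compare_models(
    models: list[PointwiseLogLik], n_boot: int = 1000, seed: int = 0
) -> ModelWeights:
    """Both weighting metrics on a shared elpd computation."""
    lpd = _elpd_matrix(models)
    st = stacking_weights(models, elpd_points=lpd)
    pb = pseudo_bma_weights(models, n_boot=n_boot, seed=seed, elpd_points=lpd)
    return ModelWeights(
        weights=pd.concat([st.weights, pb.weights], ignore_index=True)
    )
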