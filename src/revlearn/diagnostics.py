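"""Model-validation suite: posterior predictive checks, parameter recovery,
and the grid simulation locating optimal learning parameters for this task.

The grid simulation asks which (learning rate, inverse temperature)
combinations perform best in the 28-trial, frequently reversing 80:20
environment: a 60 x 60 grid over eta in [0, 1] and beta in [0, 20] is
simulated with single-learning-rate fictitious-update agents, cell
accuracies are smoothed with a Gaussian filter (std 2 cells, reflect
boundaries), and the optimum is summarized as the mean location of the ten
highest-accuracy smoothed cells. In this environment a high learning rate
and beta above roughly 3 are optimal; accuracy at beta = 0 is chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import design as dz
from .bayes import hdi
from .hier import PosteriorDraws, SamplerConfig, fit_hierarchical
from .models import get_model
from .task import (
    CohortSpec,
    generate_cohort,
    make_high_option_paths,
    simulate_blocks,
)

__all__ = [
    "OptimalitySurface",
    "RecoveryResult",
    "PpcResult",
    "grid_optimality",
    "posterior_predictive",
    "parameter_recovery",
    "recovery_table",
]


@dataclass(frozen=True)
class OptimalitySurface:
    """Accuracy over the (eta, beta) grid, raw and smoothed, with the optimum."""

    eta: np.ndarray  # (n_eta,)
    beta: np.ndarray  # (n_beta,)
    accuracy: np.ndarray  # (n_eta, n_beta), raw cell means
    smoothed: np.ndarray  # same shape, Gaussian-filtered
    optimal_eta: float
    optimal_beta: float
    optimal_accuracy: float
    top_k: int

    def to_frame(self) -> pd.DataFrame:
        e, b = np.meshgrid(self.eta, self.beta, indexing="ij")
        return pd.DataFrame(
            {
                "eta": e.ravel(),
                "beta": b.ravel(),
                "accuracy": self.accuracy.ravel(),
                "smoothed": self.smoothed.ravel(),
            }
        )


def grid_optimality(
    n_eta: int = 60,
    n_beta: int = 60,
    eta_range: tuple[float, float] = (0.0, 1.0),
    beta_range: tuple[float, float] = (0.0, 20.0),
    n_rep_per_cell: int = 200,
    n_trials: int = 28,
    phase_length: int = 7,
    p_high: float = 0.8,
    smoothing_sd: float = 2.0,
    top_k: int = 10,
    seed: int = 0,
) -> OptimalitySurface:
    """Mean accuracy of simulated agents over the learning-parameter grid.

    Each grid cell runs ``n_rep_per_cell`` independent 28-trial reversal
    blocks with a fictitious-update agent whose single learning rate applies
    to both outcome signs; accuracy is the fraction of choices of the
    currently better option, pooled over trials and replicates.
    """
    rng = np.random.default_rng(seed)
    eta = np.linspace(*eta_range, n_eta)
    beta = np.linspace(*beta_range, n_beta)
    G = n_eta * n_beta * n_rep_per_cell
    eta_g = np.repeat(eta, n_beta * n_rep_per_cell)
    beta_g = np.tile(np.repeat(beta, n_rep_per_cell), n_eta)
    high = make_high_option_paths(G, n_trials, phase_length, rng)
    choices, _ = simulate_blocks(
        "fictitious",
        {"eta_rew": eta_g, "eta_nrew": eta_g, "beta": beta_g},
        high,
        p_high,
        rng,
    )
    correct = (choices == high).mean(axis=1)
    acc = correct.reshape(n_eta, n_beta, n_rep_per_cell).mean(axis=2)
    smoothed = gaussian_filter(acc, smoothing_sd, mode="reflect")
    flat = np.argsort(smoothed.ravel())[::-1][:top_k]
    ei, bi = np.unravel_index(flat, smoothed.shape)
    return OptimalitySurface(
        eta=eta,
        beta=beta,
        accuracy=acc,
        smoothed=smoothed,
        optimal_eta=float(eta[ei].mean()),
        optimal_beta=float(beta[bi].mean()),
        optimal_accuracy=float(smoothed.ravel()[flat].mean()),
        top_k=top_k,
    )


@dataclass(frozen=True)
class PpcResult:
    """Observed vs posterior-predictive accuracy summaries."""

    per_cell: pd.DataFrame  # subject x cell x phase rows
    group: pd.DataFrame  # cell x phase rows, averaged over subjects
    n_rep: int

    @property
    def coverage(self) -> float:
        """Fraction of subject-cell-phase rows whose observed accuracy falls
        inside the 95% predictive interval."""
        return float(self.per_cell["covered"].mean())


def posterior_predictive(
    draws: PosteriorDraws,
    dataset: pd.DataFrame,
    n_rep: int = 200,
    seed: int = 0,
) -> PpcResult:
    """Re-simulate the task from posterior parameter draws and compare
    accuracy-by-phase summaries against the observed data.

    For each of ``n_rep`` randomly selected posterior draws every
    subject-cell block is simulated on a fresh schedule; predictive 95%
    intervals are per subject x cell x phase.
    """
    rng = np.random.default_rng(seed)
    spec = get_model(draws.model)
    subjects = list(draws.subjects)
    S = len(subjects)

    grp = dataset.groupby(["subject_id", "session", "feedback"])
    n_trials = int(grp.size().iloc[0])
    sample = grp.get_group(next(iter(grp.groups))).sort_values("trial")
    phase_len = int((sample["phase"] == 1).sum())
    n_phases = n_trials // phase_len

    # observed accuracy per (subject, cell, phase)
    obs = dataset.copy()
    obs = obs[obs["choice"].notna()]
    obs["correct"] = (obs["choice"] == obs["high_option"]).astype(float)
    obs_acc = (
        obs.groupby(["subject_id", "session", "feedback", "phase"])["correct"]
        .mean()
        .rename("observed")
    )

    vals = {p: draws.subject_cell_values(p).reshape(-1, S, 6) for p in spec.params}
    total = vals[spec.params[0]].shape[0]
    sel = rng.choice(total, size=n_rep, replace=n_rep > total)

    B = S * 6
    acc = np.empty((n_rep, B, n_phases))
    for i, di in enumerate(sel):
        params = {p: vals[p][di].reshape(B) for p in spec.params}
        high = make_high_option_paths(B, n_trials, phase_len, rng)
        choices, _ = simulate_blocks(spec, params, high, 0.8, rng)
        correct = (choices == high).astype(float)
        acc[i] = correct.reshape(B, n_phases, phase_len).mean(axis=2)

    lo = np.percentile(acc, 2.5, axis=0)
    hi = np.percentile(acc, 97.5, axis=0)
    mean = acc.mean(axis=0)
    rows = []
    for si, subj in enumerate(subjects):
        for r, (session, feedback) in enumerate(dz.CELLS):
            for ph in range(n_phases):
                b = si * 6 + r
                key = (subj, session, feedback, ph + 1)
                o = obs_acc.get(key, np.nan)
                rows.append(
                    {
                        "subject_id": subj,
                        "session": session,
                        "feedback": feedback,
                        "phase": ph + 1,
                        "observed": o,
                        "pred_mean": mean[b, ph],
                        "pred_lo": lo[b, ph],
                        "pred_hi": hi[b, ph],
                        "covered": bool(lo[b, ph] <= o <= hi[b, ph])
                        if np.isfinite(o)
                        else False,
                    }
                )
    per_cell = pd.DataFrame(rows)
    group = (
        per_cell.groupby(["session", "feedback", "phase"])[
            ["observed", "pred_mean", "pred_lo", "pred_hi"]
        ]
        .mean()
        .reset_index()
    )
    return PpcResult(per_cell=per_cell, group=group, n_rep=n_rep)


@dataclass(frozen=True)
class RecoveryResult:
    """Ground truth vs recovered group-level posteriors."""

    table: pd.DataFrame  # kind (mu/sigma), param, column, truth, post stats
    draws: PosteriorDraws = field(repr=False, compare=False, default=None)

    @property
    def all_covered(self) -> bool:
        return bool(self.table["covered"].all())

    @property
    def coverage(self) -> float:
        return float(self.table["covered"].mean())


def parameter_recovery(
    group_mean: dict[str, np.ndarray],
    group_sd: dict[str, np.ndarray],
    n_subjects: int = 40,
    model: str = "fictitious",
    sampler_cfg: SamplerConfig | None = None,
    seed: int = 0,
    *,
    include_sigma: bool = True,
    mass: float = 0.95,
) -> RecoveryResult:
    """Simulate a cohort from known group parameters, refit, and check that
    every ground-truth group-level value lies inside the posterior HDI.

    ``group_mean`` / ``group_sd`` are per design column on the unconstrained
    scale (the quantities the hierarchical model estimates).
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        model=model,
        group_mean=group_mean,
        group_sd=group_sd,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    draws = fit_hierarchical(
        cohort.data, model, sampler_cfg=sampler_cfg, seed=seed + 1
    )
    table = recovery_table(
        draws, group_mean, group_sd, mass=mass, include_sigma=include_sigma
    )
    return RecoveryResult(table=table, draws=draws)


def recovery_table(
    draws: PosteriorDraws,
    group_mean: dict[str, np.ndarray],
    group_sd: dict[str, np.ndarray],
    *,
    mass: float = 0.95,
    include_sigma: bool = True,
) -> pd.DataFrame:
    """Score fitted group-level posteriors against known generating values."""
    rows = []
    for p in get_model(draws.model).params:
        mu = draws.mu(p).reshape(-1, 6)
        sg = draws.sigma(p).reshape(-1, 6)
        for k, col in enumerate(dz.COLUMNS):
            for kind, truth, post in (
                ("mu", float(group_mean[p][k]), mu[:, k]),
                ("sigma", float(group_sd[p][k]), sg[:, k]),
            ):
                if kind == "sigma" and not include_sigma:
                    continue
                lo, hi_ = hdi(post, mass)
                rows.append(
                    {
                        "kind": kind,
                        "param": p,
                        "column": col,
                        "truth": truth,
                        "post_mean": float(post.mean()),
                        "hdi_low": lo,
                        "hdi_high": hi_,
                        "covered": bool(lo <= truth <= hi_),
                    }
                )
    return pd.DataFrame(rows)
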