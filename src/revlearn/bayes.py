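"""Savage-Dickey Bayes factors, credible intervals, and design utilities.

Pairwise condition differences of group-level parameters are expressed as a
standardized effect ``delta = (mu2 - mu1) / tau`` per posterior draw, on the
unconstrained scale, where ``tau`` is the (pooled) subject-level SD for that
parameter. The Bayes factor for a difference follows the Savage-Dickey
density ratio: prior density at ``delta = 0`` over posterior density at 0,
with the posterior density estimated by Gaussian KDE (Silverman bandwidth)
or, as a cross-check, by a normal approximation to the draws. BF_10 bands
follow the conventional reading: > 3 moderate, > 10 strong evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design as dz
from .hier import PosteriorDraws

__all__ = [
    "DeltaDraws",
    "BFReport",
    "effect_size_delta",
    "savage_dickey_bf",
    "hdi",
    "direction_probability",
    "required_sample_size_paired_t",
    "bf_table",
]

BF_CAP = 1e6


@dataclass(frozen=True)
class DeltaDraws:
    """Per-draw standardized difference for one pairwise comparison."""

    draws: np.ndarray
    param: str
    cell_1: tuple[str, str]  # (session, feedback) reference
    cell_2: tuple[str, str]

    @property
    def label(self) -> str:
        return (
            f"{self.param}: {self.cell_2[0]} - {self.cell_1[0]} "
            f"({self.cell_1[1]} feedback)"
        )


@dataclass(frozen=True)
class BFReport:
    """Savage-Dickey BF with 95% HDI and direction probability."""

    bf10: float
    hdi_low: float
    hdi_high: float
    p_direction: float
    param: str
    comparison: str
    capped: bool = False

    @property
    def evidence_band(self) -> str:
        if self.bf10 > 10:
            return "strong"
        if self.bf10 > 3:
            return "moderate"
        return "weak"


def effect_size_delta(
    draws: PosteriorDraws,
    param: str,
    cell_pair: tuple[tuple[str, str], tuple[str, str]],
    *,
    tau: str = "pooled",
) -> DeltaDraws:
    """Standardized pairwise difference of group-level cell means, per draw.

    Computed on the unconstrained scale. ``tau`` is the subject-level SD of
    the parameter: ``"pooled"`` takes the root mean square of the two cells'
    implied SDs (each cell's variance is the sum of its design columns'
    variances), ``"cell1"``/``"cell2"`` use a single cell's SD.
    """
    (s1, f1), (s2, f2) = cell_pair
    r1, r2 = dz.cell_index(s1, f1), dz.cell_index(s2, f2)
    theta = draws.group_cell_theta(param).reshape(-1, 6)
    mu1, mu2 = theta[:, r1], theta[:, r2]
    sigma = draws.sigma(param).reshape(-1, 6)
    X = dz.design_array()
    var_cells = (sigma**2) @ X.T  # X is binary, so X**2 == X
    if tau == "pooled":
        tau_draws = np.sqrt(0.5 * (var_cells[:, r1] + var_cells[:, r2]))
    elif tau == "cell1":
        tau_draws = np.sqrt(var_cells[:, r1])
    elif tau == "cell2":
        tau_draws = np.sqrt(var_cells[:, r2])
    else:
        raise ValueError("tau must be 'pooled', 'cell1' or 'cell2'")
    if np.any(tau_draws <= 0):
        raise ValueError("non-positive tau draw: upstream invariant breach")
    return DeltaDraws(
        draws=(mu2 - mu1) / tau_draws, param=param, cell_1=(s1, f1), cell_2=(s2, f2)
    )


def savage_dickey_bf(
    delta: DeltaDraws | np.ndarray,
    prior: stats.rv_continuous | tuple[float, float] = (0.0, 1.0),
    *,
    method: str = "kde",
    mass: float = 0.95,
) -> BFReport:
    """Savage-Dickey density-ratio Bayes factor for a point null at 0.

    ``prior`` is the effect-size expectation for ``delta`` (default standard
    normal); BF_10 = prior pdf(0) / posterior density(0). ``method="kde"``
    estimates the posterior density with a Gaussian kernel (Silverman
    bandwidth); ``method="normal"`` uses a moment-matched normal instead.
    A vanishing posterior density at 0 caps the BF at ``BF_CAP`` (flagged).
    """
    if isinstance(delta, DeltaDraws):
        x = delta.draws
        param, comparison = delta.param, delta.label
    else:
        x = np.asarray(delta, dtype=float)
        param, comparison = "", ""
    if x.size < 1000:
        raise ValueError("Savage-Dickey estimation needs at least 1000 draws")
    if isinstance(prior, tuple):
        prior_dist = stats.norm(*prior)
    else:
        prior_dist = prior
    prior0 = float(prior_dist.pdf(0.0))
    if method == "kde":
        post0 = float(stats.gaussian_kde(x, bw_method="silverman")(0.0)[0])
    elif method == "normal":
        post0 = float(stats.norm(x.mean(), x.std(ddof=1)).pdf(0.0))
    else:
        raise ValueError("method must be 'kde' or 'normal'")
    capped = False
    if post0 <= prior0 / BF_CAP:
        bf10, capped = BF_CAP, True
    else:
        bf10 = prior0 / post0
    lo, hi = hdi(x, mass)
    return BFReport(
        bf10=bf10,
        hdi_low=lo,
        hdi_high=hi,
        p_direction=direction_probability(x),
        param=param,
        comparison=comparison,
        capped=capped,
    )


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws.

    Scans contiguous windows of the sorted draws and returns the
    minimum-width one (ties broken to the first, i.e. lowest, window).
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("draws must be non-empty and finite")
    n = x.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def direction_probability(draws) -> float:
    """Fraction of draws that are strictly positive."""
    x = np.asarray(draws, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("draws must be finite")
    return float(np.mean(x > 0))


def paired_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided paired t-test power at effect size ``d`` and ``n`` pairs."""
    df = n - 1
    ncp = d * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def required_sample_size_paired_t(
    d: float, power: float = 0.80, alpha: float = 0.05, *, n_max: int = 100000
) -> int:
    """Smallest number of pairs achieving the target power (noncentral t)."""
    if not 0 < power < 1 or not 0 < alpha < 1 or d <= 0:
        raise ValueError("require d > 0 and power, alpha in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_t_power(d, n, alpha) >= power:
            return n
    raise ValueError("no sample size up to n_max reaches the target power")


#: the pairwise session contrasts reported per feedback type
SESSION_PAIRS = (
    ("baseline", "iso_total"),
    ("baseline", "iso_media"),
    ("iso_media", "iso_total"),
)


def bf_table(
    draws: PosteriorDraws,
    params: tuple[str, ...] | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
    *,
    method: str = "kde",
) -> pd.DataFrame:
    """Savage-Dickey BF, 95% HDI and direction probability for every pairwise
    session contrast within each feedback type, for each model parameter."""
    params = params or draws.spec.params
    rows = []
    for param in params:
        for feedback in dz.FEEDBACKS:
            for s1, s2 in SESSION_PAIRS:
                delta = effect_size_delta(
                    draws, param, ((s1, feedback), (s2, feedback))
                )
                rep = savage_dickey_bf(delta, prior, method=method)
                rows.append(
                    {
                        "parameter": param,
                        "feedback": feedback,
                        "comparison": f"{s2} - {s1}",
                        "BF10": rep.bf10,
                        "hdi_low": rep.hdi_low,
                        "hdi_high": rep.hdi_high,
                        "p_direction": rep.p_direction,
                        "evidence": rep.evidence_band,
                    }
                )
    return pd.DataFrame(rows)
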