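"""Value-update models and the softmax choice rule for two-option reversal learning.

Four candidate learners are implemented, all built on the Rescorla-Wagner
prediction-error idea but differing in how information is integrated:

``rw_pn``
    Reward/punishment model: the chosen option's value moves toward the
    outcome with separate learning rates after wins (``eta_rew``) and
    non-wins (``eta_nrew``).
``ewa``
    Experience-weighted attraction: an experience weight ``n`` (decaying by
    ``rho``) accumulates per option and damps the update; ``phi`` decays the
    contribution of past payoffs.
``ewa_2lr``
    EWA with separate payoff-decay rates after wins (``phi_rew``) and
    non-wins (``phi_nrew``).
``fictitious``
    Fictitious update: the chosen option is updated toward the outcome and
    the unchosen option toward the negated outcome (counterfactual), with
    the learning-rate assignment mirrored between the two.

Outcomes are coded +1 (win) / -1 (no win); the update rules branch on the
sign, so an outcome of 0 is a coding violation and is rejected.

Choice follows a softmax on the value difference with inverse temperature
``beta`` (0 = random choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "ValueState",
    "MODELS",
    "get_model",
    "initial_state",
    "update_rw_pn",
    "update_ewa",
    "update_ewa_2lr",
    "update_fictitious",
    "choice_prob",
    "sequence_loglik",
    "evaluate_blocks",
]

#: parameters bounded to the unit interval on the constrained scale
UNIT_PARAMS = frozenset(
    {"eta_rew", "eta_nrew", "rho", "phi", "phi_rew", "phi_nrew"}
)


@dataclass(frozen=True)
class ModelSpec:
    """Name and ordered parameter set of a candidate model."""

    name: str
    params: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def validate_params(self, params: Mapping[str, float]) -> None:
        missing = set(self.params) - set(params)
        extra = set(params) - set(self.params)
        if missing or extra:
            raise ValueError(
                f"model {self.name!r} expects parameters {self.params}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for name in self.params:
            v = np.asarray(params[name], dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"parameter {name!r} is not finite")
            if name in UNIT_PARAMS and (np.any(v < 0) or np.any(v > 1)):
                raise ValueError(f"parameter {name!r} must lie in [0, 1]")
            if name == "beta" and np.any(v < 0):
                raise ValueError("beta must be nonnegative")


MODELS: dict[str, ModelSpec] = {
    "rw_pn": ModelSpec("rw_pn", ("eta_rew", "eta_nrew", "beta")),
    "ewa": ModelSpec("ewa", ("rho", "phi", "beta")),
    "ewa_2lr": ModelSpec("ewa_2lr", ("rho", "phi_rew", "phi_nrew", "beta")),
    "fictitious": ModelSpec("fictitious", ("eta_rew", "eta_nrew", "beta")),
}


def get_model(name: str | ModelSpec) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {sorted(MODELS)}"
        ) from None


@dataclass(frozen=True)
class ValueState:
    """Option values (and, for the EWA family, per-option experience weights)."""

    V: np.ndarray  # shape (2,)
    n: np.ndarray = field(default_factory=lambda: np.ones(2))  # EWA only

    def __post_init__(self):
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float).copy())
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float).copy())


def initial_state() -> ValueState:
    """Fresh block-start state: both values 0, experience weights 1."""
    return ValueState(V=np.zeros(2), n=np.ones(2))


def _check_outcome(outcome: float) -> None:
    if outcome == 0:
        raise ValueError(
            "outcome 0 violates the +1/-1 win/no-win coding; the update "
            "rules branch on the outcome sign"
        )


def update_rw_pn(
    state: ValueState, choice: int, outcome: float,
    eta_rew: float, eta_nrew: float,
) -> ValueState:
    """Chosen option moves toward the outcome; rate depends on the outcome sign."""
    _check_outcome(outcome)
    eta = eta_rew if outcome > 0 else eta_nrew
    V = state.V.copy()
    V[choice] += eta * (outcome - V[choice])
    return replace(state, V=V)


def update_ewa(
    state: ValueState, choice: int, outcome: float,
    rho: float, phi: float, *, denom: str = "new",
) -> ValueState:
    """Experience-weighted attraction update of the chosen option.

    ``denom="new"`` divides by the freshly incremented experience weight
    (payoff-decay numerator uses the previous weight); ``denom="prev"``
    divides by the previous weight instead — the typeset recursion admits
    both readings, so the alternative stays switchable.
    """
    _check_outcome(outcome)
    V, n = state.V.copy(), state.n.copy()
    n_prev = n[choice]
    n_new = n_prev * rho + 1.0
    den = n_new if denom == "new" else n_prev
    V[choice] = (V[choice] * phi * n_prev + outcome) / den
    n[choice] = n_new
    return ValueState(V=V, n=n)


def update_ewa_2lr(
    state: ValueState, choice: int, outcome: float,
    rho: float, phi_rew: float, phi_nrew: float, *, denom: str = "new",
) -> ValueState:
    """EWA update with the payoff decay branching on the outcome sign."""
    phi = phi_rew if outcome > 0 else phi_nrew
    return update_ewa(state, choice, outcome, rho, phi, denom=denom)


def update_fictitious(
    state: ValueState, choice: int, outcome: float,
    eta_rew: float, eta_nrew: float,
) -> ValueState:
    """Factual update of the chosen option and counterfactual update of the other.

    The unchosen option moves toward the negated outcome, with the
    learning-rate assignment mirrored (a win for the chosen option is
    treated as a non-win for the unchosen one, and vice versa).
    """
    _check_outcome(outcome)
    other = 1 - choice
    V = state.V.copy()
    if outcome > 0:
        V[choice] += eta_rew * (outcome - V[choice])
        V[other] += eta_nrew * (-outcome - V[other])
    else:
        V[choice] += eta_nrew * (outcome - V[choice])
        V[other] += eta_rew * (-outcome - V[other])
    return replace(state, V=V)


_UPDATES = {
    "rw_pn": lambda s, c, o, p: update_rw_pn(s, c, o, p["eta_rew"], p["eta_nrew"]),
    "ewa": lambda s, c, o, p: update_ewa(s, c, o, p["rho"], p["phi"]),
    "ewa_2lr": lambda s, c, o, p: update_ewa_2lr(
        s, c, o, p["rho"], p["phi_rew"], p["phi_nrew"]
    ),
    "fictitious": lambda s, c, o, p: update_fictitious(
        s, c, o, p["eta_rew"], p["eta_nrew"]
    ),
}


def apply_update(
    model: str | ModelSpec, state: ValueState, choice: int, outcome: float,
    params: Mapping[str, float],
) -> ValueState:
    """Dispatch one value update for the named model."""
    spec = get_model(model)
    return _UPDATES[spec.name](state, choice, outcome, params)


def choice_prob(v_a, v_b, beta):
    """Softmax probability of choosing A: ``1 / (1 + exp(-beta (V_A - V_B)))``.

    Numerically stable for arbitrarily large ``|beta * (V_A - V_B)|``.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be nonnegative")
    return expit(beta * (np.asarray(v_a, dtype=float) - np.asarray(v_b, dtype=float)))


def sequence_loglik(
    model: str | ModelSpec,
    params: Mapping[str, float],
    choices: Sequence[int],
    outcomes: Sequence[float],
    *,
    per_trial: bool = False,
):
    """Log-likelihood of an observed choice sequence under one model.

    Values start at 0 (experience weights at 1) and evolve by the model's
    update rule; each observed choice contributes the log softmax
    probability of that choice given the pre-trial values.  Missing trials
    (choice coded as -1 or NaN) contribute zero and trigger no update.

    Returns the scalar sum, or ``(scalar, per_trial_vector)`` when
    ``per_trial`` is requested.
    """
    spec = get_model(model)
    spec.validate_params(params)
    ch = np.asarray(choices, dtype=float)
    ch = np.where(np.isnan(ch), -1, ch).astype(int)[None, :]
    oc = np.asarray(outcomes, dtype=float)[None, :]
    if ch.shape != oc.shape:
        raise ValueError("choices and outcomes must be aligned")
    observed = ch[0] >= 0
    if np.any(oc[0][observed] == 0):
        raise ValueError("outcome 0 violates the +1/-1 coding")
    p = {k: np.asarray([params[k]], dtype=float) for k in spec.params}
    out = evaluate_blocks(spec, p, ch, oc, per_trial=per_trial)
    total = float(out["loglik"][0])
    if per_trial:
        return total, out["pointwise"][0]
    return total


def evaluate_blocks(
    model: str | ModelSpec,
    params: Mapping[str, np.ndarray],
    choices: np.ndarray,
    outcomes: np.ndarray,
    *,
    per_trial: bool = False,
    grad: bool = False,
    engine: str = "auto",
) -> dict:
    """Vectorized sequence log-likelihood over a batch of trial blocks.

    Parameters are arrays of shape ``(B,)`` (one value per block);
    ``choices`` and ``outcomes`` are ``(B, T)`` with choice ``-1`` marking a
    missing trial.  Returns ``loglik`` of shape ``(B,)`` and optionally the
    per-trial matrix and the gradient ``(B, n_params)`` with respect to the
    constrained parameters, accumulated analytically alongside the value
    recursion (used by the hierarchical sampler).

    ``engine`` selects the compiled inner loop (``"numba"``), the pure numpy
    reference path (``"numpy"``), or the compiled path when available
    (``"auto"``); the two are numerically identical.
    """
    from . import _kernels

    spec = get_model(model)
    if engine not in ("auto", "numpy", "numba"):
        raise ValueError("engine must be 'auto', 'numpy' or 'numba'")
    use_numba = engine == "numba" or (engine == "auto" and _kernels.HAVE_NUMBA)
    if use_numba:
        ch = np.ascontiguousarray(np.asarray(choices), dtype=np.int64)
        oc = np.ascontiguousarray(np.asarray(outcomes), dtype=np.float64)
        B = ch.shape[0]
        p = {
            k: np.ascontiguousarray(
                np.broadcast_to(np.asarray(params[k], dtype=np.float64), (B,))
            )
            for k in spec.params
        }
        if spec.name in ("rw_pn", "fictitious"):
            ll, pt, g = _kernels.ll_grad_rw_fict(
                ch, oc, p["eta_rew"], p["eta_nrew"], p["beta"],
                spec.name == "fictitious",
            )
        elif spec.name == "ewa":
            ll, pt, g4 = _kernels.ll_grad_ewa(
                ch, oc, p["rho"], p["phi"], p["phi"], p["beta"]
            )
            g = np.stack([g4[:, 0], g4[:, 1] + g4[:, 2], g4[:, 3]], axis=1)
        else:  # ewa_2lr
            ll, pt, g = _kernels.ll_grad_ewa(
                ch, oc, p["rho"], p["phi_rew"], p["phi_nrew"], p["beta"]
            )
        out = {"loglik": ll}
        if per_trial:
            out["pointwise"] = pt
        if grad:
            out["grad"] = g
        return out
    return _evaluate_blocks_numpy(
        spec, params, choices, outcomes, per_trial=per_trial, grad=grad
    )


def _evaluate_blocks_numpy(
    model: str | ModelSpec,
    params: Mapping[str, np.ndarray],
    choices: np.ndarray,
    outcomes: np.ndarray,
    *,
    per_trial: bool = False,
    grad: bool = False,
) -> dict:
    """Pure-numpy reference implementation of :func:`evaluate_blocks`."""
    spec = get_model(model)
    name = spec.name
    ch = np.asarray(choices)
    oc = np.asarray(outcomes, dtype=float)
    B, T = ch.shape
    p = {k: np.broadcast_to(np.asarray(params[k], dtype=float), (B,)) for k in spec.params}
    beta = p["beta"]

    idx = np.arange(B)
    V = np.zeros((B, 2))
    ll = np.zeros(B)
    pt = np.zeros((B, T)) if per_trial else None

    if grad:
        # derivative of V wrt each learning parameter, per option
        dV = {k: np.zeros((B, 2)) for k in spec.params if k != "beta"}
        g = {k: np.zeros(B) for k in spec.params}
    if name in ("ewa", "ewa_2lr"):
        n = np.ones((B, 2))
        if grad:
            dn_rho = np.zeros((B, 2))

    for t in range(T):
        c_raw = ch[:, t]
        m = c_raw >= 0
        c = np.where(m, c_raw, 0).astype(int)
        u = 1 - c
        o = oc[:, t]
        Vc = V[idx, c]
        Vu = V[idx, u]
        dv = Vc - Vu
        z = beta * dv
        logp = -np.logaddexp(0.0, -z)
        ll += np.where(m, logp, 0.0)
        if per_trial:
            pt[:, t] = np.where(m, logp, 0.0)
        if grad:
            coef = np.where(m, expit(-z), 0.0)  # 1 - p(choice)
            g["beta"] += coef * dv
            for k, d in dV.items():
                g[k] += coef * beta * (d[idx, c] - d[idx, u])

        pos = o > 0
        if name in ("rw_pn", "fictitious"):
            er, en = p["eta_rew"], p["eta_nrew"]
            rate_c = np.where(pos, er, en)
            pe_c = o - Vc
            newVc = Vc + rate_c * pe_c
            if grad:
                dr_c = dV["eta_rew"][idx, c] * (1 - rate_c) + np.where(pos, pe_c, 0.0)
                dn_c = dV["eta_nrew"][idx, c] * (1 - rate_c) + np.where(pos, 0.0, pe_c)
            if name == "fictitious":
                rate_u = np.where(pos, en, er)
                pe_u = -o - Vu
                newVu = Vu + rate_u * pe_u
                if grad:
                    dr_u = dV["eta_rew"][idx, u] * (1 - rate_u) + np.where(pos, 0.0, pe_u)
                    dn_u = dV["eta_nrew"][idx, u] * (1 - rate_u) + np.where(pos, pe_u, 0.0)
                    dV["eta_rew"][idx, u] = np.where(m, dr_u, dV["eta_rew"][idx, u])
                    dV["eta_nrew"][idx, u] = np.where(m, dn_u, dV["eta_nrew"][idx, u])
                V[idx, u] = np.where(m, newVu, Vu)
            if grad:
                dV["eta_rew"][idx, c] = np.where(m, dr_c, dV["eta_rew"][idx, c])
                dV["eta_nrew"][idx, c] = np.where(m, dn_c, dV["eta_nrew"][idx, c])
            V[idx, c] = np.where(m, newVc, Vc)
        else:  # EWA family: chosen option only, with experience weight
            rho = p["rho"]
            if name == "ewa":
                phi = p["phi"]
            else:
                phi = np.where(pos, p["phi_rew"], p["phi_nrew"])
            n_prev = n[idx, c]
            n_new = n_prev * rho + 1.0
            newVc = (Vc * phi * n_prev + o) / n_new
            if grad:
                dnp = dn_rho[idx, c]
                dnn = dnp * rho + n_prev
                base = phi * n_prev / n_new
                d_rho = (
                    dV["rho"][idx, c] * base
                    + Vc * phi * dnp / n_new
                    - newVc * dnn / n_new
                )
                dV["rho"][idx, c] = np.where(m, d_rho, dV["rho"][idx, c])
                dphi_common = (Vc * n_prev) / n_new
                if name == "ewa":
                    d_phi = dV["phi"][idx, c] * base + dphi_common
                    dV["phi"][idx, c] = np.where(m, d_phi, dV["phi"][idx, c])
                else:
                    d_pr = dV["phi_rew"][idx, c] * base + np.where(pos, dphi_common, 0.0)
                    d_pn = dV["phi_nrew"][idx, c] * base + np.where(pos, 0.0, dphi_common)
                    dV["phi_rew"][idx, c] = np.where(m, d_pr, dV["phi_rew"][idx, c])
                    dV["phi_nrew"][idx, c] = np.where(m, d_pn, dV["phi_nrew"][idx, c])
                dn_rho[idx, c] = np.where(m, dnn, dnp)
            V[idx, c] = np.where(m, newVc, Vc)
            n[idx, c] = np.where(m, n_new, n_prev)

    out = {"loglik": ll}
    if per_trial:
        out["pointwise"] = pt
    if grad:
        out["grad"] = np.stack([g[k] for k in spec.params], axis=1)
    return out
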