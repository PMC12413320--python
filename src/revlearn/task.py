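"""Task schedules, agent simulation, and synthetic-cohort generation.

The reversal-learning task presents two options; one carries reward with
probability ``p_high`` (0.8), the other with ``1 - p_high``, and the
identity of the better option reverses every ``phase_length`` trials
(7 trials, so a 28-trial block has 4 phases). Reward availability is
pre-realized per option per trial, so counterfactual updates and replays
are well defined. A session consists of two 28-trial blocks (social and
nonsocial feedback) in a seeded random order.

The effort-based decision schedule crosses effort (hard/easy), reward
(high=4 / low=1 point) and context (social/nature) into eight balanced
conditions presented in seeded random order; only the condition list is
generated here.

The synthetic cohort emulates the study design: ``n_subjects`` subjects,
each completing two feedback blocks in each of three sessions, with
individual parameters drawn per design column from group normals on the
unconstrained scale and mapped through the probit links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import design as dz
from .models import MODELS, ModelSpec, apply_update, choice_prob, get_model, initial_state

__all__ = [
    "TaskSchedule",
    "SessionSchedule",
    "EbdmSchedule",
    "CohortSpec",
    "Cohort",
    "make_reversal_block",
    "make_session_schedule",
    "make_ebdm_schedule",
    "simulate_agent",
    "default_cohort_spec",
    "generate_cohort",
]

OUTCOME_WIN = 1
OUTCOME_NOWIN = -1


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial identity of the better option and pre-realized reward availability."""

    n_trials: int
    phase_length: int
    p_high: float
    high_option: np.ndarray  # (T,) in {0, 1}
    reward_available: np.ndarray  # (T, 2) in {0, 1}

    @property
    def n_phases(self) -> int:
        return self.n_trials // self.phase_length

    def phase_of(self, trial: int) -> int:
        """1-based phase index of a 0-based trial index."""
        return trial // self.phase_length + 1

    def validate(self) -> None:
        t = np.arange(self.n_trials)
        expected_switches = (t[1:] % self.phase_length) == 0
        actual_switches = self.high_option[1:] != self.high_option[:-1]
        if not np.array_equal(expected_switches, actual_switches):
            raise ValueError("high_option must reverse exactly at phase boundaries")
        if self.reward_available.shape != (self.n_trials, 2):
            raise ValueError("reward_available must have shape (n_trials, 2)")


def make_reversal_block(
    n_trials: int = 28,
    phase_length: int = 7,
    p_high: float = 0.8,
    seed=None,
    *,
    first_high: int | None = None,
) -> TaskSchedule:
    """Generate one reversal-learning block.

    The better option is chosen at random for the first phase (unless
    ``first_high`` pins it) and alternates at every multiple of
    ``phase_length``. Reward availability is drawn independently per trial:
    with probability ``p_high`` for the better option and ``1 - p_high``
    for the other.
    """
    if n_trials <= 0 or phase_length <= 0:
        raise ValueError("n_trials and phase_length must be positive")
    if n_trials % phase_length != 0:
        raise ValueError(
            f"phase_length {phase_length} must divide n_trials {n_trials}: "
            "phases are contiguous equal-length runs"
        )
    if not 0 < p_high < 1:
        raise ValueError("p_high must lie strictly between 0 and 1")
    rng = _as_rng(seed)
    first = int(rng.integers(0, 2)) if first_high is None else int(first_high)
    phase = np.arange(n_trials) // phase_length
    high = (first + phase) % 2
    p = np.where(high[:, None] == np.arange(2)[None, :], p_high, 1.0 - p_high)
    avail = (rng.random((n_trials, 2)) < p).astype(int)
    sched = TaskSchedule(n_trials, phase_length, float(p_high), high, avail)
    sched.validate()
    return sched


@dataclass(frozen=True)
class SessionSchedule:
    """Two independent feedback blocks in seeded presentation order."""

    order: tuple[str, str]  # permutation of ("social", "nonsocial")
    blocks: Mapping[str, TaskSchedule]

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks.values())


def make_session_schedule(
    seed=None, n_trials: int = 28, phase_length: int = 7, p_high: float = 0.8
) -> SessionSchedule:
    """One session: independent social and nonsocial blocks, order randomized."""
    rng = _as_rng(seed)
    order = ("social", "nonsocial") if rng.integers(0, 2) else ("nonsocial", "social")
    blocks = {
        label: make_reversal_block(n_trials, phase_length, p_high, rng)
        for label in order
    }
    return SessionSchedule(order=order, blocks=blocks)


EBDM_EFFORTS = ("hard", "easy")
EBDM_REWARDS = (4, 1)  # points: high / low
EBDM_CONTEXTS = ("social", "nature")


@dataclass(frozen=True)
class EbdmSchedule:
    """Balanced, seeded-order condition list for the effort-based decision task."""

    trials: pd.DataFrame  # columns: effort, reward, context

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def make_ebdm_schedule(trials_per_condition: int = 6, seed=None) -> EbdmSchedule:
    """Cross effort x reward x context (8 conditions), repeat, and shuffle."""
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    rng = _as_rng(seed)
    conditions = [
        (e, r, c) for e in EBDM_EFFORTS for r in EBDM_REWARDS for c in EBDM_CONTEXTS
    ]
    rows = conditions * trials_per_condition
    perm = rng.permutation(len(rows))
    df = pd.DataFrame(
        [rows[i] for i in perm], columns=["effort", "reward", "context"]
    )
    return EbdmSchedule(trials=df)


def simulate_agent(
    model: str | ModelSpec,
    agent_params: Mapping[str, float],
    schedule: TaskSchedule,
    seed=None,
    *,
    u: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one agent on one block.

    Choices are sampled from the model's softmax probabilities; outcomes are
    read from the schedule's pre-realized reward availability (+1 win, -1 no
    win); values evolve by the model's update rule from a fresh state.

    ``u`` optionally supplies the per-trial uniform variates used to sample
    choices (for exact replay); otherwise they are drawn from ``seed``.

    Returns a frame with 1-based ``trial`` and ``phase``, ``choice``,
    ``outcome`` and ``high_option`` columns.
    """
    spec = get_model(model)
    spec.validate_params(agent_params)
    if u is None:
        u = _as_rng(seed).random(schedule.n_trials)
    else:
        u = np.asarray(u, dtype=float)
        if u.shape != (schedule.n_trials,):
            raise ValueError("u must supply one uniform variate per trial")
    state = initial_state()
    rows = []
    for t in range(schedule.n_trials):
        p0 = choice_prob(state.V[0], state.V[1], agent_params["beta"])
        choice = 0 if u[t] < p0 else 1
        outcome = (
            OUTCOME_WIN if schedule.reward_available[t, choice] else OUTCOME_NOWIN
        )
        rows.append(
            {
                "trial": t + 1,
                "phase": schedule.phase_of(t),
                "choice": choice,
                "outcome": outcome,
                "high_option": int(schedule.high_option[t]),
            }
        )
        state = apply_update(spec, state, choice, outcome, agent_params)
    return pd.DataFrame(rows)


def make_high_option_paths(
    n_blocks: int,
    n_trials: int = 28,
    phase_length: int = 7,
    rng=None,
) -> np.ndarray:
    """Better-option identity per trial for a batch of blocks, ``(G, T)``.

    The first phase's better option is random per block; it alternates at
    every phase boundary.
    """
    rng = _as_rng(rng)
    first = rng.integers(0, 2, size=n_blocks)
    phase = np.arange(n_trials) // phase_length
    return (first[:, None] + phase[None, :]) % 2


def simulate_blocks(
    model: str | ModelSpec,
    params: Mapping[str, np.ndarray],
    high: np.ndarray,
    p_high: float,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized agent simulation over a batch of blocks.

    ``params`` maps parameter names to ``(G,)`` arrays; ``high`` is the
    ``(G, T)`` better-option path. Reward availability of the chosen option
    is realized on the fly (probability ``p_high`` when the choice matches
    the better option, ``1 - p_high`` otherwise), which is distributionally
    identical to pre-realizing both options. Returns ``(choices, outcomes)``
    as ``(G, T)`` arrays with outcomes coded +1/-1.
    """
    from scipy.special import expit

    spec = get_model(model)
    rng = _as_rng(rng)
    G, T = high.shape
    p = {k: np.broadcast_to(np.asarray(params[k], dtype=float), (G,)) for k in spec.params}
    beta = p["beta"]
    V = np.zeros((G, 2))
    if spec.name in ("ewa", "ewa_2lr"):
        n = np.ones((G, 2))
    idx = np.arange(G)
    choices = np.empty((G, T), dtype=np.int64)
    outcomes = np.empty((G, T), dtype=np.int64)
    for t in range(T):
        p0 = expit(beta * (V[:, 0] - V[:, 1]))
        c = (rng.random(G) >= p0).astype(np.int64)
        p_rew = np.where(c == high[:, t], p_high, 1.0 - p_high)
        o = np.where(rng.random(G) < p_rew, 1.0, -1.0)
        choices[:, t] = c
        outcomes[:, t] = o
        Vc = V[idx, c]
        pos = o > 0
        if spec.name in ("rw_pn", "fictitious"):
            rate_c = np.where(pos, p["eta_rew"], p["eta_nrew"])
            V[idx, c] = Vc + rate_c * (o - Vc)
            if spec.name == "fictitious":
                u = 1 - c
                Vu = V[idx, u]
                rate_u = np.where(pos, p["eta_nrew"], p["eta_rew"])
                V[idx, u] = Vu + rate_u * (-o - Vu)
        else:
            if spec.name == "ewa":
                phi = p["phi"]
            else:
                phi = np.where(pos, p["phi_rew"], p["phi_nrew"])
            n_prev = n[idx, c]
            n_new = n_prev * p["rho"] + 1.0
            V[idx, c] = (Vc * phi * n_prev + o) / n_new
            n[idx, c] = n_new
    return choices, outcomes


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for a synthetic cohort.

    Group means and subject-level SDs are given per design column (baseline
    and difference columns, see :mod:`revlearn.design`) on the unconstrained
    scale; individual cell parameters are the design-matrix row sums of
    ``mean + sd * z`` with ``z ~ N(0, 1)`` per subject per column, mapped
    through the probit links (rates to (0, 1), beta to (0, beta_upper)).
    """

    n_subjects: int = 40
    model: str = "fictitious"
    group_mean: Mapping[str, np.ndarray] = field(default_factory=dict)
    group_sd: Mapping[str, np.ndarray] = field(default_factory=dict)
    beta_upper: float = 10.0
    n_trials: int = 28
    phase_length: int = 7
    p_high: float = 0.8
    yoke_schedules: bool = False
    seed: int = 0

    def validate(self) -> None:
        spec = get_model(self.model)
        for p in spec.params:
            for d, label in ((self.group_mean, "group_mean"), (self.group_sd, "group_sd")):
                if p not in d:
                    raise ValueError(f"{label} missing parameter {p!r}")
                if np.asarray(d[p]).shape != (6,):
                    raise ValueError(f"{label}[{p!r}] must have one value per design column")
        if np.any([np.any(np.asarray(v) < 0) for v in self.group_sd.values()]):
            raise ValueError("group SDs must be nonnegative")
        if self.beta_upper <= 0:
            raise ValueError("beta_upper must be positive")


#: generating group-level means per design column, unconstrained (probit) scale.
#: Baseline columns put the average subject at eta_rew ~ 0.5, eta_nrew ~ 0.31
#: (positive-feedback learning faster than negative) and beta ~ 1.5 of an
#: upper bound of 10, matching the observed range of this task family;
#: isolation difference columns add a small positive shift.
_DEFAULT_MEANS = {
    "eta_rew": np.array([0.0, 0.0, 0.2, 0.0, 0.0, 0.2]),
    "eta_nrew": np.array([-0.5, 0.0, 0.2, -0.5, 0.2, 0.2]),
    "beta": np.array([-1.04, 0.2, 0.2, -1.04, 0.3, 0.2]),
}
_DEFAULT_SDS = {
    "eta_rew": np.array([0.4, 0.2, 0.2, 0.4, 0.2, 0.2]),
    "eta_nrew": np.array([0.4, 0.2, 0.2, 0.4, 0.2, 0.2]),
    "beta": np.array([0.4, 0.2, 0.2, 0.4, 0.2, 0.2]),
}


def default_cohort_spec(n_subjects: int = 40, seed: int = 0, **overrides) -> CohortSpec:
    """Study-condition defaults: a fictitious-update cohort with modest
    isolation effects on learning rates and inverse temperature."""
    spec = CohortSpec(
        n_subjects=n_subjects,
        model="fictitious",
        group_mean={k: v.copy() for k, v in _DEFAULT_MEANS.items()},
        group_sd={k: v.copy() for k, v in _DEFAULT_SDS.items()},
        seed=seed,
        **overrides,
    )
    spec.validate()
    return spec


@dataclass(frozen=True)
class Cohort:
    """Synthetic choice data plus the ground truth that generated it."""

    data: pd.DataFrame
    spec: CohortSpec
    subject_params: pd.DataFrame  # subject x cell x param, unconstrained + value
    blocks: Mapping[tuple, dict]  # (subject, session, feedback) -> schedule + replay u


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full cohort under the study design.

    Every subject completes two feedback blocks in each of the three
    sessions on freshly generated schedules (or a single yoked session
    schedule when ``spec.yoke_schedules``), with individual parameters drawn
    once per subject and held fixed across that subject's cells.
    """
    spec.validate()
    mspec = get_model(spec.model)
    rng = np.random.default_rng(spec.seed)
    X = dz.design_array()

    # subject-level unconstrained cell parameters
    mean = np.stack([np.asarray(spec.group_mean[p], dtype=float) for p in mspec.params], axis=1)
    sd = np.stack([np.asarray(spec.group_sd[p], dtype=float) for p in mspec.params], axis=1)
    z = rng.standard_normal((spec.n_subjects, 6, mspec.n_params))
    theta_cols = mean[None] + sd[None] * z  # (S, 6 columns, P)
    theta_cells = np.einsum("rk,skp->srp", X, theta_cols)  # (S, 6 cells, P)

    truth_rows = []
    records = []
    blocks: dict[tuple, dict] = {}
    yoked = (
        make_session_schedule(rng, spec.n_trials, spec.phase_length, spec.p_high)
        if spec.yoke_schedules
        else None
    )
    subjects = [f"s{i + 1:03d}" for i in range(spec.n_subjects)]
    for si, subj in enumerate(subjects):
        for session in dz.SESSIONS:
            sess_sched = yoked if yoked is not None else make_session_schedule(
                rng, spec.n_trials, spec.phase_length, spec.p_high
            )
            for block_pos, feedback in enumerate(sess_sched.order, start=1):
                r = dz.cell_index(session, feedback)
                params = {}
                for pi, pname in enumerate(mspec.params):
                    th = theta_cells[si, r, pi]
                    val = (
                        dz.scaled_probit_link(th, spec.beta_upper)
                        if pname == "beta"
                        else dz.probit_link(th)
                    )
                    params[pname] = float(val)
                sched = sess_sched.blocks[feedback]
                u = rng.random(sched.n_trials)
                sim = simulate_agent(mspec, params, sched, u=u)
                sim.insert(0, "subject_id", subj)
                sim.insert(1, "session", session)
                sim.insert(2, "feedback", feedback)
                sim.insert(3, "block", block_pos)
                records.append(sim)
                blocks[(subj, session, feedback)] = {"schedule": sched, "u": u}
        for r, (session, feedback) in enumerate(dz.CELLS):
            for pi, pname in enumerate(mspec.params):
                th = theta_cells[si, r, pi]
                val = (
                    dz.scaled_probit_link(th, spec.beta_upper)
                    if pname == "beta"
                    else dz.probit_link(th)
                )
                truth_rows.append(
                    {
                        "subject_id": subj,
                        "session": session,
                        "feedback": feedback,
                        "param": pname,
                        "unconstrained": float(th),
                        "value": float(val),
                    }
                )
    data = pd.concat(records, ignore_index=True)
    data["rt_ms"] = np.nan
    cols = [
        "subject_id", "session", "feedback", "block", "trial", "phase",
        "choice", "outcome", "high_option", "rt_ms",
    ]
    return Cohort(
        data=data[cols],
        spec=spec,
        subject_params=pd.DataFrame(truth_rows),
        blocks=blocks,
    )
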