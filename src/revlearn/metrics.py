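"""Model-free behavioral indices: accuracy and perseverative errors.

Accuracy is the proportion of choices of the currently better option;
perseverative errors, defined for reversal phases (2 and later), are the
proportion of trials on which the previously reinforced option — the better
option of the preceding phase — is chosen. Phase 1 has no perseverative
measure because no rule had been learned yet. With two options and no
missing trials, the perseverative-error proportion within a reversal phase
is exactly 1 - accuracy, since the previous phase's better option is the
current worse one. Missing trials are excluded from numerator and
denominator alike; phase boundaries come from the schedule annotations,
never from behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["accuracy", "perseverative_errors", "phase_summary"]

_KEYS = ["subject_id", "session", "feedback", "phase"]


def _observed(dataset: pd.DataFrame) -> pd.DataFrame:
    d = dataset.copy()
    d["choice"] = pd.to_numeric(d["choice"], errors="coerce")
    return d[d["choice"].notna() & (d["choice"] >= 0)]


def accuracy(dataset: pd.DataFrame) -> pd.DataFrame:
    """Proportion of correct (better-option) responses per subject-cell-phase."""
    d = _observed(dataset)
    d["correct"] = (d["choice"] == d["high_option"]).astype(float)
    out = (
        d.groupby(_KEYS)["correct"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    return out


def perseverative_errors(dataset: pd.DataFrame, phase: int) -> pd.DataFrame:
    """Proportion of previous-better-option choices in one reversal phase.

    ``phase`` must be 2 or later; with alternating two-option contingencies
    the previously reinforced option is ``1 - high_option`` of the current
    phase.
    """
    if phase < 2:
        raise ValueError(
            "perseverative errors are defined for reversal phases (>= 2); "
            "no rule had been learned yet in phase 1"
        )
    d = _observed(dataset)
    d = d[d["phase"] == phase]
    if d.empty:
        return pd.DataFrame(
            columns=["subject_id", "session", "feedback", "phase",
                     "perseverative", "n_trials"]
        )
    prev_high = 1 - d["high_option"]
    d["persev"] = (d["choice"] == prev_high).astype(float)
    out = (
        d.groupby(_KEYS)["persev"]
        .agg(perseverative="mean", n_trials="size")
        .reset_index()
    )
    return out


def phase_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Accuracy for every phase plus perseverative errors for phases >= 2."""
    acc = accuracy(dataset)
    phases = sorted(p for p in dataset["phase"].unique() if p >= 2)
    pieces = [perseverative_errors(dataset, p) for p in phases]
    if pieces:
        pe = pd.concat(pieces, ignore_index=True)[_KEYS + ["perseverative"]]
        out = acc.merge(pe, on=_KEYS, how="left")
    else:
        out = acc.assign(perseverative=np.nan)
    return out
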