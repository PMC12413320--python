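"""Effect-coding design matrix over the session x feedback grid, and link functions.

The within-subject design crosses three sessions (baseline, iso_media,
iso_total) with two feedback types (nonsocial, social), giving six condition
cells. Parameters are estimated per design *column* — a baseline column per
feedback type plus one difference column per isolation session — and cell
values are recovered as row sums: e.g. the iso_media/nonsocial cell equals
baseline:nonsocial + iso_media_diff:nonsocial. All columns operate on the
unconstrained (probit) scale; cell values are mapped through an
inverse-probit link, scaled by an upper bound for the inverse temperature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

SESSIONS = ("baseline", "iso_media", "iso_total")
FEEDBACKS = ("nonsocial", "social")

#: row order of the design matrix: nonsocial rows first, then social
CELLS: tuple[tuple[str, str], ...] = tuple(
    (session, feedback) for feedback in FEEDBACKS for session in SESSIONS
)

COLUMNS = (
    "baseline:nonsocial",
    "iso_media_diff:nonsocial",
    "iso_total_diff:nonsocial",
    "baseline:social",
    "iso_media_diff:social",
    "iso_total_diff:social",
)

_X = np.array(
    [
        [1, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 0, 0],
        [1, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 0, 0],
        [0, 0, 0, 1, 1, 0],
        [0, 0, 0, 1, 0, 1],
    ],
    dtype=float,
)


def build_design_matrix() -> pd.DataFrame:
    """6x6 binary effect-coding matrix with labelled rows (cells) and columns."""
    return pd.DataFrame(
        _X.copy(),
        index=[f"{s}:{f}" for s, f in CELLS],
        columns=list(COLUMNS),
    )


def design_array() -> np.ndarray:
    """The design matrix as a plain ``(6, 6)`` array (row order = CELLS)."""
    return _X.copy()


def cell_index(session: str, feedback: str) -> int:
    try:
        return CELLS.index((session, feedback))
    except ValueError:
        raise ValueError(
            f"unknown cell ({session!r}, {feedback!r}); sessions={SESSIONS}, "
            f"feedbacks={FEEDBACKS}"
        ) from None


def probit_link(theta):
    """Map unconstrained values to (0, 1) via the standard normal CDF."""
    return ndtr(np.asarray(theta, dtype=float))


def scaled_probit_link(theta, upper: float):
    """Map unconstrained values to (0, upper); used for the inverse temperature."""
    if upper <= 0:
        raise ValueError("upper bound must be positive")
    return upper * probit_link(theta)


def cell_params(column_params, design=None, link=None):
    """Row-sum column-level parameters into the six cell-level values.

    ``column_params`` has the design columns on its last axis (length 6);
    the result has cells on the last axis, optionally link-transformed.
    """
    x = _X if design is None else np.asarray(design, dtype=float)
    cp = np.asarray(column_params, dtype=float)
    if cp.shape[-1] != x.shape[1]:
        raise ValueError(
            f"column_params last axis {cp.shape[-1]} does not match the "
            f"{x.shape[1]} design columns"
        )
    cells = cp @ x.T
    return link(cells) if link is not None else cells
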