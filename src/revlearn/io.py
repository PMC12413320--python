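"""CSV / JSON / YAML serialization with strict schema validation.

Trial data travel as long-format UTF-8 CSV with a mandatory header
``subject_id,session,feedback,block,trial,phase,choice,outcome`` plus the
optional ``high_option`` and ``rt_ms`` columns (preserved when present;
floats are written at 17 significant digits for lossless round-trips).
Session and feedback labels are validated against the fixed vocabularies,
duplicate trial keys are rejected, and an outcome of 0 is rejected as a
coding violation (+1 win / -1 no win). Posterior draws serialize as a tidy
(chain, iter, parameter, value) CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from .hier import GroupPrior, PosteriorDraws, SamplerConfig

__all__ = [
    "read_choice_csv",
    "write_choice_csv",
    "write_draws",
    "read_draws",
    "write_weights_csv",
    "write_bf_csv",
    "load_config",
]

REQUIRED_COLUMNS = [
    "subject_id", "session", "feedback", "block", "trial", "phase",
    "choice", "outcome",
]
OPTIONAL_COLUMNS = ["high_option", "rt_ms"]
FLOAT_FORMAT = "%.17g"


class SchemaError(ValueError):
    """A malformed input file: message names the file and offending field."""


def write_choice_csv(dataset: pd.DataFrame, path) -> None:
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in dataset.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in dataset.columns]
    if missing:
        raise SchemaError(f"dataset missing required columns: {missing}")
    dataset[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_choice_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    unknown_sessions = set(df["session"]) - set(dz.SESSIONS)
    if unknown_sessions:
        raise SchemaError(
            f"{path}: field 'session' has unknown labels {sorted(unknown_sessions)}; "
            f"expected one of {dz.SESSIONS}"
        )
    unknown_fb = set(df["feedback"]) - set(dz.FEEDBACKS)
    if unknown_fb:
        raise SchemaError(
            f"{path}: field 'feedback' has unknown labels {sorted(unknown_fb)}; "
            f"expected one of {dz.FEEDBACKS}"
        )
    key = ["subject_id", "session", "feedback", "trial"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate trial key at line {int(df[dup].index[0]) + 2} "
            f"({tuple(first[key])})"
        )
    observed = df["choice"].notna()
    if (df.loc[observed, "outcome"] == 0).any():
        line = int(df.index[observed & (df["outcome"] == 0)][0]) + 2
        raise SchemaError(
            f"{path}: line {line}, field 'outcome': 0 violates the +1 (win) / "
            f"-1 (no win) coding"
        )
    bad = observed & ~df["outcome"].isin([1, -1])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise SchemaError(
            f"{path}: line {line}, field 'outcome': values must be +1 or -1"
        )
    return df


def write_draws(draws: PosteriorDraws, prefix) -> tuple[Path, Path]:
    """Tidy draws CSV plus JSON metadata sidecar at ``<prefix>.csv/.json``."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    C, D, K = draws.samples.shape
    frame = pd.DataFrame(
        {
            "chain": np.repeat(np.arange(C), D * K),
            "iter": np.tile(np.repeat(np.arange(D), K), C),
            "parameter": np.tile(np.asarray(draws.names, dtype=object), C * D),
            "value": draws.samples.ravel(),
        }
    )
    frame.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    meta = {
        "model": draws.model,
        "subjects": list(draws.subjects),
        "names": list(draws.names),
        "seed": draws.seed,
        "prior": vars(draws.prior).copy(),
        "sampler": vars(draws.sampler).copy(),
        "shape": [C, D, K],
        "note": "values are on the unconstrained sampling scale "
        "(sigma rows are log subject-level SDs)",
    }
    json_path.write_text(json.dumps(meta, indent=2))
    return csv_path, json_path


def read_draws(prefix) -> PosteriorDraws:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    frame = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    C, D, K = meta["shape"]
    samples = frame["value"].to_numpy().reshape(C, D, K)
    return PosteriorDraws(
        samples=samples,
        names=meta["names"],
        model=meta["model"],
        subjects=meta["subjects"],
        prior=GroupPrior(**meta["prior"]),
        sampler=SamplerConfig(**meta["sampler"]),
        seed=meta["seed"],
    )


def write_weights_csv(weights, path) -> None:
    weights.weights.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_bf_csv(bf_frame: pd.DataFrame, path) -> None:
    bf_frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


_CONFIG_KEYS = {
    "seed", "n_subjects", "model", "chains", "warmup", "draws",
    "target_accept", "beta_upper", "n_rep_per_cell", "grid_seed",
    "out_dir", "yoke_schedules",
}


def load_config(path) -> dict:
    """YAML run configuration; unknown keys are rejected by name."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text()) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg
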