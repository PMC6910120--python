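"""CSV / JSON / YAML input and output."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fieldgen import ContinuumSample
from .inference import ThresholdSet, intervals_to_percent

__all__ = [
    "read_continuum_csv",
    "write_continuum_csv",
    "read_covariate_csv",
    "result_to_dict",
]


class FormatError(ValueError):
    pass


def _looks_like_header(line: str) -> bool:
    for cell in line.strip().split(","):
        try:
            float(cell)
        except ValueError:
            return True
    return False


def read_continuum_csv(path) -> ContinuumSample:
    """Read a J x Q waveform table (rows = observations, columns = nodes).

    Accepts an optional single header row; requires rectangular numeric data
    and J >= 2.  Errors carry row/column diagnostics.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    header = 0 if _looks_like_header(first) else None
    try:
        df = pd.read_csv(path, header=header)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    values = df.to_numpy()
    bad = ~np.isfinite(pd.to_numeric(values.ravel(), errors="coerce").reshape(values.shape))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(f"{path}: non-numeric or missing cell at row {r}, column {c}")
    values = values.astype(float)
    if values.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 observation rows, got {values.shape[0]}")
    if values.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 node columns, got {values.shape[1]}")
    return ContinuumSample(values)


def write_continuum_csv(sample: ContinuumSample, path) -> None:
    """Write a sample with header ``node_0..node_{Q-1}``."""
    df = pd.DataFrame(sample.values, columns=[f"node_{i}" for i in range(sample.Q)])
    df.to_csv(path, index=False)


def read_covariate_csv(path, J: int | None = None) -> np.ndarray:
    """Read a length-J covariate vector (one value per line or one CSV row)."""
    raw = Path(path).read_text().replace(",", "\n").split()
    try:
        cov = np.array([float(v) for v in raw])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric covariate entry ({exc})") from exc
    if J is not None and cov.size != J:
        raise FormatError(f"{path}: covariate length {cov.size} != J={J}")
    return cov


def result_to_dict(tfield, thresholds: ThresholdSet, intervals: dict, seed=None) -> dict:
    """JSON-serializable analysis result: thresholds plus intervals per method."""
    return {
        **thresholds.as_dict(),
        "seed": seed,
        "t_max": float(np.max(np.abs(tfield.t))),
        "intervals": {
            method: {
                "nodes": [list(iv) for iv in ivs],
                "percent": [list(iv) for iv in intervals_to_percent(ivs, tfield.Q)],
            }
            for method, ivs in intervals.items()
        },
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
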