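"""Trajectory CSV files with a provenance header.

The file is a plain CSV of the sampled observables preceded by ``#``-prefixed
header lines embedding the full run configuration and model parameters, so
that any stored result is regenerable from the file alone (config + seed, no
hidden state).
"""

from __future__ import annotations

import io

import pandas as pd

from .config import format_config, parse_config
from .energetics import ModelParams
from .engine import TRAJECTORY_COLUMNS, RunConfig


class TrajectoryError(ValueError):
    """Malformed trajectory file."""


def write_trajectory(df: pd.DataFrame, path, config: RunConfig, params: ModelParams | None = None) -> None:
    params = params or ModelParams()
    with open(path, "w") as fh:
        fh.write("# hydropore trajectory\n")
        for line in format_config(config, params).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_trajectory(path):
    """Read a trajectory; returns (DataFrame, RunConfig, ModelParams).

    Raises :class:`TrajectoryError` naming the first offending line on
    malformed input.
    """
    header_lines = []
    body_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if body_lines:
                    raise TrajectoryError(f"line {lineno}: comment after data")
                stripped = line[1:].strip()
                if stripped and stripped != "hydropore trajectory":
                    header_lines.append(stripped)
            else:
                if not body_lines:
                    cols = [c.strip() for c in line.strip().split(",")]
                    if cols != list(TRAJECTORY_COLUMNS):
                        raise TrajectoryError(f"line {lineno}: bad column header {cols}")
                else:
                    n = len(line.strip().split(","))
                    if line.strip() and n != len(TRAJECTORY_COLUMNS):
                        raise TrajectoryError(
                            f"line {lineno}: expected {len(TRAJECTORY_COLUMNS)} fields, got {n}"
                        )
                body_lines.append(line)
    if not body_lines:
        raise TrajectoryError("no data rows found")
    config, params = parse_config("\n".join(header_lines))
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    df["step"] = df["step"].astype("int64")
    return df, config, params
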