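"""Plain-text readers and writers for count series, TPMs and reports.

Conventions: a count series is one non-negative integer per line, or a
single-column CSV with header ``count``; a transition matrix is a CSV
with ``state_0..state_n`` row/column headers plus a trailing
``tail_mass`` column; reports are JSON.  Every writer's output is
readable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ginar_core import CountSeries, GINARParams, TransitionMatrix

__all__ = [
    "read_series",
    "write_series",
    "write_tpm",
    "read_tpm",
    "write_report",
    "read_config",
]


def read_series(path) -> CountSeries:
    """Read a count series from plain text or single-column CSV."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty series file")
    lines = text.splitlines()
    if lines[0].strip().lower() == "count":
        lines = lines[1:]
    try:
        values = np.array([int(line.strip()) for line in lines if line.strip()])
    except ValueError as exc:
        raise ValueError(f"{path}: expected one non-negative integer per line") from exc
    return CountSeries(values=values)


def write_series(series: CountSeries, path, csv: bool = False) -> None:
    """Write a series one integer per line, or as CSV with ``count`` header."""
    path = Path(path)
    lines = [str(int(v)) for v in series.values]
    if csv:
        lines.insert(0, "count")
    path.write_text("\n".join(lines) + "\n")


def write_tpm(tpm: TransitionMatrix, path) -> None:
    """Write a truncated TPM as CSV with state headers and tail-mass column."""
    states = [f"state_{j}" for j in range(tpm.n + 1)]
    frame = pd.DataFrame(tpm.entries, index=states, columns=states)
    frame["tail_mass"] = tpm.tail_mass
    frame.to_csv(Path(path), index_label="")


def read_tpm(path, params: GINARParams | None = None) -> TransitionMatrix:
    """Read a TPM written by :func:`write_tpm`.

    ``params`` is attached for provenance when supplied; the file
    itself stores only the numbers.
    """
    frame = pd.read_csv(Path(path), index_col=0)
    tail = frame.pop("tail_mass").to_numpy()
    entries = frame.to_numpy()
    n = entries.shape[0] - 1
    if params is None:
        # placeholder parameters: the numbers, not the provenance, matter here
        params = GINARParams(p=0.5, rho=0.0)
    return TransitionMatrix(params=params, n=n, entries=entries, tail_mass=tail)


def write_report(report: dict, path) -> None:
    """Write a JSON report (UTF-8, indented, trailing newline)."""
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def read_config(path) -> dict[str, str]:
    """Parse a key=value config file; '#' starts a comment."""
    config: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key=value): {raw!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config
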