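"""Reading and writing traces and reports.

Traces travel as TSV/CSV with header columns ``time_s`` and ``position_nm``
(extra columns ignored, ``#`` comment lines skipped); reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import StepTrace

__all__ = ["read_trace", "write_trace", "write_report", "read_report"]


def read_trace(path) -> StepTrace:
    """Read a position-vs-time trace from TSV or CSV.

    Requires columns ``time_s`` and ``position_nm``; raises with the offending
    line numbers if any row fails to parse as a number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = {"time_s", "position_nm"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    sub = df[["time_s", "position_nm"]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    return StepTrace(
        times_s=sub["time_s"].to_numpy(),
        positions_nm=sub["position_nm"].to_numpy(),
        true_step_times=np.empty(0),
        true_step_sizes=np.empty(0),
    )


def write_trace(trace: StepTrace, path) -> None:
    """Write a trace as TSV with columns time_s, position_nm."""
    df = pd.DataFrame(
        {"time_s": trace.times_s, "position_nm": trace.positions_nm}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_report(report, path) -> None:
    """Serialize a report (anything with ``to_dict``) or plain dict as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
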