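"""Tabular readers/writers, run manifests and descriptive summaries.

All on-disk artefacts are delimited text.  Frame tables use the long
format with a ``lineage_id`` column:

    lineage_id  frame  time_min  length  mean_fluor  division

Survival cohorts, OD series, CFU plate tables and simulation traces follow
the column layouts documented on the writer functions.  Every CLI run
emits a JSON manifest (config echo, seeds, package version, input/output
digests) so deterministic stages can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import FrameSeries

__all__ = [
    "load_frame_table",
    "save_frame_table",
    "save_traces",
    "summarize_snapshot",
    "RunManifest",
]

FRAME_COLUMNS = ["lineage_id", "frame", "time_min", "length",
                 "mean_fluor", "division"]


def save_frame_table(series_list, path: str | Path, sep: str = "\t") -> None:
    """Write FrameSeries objects as one long-format delimited table."""
    rows = []
    for k, fs in enumerate(series_list):
        lid = fs.lineage_id if fs.lineage_id is not None else k
        for i in range(len(fs)):
            rows.append((lid, i, fs.t[i] * 60.0, fs.l[i], fs.M[i],
                         int(fs.division[i])))
    pd.DataFrame(rows, columns=FRAME_COLUMNS).to_csv(path, sep=sep,
                                                     index=False)


def load_frame_table(path: str | Path, sep: str = "\t") -> list[FrameSeries]:
    """Read a long-format frame table into per-lineage FrameSeries.

    Validates the schema and the uniform frame spacing; a non-uniform
    lineage raises an error naming the offending frames.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for lid, sub in df.groupby("lineage_id", sort=True):
        sub = sub.sort_values("frame")
        t_min = sub["time_min"].to_numpy(dtype=float)
        if len(t_min) >= 2:
            steps = np.diff(t_min)
            bad = np.flatnonzero(~np.isclose(steps, steps[0], rtol=1e-6))
            if len(bad):
                frames = sub["frame"].to_numpy()[bad + 1][:5]
                raise ValueError(
                    f"{path}: lineage {lid} has non-uniform spacing at "
                    f"frame(s) {frames.tolist()}")
        out.append(FrameSeries(t=t_min / 60.0,
                               l=sub["length"].to_numpy(dtype=float),
                               M=sub["mean_fluor"].to_numpy(dtype=float),
                               division=sub["division"].to_numpy(),
                               lineage_id=lid))
    return out


def save_traces(traces, path: str | Path, sep: str = "\t") -> None:
    """Write simulated lineage traces as one long-format table."""
    frames = [tr.to_frame(lineage_id=i) for i, tr in enumerate(traces)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def summarize_snapshot(values, bins: int | str = "auto"):
    """Mean, coefficient of variation and histogram of per-cell values.

    CV uses the sample standard deviation (n-1 denominator).  Returns
    (mean, cv, (counts, bin_edges)).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    mean = float(values.mean())
    cv = float(values.std(ddof=1) / mean) if mean != 0 else float("inf")
    counts, edges = np.histogram(values, bins=bins)
    return mean, cv, (counts, edges)


class RunManifest:
    """Reproducibility record of one CLI run."""

    def __init__(self, command: str, config: dict, seed: int | None):
        from . import __version__

        self.data = {
            "command": command,
            "config": config,
            "seed": seed,
            "rpospulse_version": __version__,
            "inputs": {},
            "outputs": {},
        }

    @staticmethod
    def _digest(path: str | Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    def add_input(self, path: str | Path) -> None:
        self.data["inputs"][str(path)] = self._digest(path)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"][str(path)] = self._digest(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
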