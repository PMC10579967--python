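"""Trace containers and delimited-text readers/writers.

A :class:`TraceMatrix` holds cells x timepoints fluorescence (or molecule
counts) on a shared hourly grid with at least two pre-stimulus frames — the
common currency of simulation, fitting, and feature extraction.  On disk it
is a CSV (first column ``cell_id``, remaining column names the timepoints in
hours) plus a small JSON sidecar with the stimulus metadata, mirroring how
time-lapse quantification tables are exported from imaging pipelines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["TraceMatrix", "read_traces", "write_traces"]


@dataclass
class TraceMatrix:
    """Cells x timepoints trace table with its time grid and stimulus metadata.

    ``time`` is strictly increasing, in hours, with time 0 at stimulus onset
    and >= 2 pre-stimulus points expected by the feature extractors.
    ``stimulus_onsets`` lists the onset time of each stimulation pulse.
    """

    time: np.ndarray
    values: np.ndarray
    stimulus_onsets: list[float] = field(default_factory=lambda: [0.0])
    metadata: dict = field(default_factory=dict)
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.values.shape[1] != self.time.size:
            raise ValueError(
                f"values has {self.values.shape[1]} columns but time has {self.time.size} points"
            )
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:04d}" for i in range(self.values.shape[0])]
        elif len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.time.size

    def mean_trace(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def sd_trace(self, ddof: int = 1) -> np.ndarray:
        return self.values.std(axis=0, ddof=ddof)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{t:g}" for t in self.time])
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def subset(self, idx) -> "TraceMatrix":
        idx = np.asarray(idx)
        return TraceMatrix(
            time=self.time,
            values=self.values[idx],
            stimulus_onsets=list(self.stimulus_onsets),
            metadata=dict(self.metadata),
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(idx)],
        )

    def drop_incomplete(self) -> "TraceMatrix":
        """Drop traces with any missing value, logging how many were removed
        (only complete trajectories are analysed)."""
        keep = ~np.isnan(self.values).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            log.info("dropped %d incomplete traces of %d", dropped, self.n_cells)
        return self.subset(np.flatnonzero(keep))


def write_traces(tm: TraceMatrix, path) -> None:
    """Write a TraceMatrix to ``path`` (CSV) and ``path + '.meta.json'``."""
    path = Path(path)
    tm.to_frame().to_csv(path, index=False)
    meta = {
        "stimulus_onsets": list(map(float, tm.stimulus_onsets)),
        "metadata": tm.metadata,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_traces(path, drop_incomplete: bool = True) -> TraceMatrix:
    """Read a TraceMatrix written by :func:`write_traces`.

    Raises ``ValueError`` naming the offending line for ragged rows or a
    non-monotone time header; incomplete traces are dropped with a logged
    count unless ``drop_incomplete`` is False.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[0] != "cell_id":
            raise ValueError(f"{path}: first column must be 'cell_id', got {header[0]!r}")
        try:
            time = np.array([float(c) for c in header[1:]])
        except ValueError as e:
            raise ValueError(f"{path}: malformed time header: {e}") from None
        if time.size < 2 or np.any(np.diff(time) <= 0):
            raise ValueError(f"{path}: time header must be strictly increasing")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            ids.append(parts[0])
            rows.append([float(x) if x != "" else np.nan for x in parts[1:]])
    values = np.asarray(rows, dtype=float)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    onsets = [0.0]
    metadata: dict = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        onsets = meta.get("stimulus_onsets", onsets)
        metadata = meta.get("metadata", {})
    tm = TraceMatrix(time=time, values=values, stimulus_onsets=onsets, metadata=metadata, cell_ids=ids)
    return tm.drop_incomplete() if drop_incomplete else tm
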