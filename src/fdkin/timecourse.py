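"""Time-course container and the plain-table CSV dialect.

CSV columns: ``time_s, signal, cycle, phase, conc_M`` (cycle/phase/conc are
optional annotations; phase is ``association`` or ``dissociation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd


@dataclass
class TimeCourse:
    """An annotated signal time series (one phase of one assay)."""

    times: np.ndarray
    signal: np.ndarray
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def conc(self) -> Optional[float]:
        return self.metadata.get("conc_M")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times, "signal": self.signal})
        for col in ("cycle", "phase", "conc_M"):
            if col in self.metadata:
                df[col] = self.metadata[col]
        return df


def write_timecourses(courses: List[TimeCourse], path: str | Path) -> None:
    frames = [tc.to_frame() for tc in courses]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timecourses(path: str | Path) -> List[TimeCourse]:
    """Read the CSV dialect back into one TimeCourse per (cycle, conc) group."""
    df = pd.read_csv(path)
    if "time_s" not in df or "signal" not in df:
        raise ValueError("CSV must contain columns time_s and signal")
    keys = [c for c in ("cycle", "conc_M", "phase") if c in df.columns]
    if not keys:
        return [TimeCourse(df["time_s"].to_numpy(), df["signal"].to_numpy())]
    out: List[TimeCourse] = []
    for vals, g in df.groupby(keys, sort=False):
        if not isinstance(vals, tuple):
            vals = (vals,)
        meta = dict(zip(keys, vals))
        tc = TimeCourse(
            g["time_s"].to_numpy(), g["signal"].to_numpy(),
            t0=float(g["time_s"].iloc[0]), metadata=meta,
        )
        out.append(tc)
    return out
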