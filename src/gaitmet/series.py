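"""Timestamped energy-expenditure series — the common currency of all metrics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError

#: provenance labels an EE series may carry
SOURCES = ("stride_model", "standing_heuristic", "breath", "interpolated",
           "baseline", "truth")


@dataclass
class EESeries:
    """Instantaneous energy expenditure in Watts at (possibly irregular) times.

    ``source`` labels where each value came from: the per-stride model, the
    quiet-standing heuristic, breath-by-breath respirometry, speed interpolation,
    a baseline estimator, or generator ground truth.
    """

    times: np.ndarray
    values: np.ndarray
    source: np.ndarray | str = "truth"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DataError("times and values must have the same shape")
        if isinstance(self.source, str):
            self.source = np.full(self.times.shape, self.source, dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
        if self.times.size >= 2 and np.any(np.diff(self.times) < 0):
            raise DataError("EESeries times must be non-decreasing")
        if np.any(self.values <= 0):
            raise DataError("EESeries values must be positive Watts")

    def __len__(self) -> int:
        return int(self.times.size)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation onto arbitrary times (clamped at the ends)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)

    def window(self, t_start: float, t_end: float) -> "EESeries":
        m = (self.times >= t_start) & (self.times <= t_end)
        return EESeries(self.times[m], self.values[m], self.source[m])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "watts": self.values,
                      "source": self.source}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EESeries":
        df = pd.read_csv(path)
        src = df["source"].to_numpy(object) if "source" in df else "truth"
        return cls(df["time"].to_numpy(float), df["watts"].to_numpy(float), src)


def concat_series(parts: list[EESeries]) -> EESeries:
    """Merge series, sorted by time (stable for coincident stamps)."""
    if not parts:
        return EESeries(np.empty(0), np.empty(0), np.empty(0, dtype=object))
    times = np.concatenate([p.times for p in parts])
    values = np.concatenate([p.values for p in parts])
    source = np.concatenate([p.source for p in parts])
    order = np.argsort(times, kind="stable")
    return EESeries(times[order], values[order], source[order])
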