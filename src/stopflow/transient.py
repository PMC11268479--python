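"""The ``Transient`` container: one absorbance-vs-time trace plus metadata.

A transient is the unit of all fitting.  Metadata is a free-form dict; the
synthetic generator records the true underlying parameters there so that
recovery pipelines can score themselves against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Transient"]


@dataclass
class Transient:
    """An absorbance trace A(t) with experiment metadata.

    ``time`` is in seconds (strictly increasing), ``absorbance`` in AU.
    """

    time: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must be 1-d arrays of equal length")
        if self.time.size == 0:
            raise ValueError("transient is empty")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "Transient":
        """Return the sub-transient with t_min <= t <= t_max."""
        mask = (self.time >= t_min) & (self.time <= t_max)
        if not mask.any():
            raise ValueError(f"no data points in window [{t_min}, {t_max}] s")
        return Transient(self.time[mask], self.absorbance[mask], dict(self.meta))

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write two columns ``time_s,absorbance_au`` (no comment lines)."""
        df = pd.DataFrame({"time_s": self.time, "absorbance_au": self.absorbance})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "Transient":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["time_s"].to_numpy(), df["absorbance_au"].to_numpy(), meta or {})
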