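"""Kinetic time series (plate-reader style OD traces) shared by the
growth and phenotype-microarray modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KineticSeries", "logistic"]


@dataclass(frozen=True)
class KineticSeries:
    """A single well's kinetic trace: OD versus time.

    ``time_min`` must be strictly increasing with at least two readings.
    """

    time_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("time_min and values must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a kinetic series needs at least two readings")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.time_min.size)


def logistic(t, baseline: float, amplitude: float, rate: float, midpoint: float):
    """Logistic growth/respiration curve.

    ``baseline + amplitude / (1 + exp(-rate * (t - midpoint)))``; the
    maximum slope is ``amplitude * rate / 4``, attained at ``midpoint``.
    """
    t = np.asarray(t, dtype=float)
    return baseline + amplitude / (1.0 + np.exp(-rate * (t - midpoint)))
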