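"""Replicon metadata and circular coordinate arithmetic.

All genomic coordinates in this package are 0-based with half-open
windows ``[start, end)``.  Circular replicons wrap modulo their length;
signed origin-centred offsets live in ``(-L/2, L/2]`` with the antipode
mapped to ``+L/2`` by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Replicon", "tile_windows", "signed_offset", "circular_distance"]


@dataclass(frozen=True)
class Replicon:
    """A chromosome (or plasmid) on which windows and positions live.

    Parameters
    ----------
    name : str
        Sequence name as it appears in bedGraph / annotation files.
    length_bp : int
        Replicon length in base pairs (> 0).
    circular : bool
        Bacterial chromosomes are circular; linear replicons are allowed
        but their replication origin must sit at one end for the dosage
        model to apply.
    ori_bp : int, optional
        Annotated replication origin.  Reduced modulo ``length_bp`` for
        circular replicons.  May be left unset and estimated from data.
    ter_bp : int, optional
        Replication terminus.  When unset it is derived as the point
        antipodal to ``ori_bp`` (equal fork speeds on both arms).
    """

    name: str
    length_bp: int
    circular: bool = True
    ori_bp: int | None = None
    ter_bp: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"replicon {self.name!r}: length_bp must be > 0")
        if self.ori_bp is not None:
            ori = int(self.ori_bp)
            if self.circular:
                ori %= self.length_bp
            elif not 0 <= ori <= self.length_bp:
                raise ValueError(
                    f"replicon {self.name!r}: ori_bp outside [0, length_bp]"
                )
            object.__setattr__(self, "ori_bp", ori)
        if self.ter_bp is not None:
            ter = int(self.ter_bp)
            if self.circular:
                ter %= self.length_bp
            object.__setattr__(self, "ter_bp", ter)

    @property
    def ter(self) -> int:
        """Terminus position, antipodal to the origin when not annotated."""
        if self.ter_bp is not None:
            return self.ter_bp
        if self.ori_bp is None:
            raise ValueError(f"replicon {self.name!r}: neither ter_bp nor ori_bp set")
        if self.circular:
            return (self.ori_bp + self.length_bp // 2) % self.length_bp
        # linear: the far end from the origin
        return self.length_bp if self.ori_bp < self.length_bp // 2 else 0

    def arm_lengths(self) -> tuple[float, float]:
        """(left, right) arm lengths in bp, right = ori -> ter clockwise."""
        if self.ori_bp is None:
            raise ValueError(f"replicon {self.name!r}: ori_bp not set")
        if self.circular:
            right = (self.ter - self.ori_bp) % self.length_bp
            if right == 0:
                raise ValueError(f"replicon {self.name!r}: ter coincides with ori")
            return float(self.length_bp - right), float(right)
        if self.ori_bp not in (0, self.length_bp):
            raise ValueError(
                f"replicon {self.name!r}: linear replicon needs ori at an end"
            )
        return 0.0, float(self.length_bp)

    def signed_offset(self, pos, origin: int | None = None) -> np.ndarray:
        """Signed offset of ``pos`` from the origin, in ``(-L/2, L/2]``."""
        ori = self.ori_bp if origin is None else origin
        if ori is None:
            raise ValueError(f"replicon {self.name!r}: ori_bp not set")
        return signed_offset(np.asarray(pos), ori, self.length_bp, self.circular)


def signed_offset(pos: np.ndarray, origin: float, length: int, circular: bool = True) -> np.ndarray:
    """Map positions to signed offsets from ``origin`` in ``(-L/2, L/2]``."""
    if not circular:
        return np.asarray(pos, dtype=float) - origin
    d = np.mod(np.asarray(pos, dtype=float) - origin, length)
    return np.where(d > length / 2, d - length, d)


def circular_distance(a, b, length: int) -> np.ndarray:
    """Shortest distance between positions on a circle of size ``length``."""
    d = np.mod(np.asarray(a, dtype=float) - b, length)
    return np.minimum(d, length - d)


def tile_windows(length_bp: int, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Tile ``[0, length_bp)`` with half-open windows of ``window_bp``.

    The trailing window is kept even when partial (its end is clipped to
    the replicon length); callers flag it downstream.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    starts = np.arange(0, length_bp, window_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length_bp)
    return starts, ends
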