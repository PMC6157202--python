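"""Multidistance Signal Level Difference (MSLD) transform.

MSLD is a one-dimensional adaptation of the gray-level difference texture
statistic: at distance ``d`` the transformed signal is

    y_d(i) = |x(i) - x(i + d)|,   i = 1 .. N - d,

for d = 1..K. Unlike the coarse-graining step of multiscale entropy, the
transform does not average the signal, so its variance does not shrink as
the distance grows; each level keeps the full sampling resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Signal


@dataclass
class DiffSignal:
    """MSLD output at one distance: non-negative values of length N - d."""

    values: np.ndarray
    distance: int
    source_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.source_length - self.distance:
            raise ValueError(
                f"DiffSignal length {self.values.size} != "
                f"{self.source_length} - {self.distance}"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("DiffSignal values must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class MSLDSet:
    """MSLD levels for a contiguous distance range d_min..d_max."""

    diffs: dict[int, DiffSignal]
    d_min: int
    d_max: int

    def __post_init__(self) -> None:
        expected = list(range(self.d_min, self.d_max + 1))
        if sorted(self.diffs) != expected:
            raise ValueError(
                f"MSLDSet keys {sorted(self.diffs)} are not contiguous "
                f"{self.d_min}..{self.d_max}"
            )
        lengths = {d.source_length for d in self.diffs.values()}
        if len(lengths) > 1:
            raise ValueError("all DiffSignals must share one source length")

    def __getitem__(self, d: int) -> DiffSignal:
        return self.diffs[d]

    def __iter__(self):
        return iter(range(self.d_min, self.d_max + 1))


def _as_array(signal) -> np.ndarray:
    if isinstance(signal, Signal):
        return signal.samples
    return np.asarray(signal, dtype=float)


def msld_transform(signal: Signal | np.ndarray, d: int) -> DiffSignal:
    """Absolute level difference at distance *d*.

    The distance must satisfy ``1 <= d <= N - 2`` so the result keeps at
    least two samples (the minimum any downstream entropy estimate needs).
    """
    x = _as_array(signal)
    n = x.size
    if not 1 <= d <= n - 2:
        raise ValueError(
            f"distance d={d} outside admissible range 1..{n - 2} "
            f"for a signal of length {n}"
        )
    values = np.abs(x[:-d] - x[d:])
    return DiffSignal(values=values, distance=int(d), source_length=n)


def msld_set(signal: Signal | np.ndarray, d_min: int, d_max: int) -> MSLDSet:
    """MSLD levels for every distance in ``d_min..d_max``."""
    x = _as_array(signal)
    n = x.size
    if not 1 <= d_min <= d_max <= n - 2:
        raise ValueError(
            f"distance range {d_min}..{d_max} invalid for signal of length {n} "
            f"(need 1 <= d_min <= d_max <= {n - 2})"
        )
    diffs = {d: msld_transform(x, d) for d in range(d_min, d_max + 1)}
    return MSLDSet(diffs=diffs, d_min=int(d_min), d_max=int(d_max))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Window-average a series at the given scale (multiscale-entropy style).

    Provided for comparison with MSLD: coarse-graining shrinks the variance
    of a white series roughly as 1/scale, whereas the MSLD transform does
    not reduce variance with distance.
    """
    x = np.asarray(x, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n = x.size // scale
    if n == 0:
        raise ValueError("series shorter than one window")
    return x[: n * scale].reshape(n, scale).mean(axis=1)
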