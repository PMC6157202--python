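"""Sample entropy (SampEn) estimation.

SampEn(m, r, N) = -ln(A / B), where B counts pairs of length-``m``
templates whose Chebyshev (max-norm) distance is within the tolerance, A
counts the same pairs extended to length ``m + 1``, and self-matches are
excluded. Both counts run over the same template range i = 1..N-m (the
Richman-Moorman convention), so A <= B always and SampEn >= 0 whenever it
is defined.

The optimized path counts matching pairs with a k-d tree under the
max-norm; :func:`sample_entropy_bruteforce` is a deliberately naive
triple-loop twin used to pin the optimized path in tests. Both return the
same integer match counts, hence bit-identical entropy values.

When no pairs match at length m (B = 0) or none extend to m + 1 (A = 0)
the estimate is undefined; these functions return ``None`` and leave any
finite substitution to the caller (see :func:`undefined_ceiling`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

ToleranceMode = Literal["relative_sd", "absolute"]

#: Guard for the brute-force twin: it is O(N^2 m) with Python-level loops.
BRUTEFORCE_MAX_LENGTH = 2000


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters.

    m:
        Embedding (template) length, >= 1. Default 2, the standard
        Richman-Moorman choice for physiological series.
    r:
        Tolerance. In ``relative_sd`` mode it is a fraction of the
        population standard deviation of the analysed series (the usual
        convention for the 0.1-0.25 range); in ``absolute`` mode it is
        used as-is, in signal units.
    """

    m: int = 2
    r: float = 0.25
    tolerance_mode: ToleranceMode = "relative_sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"tolerance r must be positive, got {self.r}")
        if self.tolerance_mode not in ("relative_sd", "absolute"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")


@dataclass(frozen=True)
class MatchCounts:
    """Template-match pair counts over unordered distinct pairs."""

    b_pairs: int
    a_pairs: int
    n_templates: int

    def __post_init__(self) -> None:
        if not 0 <= self.a_pairs <= self.b_pairs:
            raise ValueError(
                f"need 0 <= a_pairs <= b_pairs, got a={self.a_pairs} b={self.b_pairs}"
            )


def _validate_series(series, m: int) -> np.ndarray:
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < m + 2:
        raise ValueError(
            f"series of length {x.size} too short for m={m} (need >= {m + 2})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def count_template_matches(
    series: Sequence[float] | np.ndarray, m: int, tol: float
) -> MatchCounts:
    """Count template pairs matching within *tol* at lengths m and m + 1.

    Templates of both lengths are taken over i = 1..N-m so the two counts
    are directly comparable. A pair (i, j), i != j, matches at length L iff
    ``max_k |x(i+k) - x(j+k)| <= tol`` for k = 0..L-1 (inclusive Chebyshev
    match). Counts are over unordered distinct pairs; self-matches are
    never counted.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not tol > 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    x = _validate_series(series, m)
    n_templates = x.size - m
    templates_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    # Pairs matching at length m; extend each by its next sample for m+1.
    tree = cKDTree(templates_m)
    pairs = tree.query_pairs(tol, p=np.inf, output_type="ndarray")
    b_pairs = int(pairs.shape[0])
    if b_pairs:
        ext = np.abs(x[pairs[:, 0] + m] - x[pairs[:, 1] + m]) <= tol
        a_pairs = int(np.count_nonzero(ext))
    else:
        a_pairs = 0
    return MatchCounts(b_pairs=b_pairs, a_pairs=a_pairs, n_templates=n_templates)


def count_template_matches_bruteforce(
    series: Sequence[float] | np.ndarray, m: int, tol: float
) -> MatchCounts:
    """Exhaustive enumeration of all template pairs (verification twin)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not tol > 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    x = _validate_series(series, m)
    if x.size > BRUTEFORCE_MAX_LENGTH:
        raise ValueError(
            f"brute-force counting refuses series longer than "
            f"{BRUTEFORCE_MAX_LENGTH} (got {x.size})"
        )
    n_templates = x.size - m
    data = x.tolist()
    a_pairs = 0
    b_pairs = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(data[i + k] - data[j + k]) > tol:
                    match = False
                    break
            if match:
                b_pairs += 1
                if abs(data[i + m] - data[j + m]) <= tol:
                    a_pairs += 1
    return MatchCounts(b_pairs=b_pairs, a_pairs=a_pairs, n_templates=n_templates)


def _resolve_tolerance(x: np.ndarray, params: SampEnParams) -> float:
    if params.tolerance_mode == "absolute":
        return params.r
    sd = float(np.std(x))  # population SD
    if sd == 0.0:
        raise ValueError("relative_sd tolerance undefined for a constant series")
    return params.r * sd


def _entropy_from_counts(counts: MatchCounts) -> Optional[float]:
    if counts.b_pairs == 0 or counts.a_pairs == 0:
        return None
    return -math.log(counts.a_pairs / counts.b_pairs)


def sample_entropy(
    series: Sequence[float] | np.ndarray, params: SampEnParams = SampEnParams()
) -> Optional[float]:
    """Sample entropy of a series; ``None`` when the estimate is undefined.

    A constant series is perfectly regular and returns 0 (the limit in
    which every pair matches at every length) before any SD scaling is
    attempted, so relative tolerances are well defined for it too.
    """
    x = _validate_series(series, params.m)
    if np.all(x == x[0]):
        return 0.0
    tol = _resolve_tolerance(x, params)
    return _entropy_from_counts(count_template_matches(x, params.m, tol))


def sample_entropy_bruteforce(
    series: Sequence[float] | np.ndarray, params: SampEnParams = SampEnParams()
) -> Optional[float]:
    """Brute-force twin of :func:`sample_entropy` (identical contract)."""
    x = _validate_series(series, params.m)
    if np.all(x == x[0]):
        return 0.0
    tol = _resolve_tolerance(x, params)
    return _entropy_from_counts(count_template_matches_bruteforce(x, params.m, tol))


def undefined_ceiling(n: int, m: int) -> float:
    """Finite stand-in for an undefined SampEn on a length-*n* series.

    With N - m templates there are (N-m)(N-m-1)/2 distinct pairs, so the
    largest finite estimate is -ln(1 / #pairs) = ln((N-m)(N-m-1)/2),
    reached when exactly one pair matches at length m and also at m + 1.
    Substituting it preserves the "maximally irregular" ordering while
    keeping downstream feature vectors finite.
    """
    n_templates = n - m
    if n_templates < 2:
        raise ValueError(f"no template pairs for n={n}, m={m}")
    return math.log(n_templates * (n_templates - 1) / 2)
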