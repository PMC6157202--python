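"""MSLD-SampEn feature extraction.

The feature vector of a record is the sample entropy of each of its MSLD
levels: one value per distance d = d_min..d_max. With the default grid
(d = 1..20, m = 2, r = 0.25 of each level's own SD) a 4096-sample record
yields 20 features. Entropy is computed on each level independently, so a
wide table can be column-sliced to any narrower contiguous range without
recomputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .msld import msld_transform
from .sampen import SampEnParams, sample_entropy, undefined_ceiling
from .signal_io import LabeledSignalSet, Signal

logger = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """Per-record MSLD-SampEn features, indexed by distance."""

    record_id: str
    label: Optional[str]
    values: np.ndarray
    d_min: int
    d_max: int
    params: Optional[SampEnParams] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        width = self.d_max - self.d_min + 1
        if self.values.size != width:
            raise ValueError(
                f"{self.record_id}: {self.values.size} values for range "
                f"{self.d_min}..{self.d_max} (expected {width})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.record_id}: non-finite feature values")

    def value_at(self, d: int) -> float:
        if not self.d_min <= d <= self.d_max:
            raise KeyError(f"distance {d} outside {self.d_min}..{self.d_max}")
        return float(self.values[d - self.d_min])


@dataclass
class FeatureTable:
    """Rectangular table of feature vectors sharing one distance range."""

    rows: list[FeatureVector]
    class_names: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("feature table must have at least one row")
        first = self.rows[0]
        for row in self.rows:
            if (row.d_min, row.d_max) != (first.d_min, first.d_max):
                raise ValueError("all rows must share the same distance range")
        if self.class_names is None:
            seen: list[str] = []
            for row in self.rows:
                if row.label is not None and row.label not in seen:
                    seen.append(row.label)
            self.class_names = seen
        labels = {r.label for r in self.rows} - {None}
        missing = labels - set(self.class_names)
        if missing:
            raise ValueError(f"row labels {sorted(missing)} not in class_names")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def d_min(self) -> int:
        return self.rows[0].d_min

    @property
    def d_max(self) -> int:
        return self.rows[0].d_max

    @property
    def params(self) -> Optional[SampEnParams]:
        return self.rows[0].params

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix (n_records x n_distances) and label array."""
        X = np.vstack([r.values for r in self.rows])
        y = np.array([r.label for r in self.rows], dtype=object)
        return X, y

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"sampen_d{d}" for d in range(self.d_min, self.d_max + 1)]
        X, y = self.to_arrays()
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "label", y)
        df.insert(0, "record_id", [r.record_id for r in self.rows])
        return df

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        if len(self) != len(other) or (self.d_min, self.d_max) != (
            other.d_min,
            other.d_max,
        ):
            return False
        for a, b in zip(self.rows, other.rows):
            if a.record_id != b.record_id or a.label != b.label:
                return False
            if not np.array_equal(a.values, b.values):
                return False
        return True


def extract_features(
    signal: Signal | np.ndarray,
    d_min: int = 1,
    d_max: int = 20,
    params: SampEnParams = SampEnParams(),
) -> FeatureVector:
    """MSLD-SampEn features of one record.

    For each distance d the record is transformed to its MSLD level and
    the level's sample entropy is computed with the level's own tolerance.
    Undefined entropies (no matching template pairs) are substituted by the
    finite ceiling ln((N_d - m)(N_d - m - 1)/2), where N_d is the level
    length, so the vector is always finite.
    """
    if isinstance(signal, Signal):
        record_id, label, x = signal.record_id, signal.label, signal.samples
    else:
        record_id, label, x = "", None, np.asarray(signal, dtype=float)
    n = x.size
    if d_max > n - params.m - 2:
        raise ValueError(
            f"d_max={d_max} too large for a length-{n} signal with m={params.m} "
            f"(need d_max <= {n - params.m - 2})"
        )
    values = np.empty(d_max - d_min + 1)
    n_substituted = 0
    for d in range(d_min, d_max + 1):
        level = msld_transform(x, d)
        ent = sample_entropy(level.values, params)
        if ent is None:
            ent = undefined_ceiling(len(level), params.m)
            n_substituted += 1
        values[d - d_min] = ent
    if n_substituted:
        logger.info(
            "record %s: %d undefined SampEn value(s) replaced by ceiling",
            record_id,
            n_substituted,
        )
    return FeatureVector(
        record_id=record_id,
        label=label,
        values=values,
        d_min=d_min,
        d_max=d_max,
        params=params,
    )


def extract_feature_table(
    signal_set: LabeledSignalSet,
    d_min: int = 1,
    d_max: int = 20,
    params: SampEnParams = SampEnParams(),
) -> FeatureTable:
    """Feature table for a labelled collection, one row per record."""
    if len(signal_set) == 0:
        raise ValueError("empty signal set")
    rows = []
    for i, signal in enumerate(signal_set.signals):
        try:
            rows.append(extract_features(signal, d_min, d_max, params))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed on record {signal.record_id!r}: {exc}"
            ) from exc
        logger.debug("extracted %d/%d records", i + 1, len(signal_set))
    return FeatureTable(rows, class_names=list(signal_set.class_names))


def restrict_scales(table: FeatureTable, d_min: int, d_max: int) -> FeatureTable:
    """Column-slice a table to a narrower contiguous distance range.

    Because each distance's entropy is computed independently, slicing a
    wide table is identical to re-extracting at the narrower range.
    """
    if not (table.d_min <= d_min <= d_max <= table.d_max):
        raise ValueError(
            f"range {d_min}..{d_max} not contained in table range "
            f"{table.d_min}..{table.d_max}"
        )
    lo = d_min - table.d_min
    hi = d_max - table.d_min + 1
    rows = [
        FeatureVector(
            record_id=r.record_id,
            label=r.label,
            values=r.values[lo:hi].copy(),
            d_min=d_min,
            d_max=d_max,
            params=r.params,
        )
        for r in table.rows
    ]
    return FeatureTable(rows, class_names=list(table.class_names))


def class_mean_curves(table: FeatureTable) -> pd.DataFrame:
    """Mean feature value per class and distance (rows = distance d)."""
    df = table.to_dataframe()
    cols = [f"sampen_d{d}" for d in range(table.d_min, table.d_max + 1)]
    means = df.groupby("label")[cols].mean().T
    means.index = pd.Index(range(table.d_min, table.d_max + 1), name="d")
    return means
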