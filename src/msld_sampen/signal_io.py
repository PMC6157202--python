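"""Reading and writing single-channel EEG records and feature tables.

Records follow the plain-ASCII dialect used by the Bonn epilepsy archive:
one amplitude sample per line, 4096 samples per record, sampled at
173.61 Hz. Class labels (ictal / interictal / normal) are never encoded in
the file contents; they come from a manifest mapping labels to file paths,
or from a directory-per-class layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_FS = 173.61
"""Sampling frequency (Hz) of the Bonn epilepsy records."""


class SignalIOError(Exception):
    """Raised for unreadable, unparsable or degenerate signal files."""


@dataclass
class Signal:
    """A single-channel recording: an ordered series of real amplitudes.

    Parameters
    ----------
    samples:
        Amplitudes in microvolt (arbitrary offset). At least two samples,
        all finite.
    fs:
        Sampling frequency in Hz. Metadata only: no transform here depends
        on it beyond reporting the record duration.
    record_id:
        Opaque identifier, typically derived from the file name.
    label:
        Optional class tag, e.g. ``"ictal"``, ``"interictal"``, ``"normal"``
        or a synthetic class name.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    record_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError(
                f"signal {self.record_id!r} has {self.samples.size} samples; need >= 2"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.record_id!r} contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs


@dataclass
class LabeledSignalSet:
    """A collection of labelled signals with an ordered list of class names."""

    signals: list[Signal]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            seen: list[str] = []
            for s in self.signals:
                if s.label is not None and s.label not in seen:
                    seen.append(s.label)
            self.class_names = seen
        labels = {s.label for s in self.signals}
        missing = labels - set(self.class_names) - {None}
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in class_names")

    def __len__(self) -> int:
        return len(self.signals)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for s in self.signals:
            if s.label is not None:
                counts[s.label] += 1
        return counts

    def validate_for_classification(self) -> None:
        """Require >= 2 non-empty classes."""
        counts = self.class_counts()
        nonempty = [c for c, n in counts.items() if n > 0]
        if len(nonempty) < 2:
            raise ValueError(
                f"classification needs >= 2 non-empty classes, got {counts}"
            )


def read_signal(
    path: str | Path,
    fs: float = DEFAULT_FS,
    label: Optional[str] = None,
) -> Signal:
    """Read one Bonn-dialect ASCII record: one sample per line.

    Blank lines are ignored; integer and decimal literals are both
    accepted. The record id is the file stem.
    """
    path = Path(path)
    if not path.is_file():
        raise SignalIOError(f"no such signal file: {path}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise SignalIOError(
                    f"{path}: line {lineno}: not a number: {text!r}"
                ) from None
    if len(values) < 2:
        raise SignalIOError(f"{path}: degenerate signal ({len(values)} samples)")
    return Signal(np.array(values), fs=fs, record_id=path.stem, label=label)


def read_labeled_set(
    manifest: Mapping[str, Sequence[str | Path]],
    fs: float = DEFAULT_FS,
) -> LabeledSignalSet:
    """Read a labelled collection from a ``label -> [paths]`` manifest.

    Class names keep first-appearance (manifest) order; signals keep
    manifest order within and across classes. Any unreadable file aborts
    the read, naming the offending path.
    """
    class_names: list[str] = []
    signals: list[Signal] = []
    for label, paths in manifest.items():
        if not label:
            raise ValueError("empty class label in manifest")
        if len(paths) == 0:
            raise ValueError(f"class {label!r} has no files")
        class_names.append(label)
        for p in paths:
            signals.append(read_signal(p, fs=fs, label=label))
    return LabeledSignalSet(signals, class_names)


def read_manifest(path: str | Path) -> dict[str, list[Path]]:
    """Load a JSON manifest (label -> list of file paths, relative to it)."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    base = path.parent
    return {label: [base / p for p in paths] for label, paths in raw.items()}


def scan_class_directories(root: str | Path) -> dict[str, list[Path]]:
    """Build a manifest from a directory-per-class layout.

    Each immediate subdirectory of *root* is a class; its ``*.txt`` files
    (sorted by name) are the records.
    """
    root = Path(root)
    manifest: dict[str, list[Path]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(sub.glob("*.txt"))
        if files:
            manifest[sub.name] = files
    if not manifest:
        raise SignalIOError(f"no class directories with .txt records under {root}")
    return manifest


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write a record in the Bonn ASCII dialect (one sample per line)."""
    with open(path, "w") as fh:
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


def write_feature_table(table, path: str | Path) -> None:
    """Write a feature table as RFC-4180 CSV.

    Columns: ``record_id,label,sampen_d{d_min}..sampen_d{d_max}``. Values
    are written with the shortest round-tripping decimal representation so
    the matching reader restores them exactly.
    """
    df = table.to_dataframe()
    if df.shape[0] == 0:
        raise ValueError("refusing to write an empty feature table")
    # shortest round-tripping decimal representation, exact on re-read
    for col in df.columns:
        if col.startswith("sampen_d"):
            df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path, params=None):
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    from .features import FeatureTable, FeatureVector

    df = pd.read_csv(
        path, dtype={"record_id": str, "label": str}, float_precision="round_trip"
    )
    if df.shape[0] == 0:
        raise SignalIOError(f"{path}: empty feature table")
    feat_cols = [c for c in df.columns if c.startswith("sampen_d")]
    if not feat_cols:
        raise SignalIOError(f"{path}: no sampen_d* columns")
    distances = sorted(int(c[len("sampen_d"):]) for c in feat_cols)
    d_min, d_max = distances[0], distances[-1]
    if distances != list(range(d_min, d_max + 1)):
        raise SignalIOError(f"{path}: non-contiguous distance columns {distances}")
    cols = [f"sampen_d{d}" for d in range(d_min, d_max + 1)]
    rows = [
        FeatureVector(
            record_id=str(rec.record_id),
            label=None if pd.isna(rec.label) else str(rec.label),
            values=np.array([getattr(rec, c) for c in cols], dtype=float),
            d_min=d_min,
            d_max=d_max,
            params=params,
        )
        for rec in df.itertuples(index=False)
    ]
    return FeatureTable(rows)
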