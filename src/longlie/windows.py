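"""Sliding-window segmentation and dataset assembly.

Feature streams are cut into fixed-length windows of M frames (default
40 = 4 s at 10 Hz, the span within which a fall completes). Consecutive
windows overlap by a class-specific fraction beta; the stride is
round(M * (1 - beta)). Falls are windowed more densely than ADLs
(beta_fall > beta_adl) so the transient fall dynamics are oversampled.

Each window is a 5 x M feature matrix, flattened feature-major (all M
WHR values, then all M theta1 values, ...) into a 5*M-vector so every
feature's temporal profile stays contiguous in the flat layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import BodySegments, FEATURE_NAMES, features_table
from .pose_io import PoseSequence
from .preprocess import CleaningConfig, clean

log = logging.getLogger(__name__)


@dataclass
class WindowConfig:
    m: int = 40
    beta_fall: float = 0.75
    beta_adl: float = 0.50

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("window length M must be >= 2")
        for beta in (self.beta_fall, self.beta_adl):
            if not 0.0 < beta < 1.0:
                raise ValueError("overlap fraction beta must be in (0, 1)")
            if self.stride(beta) < 1:
                raise ValueError(f"beta={beta} gives stride < 1")

    def stride(self, beta: float) -> int:
        return max(1, round(self.m * (1.0 - beta)))

    def beta_for(self, label: str) -> float:
        return self.beta_fall if label == "fall" else self.beta_adl


@dataclass
class FeatureWindow:
    """One classifier input unit: a finite 5 x M feature matrix."""

    x: np.ndarray  # shape (5, M), rows ordered as FEATURE_NAMES
    label: str
    source: str  # "<sequence id>:<start frame>"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != len(FEATURE_NAMES):
            raise ValueError(f"window must be 5 x M, got {self.x.shape}")
        if not np.isfinite(self.x).all():
            raise ValueError("window contains non-finite features")


def window_count(length: int, m: int, stride: int) -> int:
    """Number of stride-aligned windows of length m in a stream of ``length``."""
    if length < m:
        return 0
    return (length - m) // stride + 1


def segment(features: pd.DataFrame | np.ndarray, m: int = 40,
            beta: float = 0.5, label: str = "unlabeled",
            source: str = "", drop_undefined: bool = True
            ) -> list[FeatureWindow]:
    """Cut a per-frame feature stream into overlapping 5 x m windows.

    ``features`` is frames x 5 (a :func:`features_table` output is
    accepted; its ``frame`` column is ignored). Windows start at
    multiples of the stride. Windows containing any undefined (NaN)
    frame are dropped with a log entry when ``drop_undefined`` is set.
    """
    if isinstance(features, pd.DataFrame):
        arr = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError("feature stream must be frames x 5")
    length = arr.shape[0]
    if length < m:
        warnings.warn(f"stream of {length} frames shorter than window {m}",
                      stacklevel=2)
        return []
    stride = max(1, round(m * (1.0 - beta)))
    out: list[FeatureWindow] = []
    dropped = 0
    for start in range(0, length - m + 1, stride):
        block = arr[start:start + m].T  # 5 x m
        if not np.isfinite(block).all():
            if drop_undefined:
                dropped += 1
                continue
            raise ValueError(f"undefined features in window at {start}")
        out.append(FeatureWindow(block, label, f"{source}:{start}"))
    if dropped:
        log.info("dropped %d window(s) with undefined features from %r",
                 dropped, source)
    return out


def flatten(x: np.ndarray) -> np.ndarray:
    """5 x M -> 5*M vector, feature-major."""
    return np.asarray(x, dtype=float).reshape(-1)


def unflatten(v: np.ndarray, m: int = 40) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    return np.asarray(v, dtype=float).reshape(len(FEATURE_NAMES), m)


def feature_columns(m: int = 40) -> list[str]:
    return [f"f_{i}" for i in range(len(FEATURE_NAMES) * m)]


def build_dataset(sequences: Sequence[PoseSequence],
                  cleaning: CleaningConfig | None = None,
                  windows: WindowConfig | None = None,
                  segments: BodySegments | None = None) -> pd.DataFrame:
    """Clean, featurize and window labeled sequences into a flat table.

    Returns a DataFrame with columns f_0..f_{5M-1}, label, source. Fall
    sequences are windowed with beta_fall, ADL sequences with beta_adl.
    """
    cleaning = cleaning or CleaningConfig()
    windows = windows or WindowConfig()
    rows: list[dict] = []
    for i, seq in enumerate(sequences):
        if seq.label not in {"fall", "adl"}:
            raise ValueError(f"sequence {i} is unlabeled")
        cleaned = clean(seq, cleaning)
        if len(cleaned) == 0:
            continue
        table = features_table(cleaned, segments)
        source = str(seq.metadata.get("id", f"seq{i}"))
        for win in segment(table, windows.m, windows.beta_for(seq.label),
                           seq.label, source):
            row = dict(zip(feature_columns(windows.m), flatten(win.x)))
            row["label"] = win.label
            row["source"] = win.source
            rows.append(row)
    if not rows:
        raise ValueError(
            "no usable windows: all sequences were too short, fully "
            "eliminated by cleaning, or contained undefined features"
        )
    return pd.DataFrame(rows, columns=[*feature_columns(windows.m), "label", "source"])


def write_dataset_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_dataset_csv(path: str | Path, m: int = 40) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = [*feature_columns(m), "label", "source"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: dataset columns do not match the "
                         f"expected f_0..f_{5 * m - 1},label,source layout")
    return df
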