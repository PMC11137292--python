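"""Normalization and epoching of single-channel recordings.

A recording is scaled to [0, 1] against its *whole-recording* extrema and
then cut into fixed-length, non-overlapping epochs. The epoch is the unit
on which one visibility graph — and hence one feature vector — is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Epoch",
    "normalize_recording",
    "segment_epochs",
    "load_recording",
    "epochs_to_frame",
]


@dataclass(frozen=True)
class TimeSeries:
    """A raw or normalized single-channel recording.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units. Must be non-empty and finite.
    sampling_rate : float
        Samples per second; must be positive. Never inferred from data.
    channel_id : str
        Free-text channel label.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Epoch:
    """An N-sample window of a normalized recording (values in [0, 1])."""

    q: np.ndarray
    index: int = 0
    label: int | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size < 2:
            raise ValueError("epoch needs at least 2 samples")
        if q.min() < 0.0 or q.max() > 1.0:
            raise ValueError("epoch values must lie in [0, 1]")
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return self.q.size


def normalize_recording(x: TimeSeries) -> TimeSeries:
    """Scale a recording to [0, 1] against its own min and max.

    A constant recording maps to all zeros rather than raising, so that
    downstream graph construction has a defined (chain-shaped) result.
    """
    s = x.samples
    lo, hi = s.min(), s.max()
    if hi > lo:
        out = (s - lo) / (hi - lo)
    else:
        out = np.zeros_like(s)
    return TimeSeries(out, x.sampling_rate, x.channel_id)


def segment_epochs(
    x: TimeSeries,
    n: int,
    labels: int | None = None,
    per_epoch_normalize: bool = False,
) -> list[Epoch]:
    """Cut a normalized recording into floor(L/n) consecutive epochs.

    A trailing remainder shorter than ``n`` is discarded — padding would
    fabricate visibility edges. ``per_epoch_normalize`` rescales each
    window against its own extrema instead of trusting the recording-level
    normalization; it is off by default.
    """
    if n < 2:
        raise ValueError("epoch length must be at least 2")
    if n > len(x):
        raise ValueError("recording shorter than epoch")
    k = len(x) // n
    epochs = []
    for i in range(k):
        q = x.samples[i * n : (i + 1) * n]
        if per_epoch_normalize:
            lo, hi = q.min(), q.max()
            q = (q - lo) / (hi - lo) if hi > lo else np.zeros_like(q)
        epochs.append(Epoch(q=q, index=i, label=labels))
    return epochs


def load_recording(path, sampling_rate: float, column: int | str | None = None) -> TimeSeries:
    """Read a recording from delimited text (one value per line, or CSV).

    ``column`` selects a CSV column by position or header name; by default
    the first (only) column is used.
    """
    df = pd.read_csv(path, header="infer", sep=None, engine="python")
    if column is None:
        col = df.iloc[:, 0]
        name = str(df.columns[0])
    elif isinstance(column, int):
        col = df.iloc[:, column]
        name = str(df.columns[column])
    else:
        col = df[column]
        name = column
    return TimeSeries(col.to_numpy(dtype=float), sampling_rate, channel_id=name)


def epochs_to_frame(epochs: list[Epoch]) -> pd.DataFrame:
    """Tabulate epochs one per row, with ``epoch_index`` and optional ``label``."""
    if not epochs:
        return pd.DataFrame()
    n = len(epochs[0])
    if any(len(e) != n for e in epochs):
        raise ValueError("epochs have mixed lengths")
    data = pd.DataFrame(
        np.stack([e.q for e in epochs]), columns=[f"s{i+1}" for i in range(n)]
    )
    data.insert(0, "epoch_index", [e.index for e in epochs])
    if any(e.label is not None for e in epochs):
        data["label"] = [e.label for e in epochs]
    return data
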