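"""Activity-epoch extraction from raw actigraphy records.

The stage mirrors the standard recipe for isolating high-activity periods:
the record is smoothed with a 250-sample moving average, thresholded at the
mean of the smoothed signal, and the surviving contiguous runs — read back
from the *raw* record, never the smoothed one — become candidate epochs.
A representative is then selected (the longest run by default) and
z-normalised before any entropy computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, RecordRejectionError
from .records import ActigraphyRecord, MoodState

__all__ = [
    "PreprocessConfig",
    "Epoch",
    "fill_missing",
    "moving_average",
    "extract_activity_epochs",
    "select_representative",
    "znormalize",
    "preprocess_record",
    "write_epochs_csv",
    "read_epochs_csv",
]

#: Records with more than this fraction of missing samples are rejected.
MAX_MISSING_FRACTION = 0.05


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the epoch-extraction stage.

    ``window`` is the moving-average length in samples (250 samples = 125
    min at the 30-s sampling period).  ``epoch_strategy`` selects the
    representative epochs: ``longest`` keeps the single longest run,
    ``all_ge_min`` keeps every run of at least ``min_epoch_len`` samples,
    and ``fixed_length`` truncates the longest run to its first
    ``fixed_length`` samples.  ``threshold_inclusive`` switches the
    above-threshold comparison from strict ``>`` to ``>=``.
    """

    window: int = 250
    min_epoch_len: int = 1000
    epoch_strategy: Literal["longest", "all_ge_min", "fixed_length"] = "longest"
    fixed_length: int = 1000
    threshold_inclusive: bool = False

    def validate(self) -> None:
        if not self.window >= 1:
            raise ParameterError("window must be >= 1")
        if not self.min_epoch_len >= 1:
            raise ParameterError("min_epoch_len must be >= 1")
        if not self.fixed_length >= 1:
            raise ParameterError("fixed_length must be >= 1")
        if self.epoch_strategy not in ("longest", "all_ge_min", "fixed_length"):
            raise ParameterError(f"unknown epoch_strategy {self.epoch_strategy!r}")


@dataclass
class Epoch:
    """A contiguous high-activity sub-series of one record."""

    source_id: str
    state: MoodState
    start_index: int
    values: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        self.state = MoodState(self.state)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.values.size)


def fill_missing(record: ActigraphyRecord,
                 config: PreprocessConfig | None = None) -> ActigraphyRecord:
    """Zero-fill masked samples; reject records missing more than 5 %.

    Zero is the natural fill for activity counts (absence of measured
    movement); it also keeps the filtered signal's mean threshold low so
    the fill never creates spurious activity epochs.
    """
    frac = record.missing_fraction
    if frac > MAX_MISSING_FRACTION:
        raise RecordRejectionError(
            f"record {record.subject_id!r} has {frac:.1%} missing samples "
            f"(limit {MAX_MISSING_FRACTION:.0%})",
            source_id=record.subject_id, fraction=frac)
    if not record.missing_mask.any():
        return record
    filled = record.samples.copy()
    filled[record.missing_mask] = 0.0
    return ActigraphyRecord(record.subject_id, record.state, filled)


def moving_average(values: Iterable[float], window: int) -> np.ndarray:
    """Centred moving average with truncated edge windows.

    Output has the same length as the input.  Position ``i`` averages the
    samples in ``[i - (window-1)//2, i + window//2]`` clipped to the series,
    divided by the number of samples actually available, so a constant
    input maps to itself everywhere including the edges.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ParameterError("moving_average requires a non-empty input")
    if not window >= 1:
        raise ParameterError("window must be >= 1")
    if window == 1:
        return x.copy()
    n = x.size
    half_left = (window - 1) // 2
    half_right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - half_left, 0, n)
    hi = np.clip(np.arange(n) + half_right + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def extract_activity_epochs(record: ActigraphyRecord,
                            config: PreprocessConfig | None = None) -> list[Epoch]:
    """Extract maximal runs where the smoothed signal exceeds its mean.

    The epoch values are taken from the original record at the run's
    indices; runs shorter than ``min_epoch_len`` are discarded.  Raises
    :class:`RecordRejectionError` when no run survives, leaving the record
    unrepresented in the experiment.
    """
    config = config if config is not None else PreprocessConfig()
    config.validate()
    if record.missing_mask.any():
        raise ParameterError("record still carries masked samples; apply fill_missing first")
    filtered = moving_average(record.samples, config.window)
    threshold = float(filtered.mean())
    above = filtered >= threshold if config.threshold_inclusive else filtered > threshold
    epochs = [
        Epoch(record.subject_id, record.state, int(start),
              record.samples[start:stop].copy())
        for start, stop in _runs_above(above)
        if stop - start >= config.min_epoch_len
    ]
    if not epochs:
        raise RecordRejectionError(
            f"record {record.subject_id!r} has no activity run of >= "
            f"{config.min_epoch_len} samples", source_id=record.subject_id)
    return epochs


def select_representative(epochs: list[Epoch],
                          config: PreprocessConfig | None = None) -> list[Epoch]:
    """Apply the configured selection strategy to a record's epochs.

    ``longest`` resolves length ties by earliest start index.
    """
    config = config if config is not None else PreprocessConfig()
    config.validate()
    if not epochs:
        raise ParameterError("select_representative requires at least one epoch")
    if config.epoch_strategy == "all_ge_min":
        return [e for e in epochs if len(e) >= config.min_epoch_len]
    longest = min(epochs, key=lambda e: (-len(e), e.start_index))
    if config.epoch_strategy == "longest":
        return [longest]
    # fixed_length: first fixed_length samples of the longest epoch
    cut = Epoch(longest.source_id, longest.state, longest.start_index,
                longest.values[:config.fixed_length].copy())
    return [cut]


def znormalize(epoch: Epoch) -> Epoch:
    """Rescale to zero mean and unit population standard deviation."""
    if epoch.normalised:
        raise ParameterError("epoch is already normalised")
    if len(epoch) < 2:
        raise ParameterError("znormalize requires at least 2 samples")
    sd = float(np.std(epoch.values))
    if sd == 0.0:
        raise DegenerateInputError("cannot z-normalise a constant epoch")
    values = (epoch.values - float(np.mean(epoch.values))) / sd
    return Epoch(epoch.source_id, epoch.state, epoch.start_index, values,
                 normalised=True)


def preprocess_record(record: ActigraphyRecord,
                      config: PreprocessConfig | None = None) -> list[Epoch]:
    """Full stage: fill missing -> extract runs -> select -> z-normalise."""
    config = config if config is not None else PreprocessConfig()
    filled = fill_missing(record, config)
    epochs = extract_activity_epochs(filled, config)
    chosen = select_representative(epochs, config)
    return [znormalize(e) for e in chosen]


def write_epochs_csv(epochs: list[Epoch], path) -> None:
    """Write epochs as CSV (source_id, state, start_index, position, value)."""
    frames = []
    for ep in epochs:
        frames.append(pd.DataFrame({
            "source_id": ep.source_id,
            "state": ep.state.value,
            "start_index": ep.start_index,
            "position": np.arange(len(ep), dtype=int),
            "value": ep.values,
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["source_id", "state", "start_index", "position", "value"])
    out.to_csv(path, index=False)


def read_epochs_csv(path, normalised: bool = True) -> list[Epoch]:
    """Read the CSV dialect of :func:`write_epochs_csv`; epoch boundaries
    are recovered from the ``position`` column resetting to zero."""
    df = pd.read_csv(path)
    required = {"source_id", "state", "start_index", "position", "value"}
    if not required.issubset(df.columns):
        raise ParameterError(f"epochs CSV must have columns {sorted(required)}")
    epochs: list[Epoch] = []
    starts = np.flatnonzero(df["position"].to_numpy() == 0)
    bounds = list(starts) + [len(df)]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chunk = df.iloc[lo:hi]
        epochs.append(Epoch(
            source_id=str(chunk["source_id"].iloc[0]),
            state=MoodState(chunk["state"].iloc[0]),
            start_index=int(chunk["start_index"].iloc[0]),
            values=chunk["value"].to_numpy(dtype=float),
            normalised=normalised,
        ))
    return epochs
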