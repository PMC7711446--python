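"""Actigraphy record container and its plain-text serialisation.

A record is one subject-state time series of non-negative activity counts,
one count per 30-s epoch, together with a boolean mask flagging invalid
(missing) samples.  Missing samples are represented by the mask only —
never by sentinel values — so that the fill policy remains an explicit,
testable preprocessing decision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["MoodState", "ActigraphyRecord", "write_records_csv", "read_records_csv"]


class MoodState(str, enum.Enum):
    """The three mood states of a bipolar-disorder course."""

    DEP = "dep"  # depression
    MAN = "man"  # mania
    REM = "rem"  # remission

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical iteration order used everywhere counts are reported.
STATE_ORDER: tuple[MoodState, ...] = (MoodState.DEP, MoodState.MAN, MoodState.REM)


@dataclass
class ActigraphyRecord:
    """One subject-state series of 30-s activity counts.

    Parameters
    ----------
    subject_id
        Identifier of the subject; several records may share it (multiple
        episodes per patient).
    state
        Annotated mood state of the segment.
    samples
        Activity counts, one per 30-s epoch, non-negative where unmasked.
    missing_mask
        True where the sample is invalid; values there are undefined for
        downstream use.
    """

    subject_id: str
    state: MoodState
    samples: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.state = MoodState(self.state)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.samples.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.samples.shape:
            raise ParameterError("missing_mask must match samples in length")
        valid = self.samples[~self.missing_mask]
        if valid.size and (np.min(valid) < 0 or not np.all(np.isfinite(valid))):
            raise ParameterError("unmasked activity counts must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing_mask)) if self.samples.size else 0.0

    def copy(self) -> "ActigraphyRecord":
        return ActigraphyRecord(self.subject_id, self.state,
                                self.samples.copy(), self.missing_mask.copy())


def write_records_csv(records: list[ActigraphyRecord], path) -> None:
    """Write records as CSV with columns subject_id, state, index, value,
    missing (0/1); one row per 30-s epoch, records in input order."""
    frames = []
    for rec in records:
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "state": rec.state.value,
            "index": np.arange(rec.n_samples, dtype=int),
            "value": rec.samples,
            "missing": rec.missing_mask.astype(int),
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject_id", "state", "index", "value", "missing"])
    out.to_csv(path, index=False)


def read_records_csv(path) -> list[ActigraphyRecord]:
    """Read the CSV dialect of :func:`write_records_csv`.

    Record boundaries are recovered from the ``index`` column resetting to
    zero, so several episodes of the same subject and state round-trip.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "state", "index", "value", "missing"}
    if not required.issubset(df.columns):
        raise ParameterError(f"records CSV must have columns {sorted(required)}")
    records: list[ActigraphyRecord] = []
    starts = np.flatnonzero(df["index"].to_numpy() == 0)
    bounds = list(starts) + [len(df)]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chunk = df.iloc[lo:hi]
        records.append(ActigraphyRecord(
            subject_id=str(chunk["subject_id"].iloc[0]),
            state=MoodState(chunk["state"].iloc[0]),
            samples=chunk["value"].to_numpy(dtype=float),
            missing_mask=chunk["missing"].to_numpy(dtype=int).astype(bool),
        ))
    return records
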