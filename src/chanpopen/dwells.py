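"""Containers for idealized single-channel records.

A :class:`DwellSequence` is the common currency of the pipeline: an ordered
run of dwells, each with a kinetic ``state_class`` (``open`` / ``shut`` /
``desensitized``), a ``conductance_class`` (``full`` / ``sub`` / ``zero``)
and a duration in seconds.  Both the stochastic simulator and the trace
idealizer produce one; cluster segmentation consumes one.

A :class:`Trace` is a uniformly sampled current record in pA with its
acquisition metadata (sampling rate, filter cutoff already applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = ["Dwell", "DwellSequence", "Trace"]

STATE_CLASSES = ("open", "shut", "desensitized")
CONDUCTANCE_CLASSES = ("full", "sub", "zero")


class Dwell(NamedTuple):
    state_class: str
    conductance_class: str
    duration: float


@dataclass
class DwellSequence:
    """Time-ordered dwells with maximal equal-class runs merged.

    Attributes
    ----------
    state_class, conductance_class : ndarray of str
        Per-dwell class labels.
    durations : ndarray of float
        Dwell durations in seconds, strictly positive.
    start_time : float
        Absolute start of the first dwell in seconds.
    """

    state_class: np.ndarray
    conductance_class: np.ndarray
    durations: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.state_class = np.asarray(self.state_class, dtype=object)
        self.conductance_class = np.asarray(self.conductance_class, dtype=object)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (
            len(self.state_class) == len(self.conductance_class) == len(self.durations)
        ):
            raise ValueError("dwell arrays must have equal length")
        if len(self.durations) and not np.all(self.durations > 0):
            bad = int(np.flatnonzero(~(self.durations > 0))[0])
            raise ValueError(f"dwell {bad} has non-positive duration")
        unknown = set(self.state_class) - set(STATE_CLASSES)
        if unknown:
            raise ValueError(f"unknown state_class labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.durations)

    def __iter__(self) -> Iterator[Dwell]:
        for s, c, d in zip(self.state_class, self.conductance_class, self.durations):
            yield Dwell(s, c, d)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def start_times(self) -> np.ndarray:
        """Absolute start time of every dwell."""
        out = np.empty(len(self), dtype=float)
        if len(self):
            out[0] = self.start_time
            np.cumsum(self.durations[:-1], out=out[1:])
            out[1:] += self.start_time
        return out

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, float]], start_time: float = 0.0
    ) -> "DwellSequence":
        if not records:
            return cls(
                np.empty(0, object), np.empty(0, object), np.empty(0, float), start_time
            )
        s, c, d = zip(*records)
        return cls(np.array(s, object), np.array(c, object), np.array(d, float), start_time)

    def merged(self) -> "DwellSequence":
        """Merge adjacent dwells that share both class labels."""
        if len(self) < 2:
            return self
        same = (self.state_class[1:] == self.state_class[:-1]) & (
            self.conductance_class[1:] == self.conductance_class[:-1]
        )
        starts = np.flatnonzero(np.concatenate(([True], ~same)))
        durations = np.add.reduceat(self.durations, starts)
        return DwellSequence(
            self.state_class[starts],
            self.conductance_class[starts],
            durations,
            self.start_time,
        )

    def slice(self, i: int, j: int) -> "DwellSequence":
        """Dwells ``i:j`` keeping absolute time."""
        return DwellSequence(
            self.state_class[i:j],
            self.conductance_class[i:j],
            self.durations[i:j],
            float(self.start_times[i]) if j > i else self.start_time,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start_times,
                "duration_s": self.durations,
                "state_class": self.state_class.astype(str),
                "conductance_class": self.conductance_class.astype(str),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DwellSequence":
        start = float(frame["start_s"].iloc[0]) if len(frame) else 0.0
        return cls(
            frame["state_class"].to_numpy(object),
            frame["conductance_class"].to_numpy(object),
            frame["duration_s"].to_numpy(float),
            start,
        )


@dataclass
class Trace:
    """Uniformly sampled current record.

    Attributes
    ----------
    samples : ndarray
        Current in pA.
    fs : float
        Sampling rate in Hz.
    fc : float or None
        −3 dB cutoff (Hz) of Gaussian filtering already applied, if any.
    metadata : dict
        Provenance (generator settings, filter cascade, seeds, ...).
    """

    samples: np.ndarray
    fs: float
    fc: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        if self.fc is not None and self.fc > self.fs / 2:
            raise ValueError("fc must not exceed the Nyquist frequency fs/2")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs
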