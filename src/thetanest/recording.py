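"""Core containers: multichannel LFP recordings and session annotations.

An :class:`LFPRecording` holds a ``(n_channels, n_samples)`` array together
with its sampling rate and channel labels.  A :class:`SessionAnnotation` is a
set of labeled half-open time intervals ``[onset, offset)`` describing the
behavioural session (virtual corridor, sector within the corridor, movement
epochs, stimulus presentations).  Both share one time base: sample ``i`` of
the recording maps to time ``t0 + i / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: label types accepted in a session annotation
LABEL_TYPES = ("corridor", "sector", "movement", "stimulus", "curtain", "reward")


@dataclass
class LFPRecording:
    """Multichannel local field potential trace.

    Parameters
    ----------
    samples
        Real array of shape ``(n_channels, n_samples)``, arbitrary units.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel (e.g. ``["PMCo", "CA1"]``).
    t0
        Time of sample 0 in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str] = ()
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D trace of the channel with the given label."""
        try:
            idx = list(self.channel_labels).index(label)
        except ValueError as exc:
            raise KeyError(f"no channel named {label!r}") from exc
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "LFPRecording":
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class Interval:
    """Half-open labeled interval ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float
    label_type: str
    label: str

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"interval onset must precede offset, got [{self.onset_s}, {self.offset_s})"
            )
        if self.label_type not in LABEL_TYPES:
            raise ValueError(
                f"unknown label_type {self.label_type!r}; expected one of {LABEL_TYPES}"
            )

    def contains(self, t: float) -> bool:
        return self.onset_s <= t < self.offset_s


@dataclass
class SessionAnnotation:
    """Labeled epochs of a session as half-open intervals.

    Intervals sharing a ``label_type`` must not overlap, so that any time
    point maps to at most one corridor, one sector, one movement state, etc.
    """

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [
            iv if isinstance(iv, Interval) else Interval(*iv) for iv in self.intervals
        ]
        self._validate_no_overlap()

    def _validate_no_overlap(self) -> None:
        by_type: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_type.setdefault(iv.label_type, []).append(iv)
        for label_type, ivs in by_type.items():
            ivs = sorted(ivs, key=lambda iv: iv.onset_s)
            for a, b in zip(ivs, ivs[1:]):
                if b.onset_s < a.offset_s:
                    raise ValueError(
                        f"overlapping {label_type!r} intervals: "
                        f"[{a.onset_s}, {a.offset_s}) and [{b.onset_s}, {b.offset_s})"
                    )

    def of_type(self, label_type: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label_type == label_type]

    def label_at(self, t: float, label_type: str) -> str | None:
        """Label of the given type covering time ``t``, or None."""
        for iv in self.of_type(label_type):
            if iv.contains(t):
                return iv.label
        return None

    def context_at(self, t: float) -> str | None:
        """Corridor/sector context label (e.g. ``'c3s3'``) at time ``t``."""
        corridor = self.label_at(t, "corridor")
        sector = self.label_at(t, "sector")
        if corridor is None or sector is None:
            return None
        return corridor + sector

    def in_movement(self, t: float) -> bool:
        return self.label_at(t, "movement") is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.onset_s, iv.offset_s, iv.label_type, iv.label) for iv in self.intervals],
            columns=["onset_s", "offset_s", "label_type", "label"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SessionAnnotation":
        required = {"onset_s", "offset_s", "label_type", "label"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        intervals = [
            Interval(float(r.onset_s), float(r.offset_s), str(r.label_type), str(r.label))
            for r in frame.itertuples()
        ]
        return cls(intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def tile_contexts(
    corridors: Iterable[str],
    sectors: Iterable[str],
    sector_duration_s: float,
    t0: float = 0.0,
) -> SessionAnnotation:
    """Tile a session into corridor/sector epochs, one traversal each.

    Sectors are laid out consecutively inside each corridor; corridors
    consecutively over the session.  Adds a full-session ``movement``
    interval (head-fixed navigation: the animal runs throughout).
    """
    corridors = list(corridors)
    sectors = list(sectors)
    intervals: list[Interval] = []
    t = t0
    for corridor in corridors:
        c_on = t
        for sector in sectors:
            intervals.append(Interval(t, t + sector_duration_s, "sector", sector))
            t += sector_duration_s
        intervals.append(Interval(c_on, t, "corridor", corridor))
    intervals.append(Interval(t0, t, "movement", "moving"))
    return SessionAnnotation(intervals)
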