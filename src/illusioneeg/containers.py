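"""In-memory containers shared by every pipeline stage.

Two containers carry the signal through the pipeline:

``ContinuousRecording``
    channels x samples with a sampling rate, 10-20 channel labels and a
    list of event markers (music onset, word onset, response).

``EpochSet``
    epochs x channels x time, with the time axis expressed in milliseconds
    relative to the alignment event, plus per-epoch condition / subject /
    stimulus labels.

Both are plain dataclasses over numpy arrays; all amplitudes are in
microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

EVENT_KINDS = ("music_onset", "word_onset", "response")


@dataclass
class Event:
    """A marker on the continuous time axis (sample index at the recording rate)."""

    sample: int
    kind: str
    condition: str | None = None
    stimulus_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class ContinuousRecording:
    data: np.ndarray  # (n_channels, n_samples), microvolts
    rate_hz: float
    channel_labels: list[str]
    events: list[Event] = field(default_factory=list)
    subject_id: str = "s00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        for ev in self.events:
            if not 0 <= ev.sample < self.n_samples:
                raise ValueError(
                    f"event at sample {ev.sample} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def events_of_kind(self, kind: str) -> list[Event]:
        return [ev for ev in self.events if ev.kind == kind]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(),
            rate_hz=self.rate_hz,
            channel_labels=list(self.channel_labels),
            events=[replace(ev) for ev in self.events],
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )


ALIGNMENTS = ("music_onset", "word_onset", "fixed_segment")


@dataclass
class EpochSet:
    data: np.ndarray  # (n_epochs, n_channels, n_times), microvolts
    rate_hz: float
    time_ms: np.ndarray
    channel_labels: list[str]
    condition: np.ndarray  # per-epoch condition label (str) or ""
    subject_id: np.ndarray  # per-epoch subject id (str)
    stimulus_id: np.ndarray  # per-epoch stimulus id (str) or ""
    alignment: str = "word_onset"
    baseline_window_ms: tuple[float, float] | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.stimulus_id = np.asarray(self.stimulus_id, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x time)")
        n_ep, n_ch, n_t = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel label count does not match data")
        if self.time_ms.shape != (n_t,):
            raise ValueError("time_ms length does not match data")
        for arr, name in (
            (self.condition, "condition"),
            (self.subject_id, "subject_id"),
            (self.stimulus_id, "stimulus_id"),
        ):
            if arr.shape != (n_ep,):
                raise ValueError(f"{name} must have one entry per epoch")
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if n_t > 1:
            steps = np.diff(self.time_ms)
            expected = 1000.0 / self.rate_hz
            if not np.allclose(steps, expected, rtol=1e-6, atol=1e-6):
                raise ValueError("time_ms must be uniform with spacing 1000/rate_hz")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def channel_indices(self, labels: Iterable[str]) -> np.ndarray:
        return np.array([self.channel_index(lab) for lab in labels], dtype=int)

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples with time in the closed interval ``window_ms``."""
        lo, hi = window_ms
        if lo > hi:
            raise ValueError("window must have lo <= hi")
        mask = (self.time_ms >= lo) & (self.time_ms <= hi)
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        return mask

    def select(
        self,
        condition: str | Iterable[str] | None = None,
        subject_id: str | Iterable[str] | None = None,
    ) -> "EpochSet":
        keep = np.ones(self.n_epochs, dtype=bool)
        if condition is not None:
            wanted = {condition} if isinstance(condition, str) else set(condition)
            keep &= np.array([c in wanted for c in self.condition])
        if subject_id is not None:
            wanted = {subject_id} if isinstance(subject_id, str) else set(subject_id)
            keep &= np.array([s in wanted for s in self.subject_id])
        return self.take(np.flatnonzero(keep))

    def take(self, indices: np.ndarray) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[indices],
            rate_hz=self.rate_hz,
            time_ms=self.time_ms.copy(),
            channel_labels=list(self.channel_labels),
            condition=self.condition[indices],
            subject_id=self.subject_id[indices],
            stimulus_id=self.stimulus_id[indices],
            alignment=self.alignment,
            baseline_window_ms=self.baseline_window_ms,
            info=dict(self.info),
        )

    def copy(self) -> "EpochSet":
        return self.take(np.arange(self.n_epochs))

    def conditions_present(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets that share channels, rate and time axis."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for es in sets[1:]:
        if es.channel_labels != first.channel_labels:
            raise ValueError("channel sets differ")
        if es.rate_hz != first.rate_hz or es.n_times != first.n_times:
            raise ValueError("time axes differ")
        if not np.allclose(es.time_ms, first.time_ms):
            raise ValueError("time axes differ")
    return EpochSet(
        data=np.concatenate([es.data for es in sets], axis=0),
        rate_hz=first.rate_hz,
        time_ms=first.time_ms.copy(),
        channel_labels=list(first.channel_labels),
        condition=np.concatenate([es.condition for es in sets]),
        subject_id=np.concatenate([es.subject_id for es in sets]),
        stimulus_id=np.concatenate([es.stimulus_id for es in sets]),
        alignment=first.alignment,
        baseline_window_ms=first.baseline_window_ms,
    )
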