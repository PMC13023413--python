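"""Persistence: the internal HDF5 container and external-format import.

The internal container stores recordings and epoch sets under a fixed
layout (``/data``, ``/rate``, ``/labels``, ``/events``, ``/meta``) so every
pipeline stage can round-trip its inputs and outputs.  BrainVision
(.vhdr/.eeg/.vmrk) and EDF recordings are imported through MNE's readers
and converted to :class:`ContinuousRecording` (volts -> microvolts).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import ContinuousRecording, EpochSet, Event

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "read_brainvision",
    "read_edf",
]

_STR = h5py.string_dtype(encoding="utf-8")


def save_recording(rec: ContinuousRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip",
                         compression_opts=1, track_times=False)
        f.create_dataset("rate", data=float(rec.rate_hz), track_times=False)
        f.create_dataset("labels", track_times=False,
                         data=np.array(rec.channel_labels, dtype=_STR))
        ev = np.array(
            [(e.sample, e.kind, e.condition or "", e.stimulus_id or "")
             for e in rec.events],
            dtype=[("sample", "i8"), ("kind", _STR), ("condition", _STR),
                   ("stimulus_id", _STR)],
        )
        f.create_dataset("events", data=ev, track_times=False)
        meta = dict(rec.meta, subject_id=rec.subject_id, container="recording")
        f.create_dataset("meta", data=json.dumps(meta), track_times=False)


def load_recording(path: str | Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        meta = json.loads(f["meta"][()])
        if meta.pop("container", "recording") != "recording":
            raise ValueError(f"{path} does not hold a continuous recording")
        events = [
            Event(int(r["sample"]), r["kind"].decode(),
                  r["condition"].decode() or None,
                  r["stimulus_id"].decode() or None)
            for r in f["events"][()]
        ]
        return ContinuousRecording(
            data=f["data"][()], rate_hz=float(f["rate"][()]),
            channel_labels=[s.decode() for s in f["labels"][()]],
            events=events, subject_id=meta.pop("subject_id", "s00"),
            meta=meta,
        )


def save_epochs(ep: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip",
                         compression_opts=1, track_times=False)
        f.create_dataset("rate", data=float(ep.rate_hz), track_times=False)
        f.create_dataset("time_ms", data=ep.time_ms, track_times=False)
        f.create_dataset("labels", track_times=False,
                         data=np.array(ep.channel_labels, dtype=_STR))
        for name in ("condition", "subject_id", "stimulus_id"):
            f.create_dataset(name, track_times=False,
                             data=np.array(getattr(ep, name), dtype=_STR))
        meta = {
            "container": "epochs",
            "alignment": ep.alignment,
            "baseline_window_ms": list(ep.baseline_window_ms)
            if ep.baseline_window_ms else None,
            "info": ep.info,
        }
        f.create_dataset("meta", data=json.dumps(meta), track_times=False)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = json.loads(f["meta"][()])
        if meta.get("container") != "epochs":
            raise ValueError(f"{path} does not hold an epoch set")
        bw = meta.get("baseline_window_ms")
        return EpochSet(
            data=f["data"][()], rate_hz=float(f["rate"][()]),
            time_ms=f["time_ms"][()],
            channel_labels=[s.decode() for s in f["labels"][()]],
            condition=np.array([s.decode() for s in f["condition"][()]],
                               dtype=object),
            subject_id=np.array([s.decode() for s in f["subject_id"][()]],
                                dtype=object),
            stimulus_id=np.array([s.decode() for s in f["stimulus_id"][()]],
                                 dtype=object),
            alignment=meta.get("alignment", "word_onset"),
            baseline_window_ms=tuple(bw) if bw else None,
            info=meta.get("info", {}),
        )


def _from_mne_raw(raw, subject_id: str) -> ContinuousRecording:
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    for onset, _, desc in zip(raw.annotations.onset,
                              raw.annotations.duration,
                              raw.annotations.description):
        kind = str(desc).strip().lower().replace(" ", "_")
        if kind in ("music_onset", "word_onset", "response"):
            events.append(Event(int(round(onset * raw.info["sfreq"])), kind))
    return ContinuousRecording(
        data=data, rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names), events=events,
        subject_id=subject_id, meta={"source": "import"},
    )


def read_brainvision(vhdr_path: str | Path,
                     subject_id: str = "s00") -> ContinuousRecording:
    """Import a BrainVision recording (.vhdr with its .eeg/.vmrk siblings)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True,
                                      verbose="error")
    return _from_mne_raw(raw, subject_id)


def read_edf(path: str | Path, subject_id: str = "s00") -> ContinuousRecording:
    """Import an EDF/EDF+ recording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_mne_raw(raw, subject_id)
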