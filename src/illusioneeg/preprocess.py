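"""Deterministic signal conditioning: continuous recordings -> analysis-ready epochs.

The conditioning chain mirrors a conventional auditory-ERP pipeline:
anti-aliased downsampling to 250 Hz, re-referencing to the mastoid average,
zero-phase FIR band limiting (0-125 Hz), epoching around event markers and
pre-stimulus baseline correction.  The decoder branch band-limits with a
4th-order Chebyshev type-I low-pass at 40 Hz and cuts fixed 2.5-s segments
instead.

All filters are applied zero-phase so component latencies are never
shifted.  Epoching is pure indexing - sample values are preserved exactly.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import ContinuousRecording, EpochSet, Event

logger = logging.getLogger(__name__)

__all__ = [
    "resample",
    "rereference",
    "fir_bandpass",
    "cheby_bandlimit",
    "epoch_around",
    "baseline_correct",
    "segment_fixed",
]

#: Chebyshev type-I passband ripple (dB) for the decoder's band limiting.
CHEBY_RIPPLE_DB = 0.5


def resample(rec: ContinuousRecording, target_rate_hz: float) -> ContinuousRecording:
    """Anti-aliased polyphase resampling; event indices are remapped.

    ``target_rate_hz`` must be positive and at most the current rate.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if target_rate_hz > rec.rate_hz:
        raise ValueError("upsampling is not supported")
    if target_rate_hz == rec.rate_hz:
        return rec.copy()
    frac = Fraction(target_rate_hz / rec.rate_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(rec.data, up, down, axis=1)
    ratio = target_rate_hz / rec.rate_hz
    n_new = data.shape[1]
    events = []
    for ev in rec.events:
        s = min(int(round(ev.sample * ratio)), n_new - 1)
        events.append(Event(s, ev.kind, ev.condition, ev.stimulus_id))
    return ContinuousRecording(
        data=data, rate_hz=target_rate_hz,
        channel_labels=list(rec.channel_labels), events=events,
        subject_id=rec.subject_id, meta=dict(rec.meta),
    )


def rereference(rec: ContinuousRecording,
                reference_labels: tuple[str, ...] = ("M1", "M2"),
                ) -> ContinuousRecording:
    """Subtract the samplewise mean of the reference channels from every channel."""
    for lab in reference_labels:
        if lab not in rec.channel_labels:
            raise KeyError(f"reference channel {lab!r} not present")
    idx = [rec.channel_index(lab) for lab in reference_labels]
    ref = rec.data[idx].mean(axis=0)
    out = rec.copy()
    out.data = out.data - ref[None, :]
    out.meta["reference"] = list(reference_labels)
    return out


def _fir_kernel(low_hz: float, high_hz: float, rate_hz: float,
                transition_hz: float) -> np.ndarray:
    """Linear-phase windowed-sinc kernel for the requested band.

    A 0 Hz lower edge means plain low-pass; an upper edge at Nyquist means
    plain high-pass.
    """
    nyq = rate_hz / 2.0
    numtaps = int(math.ceil(3.3 * rate_hz / transition_hz)) | 1  # odd
    if low_hz <= 0 and high_hz >= nyq:
        return np.concatenate([np.zeros(numtaps // 2), [1.0],
                               np.zeros(numtaps // 2)])
    if low_hz <= 0:
        return sps.firwin(numtaps, high_hz, fs=rate_hz, pass_zero="lowpass")
    if high_hz >= nyq:
        return sps.firwin(numtaps, low_hz, fs=rate_hz, pass_zero="highpass")
    return sps.firwin(numtaps, [low_hz, high_hz], fs=rate_hz,
                      pass_zero="bandpass")


def fir_filter_array(data: np.ndarray, rate_hz: float, low_hz: float,
                     high_hz: float, transition_hz: float = 1.0) -> np.ndarray:
    """Zero-phase FIR band filtering of (..., time) arrays.

    The symmetric linear-phase kernel is applied by 'same'-mode convolution,
    which compensates the group delay exactly.
    """
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > rate_hz / 2.0:
        raise ValueError(
            f"high_hz={high_hz} exceeds Nyquist ({rate_hz / 2.0} Hz)")
    kernel = _fir_kernel(low_hz, high_hz, rate_hz, transition_hz)
    if kernel.size >= data.shape[-1]:
        # short signals: trim the kernel rather than wrap
        half = (data.shape[-1] - 1) // 2
        mid = kernel.size // 2
        kernel = kernel[mid - half: mid + half + 1]
        kernel = kernel / kernel.sum() if low_hz <= 0 else kernel
    flat = data.reshape(-1, data.shape[-1])
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        out[i] = sps.fftconvolve(row, kernel, mode="same")
    return out.reshape(data.shape)


def fir_bandpass(rec: ContinuousRecording, low_hz: float = 0.0,
                 high_hz: float = 125.0,
                 transition_hz: float | None = None) -> ContinuousRecording:
    """Zero-phase windowed-sinc band filter (default pass band 0-125 Hz).

    The transition width defaults to 1 Hz scaled proportionally with the
    sampling rate (1 Hz at 1000 Hz).
    """
    if transition_hz is None:
        transition_hz = max(1.0 * rec.rate_hz / 1000.0, 0.25)
    out = rec.copy()
    out.data = fir_filter_array(rec.data, rec.rate_hz, low_hz, high_hz,
                                transition_hz)
    out.meta["fir_band_hz"] = (low_hz, high_hz)
    return out


def cheby_bandlimit(rec: ContinuousRecording, order: int = 4,
                    high_hz: float = 40.0) -> ContinuousRecording:
    """Zero-phase Chebyshev type-I low-pass (order 4, 40 Hz by default).

    Passband ripple is fixed at ``CHEBY_RIPPLE_DB``.  Forward-backward
    application doubles the effective ripple in dB but keeps zero phase.
    """
    if high_hz >= rec.rate_hz / 2.0:
        raise ValueError(
            f"high_hz={high_hz} must be below Nyquist ({rec.rate_hz / 2.0} Hz)")
    if high_hz <= 0:
        raise ValueError("high_hz must be positive")
    sos = sps.cheby1(order, CHEBY_RIPPLE_DB, high_hz, btype="lowpass",
                     fs=rec.rate_hz, output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, rec.data, axis=1)
    out.meta["cheby"] = {"order": order, "high_hz": high_hz,
                         "ripple_db": CHEBY_RIPPLE_DB}
    return out


def epoch_around(rec: ContinuousRecording, alignment_kind: str = "word_onset",
                 window_ms: tuple[float, float] = (-200.0, 350.0)) -> EpochSet:
    """Cut one epoch per ``alignment_kind`` event.

    Events whose window does not fit inside the recording are dropped and
    counted (``info["n_dropped"]``).  No baseline is applied.
    """
    events = rec.events_of_kind(alignment_kind)
    if not events:
        raise ValueError(f"no events of kind {alignment_kind!r}")
    rate = rec.rate_hz
    lo = int(round(window_ms[0] * rate / 1000.0))
    hi = int(round(window_ms[1] * rate / 1000.0))
    n_t = hi - lo + 1
    time_ms = (np.arange(lo, hi + 1)) * 1000.0 / rate
    epochs, cond, stim, dropped = [], [], [], 0
    for ev in events:
        start, stop = ev.sample + lo, ev.sample + hi + 1
        if start < 0 or stop > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, start:stop])
        cond.append(ev.condition or "")
        stim.append(ev.stimulus_id or "")
    if dropped:
        logger.info("epoch_around: dropped %d/%d events at recording "
                    "boundaries (%s)", dropped, len(events), rec.subject_id)
    if not epochs:
        raise ValueError("all epochs fell outside the recording")
    data = np.stack(epochs, axis=0)
    assert data.shape[2] == n_t
    return EpochSet(
        data=data, rate_hz=rate, time_ms=time_ms,
        channel_labels=list(rec.channel_labels),
        condition=np.array(cond, dtype=object),
        subject_id=np.array([rec.subject_id] * len(epochs), dtype=object),
        stimulus_id=np.array(stim, dtype=object),
        alignment=alignment_kind,
        info={"n_dropped": dropped},
    )


def baseline_correct(ep: EpochSet,
                     window_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    mask = ep.time_mask(window_ms)
    out = ep.copy()
    out.data = ep.data - ep.data[:, :, mask].mean(axis=2, keepdims=True)
    out.baseline_window_ms = tuple(window_ms)
    return out


def segment_fixed(rec: ContinuousRecording, length_s: float = 2.5) -> EpochSet:
    """Cut consecutive non-overlapping segments; the trailing remainder is dropped."""
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    n_seg_t = int(round(length_s * rec.rate_hz))
    n_segments = rec.n_samples // n_seg_t
    if n_segments == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s is shorter than one "
            f"{length_s} s segment")
    data = rec.data[:, : n_segments * n_seg_t]
    data = data.reshape(rec.n_channels, n_segments, n_seg_t).transpose(1, 0, 2)
    time_ms = np.arange(n_seg_t) * 1000.0 / rec.rate_hz
    lang = rec.meta.get("language", "")
    return EpochSet(
        data=data.copy(), rate_hz=rec.rate_hz, time_ms=time_ms,
        channel_labels=list(rec.channel_labels),
        condition=np.array([lang] * n_segments, dtype=object),
        subject_id=np.array([rec.subject_id] * n_segments, dtype=object),
        stimulus_id=np.array([f"seg_{i:04d}" for i in range(n_segments)],
                             dtype=object),
        alignment="fixed_segment",
    )
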