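"""Time-frequency analysis and the beta/gamma dominance index.

Morlet wavelet decomposition (7 cycles, 2-80 Hz in 1 Hz steps by default),
decibel baselining against the pre-stimulus window, band power extraction
(beta 13-30 Hz, gamma 30-50 Hz), Hilbert amplitude envelopes of
band-filtered ERPs, and the dominance index: the ratio of the beta to the
gamma envelope, with sustained deviations from unity (>= 100 ms) labelled
as beta- or gamma-dominated intervals.

The dominance ratio is computed on grand-averaged, ROI-averaged,
band-filtered ERPs (conditions averaged over trials, then over the ROI
channels), not per trial.  Signals are reflection-padded before wavelet and
analytic-signal computation; edge-affected samples are flagged per
frequency and excluded from statistics by callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EpochSet
from .montage import ROI_CHANNELS
from .preprocess import fir_filter_array

logger = logging.getLogger(__name__)

__all__ = [
    "TFRepresentation",
    "Envelope",
    "DominanceProfile",
    "default_freqs",
    "morlet_power",
    "morlet_tfr",
    "db_normalize",
    "band_power",
    "band_envelope",
    "dominance_profile",
]

BETA_BAND_HZ = (13.0, 30.0)
GAMMA_BAND_HZ = (30.0, 50.0)
#: Sub-band presets for the dominance analysis.
HIGH_BETA_BAND_HZ = (20.0, 30.0)
LOW_GAMMA_BAND_HZ = (30.0, 50.0)


def default_freqs() -> np.ndarray:
    """2-80 Hz in 1 Hz steps."""
    return np.arange(2.0, 81.0, 1.0)


@dataclass
class TFRepresentation:
    power: np.ndarray            # (n_epochs, n_freqs, n_times) or (n_freqs, n_times)
    freqs_hz: np.ndarray
    time_ms: np.ndarray
    normalization: str = "raw"   # "raw" | "dB"
    baseline_window_ms: tuple[float, float] | None = None
    n_cycles: float = 7.0
    #: per-frequency count of edge-contaminated samples at each end.
    edge_margin: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def is_trial_resolved(self) -> bool:
        return self.power.ndim == 3

    def trial_average(self) -> "TFRepresentation":
        if not self.is_trial_resolved:
            return self
        return TFRepresentation(
            power=self.power.mean(axis=0), freqs_hz=self.freqs_hz.copy(),
            time_ms=self.time_ms.copy(), normalization=self.normalization,
            baseline_window_ms=self.baseline_window_ms,
            n_cycles=self.n_cycles, edge_margin=self.edge_margin.copy(),
        )


def _morlet_wavelet(freq_hz: float, rate_hz: float, n_cycles: float,
                    ) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at +/- 3.5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(3.5 * sigma_t * rate_hz))
    t = np.arange(-half, half + 1) / rate_hz
    w = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_power(signals: np.ndarray, rate_hz: float,
                 freqs_hz: np.ndarray | None = None, n_cycles: float = 7.0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Squared-magnitude Morlet convolution of (..., time) signals.

    Returns ``(power, edge_margin)`` with power shaped (..., n_freqs,
    n_times) and edge_margin the per-frequency count of samples at each end
    whose value draws on reflected padding (half the wavelet support).
    """
    freqs = default_freqs() if freqs_hz is None else np.asarray(freqs_hz, float)
    if (freqs >= rate_hz / 2.0).any():
        raise ValueError("wavelet frequencies must stay below Nyquist")
    x = np.asarray(signals, dtype=float)
    shape = x.shape
    flat = x.reshape(-1, shape[-1])
    n_t = shape[-1]
    out = np.empty((flat.shape[0], freqs.size, n_t))
    margins = np.empty(freqs.size, dtype=int)
    for k, f in enumerate(freqs):
        w = _morlet_wavelet(f, rate_hz, n_cycles)
        half = w.size // 2
        margins[k] = min(half, n_t)
        pad = min(half, n_t - 1)
        padded = np.pad(flat, ((0, 0), (pad, pad)), mode="reflect")
        conv = sps.fftconvolve(padded, w[None, :], mode="same", axes=1)
        out[:, k, :] = np.abs(conv[:, pad: pad + n_t]) ** 2
    return out.reshape(*shape[:-1], freqs.size, n_t), margins


def morlet_tfr(ep: EpochSet, freqs_hz: np.ndarray | None = None,
               n_cycles: float = 7.0,
               channels: tuple[str, ...] = ROI_CHANNELS) -> TFRepresentation:
    """Per-trial Morlet power on the ROI, averaged across the ROI channels.

    Power is computed per channel and then averaged (power first, channels
    second), so induced activity is retained.  Low frequencies whose
    wavelet exceeds the epoch are fully edge-flagged rather than rejected.
    """
    freqs = default_freqs() if freqs_hz is None else np.asarray(freqs_hz, float)
    idx = ep.channel_indices(channels)
    power, margins = morlet_power(ep.data[:, idx, :], ep.rate_hz, freqs,
                                  n_cycles)
    power = power.mean(axis=1)  # average over channels
    full = margins >= ep.n_times
    if full.any():
        logger.info("morlet_tfr: %d frequency rows fully edge-contaminated "
                    "(epoch shorter than the wavelet)", int(full.sum()))
    return TFRepresentation(power=power, freqs_hz=freqs,
                            time_ms=ep.time_ms.copy(), normalization="raw",
                            n_cycles=n_cycles, edge_margin=margins)


def db_normalize(tf: TFRepresentation,
                 baseline_ms: tuple[float, float] = (-200.0, 0.0),
                 ) -> TFRepresentation:
    """Decibel change relative to mean baseline power, per frequency.

    Computed on trial-averaged power: value = 10*log10(power / mean
    baseline power at that frequency).
    """
    if tf.normalization == "dB":
        raise ValueError("already dB-normalized")
    avg = tf.trial_average()
    mask = (avg.time_ms >= baseline_ms[0]) & (avg.time_ms <= baseline_ms[1])
    if not mask.any():
        raise ValueError(f"baseline {baseline_ms} outside the epoch time axis")
    base = avg.power[:, mask].mean(axis=1)
    bad = np.flatnonzero(base <= 0)
    if bad.size:
        raise ValueError(
            "zero baseline power at frequency rows "
            f"{avg.freqs_hz[bad].tolist()} Hz")
    db = 10.0 * np.log10(avg.power / base[:, None])
    return TFRepresentation(power=db, freqs_hz=avg.freqs_hz,
                            time_ms=avg.time_ms, normalization="dB",
                            baseline_window_ms=tuple(baseline_ms),
                            n_cycles=avg.n_cycles, edge_margin=avg.edge_margin)


def band_power(tf: TFRepresentation,
               band_hz: tuple[float, float]) -> np.ndarray:
    """Mean over the band's frequency rows (inclusive bounds)."""
    lo, hi = band_hz
    mask = (tf.freqs_hz >= lo) & (tf.freqs_hz <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} contains no frequency rows")
    axis = -2
    return tf.power[..., mask, :].mean(axis=axis)


@dataclass
class Envelope:
    """Hilbert amplitude envelope of a band-filtered signal."""

    values: np.ndarray
    band_hz: tuple[float, float]
    rate_hz: float
    margin_samples: int  # edge samples affected by filter + transform transients

    @property
    def interior(self) -> np.ndarray:
        m = self.margin_samples
        return self.values[m: self.values.size - m] if m else self.values


def band_envelope(waveform: np.ndarray, rate_hz: float,
                  band_hz: tuple[float, float],
                  transition_hz: float = 4.0,
                  extra_margin_ms: float = 50.0) -> Envelope:
    """Magnitude of the analytic signal of the band-filtered waveform.

    The waveform is zero-phase FIR band-filtered first (reflection padding
    absorbs filter and Hilbert transients), then the analytic signal is
    taken.  ``margin_samples`` flags the edge span a caller should exclude
    from statistics.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if band_hz[1] > rate_hz / 2.0:
        raise ValueError("band exceeds Nyquist")
    numtaps = int(np.ceil(3.3 * rate_hz / transition_hz)) | 1
    pad = min(numtaps // 2, x.size - 1)
    padded = np.pad(x, pad, mode="reflect")
    filtered = fir_filter_array(padded, rate_hz, band_hz[0], band_hz[1],
                                transition_hz)
    env = np.abs(sps.hilbert(filtered))[pad: pad + x.size]
    margin = min(pad + int(round(extra_margin_ms * rate_hz / 1000.0)),
                 x.size // 2)
    return Envelope(values=env, band_hz=tuple(band_hz), rate_hz=rate_hz,
                    margin_samples=margin)


@dataclass
class DominanceInterval:
    t_start_ms: float
    t_end_ms: float
    label: str  # "beta" | "gamma"


@dataclass
class DominanceProfile:
    ratio: np.ndarray
    time_ms: np.ndarray
    intervals: list[DominanceInterval]
    min_duration_ms: float = 100.0

    def first_onset(self, label: str) -> float | None:
        for iv in self.intervals:
            if iv.label == label:
                return iv.t_start_ms
        return None


def dominance_profile(beta_env: np.ndarray, gamma_env: np.ndarray,
                      time_ms: np.ndarray,
                      min_duration_ms: float = 100.0) -> DominanceProfile:
    """Beta/gamma envelope ratio with sustained-dominance intervals.

    Ratio > 1 marks beta dominance, < 1 gamma dominance.  Maximal runs of a
    constant dominance sign shorter than ``min_duration_ms`` are discarded;
    samples where the ratio equals 1 exactly break a run (neither band
    dominant).  Samples with zero gamma envelope are excluded and logged.
    """
    beta = np.asarray(beta_env, dtype=float)
    gamma = np.asarray(gamma_env, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    if beta.shape != gamma.shape or beta.shape != t.shape:
        raise ValueError("beta, gamma and time axes must match")
    valid = gamma != 0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("dominance_profile: %d zero-gamma samples excluded", n_bad)
    ratio = np.full_like(beta, np.nan)
    np.divide(beta, gamma, out=ratio, where=valid)
    state = np.zeros(beta.size, dtype=int)  # +1 beta, -1 gamma, 0 neither
    state[valid & (ratio > 1.0)] = 1
    state[valid & (ratio < 1.0)] = -1
    dt_ms = 1000.0 / _rate_from_time(t)
    intervals: list[DominanceInterval] = []
    i = 0
    while i < state.size:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < state.size and state[j + 1] == state[i]:
            j += 1
        duration = (j - i + 1) * dt_ms
        if duration >= min_duration_ms:
            intervals.append(DominanceInterval(
                t_start_ms=float(t[i]), t_end_ms=float(t[j]),
                label="beta" if state[i] > 0 else "gamma"))
        i = j + 1
    return DominanceProfile(ratio=ratio, time_ms=t, intervals=intervals,
                            min_duration_ms=min_duration_ms)


def _rate_from_time(time_ms: np.ndarray) -> float:
    if time_ms.size < 2:
        return 1000.0
    return 1000.0 / float(time_ms[1] - time_ms[0])
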