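"""Seeded synthetic-EEG cohort generator.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any recorded data:

* per-subject continuous recordings containing 100 trials (20 per
  condition, randomized order) of spatially correlated 1/f background
  noise plus condition-dependent N1/P2 half-cosine deflections with a
  fronto-central topography, phase-locked beta/gamma bursts, and a
  language-class spatial-covariance signature active during the audio;
* per-subject pairs of long "audiobook" recordings whose channel
  covariance differs by language class (the decoder's training data);
* ordinal 3-point behavioral ratings per trial.

Everything is deterministic given ``SimConfig.seed``: identical config and
seed reproduce identical bytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig, CONDITIONS
from .containers import ContinuousRecording, EpochSet, Event
from .montage import gaussian_pattern, spatial_kernel

__all__ = [
    "generate_cohort",
    "generate_subject_recording",
    "generate_epoch_cohort",
    "generate_audiobook_pair",
    "generate_ratings",
    "trial_schedule",
]


# --------------------------------------------------------------------- #
# noise and signal primitives
# --------------------------------------------------------------------- #

def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    """Deterministic per-purpose random stream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
               exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent along the last axis.

    Shaped in the frequency domain (amplitude ~ f**(-exponent/2), DC removed),
    then normalized to unit standard deviation per series.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0.0:
        out = white
    else:
        spec = np.fft.rfft(white, axis=-1)
        freqs = np.fft.rfftfreq(n, d=1.0)  # slope is d-invariant
        scale = np.zeros_like(freqs)
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
        spec *= scale
        out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def band_noise(rng: np.random.Generator, n: int, rate_hz: float,
               band_hz: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise restricted to ``band_hz`` (brick-wall in frequency)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec[(freqs < band_hz[0]) | (freqs > band_hz[1])] = 0.0
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _noise_mixing(config: SimConfig) -> np.ndarray:
    """Cholesky factor of the spatial correlation kernel (unit diagonal)."""
    k = spatial_kernel(config.channel_labels, config.noise["spatial_scale"])
    # tiny jitter keeps the factorization stable for dense montages
    return np.linalg.cholesky(k + 1e-10 * np.eye(k.shape[0]))


def background_noise(config: SimConfig, rng: np.random.Generator,
                     n_samples: int, chol: np.ndarray | None = None) -> np.ndarray:
    """(n_channels, n_samples) spatially correlated pink background, in uV."""
    amp = float(config.noise["amplitude_uv"])
    n_ch = config.n_channels
    if amp == 0.0:
        return np.zeros((n_ch, n_samples))
    if chol is None:
        chol = _noise_mixing(config)
    series = pink_noise(rng, (n_ch, n_samples), float(config.noise["exponent"]))
    return amp * (chol @ series)


def half_cosine(t_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    """Half-cosine bump: cos(pi*(t-peak)/width) on |t-peak| <= width/2, else 0."""
    u = (np.asarray(t_ms, dtype=float) - peak_ms) / width_ms
    out = np.where(np.abs(u) <= 0.5, np.cos(np.pi * u), 0.0)
    return out


def half_cosine_window_mean(window_ms: tuple[float, float], peak_ms: float,
                            width_ms: float) -> float:
    """Closed-form mean of the half-cosine bump over a closed window."""
    lo = max(window_ms[0], peak_ms - width_ms / 2.0)
    hi = min(window_ms[1], peak_ms + width_ms / 2.0)
    if hi <= lo:
        return 0.0
    a = np.pi * (lo - peak_ms) / width_ms
    b = np.pi * (hi - peak_ms) / width_ms
    integral = (np.sin(b) - np.sin(a)) * width_ms / np.pi
    return float(integral / (window_ms[1] - window_ms[0]))


def burst_envelope(t_ms: np.ndarray, bursts: list, ramp_ms: float) -> np.ndarray:
    """Sum of raised-cosine-ramped burst windows evaluated on ``t_ms``."""
    t = np.asarray(t_ms, dtype=float)
    env = np.zeros_like(t)
    for (t0, t1, amp) in bursts:
        ramp = min(ramp_ms, (t1 - t0) / 2.0)
        e = np.zeros_like(t)
        inside = (t >= t0) & (t <= t1)
        e[inside] = 1.0
        if ramp > 0:
            up = inside & (t < t0 + ramp)
            e[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - t0) / ramp))
            down = inside & (t > t1 - ramp)
            e[down] = 0.5 * (1.0 - np.cos(np.pi * (t1 - t[down]) / ramp))
        env += amp * e
    return env


# --------------------------------------------------------------------- #
# trial schedule
# --------------------------------------------------------------------- #

@dataclass
class Trial:
    index: int
    condition: str
    stimulus_id: str
    music_onset_s: float
    word_onset_s: float
    audio_end_s: float


def trial_schedule(config: SimConfig, subject_index: int) -> list[Trial]:
    """Randomized per-subject trial order with per-trial timing.

    Stimulus identities are shared across subjects (each subject hears the
    same 100 excerpts, in subject-specific random order), which is what
    makes group-averaging by stimulus possible.
    """
    rng = _rng(config, subject_index, 0)
    stimuli = [f"{c}_{j:02d}" for c in CONDITIONS
               for j in range(config.trials_per_condition)]
    order = rng.permutation(len(stimuli))
    lo_d, hi_d = config.audio_duration_range_s
    lo_l, hi_l = config.word_onset_lag_range_s
    trials: list[Trial] = []
    t = 0.0
    for i, idx in enumerate(order):
        stim = stimuli[idx]
        cond = stim.split("_")[0]
        music = t + config.pre_music_gap_s
        lag = rng.uniform(lo_l, hi_l)
        duration = rng.uniform(lo_d, hi_d)
        trials.append(Trial(
            index=i, condition=cond, stimulus_id=stim,
            music_onset_s=music, word_onset_s=music + lag,
            audio_end_s=music + duration,
        ))
        t = music + duration + config.post_audio_gap_s
    return trials


# --------------------------------------------------------------------- #
# per-trial stimulus signal
# --------------------------------------------------------------------- #

def _erp_pattern(config: SimConfig) -> np.ndarray:
    return gaussian_pattern(config.channel_labels, config.erp_center,
                            config.erp_sigma)


def _language_pattern(config: SimConfig, language: str,
                      jitter: np.ndarray) -> np.ndarray:
    spec = config.language_covariance[language]
    center = (spec["center"][0] + jitter[0], spec["center"][1] + jitter[1])
    return gaussian_pattern(config.channel_labels, center, spec["sigma"])


def _subject_jitter(config: SimConfig, subject_index: int) -> dict[str, np.ndarray]:
    rng = _rng(config, subject_index, 6)
    return {lang: rng.normal(0.0, config.subject_pattern_jitter, size=2)
            for lang in sorted(config.language_covariance)}


def _trial_signal(config: SimConfig, trial: Trial, t_rel_word_s: np.ndarray,
                  rng: np.random.Generator, erp_pattern: np.ndarray,
                  jitter: dict[str, np.ndarray]) -> np.ndarray:
    """Stimulus-driven activity (channels x time) on a time axis relative to
    word onset, in uV.  Active only while the audio plays."""
    n_t = t_rel_word_s.size
    t_ms = t_rel_word_s * 1000.0
    active = ((t_rel_word_s >= trial.music_onset_s - trial.word_onset_s)
              & (t_rel_word_s <= trial.audio_end_s - trial.word_onset_s))

    gains = config.erp_gains[trial.condition]
    roi_time = (-float(gains["n1_gain"])
                * half_cosine(t_ms, config.n1_peak_ms, config.n1_width_ms)
                + float(gains["p2_gain"])
                * half_cosine(t_ms, config.p2_peak_ms, config.p2_width_ms))

    for band, carrier in (("beta", config.beta_carrier_hz),
                          ("gamma", config.gamma_carrier_hz)):
        bursts = config.band_dynamics[trial.condition].get(band, [])
        if bursts:
            env = burst_envelope(t_ms, bursts, config.burst_ramp_ms)
            # phase-locked carrier so the burst survives trial averaging
            roi_time = roi_time + env * np.sin(2 * np.pi * carrier * t_rel_word_s)

    signal = np.outer(erp_pattern, roi_time * active)

    lang, scale = config.condition_language[trial.condition]
    spec = config.language_covariance[lang]
    gain = float(spec["gain_uv"]) * float(scale)
    if gain > 0:
        src = band_noise(rng, n_t, config.rate_hz, tuple(spec["band_hz"]))
        pattern = _language_pattern(config, lang, jitter[lang])
        signal += gain * np.outer(pattern, src * active)
    return signal


# --------------------------------------------------------------------- #
# public generators
# --------------------------------------------------------------------- #

def generate_subject_recording(config: SimConfig,
                               subject_index: int) -> ContinuousRecording:
    """One subject's continuous main-task recording with event markers."""
    trials = trial_schedule(config, subject_index)
    rate = config.rate_hz
    total_s = trials[-1].audio_end_s + config.post_audio_gap_s
    n_samples = int(np.ceil(total_s * rate))
    noise_rng = _rng(config, subject_index, 1)
    src_rng = _rng(config, subject_index, 2)
    chol = _noise_mixing(config)
    data = background_noise(config, noise_rng, n_samples, chol)

    erp_pat = _erp_pattern(config)
    jitter = _subject_jitter(config, subject_index)
    events: list[Event] = []
    for trial in trials:
        w = int(round(trial.word_onset_s * rate))
        m = int(round(trial.music_onset_s * rate))
        stop = min(int(round(trial.audio_end_s * rate)) + 1, n_samples)
        start = m
        t_rel = (np.arange(start, stop) - w) / rate
        data[:, start:stop] += _trial_signal(config, trial, t_rel, src_rng,
                                             erp_pat, jitter)
        events.append(Event(m, "music_onset", trial.condition, trial.stimulus_id))
        events.append(Event(w, "word_onset", trial.condition, trial.stimulus_id))
        r = min(stop, n_samples - 1)
        events.append(Event(r, "response", trial.condition, trial.stimulus_id))

    return ContinuousRecording(
        data=data, rate_hz=rate, channel_labels=config.channel_labels,
        events=events, subject_id=f"sub-{subject_index:02d}",
        meta={"kind": "main_task"},
    )


def generate_cohort(config: SimConfig) -> tuple[list[ContinuousRecording],
                                                pd.DataFrame]:
    """Full cohort: one main-task recording per subject plus the rating table."""
    recs = [generate_subject_recording(config, i)
            for i in range(config.n_subjects)]
    ratings = generate_ratings(config)
    return recs, ratings


def generate_epoch_cohort(config: SimConfig,
                          window_ms: tuple[float, float] = (-200.0, 800.0),
                          ) -> list[EpochSet]:
    """Epoch-level fast path: word-onset-aligned epochs per subject.

    Statistically equivalent to epoching the continuous recordings (same
    trial model, templates, bursts, language signatures and noise model) but
    generates only the samples inside the epoch window.  Uses its own random
    streams, so individual noise values differ from the continuous path.
    """
    rate = config.rate_hz
    n_t = int(round((window_ms[1] - window_ms[0]) * rate / 1000.0)) + 1
    t_ms = window_ms[0] + np.arange(n_t) * 1000.0 / rate
    t_s = t_ms / 1000.0
    chol = _noise_mixing(config)
    erp_pat = _erp_pattern(config)
    amp = float(config.noise["amplitude_uv"])
    exponent = float(config.noise["exponent"])

    out: list[EpochSet] = []
    for subj in range(config.n_subjects):
        trials = trial_schedule(config, subj)
        noise_rng = _rng(config, subj, 3)
        src_rng = _rng(config, subj, 4)
        jitter = _subject_jitter(config, subj)
        n_ep = len(trials)
        if amp > 0:
            noise = pink_noise(noise_rng, (n_ep, config.n_channels, n_t), exponent)
            data = amp * np.einsum("ij,ejt->eit", chol, noise)
        else:
            data = np.zeros((n_ep, config.n_channels, n_t))
        cond = np.empty(n_ep, dtype=object)
        stim = np.empty(n_ep, dtype=object)
        for e, trial in enumerate(trials):
            data[e] += _trial_signal(config, trial, t_s, src_rng, erp_pat, jitter)
            cond[e] = trial.condition
            stim[e] = trial.stimulus_id
        out.append(EpochSet(
            data=data, rate_hz=rate, time_ms=t_ms,
            channel_labels=config.channel_labels,
            condition=cond,
            subject_id=np.array([f"sub-{subj:02d}"] * n_ep, dtype=object),
            stimulus_id=stim, alignment="word_onset",
        ))
    return out


def generate_audiobook_pair(config: SimConfig, subject_index: int,
                            duration_s: float | None = None,
                            ) -> tuple[ContinuousRecording, ContinuousRecording]:
    """(English, Italian) audiobook recordings for one subject.

    The two recordings share the background-noise statistics and differ only
    in the spatial covariance contributed by the language source.  If the two
    language specifications are identical a warning is emitted: the classes
    are non-separable by design.
    """
    spec_e = config.language_covariance["english"]
    spec_i = config.language_covariance["italian"]
    if spec_e == spec_i:
        warnings.warn("identical language covariance specifications: "
                      "classes are non-separable by design", stacklevel=2)
    duration = config.audiobook_duration_s if duration_s is None else duration_s
    n_samples = int(round(duration * config.rate_hz))
    chol = _noise_mixing(config)
    jitter = _subject_jitter(config, subject_index)
    recs = []
    for k, lang in enumerate(("english", "italian")):
        rng = _rng(config, subject_index, 10 + k)
        data = background_noise(config, rng, n_samples, chol)
        spec = config.language_covariance[lang]
        gain = float(spec["gain_uv"])
        if gain > 0:
            src = band_noise(rng, n_samples, config.rate_hz,
                             tuple(spec["band_hz"]))
            pattern = _language_pattern(config, lang, jitter[lang])
            data += gain * np.outer(pattern, src)
        recs.append(ContinuousRecording(
            data=data, rate_hz=config.rate_hz,
            channel_labels=config.channel_labels,
            events=[], subject_id=f"sub-{subject_index:02d}",
            meta={"kind": "audiobook", "language": lang},
        ))
    return recs[0], recs[1]


def generate_ratings(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-trial 3-point ratings and recognition flags for the whole cohort.

    Ratings are drawn independently per trial from the condition's
    probability vector; trial order matches each subject's schedule.
    """
    rows = []
    for subj in range(config.n_subjects):
        trials = trial_schedule(config, subj)
        stream = (config.seed if seed is None else seed)
        rng = np.random.default_rng(np.random.SeedSequence([stream, subj, 5]))
        for trial in trials:
            probs = np.asarray(config.rating_probs[trial.condition], dtype=float)
            rating = int(rng.choice([1, 2, 3], p=probs))
            recognized = bool(rng.random() < config.recognized_prob)
            rows.append({
                "subject_id": f"sub-{subj:02d}",
                "trial_id": trial.index,
                "condition": trial.condition,
                "rating": rating,
                "recognized": "yes" if recognized else "no",
            })
    return pd.DataFrame(rows)
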