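"""Simulation and pipeline configuration.

``SimConfig`` fixes the statistical structure of the synthetic cohort: ERP
component gains per condition, beta/gamma burst dynamics, the two language
spatial-covariance signatures the decoder is asked to recover, the
background-noise model and the behavioral rating distributions.  Defaults
emulate a 21-subject, 64-channel, 1000 Hz study with 100 trials split
evenly over five prior-congruence conditions (CEng, CIta, IEng, IIta, SW).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .montage import select_montage, ROI_CHANNELS, MASTOIDS

#: The five prior-congruence conditions: congruent English, congruent /
#: illusory Italian, incongruent English, incongruent Italian, scrambled words.
CONDITIONS = ("CEng", "CIta", "IEng", "IIta", "SW")


def _default_erp_gains() -> dict[str, dict[str, float]]:
    # P2 gains keep the qualitative ordering IEng > CIta >= CEng,
    # IIta > CIta, IIta < IEng, with SW near the incongruent level.
    return {
        "CEng": {"n1_gain": 1.5, "p2_gain": 1.0},
        "CIta": {"n1_gain": 1.8, "p2_gain": 3.2},
        "IEng": {"n1_gain": 3.5, "p2_gain": 6.0},
        "IIta": {"n1_gain": 3.0, "p2_gain": 5.4},
        "SW": {"n1_gain": 3.0, "p2_gain": 5.2},
    }


def _default_band_dynamics() -> dict[str, dict[str, list]]:
    # Each band holds (start_ms, end_ms, amplitude_uv) burst windows relative
    # to word onset.  Congruent trials are beta-dominated throughout; the
    # illusory condition flips from gamma to beta earlier (250 ms) than the
    # incongruent English condition (450 ms).
    return {
        "CEng": {"beta": [(0, 800, 1.2)], "gamma": [(0, 800, 0.35)]},
        "CIta": {"beta": [(250, 800, 1.1)], "gamma": [(0, 250, 1.1), (250, 800, 0.3)]},
        "IEng": {"beta": [(450, 800, 1.0)], "gamma": [(0, 450, 1.2), (450, 800, 0.3)]},
        "IIta": {"beta": [(500, 800, 0.8)], "gamma": [(0, 500, 1.0), (500, 800, 0.4)]},
        "SW": {"beta": [(400, 800, 0.7)], "gamma": [(0, 400, 0.9), (400, 800, 0.4)]},
    }


def _default_language_covariance() -> dict[str, dict]:
    # One broadband source per language class, mixed into the channels with a
    # lateralized Gaussian topography.  Only the spatial covariance differs
    # between classes; this is the structure CSP is designed to pick up.
    return {
        "english": {"center": (-0.55, 0.05), "sigma": 0.35, "gain_uv": 8.0,
                    "band_hz": (4.0, 30.0)},
        "italian": {"center": (0.55, 0.05), "sigma": 0.35, "gain_uv": 8.0,
                    "band_hz": (4.0, 30.0)},
    }


def _default_condition_language() -> dict[str, tuple[str, float]]:
    # (language class, signature strength) carried by trials of each
    # condition; the illusory condition carries the Italian signature.
    return {
        "CEng": ("english", 1.0),
        "CIta": ("italian", 1.0),
        "IEng": ("english", 0.5),
        "IIta": ("english", 0.5),
        "SW": ("english", 1.2),
    }


def _default_rating_probs() -> dict[str, list[float]]:
    # P(rating = 1, 2, 3): congruent and illusory trials are judged to
    # match, incongruent and scrambled trials are not.
    return {
        "CEng": [0.05, 0.15, 0.80],
        "CIta": [0.10, 0.25, 0.65],
        "IEng": [0.80, 0.15, 0.05],
        "IIta": [0.75, 0.20, 0.05],
        "SW": [0.85, 0.12, 0.03],
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic EEG cohort generator."""

    n_subjects: int = 21
    n_channels: int = 64
    rate_hz: float = 1000.0
    trials_per_condition: int = 20

    #: condition -> {"n1_gain", "p2_gain"} in microvolts.
    erp_gains: dict = field(default_factory=_default_erp_gains)
    #: condition -> band -> list of (start_ms, end_ms, amplitude_uv) bursts.
    band_dynamics: dict = field(default_factory=_default_band_dynamics)
    #: language class -> spatial source specification.
    language_covariance: dict = field(default_factory=_default_language_covariance)
    #: condition -> (language class, signature gain multiplier).
    condition_language: dict = field(default_factory=_default_condition_language)
    #: background-noise model: 1/f^exponent spectrum, squared-exponential
    #: spatial correlation on the idealized layout, per-channel RMS in uV.
    noise: dict = field(default_factory=lambda: {
        "exponent": 1.0, "spatial_scale": 0.35, "amplitude_uv": 10.0})
    #: condition -> probability vector over ratings (1, 2, 3).
    rating_probs: dict = field(default_factory=_default_rating_probs)
    #: probability a song is reported as recognized (all conditions).
    recognized_prob: float = 0.3

    # trial timing (seconds)
    audio_duration_range_s: tuple[float, float] = (1.0, 4.25)
    word_onset_lag_range_s: tuple[float, float] = (0.0, 0.5)
    pre_music_gap_s: float = 0.4
    post_audio_gap_s: float = 1.0

    # audiobook recordings
    audiobook_duration_s: float = 660.0

    # oscillatory burst carriers (Hz); phase-locked so they survive averaging
    beta_carrier_hz: float = 21.0
    gamma_carrier_hz: float = 38.0
    burst_ramp_ms: float = 50.0

    # ERP template shape (half-cosine bumps)
    n1_peak_ms: float = 110.0
    n1_width_ms: float = 60.0
    p2_peak_ms: float = 200.0
    p2_width_ms: float = 100.0
    erp_center: tuple[float, float] = (0.0, 0.0)
    erp_sigma: float = 0.6

    #: std of the per-subject jitter applied to language-source centers.
    subject_pattern_jitter: float = 0.03

    seed: int = 0

    # ------------------------------------------------------------------ #

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        # montage check (raises for unsupported channel counts)
        select_montage(self.n_channels)

        for name, mapping in (
            ("erp_gains", self.erp_gains),
            ("band_dynamics", self.band_dynamics),
            ("condition_language", self.condition_language),
            ("rating_probs", self.rating_probs),
        ):
            for cond in mapping:
                if cond not in CONDITIONS:
                    raise ValueError(
                        f"{name} names unknown condition {cond!r}; "
                        f"valid conditions are {CONDITIONS}"
                    )
            missing = [c for c in CONDITIONS if c not in mapping]
            if missing:
                raise ValueError(f"{name} missing conditions {missing}")

        for cond, gains in self.erp_gains.items():
            for key in ("n1_gain", "p2_gain"):
                v = float(gains[key])
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{cond} {key} must be finite and >= 0")
        for cond, bands in self.band_dynamics.items():
            for band, bursts in bands.items():
                if band not in ("beta", "gamma"):
                    raise ValueError(f"unknown band {band!r} in band_dynamics")
                for (t0, t1, amp) in bursts:
                    if not (np.isfinite(amp) and amp >= 0):
                        raise ValueError("burst amplitudes must be finite and >= 0")
                    if t1 <= t0:
                        raise ValueError("burst end must follow burst start")
        amp = float(self.noise["amplitude_uv"])
        if not np.isfinite(amp) or amp < 0:
            raise ValueError("noise amplitude must be finite and >= 0")
        for cond, probs in self.rating_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (3,) or (p < 0).any():
                raise ValueError(f"rating_probs[{cond!r}] must be 3 nonnegative values")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"rating_probs[{cond!r}] must sum to 1 within 1e-9")
        for lang, spec in self.language_covariance.items():
            if float(spec["gain_uv"]) < 0:
                raise ValueError(f"language_covariance[{lang!r}] gain must be >= 0")
        for cond, (lang, scale) in self.condition_language.items():
            if lang not in self.language_covariance:
                raise ValueError(
                    f"condition_language[{cond!r}] references unknown "
                    f"language class {lang!r}"
                )

    # ------------------------------------------------------------------ #

    @property
    def channel_labels(self) -> list[str]:
        return select_montage(self.n_channels)

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(CONDITIONS)

    @property
    def roi(self) -> tuple[str, ...]:
        return ROI_CHANNELS

    @property
    def mastoids(self) -> tuple[str, ...]:
        return MASTOIDS

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("audio_duration_range_s", "word_onset_lag_range_s",
                    "erp_center"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "condition_language" in d:
            d["condition_language"] = {
                c: tuple(v) for c, v in d["condition_language"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "simulate" in payload:  # shared pipeline config file
            payload = payload["simulate"]
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
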