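"""Idealized 10-20 / 10-10 electrode layout.

Positions live on an abstract unit disk (nose up, +x to the subject's
right).  They are used for the spatial-correlation kernel of the synthetic
background noise and for topographic source/component patterns; no forward
head model is implied.
"""

from __future__ import annotations

import numpy as np

#: Fronto-centro-parietal midline region of interest used for ERP and
#: oscillatory analyses.
ROI_CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz")

#: Mastoid reference electrodes.
MASTOIDS = ("M1", "M2")

# Row layout: (y coordinate, channel labels left -> right).
_ROWS = [
    (0.90, ["Fp1", "Fpz", "Fp2"]),
    (0.70, ["AF7", "AF3", "AFz", "AF4", "AF8"]),
    (0.50, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    (0.25, ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
    (0.00, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    (-0.25, ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
    (-0.50, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    (-0.70, ["PO7", "PO3", "POz", "PO4", "PO8"]),
    (-0.90, ["O1", "Oz", "O2"]),
    (-1.00, ["Iz"]),
]


def _build_positions() -> dict[str, tuple[float, float]]:
    pos: dict[str, tuple[float, float]] = {}
    for y, labels in _ROWS:
        n = len(labels)
        half_width = float(np.sqrt(max(1.15 - y * y, 0.05)))
        for i, lab in enumerate(labels):
            frac = 0.0 if n == 1 else (2.0 * i / (n - 1) - 1.0)
            pos[lab] = (frac * half_width * 0.92, y)
    pos["M1"] = (-1.10, -0.20)
    pos["M2"] = (1.10, -0.20)
    return pos


#: label -> (x, y) on the idealized disk.
POSITIONS: dict[str, tuple[float, float]] = _build_positions()

#: Full 64-channel montage in a fixed canonical order (62 scalp + M1, M2).
CHANNELS_64: tuple[str, ...] = tuple(
    lab for _, labels in _ROWS for lab in labels
) + MASTOIDS

# Priority order used when a reduced montage is requested: the analysis ROI
# and the mastoid references always come first.
_PRIORITY = list(ROI_CHANNELS) + list(MASTOIDS) + [
    "F3", "F4", "C3", "C4", "P3", "P4", "T7", "T8",
    "O1", "Oz", "O2", "Fp1", "Fp2", "FC3", "FC4", "CP3", "CP4",
]


def select_montage(n_channels: int) -> list[str]:
    """Return ``n_channels`` labels; ROI channels and mastoids are always kept.

    ``n_channels`` must be at least 7 (five ROI channels plus M1/M2) and at
    most 64.
    """
    if not 7 <= n_channels <= len(CHANNELS_64):
        raise ValueError(
            f"n_channels must be in [7, {len(CHANNELS_64)}], got {n_channels}"
        )
    if n_channels == len(CHANNELS_64):
        return list(CHANNELS_64)
    chosen: list[str] = []
    for lab in _PRIORITY + list(CHANNELS_64):
        if lab not in chosen:
            chosen.append(lab)
        if len(chosen) == n_channels:
            break
    # report in canonical order for stable channel indexing
    return [lab for lab in CHANNELS_64 if lab in chosen]


def positions_array(labels: list[str] | tuple[str, ...]) -> np.ndarray:
    """(n_channels, 2) coordinates for ``labels``."""
    try:
        return np.array([POSITIONS[lab] for lab in labels], dtype=float)
    except KeyError as err:
        raise KeyError(f"unknown channel label {err.args[0]!r}") from None


def gaussian_pattern(
    labels: list[str] | tuple[str, ...],
    center: tuple[float, float],
    sigma: float,
) -> np.ndarray:
    """Unit-peak Gaussian spatial pattern over ``labels`` centred at ``center``."""
    xy = positions_array(labels)
    d2 = np.sum((xy - np.asarray(center, dtype=float)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def spatial_kernel(
    labels: list[str] | tuple[str, ...], correlation_length: float
) -> np.ndarray:
    """Squared-exponential channel correlation kernel on the idealized layout."""
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    xy = positions_array(labels)
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * correlation_length**2))
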