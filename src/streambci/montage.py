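"""Electrode montage: the 64 recorded EEG labels, EOG labels, and 2-D positions.

Positions come from the standard 10-10 template and are used only to build
plausible scalp topographies for the synthetic ERP components; no spatial
claim in the analysis depends on their exact values.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 64 EEG channels of the recording setup, in acquisition order.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Vertical and horizontal electrooculogram channels.
EOG_CHANNELS: tuple[str, ...] = ("vEOG", "hEOG")

ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS


def channel_types(labels: "list[str] | tuple[str, ...]" = ALL_CHANNELS) -> list[str]:
    """Return 'EEG'/'EOG' for each label (EOG detected by name)."""
    return ["EOG" if lab in EOG_CHANNELS or "EOG" in lab.upper() else "EEG"
            for lab in labels]


@lru_cache(maxsize=1)
def positions_2d() -> dict[str, np.ndarray]:
    """2-D head-plane coordinates (metres, nose along +y) for the EEG labels."""
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older template name
        montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    return {lab: np.asarray(pos3d[lab][:2], dtype=float) for lab in EEG_CHANNELS}


def gaussian_scalp_map(center: str, sigma_m: float = 0.045,
                       labels: "tuple[str, ...]" = ALL_CHANNELS) -> np.ndarray:
    """Unit-peak Gaussian weight over channels, centred on an EEG electrode.

    EOG channels receive weight 0 — cortical components do not project onto
    the ocular leads in this model.  ``sigma_m`` is the spatial half-width
    parameter in metres on the 2-D projected head.
    """
    pos = positions_2d()
    if center not in pos:
        raise ValueError(f"unknown montage channel: {center!r}")
    c = pos[center]
    weights = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab in pos:
            d2 = float(np.sum((pos[lab] - c) ** 2))
            weights[i] = np.exp(-d2 / (2.0 * sigma_m**2))
    peak = np.max(np.abs(weights))
    if peak > 0:
        weights /= peak
    return weights
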