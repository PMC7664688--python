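"""The 21-channel extended 10-20 montage used throughout the package.

Positions are approximate unit-sphere coordinates (x = right, y = anterior,
z = superior) of the standard 10-20 placements; they are used only for
distance-weighted interpolation of rejected channels, where centimetre-level
accuracy is irrelevant.
"""

from __future__ import annotations

import numpy as np

#: Channel order is fixed package-wide; feature columns follow it.
CHANNELS_1020: tuple[str, ...] = (
    "FP1", "FPz", "FP2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

_S = np.sin
_C = np.cos


def _pos(azimuth_deg: float, inclination_deg: float) -> tuple[float, float, float]:
    # azimuth measured from anterior midline, positive to the right;
    # inclination measured from the vertex (Cz).
    az = np.deg2rad(azimuth_deg)
    inc = np.deg2rad(inclination_deg)
    return (float(_S(inc) * _S(az)), float(_S(inc) * _C(az)), float(_C(inc)))


#: unit-sphere electrode positions, keyed by channel name
POSITIONS: dict[str, tuple[float, float, float]] = {
    "FP1": _pos(-18, 90), "FPz": _pos(0, 90), "FP2": _pos(18, 90),
    "F7": _pos(-54, 90), "F8": _pos(54, 90),
    "F3": _pos(-39, 60), "Fz": _pos(0, 45), "F4": _pos(39, 60),
    "T3": _pos(-90, 90), "T4": _pos(90, 90),
    "C3": _pos(-90, 45), "Cz": _pos(0, 0), "C4": _pos(90, 45),
    "T5": _pos(-126, 90), "T6": _pos(126, 90),
    "P3": _pos(-141, 60), "Pz": _pos(180, 45), "P4": _pos(141, 60),
    "O1": _pos(-162, 90), "Oz": _pos(180, 90), "O2": _pos(162, 90),
}

#: named channel subsets for the restricted-montage analyses
CHANNEL_SUBSETS: dict[str, tuple[str, ...]] = {
    "frontopolar": ("FP1", "FPz", "FP2"),   # Brodmann area 10
    "mid_frontal": ("F3", "Fz", "F4"),      # middle frontal gyrus
    "all": CHANNELS_1020,
}


def position_array(names: tuple[str, ...] = CHANNELS_1020) -> np.ndarray:
    """(n, 3) array of electrode positions for ``names``."""
    return np.array([POSITIONS[n] for n in names], dtype=float)


def validate_channels(names) -> list[str]:
    """Check channel names against the montage; raise with the valid list."""
    bad = [n for n in names if n not in CHANNELS_1020]
    if bad:
        raise ValueError(
            f"unknown channel name(s) {bad}; valid names: {list(CHANNELS_1020)}"
        )
    return list(names)
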