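"""Shared containers for calibrated multi-channel spindle images.

All spatial quantities carry explicit µm units. Pixel convention: (row, col)
indices, 0-based, pixel centers at integer coordinates, physical position =
index × ``pixel_size_um``. Channel roles are free-form strings; the four the
simulator and pipeline use throughout are ``pole`` (γ-tubulin), ``tubulin``
(α-tubulin), ``dna`` (DNA or centromere marker) and ``motor`` (KIF18A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: FWHM of a Gaussian with unit standard deviation: 2·sqrt(2·ln 2).
FWHM_FACTOR: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Channel order used by the simulator and the TIFF writer.
CHANNEL_ROLES: tuple[str, ...] = ("pole", "tubulin", "dna", "motor")


@dataclass
class SpindleImage:
    """Calibrated multi-channel 2D fluorescence image.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, rows, cols)``, photon-count scale.
    channels
        Channel role for each plane of ``data``, in order.
    pixel_size_um
        Physical pixel pitch in µm (square pixels).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError(
                f"image data must be (channels, rows, cols); got shape {self.data.shape}"
            )
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} planes but {len(self.channels)} channel roles"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def shape_um(self) -> tuple[float, float]:
        r, c = self.shape_px
        return (r - 1) * self.pixel_size_um, (c - 1) * self.pixel_size_um

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D plane for a channel role."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not present; available: {self.channels}"
            ) from None
        return self.data[idx]

    def has_channel(self, role: str) -> bool:
        return role in self.channels

    def contains_um(self, point_um: tuple[float, float]) -> bool:
        """True if a (row_um, col_um) point lies inside the image bounds."""
        r_um, c_um = self.shape_um
        return 0.0 <= point_um[0] <= r_um and 0.0 <= point_um[1] <= c_um


@dataclass
class TimeLapse:
    """Ordered multi-channel frames with timestamps relative to treatment.

    ``timestamps_s[i] = (i − treatment_frame) · frame_interval_s``, so the
    treatment frame has timestamp 0 and pre-treatment frames are negative.
    """

    frames: list[SpindleImage]
    timestamps_s: np.ndarray
    treatment_frame: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if len(self.frames) != self.timestamps_s.size:
            raise ValueError("one timestamp per frame required")
        if len(self.frames) < 2:
            raise ValueError("a time lapse needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um

    def frame_at(self, t_s: float) -> tuple[int, SpindleImage]:
        """Frame nearest (in time) to ``t_s`` seconds relative to treatment."""
        idx = int(np.argmin(np.abs(self.timestamps_s - t_s)))
        return idx, self.frames[idx]
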