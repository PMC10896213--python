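"""Pole-anchored line-scan profiling of motor localization.

Implements the fixed-width line-scan procedure used to quantify where the
KIF18A motor sits along a half-spindle: a line is anchored at a γ-tubulin
pole signal and drawn toward the spindle center; intensities of every
channel along that line are recorded (averaging over a perpendicular
width), normalized internally to their own maxima, aligned across cells on
the reference-channel (pole) peak, averaged, and summarized by the distance
from the pole to the maximum motor signal.

Sampling follows the Fiji wide-line convention: samples at pixel-pitch
steps along the line, each the mean of ``width_px`` bilinear sub-samples
spaced one pixel apart perpendicular to the line, centered on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import SpindleImage

#: Fraction of scans that must cover a position for it to enter the mean profile.
DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class LineScan:
    """Per-channel intensity versus distance along one sampling line.

    ``positions_um`` start at 0 at the pole-end anchor and increase toward
    the spindle center with uniform (pixel-pitch) spacing.
    """

    positions_um: np.ndarray
    intensities: dict[str, np.ndarray]
    width_px: int
    source_cell_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.ndim != 1 or self.positions_um.size < 2:
            raise ValueError("positions_um must be a 1D vector of >= 2 samples")
        steps = np.diff(self.positions_um)
        if np.any(steps <= 0):
            raise ValueError("positions_um must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("positions_um must be uniformly spaced")
        self.intensities = {k: np.asarray(v, dtype=float) for k, v in self.intensities.items()}
        for role, v in self.intensities.items():
            if v.shape != self.positions_um.shape:
                raise ValueError(f"channel {role!r} length does not match positions")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    @property
    def pitch_um(self) -> float:
        return float(self.positions_um[1] - self.positions_um[0])

    def channel(self, role: str) -> np.ndarray:
        if role not in self.intensities:
            raise KeyError(f"channel role {role!r} not present in scan "
                           f"{self.source_cell_id!r}; available: {sorted(self.intensities)}")
        return self.intensities[role]


@dataclass
class AlignedScanSet:
    """Scans shifted to a common axis with the reference peak at position 0."""

    scans: list[LineScan]
    alignment_channel: str
    mean_positions_um: np.ndarray
    mean_profile: dict[str, np.ndarray]
    n_scans: int
    meta: dict = field(default_factory=dict)


def extract_profile(
    image: SpindleImage,
    anchor_um: tuple[float, float],
    toward_um: tuple[float, float],
    length_um: float,
    width_px: int = 10,
    cell_id: str = "",
) -> LineScan:
    """Sample a fixed-width line scan from ``anchor_um`` toward ``toward_um``.

    Samples are taken at pixel-pitch steps; each reported value is the mean
    of ``width_px`` bilinear samples perpendicular to the line, centered on
    it. Raises if any sample falls outside the image, naming the first
    out-of-bounds arclength.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if length_um <= 0:
        raise ValueError("length_um must be > 0")
    d = np.array([toward_um[0] - anchor_um[0], toward_um[1] - anchor_um[1]], dtype=float)
    norm = math.hypot(*d)
    if norm == 0:
        raise ValueError("zero-length direction: anchor and toward coincide")
    u = d / norm                      # along-line unit vector (row, col)
    v = np.array([-u[1], u[0]])       # perpendicular unit vector

    px = image.pixel_size_um
    n_steps = int(math.floor(length_um / px + 1e-9)) + 1
    arclengths = np.arange(n_steps) * px
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * px

    anchor = np.asarray(anchor_um, dtype=float)
    # sample grid in µm: (n_steps, width_px, 2)
    pts = (anchor[None, None, :]
           + arclengths[:, None, None] * u[None, None, :]
           + offsets[None, :, None] * v[None, None, :])
    coords_px = pts / px
    rows, cols = image.shape_px
    out = ((coords_px[..., 0] < 0) | (coords_px[..., 0] > rows - 1)
           | (coords_px[..., 1] < 0) | (coords_px[..., 1] > cols - 1))
    if out.any():
        bad = int(np.argmax(out.any(axis=1)))
        raise ValueError(
            f"line leaves the image: first out-of-bounds sample at arclength "
            f"{arclengths[bad]:.3f} µm (of {length_um} µm requested)"
        )

    flat = coords_px.reshape(-1, 2).T
    intensities = {}
    for role in image.channels:
        vals = ndimage.map_coordinates(image.channel(role), flat, order=1, mode="nearest")
        intensities[role] = vals.reshape(n_steps, width_px).mean(axis=1)
    return LineScan(arclengths, intensities, width_px, source_cell_id=cell_id)


def normalize_internal(scan: LineScan) -> LineScan:
    """Divide each channel by its own maximum (internal normalization).

    Maxima become exactly 1; positions are unchanged. Raises for a channel
    with non-positive maximum (degenerate profile), naming the channel.
    """
    normed = {}
    for role, vals in scan.intensities.items():
        m = vals.max()
        if m <= 0:
            raise ValueError(f"channel {role!r} has non-positive maximum; "
                             "cannot normalize a degenerate profile")
        normed[role] = vals / m
    return replace(scan, intensities=normed, meta=dict(scan.meta, normalized=True))


def detect_pole_anchor(
    image: SpindleImage,
    roi: tuple[int, int, int, int] | None = None,
    channel: str = "pole",
) -> tuple[float, float]:
    """Locate a pole as the global maximum of the 3×3-mean-smoothed pole channel.

    ``roi`` restricts the search to pixel rows [r0, r1) and columns
    [c0, c1). Ties resolve to the smallest row, then smallest column.
    Returns (row_um, col_um).
    """
    plane = ndimage.uniform_filter(image.channel(channel), size=3, mode="nearest")
    r0, c0 = 0, 0
    if roi is not None:
        r0, c0, r1, c1 = roi
        plane = plane[r0:r1, c0:c1]
        if plane.size == 0:
            raise ValueError("empty ROI for pole detection")
    idx = np.unravel_index(int(np.argmax(plane)), plane.shape)  # first occurrence: min row, then col
    return ((idx[0] + r0) * image.pixel_size_um, (idx[1] + c0) * image.pixel_size_um)


def align_scans(
    scans: Sequence[LineScan],
    reference: str = "pole",
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> AlignedScanSet:
    """Shift each scan so its reference-channel peak sits at position 0, then average.

    The mean profile is the pointwise mean over all scans covering each
    position; positions covered by fewer than ``min_coverage`` of the scans
    are dropped. All scans must share the reference channel and pitch.
    """
    if len(scans) == 0:
        raise ValueError("align_scans requires at least one scan")
    pitch = scans[0].pitch_um
    shifted: list[LineScan] = []
    for s in scans:
        if reference not in s.intensities:
            raise ValueError(f"reference channel {reference!r} missing from scan "
                             f"{s.source_cell_id!r}")
        if not math.isclose(s.pitch_um, pitch, rel_tol=1e-9):
            raise ValueError("all scans must share the same sampling pitch")
        peak = int(np.argmax(s.channel(reference)))
        shift = s.positions_um[peak]
        shifted.append(replace(s, positions_um=s.positions_um - shift,
                               meta=dict(s.meta, alignment_shift_um=float(shift))))

    # accumulate on an integer pitch grid (positions are pitch multiples)
    idx_lists = [np.round(s.positions_um / pitch).astype(int) for s in shifted]
    lo = min(int(i[0]) for i in idx_lists)
    hi = max(int(i[-1]) for i in idx_lists)
    grid_len = hi - lo + 1
    channels = sorted(set.intersection(*(set(s.intensities) for s in shifted)))
    sums = {role: np.zeros(grid_len) for role in channels}
    counts = np.zeros(grid_len)
    for s, idx in zip(shifted, idx_lists):
        sl = slice(idx[0] - lo, idx[-1] - lo + 1)
        counts[sl] += 1
        for role in channels:
            sums[role][sl] += s.channel(role)

    keep = counts >= min_coverage * len(shifted) - 1e-9
    if not keep.any():
        raise ValueError("no positions satisfy the coverage requirement")
    positions = (np.arange(lo, hi + 1)[keep]) * pitch
    mean_profile = {role: sums[role][keep] / counts[keep] for role in channels}
    return AlignedScanSet(shifted, reference, positions, mean_profile, len(shifted))


def distance_to_max(
    scan_or_set: LineScan | AlignedScanSet,
    target: str = "motor",
) -> float:
    """Distance (µm) from the aligned pole position to the target-channel maximum.

    For a single aligned scan, this is the position of the target channel's
    global maximum; for an :class:`AlignedScanSet` the mean profile is used.
    Ties resolve to the smaller distance (closest to the pole); a tie is
    recorded in the object's metadata. A flat target channel raises.
    """
    if isinstance(scan_or_set, AlignedScanSet):
        if target not in scan_or_set.mean_profile:
            raise KeyError(f"target channel {target!r} not in mean profile")
        positions = scan_or_set.mean_positions_um
        vals = scan_or_set.mean_profile[target]
        meta = scan_or_set.meta
    else:
        positions = scan_or_set.positions_um
        vals = scan_or_set.channel(target)
        meta = scan_or_set.meta
    if np.ptp(vals) == 0:
        raise ValueError(f"target channel {target!r} is flat: no unique maximum")
    peak = int(np.argmax(vals))  # first occurrence = smallest distance
    if np.count_nonzero(vals == vals[peak]) > 1:
        meta["distance_to_max_tie"] = True
    return float(positions[peak])


def distances_for_set(aligned: AlignedScanSet, target: str = "motor") -> np.ndarray:
    """Per-scan distance-to-max for every member of an aligned set."""
    return np.array([distance_to_max(s, target) for s in aligned.scans])
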