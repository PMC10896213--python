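"""Live-cell motor relocalization: final/initial ratio profiles and AUC.

For each cell, the motor-channel fluorescence profile across a rectangular
spindle ROI is measured at an initial timepoint (before treatment) and a
final timepoint (after treatment). Both profiles are resampled onto a
common 0–100% spindle-length grid, divided pointwise (final/initial), and
the ratio curve is summarized by its trapezoidal area under the curve over
[0, 100] with baseline y = 0. An untreated cell gives ratio ≡ 1 and
AUC = 100; a central gap pulls the mid-spindle ratio below 1 while pole
accumulation pushes the ends above it.

Profiles are kept in raw intensity units — no internal normalization —
because the ratio requires commensurate scales between timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpindleImage, TimeLapse

DEFAULT_GRID_POINTS = 101
DEFAULT_T_INITIAL_S = -90.0
DEFAULT_T_FINAL_S = 720.0
#: Denominator floor, as a fraction of the initial profile's mean intensity.
DENOMINATOR_FLOOR_FRACTION = 0.01


@dataclass
class RatioProfile:
    """Final/initial fluorescence ratio versus percent spindle length."""

    percent_length: np.ndarray
    ratio: np.ndarray
    cell_id: str = ""
    t_initial_s: float = DEFAULT_T_INITIAL_S
    t_final_s: float = DEFAULT_T_FINAL_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.percent_length = np.asarray(self.percent_length, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.percent_length.shape != self.ratio.shape:
            raise ValueError("grid and ratio must have the same length")
        if self.percent_length[0] != 0.0 or self.percent_length[-1] != 100.0:
            raise ValueError("percent_length grid must cover [0, 100] inclusive")
        steps = np.diff(self.percent_length)
        if not np.allclose(steps, steps[0]):
            raise ValueError("percent_length grid must be uniform")
        if np.any(self.ratio <= 0):
            raise ValueError("ratio must be positive everywhere (guarded denominator)")

    @property
    def auc(self) -> float:
        """Trapezoidal integral of the ratio over [0, 100] percent length."""
        return float(np.trapezoid(self.ratio, self.percent_length))


def project_z(stack: np.ndarray, method: str = "max") -> np.ndarray:
    """Project a z-stack (z, rows, cols) to a single plane (max or mean)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("z projection expects a (z, rows, cols) stack")
    if method == "max":
        return stack.max(axis=0)
    if method == "mean":
        return stack.mean(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


def spindle_profile_at(
    frame: SpindleImage,
    roi: tuple[int, int, int, int],
    channel: str = "motor",
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean intensity across a rectangular spindle ROI.

    ``roi`` is (row0, col0, row1, col1) in pixels, half-open, with the
    spindle long axis along the columns. Returns (positions_um, intensity)
    in raw units.
    """
    r0, c0, r1, c1 = roi
    rows, cols = frame.shape_px
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"ROI {roi} falls outside the {rows}x{cols} frame")
    sub = frame.channel(channel)[r0:r1, c0:c1]
    positions_um = np.arange(c1 - c0) * frame.pixel_size_um
    return positions_um, sub.mean(axis=0)


def ratio_profile(
    initial: tuple[np.ndarray, np.ndarray],
    final: tuple[np.ndarray, np.ndarray],
    grid_points: int = DEFAULT_GRID_POINTS,
    cell_id: str = "",
    t_initial_s: float = DEFAULT_T_INITIAL_S,
    t_final_s: float = DEFAULT_T_FINAL_S,
) -> RatioProfile:
    """Resample two profiles to a percent-length grid and divide final by initial.

    Each profile is mapped onto its own 0–100% spindle-length scale by
    linear interpolation (so spindles of different length are comparable),
    then divided pointwise. The denominator is floored at 1% of the initial
    profile's mean; floor hits are counted in the result metadata. Profiles
    whose physical lengths differ by more than 2× are rejected as grossly
    mismatched ROIs.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    (xi, yi), (xf, yf) = initial, final
    xi = np.asarray(xi, float); yi = np.asarray(yi, float)
    xf = np.asarray(xf, float); yf = np.asarray(yf, float)
    if xi.size < 2 or xf.size < 2:
        raise ValueError("profiles need at least 2 samples")
    len_i, len_f = xi[-1] - xi[0], xf[-1] - xf[0]
    if len_i <= 0 or len_f <= 0:
        raise ValueError("profile positions must be increasing")
    if max(len_i, len_f) / min(len_i, len_f) > 2.0:
        raise ValueError(
            f"grossly mismatched ROIs: profile lengths {len_i:.2f} and {len_f:.2f} µm "
            "differ by more than 2x"
        )
    if yi.mean() <= 0 or yf.mean() <= 0:
        raise ValueError("profiles must have positive mean intensity")

    grid = np.linspace(0.0, 100.0, grid_points)
    init_r = np.interp(grid, (xi - xi[0]) / len_i * 100.0, yi)
    fin_r = np.interp(grid, (xf - xf[0]) / len_f * 100.0, yf)
    floor = DENOMINATOR_FLOOR_FRACTION * yi.mean()
    floored = int(np.count_nonzero(init_r < floor))
    ratio = fin_r / np.maximum(init_r, floor)
    meta = {"denominator_floor": floor, "floored_points": floored}
    return RatioProfile(grid, ratio, cell_id=cell_id,
                        t_initial_s=t_initial_s, t_final_s=t_final_s, meta=meta)


def auc(rp: RatioProfile) -> float:
    """Area under the ratio curve over [0, 100] percent length, baseline 0."""
    return rp.auc


def relocalization_auc(
    timelapse: TimeLapse,
    roi: tuple[int, int, int, int],
    channel: str = "motor",
    t_initial_s: float = DEFAULT_T_INITIAL_S,
    t_final_s: float = DEFAULT_T_FINAL_S,
    grid_points: int = DEFAULT_GRID_POINTS,
    cell_id: str = "",
) -> RatioProfile:
    """Per-cell pipeline: pick initial/final frames, profile the ROI, ratio them.

    The frames nearest the requested timepoints (seconds relative to
    treatment) are used; the actual timestamps land in the result.
    """
    i0, frame0 = timelapse.frame_at(t_initial_s)
    i1, frame1 = timelapse.frame_at(t_final_s)
    t0 = float(timelapse.timestamps_s[i0])
    t1 = float(timelapse.timestamps_s[i1])
    if not t0 < 0.0 < t1:
        raise ValueError(
            f"initial/final frames must straddle treatment: got t_initial={t0} s, "
            f"t_final={t1} s"
        )
    prof0 = spindle_profile_at(frame0, roi, channel=channel)
    prof1 = spindle_profile_at(frame1, roi, channel=channel)
    return ratio_profile(prof0, prof1, grid_points=grid_points, cell_id=cell_id,
                         t_initial_s=t0, t_final_s=t1)
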