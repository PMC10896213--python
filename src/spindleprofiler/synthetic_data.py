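"""Synthetic spindle images, time lapses, count tables, growth and dose data.

Every generator in this module produces (artifact, manifest) pairs: the
manifest records the hidden truths (spindle length, chromosome-band FWHM,
motor peak offset, growth fold change, IC50) so each downstream measurement
can be tested by parameter recovery with no external data.

Image model
-----------
Channels are rendered as sums of 2D Gaussian sources on a calibrated pixel
grid — single focal plane, no PSF convolution, no z:

* ``pole``    one isotropic spot per spindle pole (γ-tubulin analogue);
* ``dna``     a band centered at the spindle midpoint, narrow along the
  pole-to-pole axis (axial σ = ``dna_band_sigma_um``) and wide across it —
  the metaphase plate;
* ``motor``   one peak per principal pole, placed ``motor_peak_offset_um``
  from that pole along the axis toward the spindle center. A large offset
  is the plus-end-tip phenotype; an offset near 0 is pole accumulation;
* ``tubulin`` an anisotropic fan between the poles (elongated Gaussian).

Amplitudes are peak photon counts; a constant background is added per
channel, and noise (Poisson on the expected counts, or additive Gaussian)
is applied last using the spec's seed. With ``noise_model="none"`` the
renders are deterministic and per-channel pixel sums match the analytic
Gaussian masses to truncation accuracy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FWHM_FACTOR, CHANNEL_ROLES, SpindleImage, TimeLapse

# Fixed render-geometry defaults (µm). The paper-facing parameters (band
# sigma, motor offset, ...) live in the specs; these shape constants only
# set the transverse extent of sources and are not measured by the pipeline.
DNA_TRANSVERSE_SIGMA_UM = 3.0
TUBULIN_TRANSVERSE_SIGMA_UM = 1.5
MULTIPOLAR_MIN_SEPARATION_UM = 2.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SpindleSpec:
    """Parameters of one rendered spindle image.

    Coordinates are (row_um, col_um); both poles and every derived source
    must land inside the image. ``channel_amplitudes`` maps the channel role
    to its peak photon count.
    """

    image_shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = 0.1
    pole_a: tuple[float, float] = (8.0, 2.0)
    pole_b: tuple[float, float] = (8.0, 14.0)
    pole_spot_sigma_um: float = 0.5
    channel_amplitudes: dict = field(
        default_factory=lambda: {"pole": 200.0, "tubulin": 100.0, "dna": 150.0, "motor": 120.0}
    )
    dna_band_sigma_um: float = 1.5
    motor_peak_offset_um: float = 3.5
    motor_peak_sigma_um: float = 0.6
    background: float = 10.0
    noise_model: str = "poisson"  # "none" | "poisson" | "gaussian"
    gaussian_sd: float = 0.0
    n_poles: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 2 or cols < 2:
            raise ValueError("image_shape must be at least 2x2 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if tuple(self.pole_a) == tuple(self.pole_b):
            raise ValueError("pole_a and pole_b must be distinct")
        bounds = ((rows - 1) * self.pixel_size_um, (cols - 1) * self.pixel_size_um)
        for name, p in (("pole_a", self.pole_a), ("pole_b", self.pole_b)):
            if not (0 <= p[0] <= bounds[0] and 0 <= p[1] <= bounds[1]):
                raise ValueError(f"{name} at {p} µm lies outside image bounds {bounds} µm")
        for sig_name in ("pole_spot_sigma_um", "dna_band_sigma_um", "motor_peak_sigma_um"):
            if getattr(self, sig_name) <= 0:
                raise ValueError(f"{sig_name} must be > 0")
        for role, amp in self.channel_amplitudes.items():
            if amp < 0:
                raise ValueError(f"negative amplitude for channel {role!r}")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.motor_peak_offset_um < 0:
            raise ValueError("motor_peak_offset_um must be >= 0")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model == "gaussian" and self.gaussian_sd <= 0:
            raise ValueError("gaussian noise requires gaussian_sd > 0")
        if self.n_poles < 2:
            raise ValueError("n_poles must be >= 2")

    @property
    def spindle_length_um(self) -> float:
        return float(math.dist(self.pole_a, self.pole_b))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["pole_a"] = list(self.pole_a)
        d["pole_b"] = list(self.pole_b)
        return d


@dataclass
class TimeLapseSpec:
    """A spindle rendered over time with a treatment applied at one frame.

    After treatment, motor signal within ``gap_halfwidth_um(t)`` of the
    spindle midpoint (axial distance) is suppressed, and a motor component
    located at the poles grows by ``pole_gain(t)`` — emulating loss of the
    motor from microtubule plus-ends and its accumulation at spindle poles.
    Both treatment functions take seconds after treatment and must be
    non-decreasing; before treatment they do not apply.
    """

    base: SpindleSpec
    frame_interval_s: float = 30.0
    n_frames: int = 28
    treatment_frame: int = 3
    gap_halfwidth_um: Callable[[float], float] | float = 0.0
    pole_gain: Callable[[float], float] | float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("a time lapse needs n_frames >= 2")
        if not (0 <= self.treatment_frame < self.n_frames):
            raise ValueError("treatment_frame must lie in [0, n_frames)")
        ts = self.post_treatment_times_s()
        gaps = [self.gap_at(t) for t in ts]
        gains = [self.gain_at(t) for t in ts]
        if any(np.diff(gaps) < -1e-12):
            raise ValueError("gap_halfwidth_um must be non-decreasing after treatment")
        if any(np.diff(gains) < -1e-12):
            raise ValueError("pole_gain must be non-decreasing after treatment")
        if gaps and gaps[0] < 0:
            raise ValueError("gap_halfwidth_um must be >= 0")
        if gains and gains[0] < 0:
            raise ValueError("pole_gain must be >= 0")

    def post_treatment_times_s(self) -> np.ndarray:
        idx = np.arange(self.treatment_frame, self.n_frames)
        return (idx - self.treatment_frame) * self.frame_interval_s

    def gap_at(self, t_s: float) -> float:
        g = self.gap_halfwidth_um
        return float(g(t_s)) if callable(g) else float(g)

    def gain_at(self, t_s: float) -> float:
        g = self.pole_gain
        return float(g(t_s)) if callable(g) else float(g)


def linear_ramp(rate_per_s: float, start: float = 0.0, cap: float = math.inf) -> Callable[[float], float]:
    """Non-decreasing ramp ``min(start + rate·t, cap)`` for treatment dynamics."""
    if rate_per_s < 0:
        raise ValueError("rate_per_s must be >= 0")

    def ramp(t_s: float) -> float:
        return min(start + rate_per_s * max(t_s, 0.0), cap)

    return ramp


@dataclass
class PopulationSpec:
    """Per-field cell-count sampling model for mitotic-index experiments."""

    n_fields: int = 20
    cells_per_field_mean: float = 100.0
    p_mitotic: float = 0.05
    p_multipolar_given_mitotic: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self.cells_per_field_mean <= 0:
            raise ValueError("cells_per_field_mean must be > 0")
        for name in ("p_mitotic", "p_multipolar_given_mitotic"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GrowthSpec:
    """Logistic proliferation model sampled at a fixed imaging cadence.

    ``doubling_time_h = inf`` models an arrested population;
    ``carrying_capacity = inf`` reduces the model to pure exponential growth.
    """

    n0: float = 100.0
    doubling_time_h: float = 24.0
    carrying_capacity: float = math.inf
    sample_interval_h: float = 2.0
    horizon_h: float = 120.0
    count_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be > 0 (inf for arrest)")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be > 0 (inf for exponential)")
        if self.sample_interval_h <= 0:
            raise ValueError("sample_interval_h must be > 0")
        if self.horizon_h < self.sample_interval_h:
            raise ValueError("horizon_h must be >= sample_interval_h")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")


@dataclass
class DoseSpec:
    """4PL inhibition curve with replicate noise and control wells.

    ``signal(c) = bottom + (top − bottom) / (1 + (c / ic50)^hill)`` — the
    uninhibited luminescence ``top`` decays to ``bottom`` with a variable
    Hill slope. Concentrations follow the assay's serial-dilution layout.
    """

    top: float = 100.0
    bottom: float = 0.0
    ic50: float = 8.2
    hill: float = 1.0
    concentrations: Sequence[float] = field(
        default_factory=lambda: tuple(1000.0 / 4.0 ** k for k in range(10))
    )
    replicate_sd: float = 0.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.concentrations = tuple(sorted(float(c) for c in self.concentrations))
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def signal_at(self, c: float) -> float:
        return self.bottom + (self.top - self.bottom) / (1.0 + (c / self.ic50) ** self.hill)


# ---------------------------------------------------------------------------
# Ground-truth manifest
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    """Hidden parameters of one rendered artifact, for recovery testing.

    Exactly one manifest accompanies each generated artifact. ``spec`` is a
    JSON-serializable snapshot of the generating spec; the ``true_*`` fields
    are the derived quantities the pipeline is supposed to recover.
    """

    kind: str
    spec: dict
    true_spindle_length_um: float | None = None
    true_dna_fwhm_um: float | None = None
    true_motor_offset_um: float | None = None
    pole_positions_um: list | None = None
    n_poles: int | None = None
    timestamps_s: list | None = None
    gap_halfwidth_um: list | None = None
    pole_gain: list | None = None
    true_fold_change: float | None = None
    true_ic50_nM: float | None = None

    def __post_init__(self) -> None:
        for name in ("true_spindle_length_um", "true_dna_fwhm_um",
                     "true_motor_offset_um", "true_fold_change", "true_ic50_nM"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"manifest truth {name} must be finite, got {v}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class _Source:
    """One elliptical 2D Gaussian source: peak amplitude, µm geometry."""

    name: str
    channel: str
    center_um: tuple[float, float]
    sigma_par_um: float
    sigma_perp_um: float
    axis: tuple[float, float]  # unit vector (row, col) of the 'parallel' direction
    amplitude: float

    def mass_photons(self, pixel_size_um: float) -> float:
        """Analytic integral of the source over the plane, in photon·pixels."""
        return self.amplitude * 2.0 * math.pi * self.sigma_par_um * self.sigma_perp_um / pixel_size_um ** 2

    def render(self, row_um: np.ndarray, col_um: np.ndarray) -> np.ndarray:
        dr = row_um - self.center_um[0]
        dc = col_um - self.center_um[1]
        u = dr * self.axis[0] + dc * self.axis[1]
        v = -dr * self.axis[1] + dc * self.axis[0]
        return self.amplitude * np.exp(
            -(u ** 2) / (2.0 * self.sigma_par_um ** 2) - (v ** 2) / (2.0 * self.sigma_perp_um ** 2)
        )


def _axis_unit(pole_a, pole_b) -> tuple[float, float]:
    d = (pole_b[0] - pole_a[0], pole_b[1] - pole_a[1])
    n = math.hypot(*d)
    return d[0] / n, d[1] / n


def _extra_pole_positions(spec: SpindleSpec) -> list[tuple[float, float]]:
    """Place poles 3..n off-axis around the spindle midpoint.

    Extra poles sit at radius max(L/2, 2 µm) from the midpoint at angles
    >= 45° away from the main axis, alternating sides, so every pair of
    poles is separated by >= 2 µm and pole counting is unambiguous.
    """
    a, b = spec.pole_a, spec.pole_b
    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    base_angle = math.atan2(b[0] - mid[0], b[1] - mid[1])
    radius = max(spec.spindle_length_um / 2.0, MULTIPOLAR_MIN_SEPARATION_UM)
    offsets_deg = [90.0, -90.0, 135.0, -135.0, 67.5, -67.5]
    n_extra = spec.n_poles - 2
    if n_extra > len(offsets_deg):
        raise ValueError(f"n_poles={spec.n_poles} exceeds the supported maximum of {2 + len(offsets_deg)}")
    poles = []
    for k in range(n_extra):
        ang = base_angle + math.radians(offsets_deg[k])
        poles.append((mid[0] + radius * math.sin(ang), mid[1] + radius * math.cos(ang)))
    return poles


def _spindle_sources(spec: SpindleSpec) -> list[_Source]:
    amps = {role: float(spec.channel_amplitudes.get(role, 0.0)) for role in CHANNEL_ROLES}
    a, b = tuple(spec.pole_a), tuple(spec.pole_b)
    axis = _axis_unit(a, b)
    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    L = spec.spindle_length_um
    poles = [a, b] + _extra_pole_positions(spec)

    sources: list[_Source] = []
    for i, p in enumerate(poles):
        sources.append(_Source(f"pole_{i}", "pole", p, spec.pole_spot_sigma_um,
                               spec.pole_spot_sigma_um, axis, amps["pole"]))
    # metaphase plate: narrow along the axis, wide across it
    sources.append(_Source("dna_band", "dna", mid, spec.dna_band_sigma_um,
                           DNA_TRANSVERSE_SIGMA_UM, axis, amps["dna"]))
    # motor peaks, one per principal pole, offset toward the center
    off = spec.motor_peak_offset_um
    for name, p, sgn in (("motor_a", a, +1.0), ("motor_b", b, -1.0)):
        c = (p[0] + sgn * off * axis[0], p[1] + sgn * off * axis[1])
        sources.append(_Source(name, "motor", c, spec.motor_peak_sigma_um,
                               spec.motor_peak_sigma_um, axis, amps["motor"]))
    # tubulin fan between the principal poles
    sources.append(_Source("tubulin_fan", "tubulin", mid, L / 4.0,
                           TUBULIN_TRANSVERSE_SIGMA_UM, axis, amps["tubulin"]))
    # fans connecting extra poles to the spindle body
    for i, p in enumerate(poles[2:], start=2):
        c = ((p[0] + mid[0]) / 2.0, (p[1] + mid[1]) / 2.0)
        d = math.dist(p, mid)
        fan_axis = _axis_unit(p, mid)
        sources.append(_Source(f"tubulin_fan_{i}", "tubulin", c, max(d / 4.0, 0.5),
                               TUBULIN_TRANSVERSE_SIGMA_UM, fan_axis, amps["tubulin"]))
    return sources


def _pole_motor_sources(spec: SpindleSpec) -> list[_Source]:
    """Motor component sitting exactly at the principal poles (for treatment gain)."""
    amp = float(spec.channel_amplitudes.get("motor", 0.0))
    axis = _axis_unit(spec.pole_a, spec.pole_b)
    return [
        _Source(f"motor_pole_{i}", "motor", tuple(p), spec.motor_peak_sigma_um,
                spec.motor_peak_sigma_um, axis, amp)
        for i, p in enumerate((spec.pole_a, spec.pole_b))
    ]


def _check_sources_in_bounds(spec: SpindleSpec, sources: list[_Source]) -> None:
    rows, cols = spec.image_shape
    r_max = (rows - 1) * spec.pixel_size_um
    c_max = (cols - 1) * spec.pixel_size_um
    for s in sources:
        r, c = s.center_um
        if not (0 <= r <= r_max and 0 <= c <= c_max):
            raise ValueError(
                f"source {s.name!r} ({s.channel} channel) at ({r:.2f}, {c:.2f}) µm "
                f"lies outside the image bounds ({r_max:.2f}, {c_max:.2f}) µm"
            )


def _expected_channels(spec: SpindleSpec, sources: list[_Source]) -> np.ndarray:
    rows, cols = spec.image_shape
    row_um = np.arange(rows, dtype=float)[:, None] * spec.pixel_size_um
    col_um = np.arange(cols, dtype=float)[None, :] * spec.pixel_size_um
    expected = np.full((len(CHANNEL_ROLES), rows, cols), float(spec.background))
    for s in sources:
        if s.amplitude > 0:
            expected[CHANNEL_ROLES.index(s.channel)] += s.render(row_um, col_um)
    return expected


def _apply_noise(expected: np.ndarray, spec: SpindleSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return expected.copy()
    if spec.noise_model == "poisson":
        return rng.poisson(expected).astype(float)
    return expected + rng.normal(0.0, spec.gaussian_sd, size=expected.shape)


def render_spindle_image(spec: SpindleSpec) -> tuple[SpindleImage, GroundTruthManifest]:
    """Render one spindle image and its ground-truth manifest."""
    sources = _spindle_sources(spec)
    _check_sources_in_bounds(spec, sources)
    expected = _expected_channels(spec, sources)
    rng = np.random.default_rng(spec.seed)
    data = _apply_noise(expected, spec, rng)
    poles = [list(spec.pole_a), list(spec.pole_b)] + [list(p) for p in _extra_pole_positions(spec)]
    image = SpindleImage(data, CHANNEL_ROLES, spec.pixel_size_um)
    manifest = GroundTruthManifest(
        kind="spindle_image",
        spec=spec.to_dict(),
        true_spindle_length_um=spec.spindle_length_um,
        true_dna_fwhm_um=FWHM_FACTOR * spec.dna_band_sigma_um,
        true_motor_offset_um=spec.motor_peak_offset_um,
        pole_positions_um=poles,
        n_poles=spec.n_poles,
    )
    return image, manifest


def analytic_channel_masses(spec: SpindleSpec) -> dict[str, float]:
    """Per-channel analytic source mass (photon·pixels), excluding background."""
    masses = {role: 0.0 for role in CHANNEL_ROLES}
    for s in _spindle_sources(spec):
        masses[s.channel] += s.mass_photons(spec.pixel_size_um)
    return masses


def render_timelapse(spec: TimeLapseSpec) -> tuple[TimeLapse, GroundTruthManifest]:
    """Render an ordered frame sequence with post-treatment motor dynamics.

    Frames before ``treatment_frame`` share the same expectation. From the
    treatment frame on, the motor channel's expectation becomes
    ``mask_t · base + (pole_gain(t) − 1) · pole_component`` where ``mask_t``
    zeroes the axial band within ``gap_halfwidth_um(t)`` of the midpoint.
    Noise, when enabled, is drawn fresh per frame from the seeded generator.
    """
    base = spec.base
    sources = _spindle_sources(base)
    pole_motor = _pole_motor_sources(base)
    _check_sources_in_bounds(base, sources + pole_motor)

    rows, cols = base.image_shape
    row_um = np.arange(rows, dtype=float)[:, None] * base.pixel_size_um
    col_um = np.arange(cols, dtype=float)[None, :] * base.pixel_size_um
    motor_idx = CHANNEL_ROLES.index("motor")

    expected0 = _expected_channels(base, sources)
    motor_signal0 = expected0[motor_idx] - base.background
    pole_component = np.zeros((rows, cols))
    for s in pole_motor:
        if s.amplitude > 0:
            pole_component += s.render(row_um, col_um)

    a, b = base.pole_a, base.pole_b
    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    axis = _axis_unit(a, b)
    axial = (row_um - mid[0]) * axis[0] + (col_um - mid[1]) * axis[1]

    rng = np.random.default_rng(base.seed)
    timestamps = (np.arange(spec.n_frames) - spec.treatment_frame) * spec.frame_interval_s
    frames: list[SpindleImage] = []
    gaps, gains = [], []
    for i, t in enumerate(timestamps):
        if i < spec.treatment_frame:
            gap, gain = 0.0, 1.0
        else:
            gap, gain = spec.gap_at(t), spec.gain_at(t)
        gaps.append(gap)
        gains.append(gain)
        expected = expected0.copy()
        mask = (np.abs(axial) >= gap).astype(float)
        expected[motor_idx] = base.background + motor_signal0 * mask + (gain - 1.0) * pole_component
        data = _apply_noise(expected, base, rng)
        frames.append(SpindleImage(data, CHANNEL_ROLES, base.pixel_size_um,
                                   meta={"timestamp_s": float(t)}))

    tl = TimeLapse(frames, timestamps, spec.treatment_frame)
    manifest = GroundTruthManifest(
        kind="timelapse",
        spec={"base": base.to_dict(), "frame_interval_s": spec.frame_interval_s,
              "n_frames": spec.n_frames, "treatment_frame": spec.treatment_frame},
        true_spindle_length_um=base.spindle_length_um,
        true_motor_offset_um=base.motor_peak_offset_um,
        pole_positions_um=[list(a), list(b)],
        n_poles=base.n_poles,
        timestamps_s=[float(t) for t in timestamps],
        gap_halfwidth_um=[float(g) for g in gaps],
        pole_gain=[float(g) for g in gains],
    )
    return tl, manifest


# ---------------------------------------------------------------------------
# Tabular generators
# ---------------------------------------------------------------------------

def sample_population_counts(spec: PopulationSpec) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Sample a per-field count table: total, mitotic, multipolar.

    Totals are Poisson, mitotic cells Binomial(total, p_mitotic) and
    multipolar cells Binomial(mitotic, p_multipolar_given_mitotic).
    """
    rng = np.random.default_rng(spec.seed)
    total = rng.poisson(spec.cells_per_field_mean, size=spec.n_fields)
    mitotic = rng.binomial(total, spec.p_mitotic)
    multipolar = rng.binomial(mitotic, spec.p_multipolar_given_mitotic)
    table = pd.DataFrame({
        "field_id": np.arange(spec.n_fields),
        "total": total,
        "mitotic": mitotic,
        "multipolar": multipolar,
    })
    manifest = GroundTruthManifest(kind="population_counts", spec=asdict(spec))
    return table, manifest


def logistic_growth(t_h: np.ndarray, spec: GrowthSpec) -> np.ndarray:
    """Closed-form logistic count curve; exponential when K = inf, flat when Td = inf."""
    t_h = np.asarray(t_h, dtype=float)
    if math.isinf(spec.doubling_time_h):
        return np.full_like(t_h, spec.n0)
    growth = np.exp2(t_h / spec.doubling_time_h)
    if math.isinf(spec.carrying_capacity):
        return spec.n0 * growth
    K = spec.carrying_capacity
    return K / (1.0 + (K / spec.n0 - 1.0) / growth)


def simulate_growth_curve(spec: GrowthSpec) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Sample one well's (time_h, count) series from the logistic model.

    Multiplicative noise is mean-preserving lognormal with the requested
    coefficient of variation; cv = 0 returns the exact closed form.
    """
    n_samples = int(math.floor(spec.horizon_h / spec.sample_interval_h)) + 1
    t = np.arange(n_samples) * spec.sample_interval_h
    counts = logistic_growth(t, spec)
    if spec.count_noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = math.sqrt(math.log(1.0 + spec.count_noise_cv ** 2))
        counts = counts * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=counts.shape)
    table = pd.DataFrame({"time_h": t, "count": counts})
    truth_final = float(logistic_growth(np.array([t[-1]]), spec)[0])
    spec_dict = asdict(spec)
    # JSON round-trips: inf is not valid JSON, store as string sentinel
    for k, v in spec_dict.items():
        if isinstance(v, float) and math.isinf(v):
            spec_dict[k] = "inf"
    manifest = GroundTruthManifest(kind="growth_curve", spec=spec_dict,
                                   true_fold_change=truth_final / spec.n0)
    return table, manifest


#: Reserved concentration codes for control wells in dose tables.
POSITIVE_CONTROL_CODE = 0.0   # enzyme, no compound -> uninhibited signal
NEGATIVE_CONTROL_CODE = -1.0  # no enzyme -> fully inhibited (floor) signal


def simulate_dose_response(spec: DoseSpec) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Sample a luminescence dose table with control wells.

    The output is tidy (concentration_nM, replicate, signal); positive and
    negative control wells carry the reserved concentration codes 0 and −1.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_replicates):
        for c in spec.concentrations:
            rows.append((c, rep, spec.signal_at(c)))
        rows.append((POSITIVE_CONTROL_CODE, rep, spec.top))
        rows.append((NEGATIVE_CONTROL_CODE, rep, spec.bottom))
    table = pd.DataFrame(rows, columns=["concentration_nM", "replicate", "signal"])
    if spec.replicate_sd > 0:
        table["signal"] += rng.normal(0.0, spec.replicate_sd, size=len(table))
    spec_dict = asdict(spec)
    spec_dict["concentrations"] = list(spec.concentrations)
    manifest = GroundTruthManifest(kind="dose_response", spec=spec_dict,
                                   true_ic50_nM=spec.ic50)
    return table, manifest
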