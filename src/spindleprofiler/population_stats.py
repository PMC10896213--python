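"""Counting statistics and kinetic-proliferation metrics.

Mitotic index (% of cells in mitosis) and multipolar fraction (% of mitotic
cells with >2 spindle poles) are computed on counts pooled across fields;
condition pairs are compared with a 2×2 Pearson chi-squared test on the
pooled counts (no continuity correction, df = 1). Spindle-pole counting on
images finds pole-channel maxima gated by local spindle (tubulin) signal.
Proliferation series are normalized to their first timepoint; per-well fold
change is referenced to the control-condition mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max

from .core import SpindleImage

POLE_RELATIVE_THRESHOLD = 0.3
POLE_MIN_SEPARATION_UM = 2.0
#: Tubulin gate: a pole peak counts only if local tubulin exceeds the
#: background level (10th percentile of the smoothed channel, which is
#: unaffected by the spindle occupying much of the frame) by this fraction
#: of the dynamic range above background.
TUBULIN_GATE_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

@dataclass
class ConditionCounts:
    """Per-field (total, mitotic, multipolar) counts for one condition."""

    condition: str
    total: np.ndarray
    mitotic: np.ndarray
    multipolar: np.ndarray

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=int)
        self.mitotic = np.asarray(self.mitotic, dtype=int)
        self.multipolar = np.asarray(self.multipolar, dtype=int)
        if not (self.total.shape == self.mitotic.shape == self.multipolar.shape):
            raise ValueError("count vectors must share length")
        bad = ~((0 <= self.multipolar) & (self.multipolar <= self.mitotic)
                & (self.mitotic <= self.total))
        if bad.any():
            raise ValueError(
                f"invalid counts in fields {np.flatnonzero(bad).tolist()}: "
                "need 0 <= multipolar <= mitotic <= total"
            )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, condition: str = "") -> "ConditionCounts":
        return cls(condition, table["total"].to_numpy(),
                   table["mitotic"].to_numpy(), table["multipolar"].to_numpy())

    @property
    def pooled_total(self) -> int:
        return int(self.total.sum())

    @property
    def pooled_mitotic(self) -> int:
        return int(self.mitotic.sum())

    @property
    def pooled_multipolar(self) -> int:
        return int(self.multipolar.sum())

    def per_field_mitotic_index(self) -> np.ndarray:
        """Per-field mitotic percentage (fields with zero cells give NaN)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.total > 0, 100.0 * self.mitotic / self.total, np.nan)


def mitotic_index(counts: ConditionCounts) -> float:
    """Pooled mitotic index: 100 × Σ mitotic / Σ total."""
    if counts.pooled_total == 0:
        raise ValueError(f"condition {counts.condition!r} has zero total cells")
    return 100.0 * counts.pooled_mitotic / counts.pooled_total


def multipolar_fraction(counts: ConditionCounts) -> float:
    """Pooled multipolar percentage: 100 × Σ multipolar / Σ mitotic."""
    if counts.pooled_mitotic == 0:
        raise ValueError(f"condition {counts.condition!r} has zero mitotic cells")
    return 100.0 * counts.pooled_multipolar / counts.pooled_mitotic


@dataclass
class ChiSquareResult:
    """2×2 Pearson chi-squared comparison of two conditions."""

    statistic: float
    p_value: float
    table: np.ndarray
    df: int = 1
    low_expected: bool = False
    conditions: tuple[str, str] = ("a", "b")
    outcome: str = "mitotic"


def _outcome_pair(c: ConditionCounts, outcome: str) -> tuple[int, int]:
    if outcome == "mitotic":
        return c.pooled_mitotic, c.pooled_total - c.pooled_mitotic
    if outcome == "multipolar":
        return c.pooled_multipolar, c.pooled_mitotic - c.pooled_multipolar
    raise ValueError(f"unknown outcome {outcome!r}; use 'mitotic' or 'multipolar'")


def chisq_compare(a: ConditionCounts, b: ConditionCounts,
                  outcome: str = "mitotic") -> ChiSquareResult:
    """Pearson chi-squared on the pooled 2×2 table (outcome vs rest), df = 1.

    No continuity correction. An expected cell below 1 sets a
    ``low_expected`` warning flag; a degenerate table (an outcome column
    summing to zero) returns statistic 0, p = 1 with the flag set.
    """
    table = np.array([_outcome_pair(a, outcome), _outcome_pair(b, outcome)], dtype=float)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("both conditions need nonzero denominators")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected == 0).any():
        return ChiSquareResult(0.0, 1.0, table, low_expected=True,
                               conditions=(a.condition, b.condition), outcome=outcome)
    statistic = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic, p, table, low_expected=bool((expected < 1).any()),
                           conditions=(a.condition, b.condition), outcome=outcome)


def chisq_table(conditions: Sequence[ConditionCounts],
                outcome: str = "mitotic") -> ChiSquareResult:
    """Full R×2 contingency chi-squared over several conditions (df = R−1)."""
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    table = np.array([_outcome_pair(c, outcome) for c in conditions], dtype=float)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("every condition needs a nonzero denominator")
    statistic, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(statistic), float(p), table, df=int(df),
                           low_expected=bool((expected < 1).any()),
                           conditions=tuple(c.condition for c in conditions),
                           outcome=outcome)


# ---------------------------------------------------------------------------
# Pole counting
# ---------------------------------------------------------------------------

def pole_count(
    image: SpindleImage,
    relative_threshold: float = POLE_RELATIVE_THRESHOLD,
    min_separation_um: float = POLE_MIN_SEPARATION_UM,
) -> int:
    """Count spindle poles: smoothed pole-channel maxima gated by tubulin.

    Local maxima of the 3×3-mean-smoothed pole channel above
    ``relative_threshold`` of the global maximum, separated by at least
    ``min_separation_um``, are retained only where the (smoothed) tubulin
    channel locally exceeds its background estimate.
    """
    plane = image.channel("pole")
    if np.ptp(plane) == 0:
        raise ValueError("pole channel is empty or constant: cannot count poles")
    smoothed = ndimage.uniform_filter(plane, size=3, mode="nearest")
    min_dist_px = max(1, int(math.ceil(min_separation_um / image.pixel_size_um)))
    peaks = peak_local_max(smoothed, min_distance=min_dist_px,
                           threshold_rel=relative_threshold, exclude_border=False)
    if image.has_channel("tubulin"):
        tub = ndimage.uniform_filter(image.channel("tubulin"), size=3, mode="nearest")
        bg = float(np.percentile(tub, 10))
        gate = bg + TUBULIN_GATE_FRACTION * (float(tub.max()) - bg)
        peaks = [p for p in peaks if tub[p[0], p[1]] > gate]
    return len(peaks)


# ---------------------------------------------------------------------------
# Proliferation
# ---------------------------------------------------------------------------

@dataclass
class GrowthSeries:
    """One well's ordered (time_h, count) proliferation series."""

    well_id: str
    condition: str
    time_h: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time_h.shape != self.counts.shape or self.time_h.size < 2:
            raise ValueError("series needs matching time/count vectors of length >= 2")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.counts[0] <= 0:
            raise ValueError(f"well {self.well_id!r}: zero initial count, cannot normalize")

    @property
    def normalized_counts(self) -> np.ndarray:
        """Counts divided by the first-timepoint count."""
        return self.counts / self.counts[0]

    @property
    def fold_change(self) -> float:
        """Final count divided by initial count."""
        return float(self.counts[-1] / self.counts[0])


def growth_series_from_table(table: pd.DataFrame) -> list[GrowthSeries]:
    """Build per-well series from a tidy (condition, well_id, time_h, count) table."""
    series = []
    for (cond, well), g in table.groupby(["condition", "well_id"], sort=False):
        g = g.sort_values("time_h")
        series.append(GrowthSeries(str(well), str(cond),
                                   g["time_h"].to_numpy(), g["count"].to_numpy()))
    return series


def growth_metrics(
    series: Sequence[GrowthSeries],
    reference_condition: str,
) -> dict:
    """Per-well fold changes referenced to control, plus mean ± sd curves.

    Returns a dict with ``per_well`` — a tidy frame holding each well's fold
    change and its fold change divided by the reference-condition mean —
    and ``curves`` — per-condition mean and sd of the normalized count
    curves at each timepoint. The reference condition's mean normalized
    fold change is 1 by construction.
    """
    if len(series) == 0:
        raise ValueError("growth_metrics requires at least one series")
    conditions = {s.condition for s in series}
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} not present "
                         f"(have {sorted(conditions)})")
    ref_folds = [s.fold_change for s in series if s.condition == reference_condition]
    ref_mean = float(np.mean(ref_folds))
    per_well = pd.DataFrame({
        "condition": [s.condition for s in series],
        "well_id": [s.well_id for s in series],
        "fold_change": [s.fold_change for s in series],
        "normalized_fold_change": [s.fold_change / ref_mean for s in series],
    })
    curve_rows = []
    for cond in sorted(conditions):
        members = [s for s in series if s.condition == cond]
        times = members[0].time_h
        for s in members[1:]:
            if not np.array_equal(s.time_h, times):
                raise ValueError(f"wells of condition {cond!r} have mismatched timepoints")
        norm = np.vstack([s.normalized_counts for s in members])
        for t, m, sd in zip(times, norm.mean(axis=0), norm.std(axis=0, ddof=0)):
            curve_rows.append((cond, float(t), float(m), float(sd)))
    curves = pd.DataFrame(curve_rows, columns=["condition", "time_h", "mean_norm", "sd_norm"])
    return {"per_well": per_well, "curves": curves, "reference_mean_fold": ref_mean}
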