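"""ATPase-inhibition dose–response: percent inhibition and the 4PL fit.

Raw luminescence is converted to percent inhibition with
``100 · (pos − sample) / (pos − neg)`` where ``pos`` is the uninhibited
(enzyme, no compound) control and ``neg`` the no-enzyme floor. The
inhibition curve is then fitted with the variable-slope four-parameter
logistic in log10-concentration space,

    y(c) = bottom + (top − bottom) / (1 + 10^(hill · (log10 IC50 − log10 c)))

yielding the IC50 and Hill slope. Replicates are fitted pointwise by
default; averaging per concentration first is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic_data import NEGATIVE_CONTROL_CODE, POSITIVE_CONTROL_CODE

HILL_BOUNDS = (0.1, 10.0)
#: An inhibition curve spanning fewer than this many percentage points is
#: flagged as too shallow to constrain an IC50.
SHALLOW_SPAN_PCT = 20.0


def percent_inhibition(sample, pos: float, neg: float):
    """Percent inhibition: ``100 · (pos − sample) / (pos − neg)``.

    Accepts scalar or array ``sample``. Values outside [0, 100] are
    possible with noisy signals and are deliberately not clipped.
    """
    if pos == neg:
        raise ValueError("positive and negative control signals coincide")
    sample = np.asarray(sample, dtype=float)
    out = 100.0 * (pos - sample) / (pos - neg)
    return float(out) if out.ndim == 0 else out


@dataclass
class InhibitionCurve:
    """Replicate-resolved percent inhibition versus concentration."""

    concentrations_nM: np.ndarray
    percent_inhibition: np.ndarray
    positive_control_signal: float
    negative_control_signal: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.percent_inhibition = np.asarray(self.percent_inhibition, dtype=float)
        if self.concentrations_nM.shape != self.percent_inhibition.shape:
            raise ValueError("concentration and inhibition vectors must share length")
        if np.any(self.concentrations_nM <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.positive_control_signal == self.negative_control_signal:
            raise ValueError("control signals must be distinct")

    @classmethod
    def from_signal_table(cls, table: pd.DataFrame) -> "InhibitionCurve":
        """Build a curve from a tidy (concentration_nM, replicate, signal) table.

        Control wells are flagged by reserved concentration codes:
        0 = positive control (enzyme, no compound), −1 = negative control
        (no enzyme). Controls are averaged; sample wells stay
        replicate-resolved.
        """
        conc = table["concentration_nM"].to_numpy(dtype=float)
        pos_rows = conc == POSITIVE_CONTROL_CODE
        neg_rows = conc == NEGATIVE_CONTROL_CODE
        if not pos_rows.any() or not neg_rows.any():
            raise ValueError("signal table must contain positive (code 0) and "
                             "negative (code -1) control wells")
        pos = float(table.loc[pos_rows, "signal"].mean())
        neg = float(table.loc[neg_rows, "signal"].mean())
        samples = table.loc[~(pos_rows | neg_rows)]
        inhibition = percent_inhibition(samples["signal"].to_numpy(), pos, neg)
        return cls(samples["concentration_nM"].to_numpy(dtype=float), inhibition, pos, neg)


@dataclass
class FourPLFit:
    """Variable-slope four-parameter logistic fit of an inhibition curve."""

    top: float
    bottom: float
    ic50_nM: float | None
    hill: float
    rss: float
    converged: bool
    shallow: bool = False
    meta: dict = field(default_factory=dict)

    def predict(self, concentrations_nM) -> np.ndarray:
        c = np.asarray(concentrations_nM, dtype=float)
        if self.ic50_nM is None:
            raise ValueError("fit did not converge: no IC50 to predict with")
        return _four_pl(np.log10(c), self.top, self.bottom,
                        math.log10(self.ic50_nM), self.hill)


def _four_pl(logc: np.ndarray, top: float, bottom: float,
             log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


def fit_4pl(curve: InhibitionCurve, average_replicates: bool = False) -> FourPLFit:
    """Least-squares 4PL fit in log10-concentration space.

    Initialization: top = max y, bottom = min y, IC50 = concentration
    interpolated nearest 50% inhibition, hill = 1. Bounds: hill in
    [0.1, 10], IC50 within two decades of the tested range. Non-convergence
    returns ``converged=False`` with the IC50 reported as missing.
    """
    conc = curve.concentrations_nM
    y = curve.percent_inhibition
    if average_replicates:
        frame = pd.DataFrame({"c": conc, "y": y}).groupby("c", as_index=False).mean()
        conc, y = frame["c"].to_numpy(), frame["y"].to_numpy()
    if np.unique(conc).size < 5:
        raise ValueError("4PL fit requires at least 5 distinct concentrations")
    logc = np.log10(conc)
    order = np.argsort(logc)

    top0, bottom0 = float(y.max()), float(y.min())
    span = top0 - bottom0
    shallow = span < SHALLOW_SPAN_PCT
    # concentration nearest half-maximal inhibition, by interpolation on the
    # sorted mean response
    half = (top0 + bottom0) / 2.0
    y_sorted = y[order]
    logc_sorted = logc[order]
    crossing = np.nonzero(np.diff(np.sign(y_sorted - half)))[0]
    if crossing.size:
        i = int(crossing[0])
        x0, x1 = logc_sorted[i], logc_sorted[i + 1]
        f0, f1 = y_sorted[i] - half, y_sorted[i + 1] - half
        log_ic50_0 = x0 - f0 * (x1 - x0) / (f1 - f0) if f1 != f0 else x0
    else:
        log_ic50_0 = float(np.median(logc))
    p0 = (top0, bottom0, log_ic50_0, 1.0)
    lo = [bottom0 - max(span, 1.0), bottom0 - max(span, 1.0), logc.min() - 2.0, HILL_BOUNDS[0]]
    hi = [top0 + max(span, 1.0), top0 + max(span, 1.0), logc.max() + 2.0, HILL_BOUNDS[1]]
    p0 = tuple(np.clip(p0, lo, hi))
    try:
        popt, _ = optimize.curve_fit(_four_pl, logc, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = np.array(p0), False
    rss = float(np.sum((y - _four_pl(logc, *popt)) ** 2))
    return FourPLFit(
        top=float(popt[0]), bottom=float(popt[1]),
        ic50_nM=float(10.0 ** popt[2]) if converged else None,
        hill=float(popt[3]), rss=rss, converged=converged, shallow=shallow,
        meta={"n_points": int(y.size), "average_replicates": average_replicates},
    )
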