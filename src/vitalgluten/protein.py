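"""Gluten protein composition from gel-permeation HPLC traces.

Gliadins (extracted with aqueous ethanol) and glutenins (extracted with
a reducing/denaturing solvent) are separated by size on a GP-HPLC
column; fixed retention-time windows partition each extract's trace
into high- (HMW), medium- (MMW) and low-molecular-weight (LMW)
fractions.  Window areas are converted to protein masses through a
linear calibration against a reference gliadin standard, and the six
masses are expressed as percentages of total gluten protein, from which
the gliadin-to-glutenin (GLIA/GLUT) ratio follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .aggregation import DataQualityWarning

__all__ = [
    "Chromatogram",
    "RetentionWindows",
    "CalibrationModel",
    "ProteinComposition",
    "GLIADIN_WINDOWS",
    "GLUTENIN_WINDOWS",
    "fit_calibration",
    "integrate_windows",
    "compose",
]


@dataclass(frozen=True)
class RetentionWindows:
    """Contiguous half-open [start, end) retention windows in minutes.

    The final window is closed at its right edge.  Shared boundary
    values make the partition exact: no minute of the trace is counted
    twice or dropped.
    """

    hmw: tuple[float, float]
    mmw: tuple[float, float]
    lmw: tuple[float, float]

    def __post_init__(self) -> None:
        w = [self.hmw, self.mmw, self.lmw]
        if any(a >= b for a, b in w):
            raise ValueError("each window must have start < end")
        if self.hmw[1] != self.mmw[0] or self.mmw[1] != self.lmw[0]:
            raise ValueError("windows must be contiguous")


#: retention windows for the gliadin extract (min)
GLIADIN_WINDOWS = RetentionWindows(hmw=(6.0, 8.1), mmw=(8.1, 9.1), lmw=(9.1, 13.0))
#: retention windows for the glutenin extract (min)
GLUTENIN_WINDOWS = RetentionWindows(hmw=(6.0, 7.4), mmw=(7.4, 8.6), lmw=(8.6, 13.0))


@dataclass
class Chromatogram:
    """An absorbance trace of one extract over retention time (min)."""

    retention: np.ndarray
    signal: np.ndarray
    extract_label: str = "gliadin"

    def __post_init__(self) -> None:
        self.retention = np.asarray(self.retention, float)
        self.signal = np.asarray(self.signal, float)
        if self.retention.shape != self.signal.shape or self.retention.ndim != 1:
            raise ValueError("retention and signal must be 1-d arrays of equal length")
        if np.any(np.diff(self.retention) <= 0):
            raise ValueError("retention must be strictly increasing")
        if self.extract_label not in ("gliadin", "glutenin"):
            raise ValueError("extract_label must be 'gliadin' or 'glutenin'")
        if self.retention[0] > 6.0 or self.retention[-1] < 13.0:
            raise ValueError("chromatogram must cover 6.0-13.0 min")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear response ``area = slope * mass + intercept`` (area per ug)."""

    slope: float
    intercept: float
    r_squared: float

    def mass_of(self, area: float) -> float:
        return (area - self.intercept) / self.slope


#: pass-through calibration (area numerically equals mass)
IDENTITY_CALIBRATION = CalibrationModel(slope=1.0, intercept=0.0, r_squared=1.0)

# mass range (ug) of the reference-gliadin standards
_STANDARD_RANGE = (11.6, 46.6)


def fit_calibration(standards) -> CalibrationModel:
    """Ordinary least-squares line through (mass ug, area) standards."""
    masses = np.asarray([m for m, _ in standards], float)
    areas = np.asarray([a for _, a in standards], float)
    if masses.size < 2 or np.unique(masses).size < 2:
        raise ValueError("calibration needs at least 2 distinct masses")
    if masses.min() < _STANDARD_RANGE[0] or masses.max() > _STANDARD_RANGE[1]:
        warnings.warn("calibration standards outside the reference range "
                      f"{_STANDARD_RANGE} ug", DataQualityWarning, stacklevel=2)
    res = stats.linregress(masses, areas)
    if res.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2))


def integrate_windows(chrom: Chromatogram, windows: RetentionWindows | None = None,
                      cal: CalibrationModel = IDENTITY_CALIBRATION, *,
                      baseline_correct: bool = True) -> tuple[float, float, float]:
    """Masses (ug) of the HMW, MMW and LMW windows of one extract.

    Window areas use trapezoidal integration with boundary ordinates
    interpolated linearly; by default the minimum signal over the full
    6.0-13.0 min range is subtracted first as a flat baseline.
    Negative inverse-calibrated masses are clamped to zero.
    """
    if windows is None:
        windows = GLIADIN_WINDOWS if chrom.extract_label == "gliadin" else GLUTENIN_WINDOWS
    t, y = chrom.retention, chrom.signal
    span = (windows.hmw[0], windows.lmw[1])
    if t[0] > span[0] or t[-1] < span[1]:
        raise ValueError("chromatogram does not cover the retention windows")
    if baseline_correct:
        sel = (t >= span[0]) & (t <= span[1])
        y = y - y[sel].min()
    masses = []
    for a, b in (windows.hmw, windows.mmw, windows.lmw):
        inner = (t > a) & (t < b)
        xs = np.concatenate(([a], t[inner], [b]))
        ys = np.interp(xs, t, y)
        mass = cal.mass_of(float(np.trapezoid(ys, xs)))
        if mass < 0:
            warnings.warn(f"negative mass in window [{a}, {b}) clamped to 0",
                          DataQualityWarning, stacklevel=2)
            mass = 0.0
        masses.append(mass)
    return tuple(masses)


@dataclass
class ProteinComposition:
    """Relative gluten protein composition, in % of total gluten protein."""

    hmw_gliadins: float
    mmw_gliadins: float
    lmw_gliadins: float
    hmw_glutenins: float
    mmw_glutenins: float
    lmw_glutenins: float

    @property
    def gliadins(self) -> float:
        return self.hmw_gliadins + self.mmw_gliadins + self.lmw_gliadins

    @property
    def glutenins(self) -> float:
        return self.hmw_glutenins + self.mmw_glutenins + self.lmw_glutenins

    @property
    def glia_glut_ratio(self) -> float:
        if self.glutenins == 0:
            warnings.warn("zero glutenin total: GLIA/GLUT ratio undefined",
                          DataQualityWarning, stacklevel=2)
            return float("nan")
        return self.gliadins / self.glutenins

    def as_dict(self) -> dict[str, float]:
        return {
            "hmw_gliadins": self.hmw_gliadins,
            "mmw_gliadins": self.mmw_gliadins,
            "lmw_gliadins": self.lmw_gliadins,
            "gliadins": self.gliadins,
            "hmw_glutenins": self.hmw_glutenins,
            "mmw_glutenins": self.mmw_glutenins,
            "lmw_glutenins": self.lmw_glutenins,
            "glutenins": self.glutenins,
            "glia_glut_ratio": self.glia_glut_ratio,
        }


def compose(gliadin_masses, glutenin_masses) -> ProteinComposition:
    """Relative composition from six window masses (consistent units)."""
    glia = np.asarray(gliadin_masses, float)
    glut = np.asarray(glutenin_masses, float)
    if glia.shape != (3,) or glut.shape != (3,):
        raise ValueError("expected three gliadin and three glutenin masses")
    if np.any(glia < 0) or np.any(glut < 0):
        raise ValueError("masses must be non-negative")
    total = float(glia.sum() + glut.sum())
    if total <= 0:
        raise ValueError("zero grand total: composition undefined")
    g = 100.0 * glia / total
    u = 100.0 * glut / total
    return ProteinComposition(hmw_gliadins=float(g[0]), mmw_gliadins=float(g[1]),
                              lmw_gliadins=float(g[2]), hmw_glutenins=float(u[0]),
                              mmw_glutenins=float(u[1]), lmw_glutenins=float(u[2]))
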