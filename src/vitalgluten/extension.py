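"""Microscale extension (force vs. distance) curve analysis.

A Kieffer-rig extension test stretches a moulded gluten strand and
records the resisting force until the strand ruptures.  The features
extracted here follow the conventional nomenclature:

* ``R_max`` (N) -- maximum resistance to extension;
* ``E_Rmax`` (mm) -- hook travel at ``R_max``;
* ``A_Rmax`` (mJ) -- area under the curve up to ``E_Rmax``
  (N x mm = mJ, no conversion factor);
* ``E_max`` (mm) -- extensibility, the distance at rupture;
* ``A_max`` (mJ) -- area under the curve up to ``E_max``.

Rupture is detected as the first post-peak sample-to-sample force drop
exceeding the break sensitivity (default 0.020 N, the documented
instrument setting); ``E_max`` is the last point before that drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .aggregation import DataQualityWarning

__all__ = [
    "ExtensionCurve",
    "ExtensionFeatures",
    "RuptureResult",
    "detect_rupture",
    "extract_extension_features",
    "mean_features",
    "BREAK_SENSITIVITY_N",
]

#: instrument break sensitivity in newtons
BREAK_SENSITIVITY_N = 0.020


@dataclass
class ExtensionCurve:
    """A force trace: distance in mm (strictly increasing from 0), force in N."""

    distance: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, float)
        self.force = np.asarray(self.force, float)
        if self.distance.ndim != 1 or self.distance.shape != self.force.shape:
            raise ValueError("distance and force must be 1-d arrays of equal length")
        if self.distance.size < 10:
            raise ValueError("extension curve needs at least 10 points")
        if not (np.all(np.isfinite(self.distance)) and np.all(np.isfinite(self.force))):
            raise ValueError("extension curve contains non-finite values")
        if self.distance[0] < 0 or np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance must be strictly increasing from 0")
        if np.any(np.diff(self.distance) > 1.0 + 1e-9):
            raise ValueError("sampling interval must not exceed 1 mm")
        if np.any(self.force < 0):
            raise ValueError("force must be non-negative")


class RuptureResult(NamedTuple):
    e_max: float
    ruptured: bool


@dataclass
class ExtensionFeatures:
    r_max: float
    e_rmax: float
    a_rmax: float
    e_max: float
    a_max: float
    ratio_ermax_rmax: float  # mm/N, the tabulated (non-significant) variant
    ratio_emax_rmax: float   # mm/N
    ruptured: bool = True


def detect_rupture(curve: ExtensionCurve,
                   break_sensitivity: float = BREAK_SENSITIVITY_N) -> RuptureResult:
    """Distance at rupture.

    Scans samples after the global force maximum for the first drop
    ``force[i] - force[i+1] > break_sensitivity``; ``E_max`` is
    ``distance[i]``.  Without such a drop the curve never ruptured:
    the final distance is returned with ``ruptured=False``.
    """
    f = curve.force
    ipk = int(np.argmax(f))
    drops = np.flatnonzero(f[ipk:-1] - f[ipk + 1:] > break_sensitivity)
    if drops.size == 0:
        warnings.warn("no rupture detected within the recorded range",
                      DataQualityWarning, stacklevel=2)
        return RuptureResult(float(curve.distance[-1]), False)
    return RuptureResult(float(curve.distance[ipk + drops[0]]), True)


def extract_extension_features(curve: ExtensionCurve,
                               break_sensitivity: float = BREAK_SENSITIVITY_N,
                               ) -> ExtensionFeatures:
    """Extract all extension features from one force-distance curve."""
    d, f = curve.distance, curve.force
    e_max, ruptured = detect_rupture(curve, break_sensitivity)
    pre = d <= e_max
    i_rmax = int(np.argmax(f[pre]))  # earliest index on ties
    r_max = float(f[i_rmax])
    e_rmax = float(d[i_rmax])
    a_rmax = _area_to(d, f, e_rmax)
    a_max = _area_to(d, f, e_max)
    return ExtensionFeatures(
        r_max=r_max, e_rmax=e_rmax, a_rmax=a_rmax, e_max=e_max, a_max=a_max,
        ratio_ermax_rmax=e_rmax / r_max if r_max > 0 else float("nan"),
        ratio_emax_rmax=e_max / r_max if r_max > 0 else float("nan"),
        ruptured=ruptured,
    )


def _area_to(d: np.ndarray, f: np.ndarray, upto: float) -> float:
    """Trapezoidal area of force over [d[0], upto], endpoint interpolated."""
    inner = d < upto
    xs = np.concatenate((d[inner], [upto]))
    ys = np.concatenate((f[inner], [np.interp(upto, d, f)]))
    return float(np.trapezoid(ys, xs))


def mean_features(replicates: list[ExtensionFeatures]) -> ExtensionFeatures:
    """Arithmetic mean of replicate feature sets (per-sample aggregation)."""
    if not replicates:
        raise ValueError("no replicate features to average")

    def m(attr):
        return float(np.mean([getattr(r, attr) for r in replicates]))

    return ExtensionFeatures(
        r_max=m("r_max"), e_rmax=m("e_rmax"), a_rmax=m("a_rmax"),
        e_max=m("e_max"), a_max=m("a_max"),
        ratio_ermax_rmax=m("ratio_ermax_rmax"),
        ratio_emax_rmax=m("ratio_emax_rmax"),
        ruptured=all(r.ruptured for r in replicates),
    )
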