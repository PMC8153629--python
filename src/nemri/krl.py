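"""Numerical reduction of the whole-blood free-radical hemolysis assay.

The assay exposes red blood cells to a controlled free-radical attack and
records the hemolysis fraction over time; the blood's overall antioxidant
resistance is read as the time to 50% hemolysis (T50%). A formulation's
antioxidant (or prooxidant) effect is the percent change of T50% versus a
control run, optionally expressed in Trolox equivalents per gram of tested
emulsion via a calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "HemolysisCurve",
    "TroloxCalibration",
    "AntioxidantResult",
    "t50_hemolysis",
    "percent_change_t50",
    "trolox_equivalent",
]


@dataclass
class HemolysisCurve:
    """Hemolysis kinetics: percent lysis on an increasing time grid (min)."""

    time_min: np.ndarray
    hemolysis_pct: np.ndarray
    label: str = ""
    dose_mg_per_l: float | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.hemolysis_pct = np.asarray(self.hemolysis_pct, dtype=float)
        if self.time_min.shape != self.hemolysis_pct.shape:
            raise ValueError("time and hemolysis arrays must match")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any((self.hemolysis_pct < 0) | (self.hemolysis_pct > 100)):
            raise ValueError("hemolysis values must lie in [0, 100] percent")


@dataclass
class TroloxCalibration:
    """Monotone map from Trolox mass (mg) to T50% shift (min)."""

    trolox_mg: np.ndarray
    delta_t50_min: np.ndarray

    def __post_init__(self) -> None:
        self.trolox_mg = np.asarray(self.trolox_mg, dtype=float)
        self.delta_t50_min = np.asarray(self.delta_t50_min, dtype=float)
        if self.trolox_mg.size < 2:
            raise ValueError("calibration needs >= 2 points")
        if np.any(np.diff(self.trolox_mg) <= 0) or np.any(np.diff(self.delta_t50_min) <= 0):
            raise ValueError("calibration must be strictly increasing")


@dataclass
class AntioxidantResult:
    t50_min: float
    percent_change: float | None = None
    trolox_mg_per_g: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.t50_min <= 0:
            raise ValueError("T50 must be > 0")
        if self.trolox_mg_per_g is not None and self.trolox_mg_per_g < 0:
            raise ValueError("Trolox equivalent must be >= 0")


def _first_upward_crossing(t: np.ndarray, h: np.ndarray, level: float) -> list[int]:
    """Indices i with h[i] < level <= h[i+1] (upward bracketing samples)."""
    return [int(i) for i in np.nonzero((h[:-1] < level) & (h[1:] >= level))[0]]


def t50_hemolysis(curve: HemolysisCurve, level: float = 50.0) -> tuple[float, list[str]]:
    """Time of 50% hemolysis by linear interpolation at the first upward
    crossing.

    A curve that never reaches the level is rejected. When noise produces
    several crossings, a 3-point median filter is applied first and the
    first crossing of the smoothed curve is used; the result carries a
    ``multiple-crossings`` flag.
    """
    t, h = curve.time_min, curve.hemolysis_pct
    flags: list[str] = []
    if h.max() < level:
        raise ValueError(f"curve never reaches {level}% hemolysis")
    if h[0] >= level:
        raise ValueError(f"curve already above {level}% at the first sample")
    crossings = _first_upward_crossing(t, h, level)
    if len(crossings) > 1:
        flags.append("multiple-crossings")
        h = median_filter(h, size=3, mode="nearest")
        crossings = _first_upward_crossing(t, h, level)
        if not crossings:
            raise ValueError("no crossing left after smoothing")
    i = crossings[0]
    frac = (level - h[i]) / (h[i + 1] - h[i])
    return float(t[i] + frac * (t[i + 1] - t[i])), flags


def percent_change_t50(sample_t50_min: float, control_t50_min: float) -> float:
    """Antioxidant effect: 100 * (sample - control) / control.

    Positive values mean delayed hemolysis (antioxidant); negative,
    accelerated hemolysis (prooxidant). The measure is invariant under a
    common rescaling of both times.
    """
    if control_t50_min <= 0:
        raise ValueError("control T50 must be > 0")
    return 100.0 * (sample_t50_min - control_t50_min) / control_t50_min


def trolox_equivalent(
    delta_t50_min: float, calibration: TroloxCalibration, ne_mass_g: float
) -> float:
    """Trolox-equivalent antioxidant capacity, mg per gram of emulsion.

    The calibration (Trolox mg -> T50 shift) is inverted by linear
    interpolation at the sample's T50 shift, then divided by the emulsion
    mass tested. Shifts outside the calibrated range are rejected rather
    than extrapolated.
    """
    if ne_mass_g <= 0:
        raise ValueError("emulsion mass must be > 0")
    lo, hi = calibration.delta_t50_min[0], calibration.delta_t50_min[-1]
    if not lo <= delta_t50_min <= hi:
        raise ValueError(
            f"T50 shift {delta_t50_min:.3g} min outside calibration range [{lo:.3g}, {hi:.3g}] min"
        )
    mg = float(np.interp(delta_t50_min, calibration.delta_t50_min, calibration.trolox_mg))
    return mg / ne_mass_g
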