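"""Calibration-slope comparison and S/N-based detection limits.

Two device-evaluation tools live here. The first compares ordinary
least-squares calibration slopes between paired experiments (pad + buffer
vs buffer only): a slope ratio below 100% means the pad withholds analyte,
and the comparison repeated on IS-normalized responses shows how much of
that loss the internal standard compensates.

The second determines the limit of detection and limit of quantification
from discrete spiked levels using signal-to-noise thresholds of 3 and 10.
Noise is quantified as the standard deviation of a declared baseline
window (not peak-to-peak); limits are reported as tested grid levels,
never interpolated, and a level qualifies only if *every* replicate
injection passes the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .nd import ND, NDType, is_nd

__all__ = [
    "CalibrationFit",
    "ChromTrace",
    "LimitResult",
    "calibration_fit",
    "slope_ratio_recovery",
    "signal_to_noise",
    "determine_lod_loq",
    "InsufficientDataError",
]

SN_LOD = 3.0
SN_LOQ = 10.0


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationFit:
    """Unweighted OLS line through (level, response) pairs."""

    analyte: str
    response_mode: str  # "absolute_area" | "is_normalized"
    slope: float
    intercept: float
    r_squared: float
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.levels)) < 3:
            raise InsufficientDataError("calibration needs >= 3 distinct levels")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of range: {self.r_squared}")

    def predict(self, level: float) -> float:
        return self.slope * level + self.intercept


@dataclass(frozen=True)
class ChromTrace:
    """A chromatogram segment with declared peak and noise windows.

    ``peak_window`` and ``noise_window`` are (start, stop) index ranges
    (half-open). The noise window must hold at least 20 points and must
    not overlap the peak window, so the baseline statistics are not
    contaminated by the peak itself.
    """

    sampling_interval: float
    intensities: np.ndarray
    peak_window: tuple[int, int]
    noise_window: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        n = len(self.intensities)
        for name, (lo, hi) in (("peak_window", self.peak_window), ("noise_window", self.noise_window)):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"{name} {lo, hi} out of range for {n} points")
        p0, p1 = self.peak_window
        n0, n1 = self.noise_window
        if max(p0, n0) < min(p1, n1):
            raise ValueError("peak and noise windows overlap")
        if n1 - n0 < 20:
            raise ValueError("noise window must span at least 20 points")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.intensities)) * self.sampling_interval


@dataclass(frozen=True)
class LimitResult:
    """LOD/LOQ drawn from the tested level grid (nd if no level qualifies)."""

    analyte: str
    arm: str
    lod: float | NDType
    loq: float | NDType
    per_level: dict = field(default_factory=dict)  # level -> min replicate S/N

    def __post_init__(self) -> None:
        if not is_nd(self.lod) and not is_nd(self.loq) and self.lod > self.loq:
            raise ValueError("LOD cannot exceed LOQ")


def calibration_fit(
    levels: Sequence[float],
    responses: Sequence[float],
    analyte: str = "",
    response_mode: str = "absolute_area",
) -> CalibrationFit:
    """Ordinary least squares (free intercept, unweighted) of response on
    concentration."""
    levels = [float(x) for x in levels]
    responses = list(responses)
    if len(levels) != len(responses):
        raise ValueError("levels and responses must be matched")
    if any(is_nd(r) or r is None for r in responses):
        raise ValueError("responses must be non-nd for calibration")
    if len(set(levels)) < 3:
        raise InsufficientDataError("calibration needs >= 3 distinct levels")
    fit = stats.linregress(levels, [float(r) for r in responses])
    r2 = 0.0 if math.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    return CalibrationFit(
        analyte=analyte,
        response_mode=response_mode,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        levels=tuple(levels),
    )


def slope_ratio_recovery(fit_a: CalibrationFit, fit_b: CalibrationFit) -> float:
    """100 × slope_a / slope_b for two comparable calibrations.

    Used with fit_a = pad + buffer (Tube a) and fit_b = buffer only
    (Tube b): values below 100 indicate analyte loss to the pad. On
    IS-normalized responses the two slopes should nearly coincide when the
    IS compensates the loss.
    """
    if fit_a.analyte != fit_b.analyte:
        raise ValueError("slope ratio requires the same analyte")
    if fit_a.response_mode != fit_b.response_mode:
        raise ValueError("slope ratio requires the same response mode")
    if not set(fit_a.levels) & set(fit_b.levels):
        raise ValueError("calibrations share no levels")
    if fit_b.slope <= 0:
        raise ZeroDivisionError("reference slope must be positive")
    return 100.0 * fit_a.slope / fit_b.slope


def signal_to_noise(trace: ChromTrace) -> float:
    """(peak max − baseline) / noise SD.

    Baseline is the mean of the noise window; noise is its sample SD.
    A zero noise SD returns ``inf`` (the infinite-S/N sentinel). A peak
    window at or below baseline yields an S/N of at most 0 (clipped)."""
    noise = trace.intensities[slice(*trace.noise_window)]
    peak = trace.intensities[slice(*trace.peak_window)]
    baseline = float(noise.mean())
    sd = float(noise.std(ddof=1))
    if sd == 0.0:
        return math.inf
    return max(0.0, (float(peak.max()) - baseline) / sd)


def determine_lod_loq(
    per_level_sn: Mapping[float, Sequence[float]],
    analyte: str = "",
    arm: str = "",
    sn_lod: float = SN_LOD,
    sn_loq: float = SN_LOQ,
) -> LimitResult:
    """Pick LOD/LOQ off the tested level grid.

    LOD is the lowest level whose every replicate S/N is >= 3; LOQ the
    lowest with every replicate >= 10; nd when no level qualifies.
    """
    if not per_level_sn:
        raise InsufficientDataError("empty per-level S/N map")
    if len(per_level_sn) < 2:
        raise InsufficientDataError("need at least 2 tested levels")
    if any(len(v) < 1 for v in per_level_sn.values()):
        raise InsufficientDataError("every level needs at least one replicate")
    lod: float | NDType = ND
    loq: float | NDType = ND
    per_level = {}
    for level in sorted(per_level_sn):
        sns = [float(s) for s in per_level_sn[level]]
        per_level[level] = min(sns)
        if is_nd(lod) and all(s >= sn_lod for s in sns):
            lod = level
        if is_nd(loq) and all(s >= sn_loq for s in sns):
            loq = level
    return LimitResult(analyte=analyte, arm=arm, lod=lod, loq=loq, per_level=per_level)


def limits_grid(results: Sequence[LimitResult], sn_lod: float = SN_LOD, sn_loq: float = SN_LOQ) -> str:
    """Render LimitResults as a +/++/nd coded text grid (rows = levels,
    columns = analyte/arm)."""
    levels = sorted({lvl for r in results for lvl in r.per_level})
    headers = [f"{r.analyte}:{r.arm}" for r in results]
    width = max([12] + [len(h) for h in headers])
    lines = ["  ".join(["conc".ljust(width)] + [h.ljust(width) for h in headers])]
    for lvl in levels:
        cells = []
        for r in results:
            sn = r.per_level.get(lvl)
            if sn is None:
                cells.append("-")
            elif not is_nd(r.loq) and lvl == r.loq:
                cells.append("++")
            elif not is_nd(r.lod) and lvl == r.lod:
                cells.append("+")
            elif sn < sn_lod:
                cells.append("nd")
            else:
                cells.append("-")
        lines.append("  ".join([f"{lvl:g}".ljust(width)] + [c.ljust(width) for c in cells]))
    return "\n".join(lines)
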