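"""Real-sample reporting: external-standard ratios, nd calling, and the
marker-window assessment.

Volunteer oral-fluid samples taken after coca-tea ingestion are quantified
only as area ratios against an external standard (SKF, proadifen) added
after extraction, immediately before injection — it normalizes injection-
to-injection response without tracking extraction or collection losses.

The fitness-for-purpose question for a collection arm is a *time-window*
one: the coca-leaf markers (hygrine and cuscohygrine, lost during illicit
cocaine production) must stay detectable for at least as long as cocaine
itself stays above the confirmation cut-off. An arm where cocaine is still
positive after the markers have dropped below the detection limit cannot
distinguish legal leaf consumption from cocaine use in that window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .nd import ND, NDType, is_nd

__all__ = [
    "TimecoursePoint",
    "WindowAssessment",
    "external_standard_ratio",
    "call_detection",
    "assess_marker_window",
    "AssessmentError",
    "MARKERS",
]

#: Primary coca-leaf markers used by the window criterion.
MARKERS = ("HYG", "CUS")

SN_DETECTION = 3.0


class AssessmentError(ValueError):
    pass


@dataclass(frozen=True)
class TimecoursePoint:
    """One analyte's external-standard ratio at one sampling time."""

    volunteer: int
    arm: str
    time_min: float
    analyte: str
    ratio: float | NDType

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")
        if not is_nd(self.ratio) and self.ratio < 0:
            raise ValueError("ratio must be >= 0 or nd")


@dataclass(frozen=True)
class WindowAssessment:
    """Per-arm verdict of the marker-window criterion."""

    arm: str
    markers_present_while_coc_positive: bool
    last_detectable_min: dict
    coc_positive_times: tuple[float, ...]
    cutoff_equivalent_ratio: float | None


def external_standard_ratio(
    analyte_area: float | NDType, skf_area: float
) -> float | NDType:
    """analyte area / external-standard area; nd propagates."""
    if is_nd(analyte_area):
        return ND
    if is_nd(skf_area) or skf_area is None or skf_area <= 0:
        raise ZeroDivisionError("external-standard area must be positive")
    return analyte_area / skf_area


def call_detection(sn: float, threshold: float = SN_DETECTION) -> float | NDType:
    """nd iff S/N is strictly below 3; the boundary S/N = 3 counts as
    detected. Returns the S/N when detected."""
    return sn if sn >= threshold else ND


def assess_marker_window(
    series: Iterable[TimecoursePoint],
    cutoff_equivalent_ratio: float | None = None,
    markers: Sequence[str] = MARKERS,
) -> dict[str, WindowAssessment]:
    """Apply the marker-window criterion per collection arm.

    A time point is *COC-positive* when the cocaine ratio is detected and
    (if a cutoff-equivalent ratio is configured) at or above it. Real
    samples are quantified only as external-standard ratios, so mapping
    the concentration cut-off into ratio units requires a calibration the
    study design does not include; with ``cutoff_equivalent_ratio=None``
    every detected cocaine point counts as positive (the conservative
    default). An arm passes when at least one marker (HYG or CUS) is
    detected at every COC-positive time point.
    """
    points = list(series)
    if not points:
        raise AssessmentError("empty series")
    arms = sorted({p.arm for p in points})
    out: dict[str, WindowAssessment] = {}
    for arm in arms:
        arm_points = [p for p in points if p.arm == arm]
        coc = [p for p in arm_points if p.analyte == "COC"]
        if not coc:
            raise AssessmentError(f"{arm}: no COC series, assessment undefined")
        if not any(p.analyte in markers for p in arm_points):
            raise AssessmentError(f"{arm}: no marker series (need one of {markers})")
        positive_times = sorted(
            p.time_min
            for p in coc
            if not is_nd(p.ratio)
            and (cutoff_equivalent_ratio is None or p.ratio >= cutoff_equivalent_ratio)
        )
        last_detect: dict[str, float | NDType] = {}
        for p in arm_points:
            if is_nd(p.ratio):
                last_detect.setdefault(p.analyte, ND)
                continue
            prev = last_detect.get(p.analyte)
            if prev is None or is_nd(prev) or p.time_min > prev:
                last_detect[p.analyte] = p.time_min
        ok = True
        for t in positive_times:
            detected_markers = [
                p
                for p in arm_points
                if p.analyte in markers and p.time_min == t and not is_nd(p.ratio)
            ]
            if not detected_markers:
                ok = False
                break
        out[arm] = WindowAssessment(
            arm=arm,
            markers_present_while_coc_positive=ok,
            last_detectable_min=last_detect,
            coc_positive_times=tuple(positive_times),
            cutoff_equivalent_ratio=cutoff_equivalent_ratio,
        )
    return out


def timecourse_grid(points: Sequence[TimecoursePoint]) -> str:
    """Render a volunteer time course as an aligned text grid (rows =
    arm–time, columns = analytes, nd printed literally)."""
    analytes = list(dict.fromkeys(p.analyte for p in points))
    volunteers = sorted({p.volunteer for p in points})
    lines = []
    for vol in volunteers:
        lines.append(f"Volunteer {vol}")
        header = ["sample"] + analytes
        widths = [max(10, len(h)) for h in header]
        lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
        keys = sorted(
            {(p.arm, p.time_min) for p in points if p.volunteer == vol},
            key=lambda k: (k[1], k[0]),
        )
        for arm, t in keys:
            cells = [f"{arm[:1].upper()}-{t:g} min"]
            for analyte in analytes:
                match = [
                    p
                    for p in points
                    if p.volunteer == vol and p.arm == arm and p.time_min == t and p.analyte == analyte
                ]
                if not match:
                    cells.append("-")
                else:
                    r = match[0].ratio
                    cells.append("nd" if is_nd(r) else f"{r:.2f}")
            lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
        lines.append("")
    return "\n".join(lines)
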