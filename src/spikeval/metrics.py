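"""Validation statistics for the three-set spiking design.

All statistics are ratios of replicate-group means:

* matrix effect            ``ME%  = (B/A − 1) × 100``  (signed; + enhancement, − suppression)
* extraction recovery      ``RE%  = C/B × 100``        (matrix effect cancels)
* process efficiency       ``RA%  = C/A × 100``        (apparent recovery)
* pad-transfer recovery    ``R%   = TubeA/TubeB × 100``

and each has an IS-normalized variant computed on per-injection
``area / is_area`` ratios before averaging. The three absolute statistics
are linked by the consistency identity

    RA = (1 + ME%/100) × RE%,

i.e. C/A = (B/A)·(C/B). The enhancement-style ME% used here must be moved
back to the ratio scale (B/A = 1 + ME%/100) before multiplying; the
identity helper does that conversion explicitly.

ME is flagged when |ME%| exceeds 25, and any statistic's precision is
flagged when its CV% exceeds 15 (20 near the limit of quantification) —
the acceptance thresholds of the LC-MS/MS validation guidelines, applied
here in the absence of GC-MS-specific ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .nd import ND, NDType, is_nd

__all__ = [
    "Metric",
    "MetricResult",
    "AcceptanceFlag",
    "matrix_effect",
    "matrix_effect_normalized",
    "extraction_recovery",
    "process_efficiency",
    "matuszewski_identity",
    "pad_transfer_recovery",
    "acceptance_flags",
    "ratio_metric",
    "ME_LIMIT",
    "CV_LIMIT",
    "CV_LIMIT_NEAR_LOQ",
]

ME_LIMIT = 25.0
CV_LIMIT = 15.0
CV_LIMIT_NEAR_LOQ = 20.0


class Metric(str, enum.Enum):
    ME = "ME"
    ME_N = "ME_n"
    RE = "RE"
    RE_N = "RE_n"
    RA = "RA"
    RA_N = "RA_n"
    R_PAD = "R_pad"
    R_PAD_N = "R_pad_n"


#: metric → (numerator set kind, denominator set kind, normalized?)
SIGNED_METRICS = frozenset({Metric.ME, Metric.ME_N})
NORMALIZED_METRICS = frozenset({Metric.ME_N, Metric.RE_N, Metric.RA_N, Metric.R_PAD_N})


@dataclass(frozen=True)
class MetricResult:
    """One validation statistic for one analyte × arm × level cell."""

    metric: Metric
    analyte: str
    arm: str
    conc: float
    value: float | NDType
    cv: float | None
    n: int
    numerator_mean: float | NDType | None = None
    denominator_mean: float | NDType | None = None
    day_range: tuple[float, float] | None = None
    surrogate_is: bool | None = None  # normalized via a different-molecule IS

    def __post_init__(self) -> None:
        if not is_nd(self.value) and self.metric not in SIGNED_METRICS:
            if self.value < 0:
                raise ValueError(f"{self.metric.value} cannot be negative")


@dataclass(frozen=True)
class AcceptanceFlag:
    """Guideline exceedance flags for one metric cell."""

    me_exceeds: bool
    cv_exceeds: bool
    near_loq: bool
    evaluable: bool = True


def _check_ratio(numerator, denominator, what: str) -> float | NDType | None:
    """Shared nd / zero-denominator handling. Returns the ratio, ND, or
    raises ZeroDivisionError."""
    if is_nd(numerator) or is_nd(denominator):
        return ND
    if denominator == 0:
        raise ZeroDivisionError(f"{what}: denominator mean is zero, ratio undefined")
    return numerator / denominator


def matrix_effect(mean_b: float | NDType, mean_a: float | NDType) -> float | NDType:
    """Signed matrix effect (B/A − 1) × 100 from post-extraction-spike (B)
    and neat-standard (A) group means. Positive = enhancement, negative =
    suppression."""
    ratio = _check_ratio(mean_b, mean_a, "matrix_effect")
    if is_nd(ratio):
        return ND
    return (ratio - 1.0) * 100.0


def matrix_effect_normalized(
    mean_b_over_is: float | NDType, mean_a_over_is: float | NDType
) -> float | NDType:
    """Matrix effect on IS-normalized responses: ((B/IS)/(A/IS) − 1) × 100.

    The per-injection ``area/is_area`` ratios must be formed before
    averaging (see :meth:`ExperimentTable.normalized_ratios`)."""
    return matrix_effect(mean_b_over_is, mean_a_over_is)


def extraction_recovery(mean_c: float | NDType, mean_b: float | NDType) -> float | NDType:
    """True extraction recovery C/B × 100. Using B (matrix, no extraction
    loss) as the reference cancels the matrix effect; dividing by A instead
    silently folds the matrix effect into the 'recovery'."""
    ratio = _check_ratio(mean_c, mean_b, "extraction_recovery")
    if is_nd(ratio):
        return ND
    return ratio * 100.0


def process_efficiency(mean_c: float | NDType, mean_a: float | NDType) -> float | NDType:
    """Process efficiency (apparent recovery) C/A × 100: the overall signal
    yield of matrix + extraction relative to the neat standard."""
    ratio = _check_ratio(mean_c, mean_a, "process_efficiency")
    if is_nd(ratio):
        return ND
    return ratio * 100.0


def matuszewski_identity(me_enhancement: float, re: float) -> float:
    """Reconstruct process efficiency from ME% and RE%:
    RA = (1 + ME%/100) × RE%.

    The enhancement-style ME% is converted back to the ratio scale
    (B/A = 1 + ME%/100) so that RA = (B/A)·(C/B)·100 holds exactly.
    """
    if is_nd(me_enhancement) or is_nd(re):
        return ND
    if re < 0:
        raise ValueError("extraction recovery must be >= 0")
    if me_enhancement <= -100.0:
        raise ValueError("ME% <= -100 implies a nonpositive B/A ratio")
    return (1.0 + me_enhancement / 100.0) * re


def pad_transfer_recovery(
    mean_tube_a: float | NDType, mean_tube_b: float | NDType
) -> float | NDType:
    """Percent of analyte transferred from the device pad into the buffer:
    area(Tube a, pad + buffer) / area(Tube b, buffer only) × 100."""
    ratio = _check_ratio(mean_tube_a, mean_tube_b, "pad_transfer_recovery")
    if is_nd(ratio):
        return ND
    return ratio * 100.0


def acceptance_flags(
    metric: MetricResult,
    near_loq: bool = False,
    me_limit: float = ME_LIMIT,
    cv_limit: float = CV_LIMIT,
    cv_limit_near_loq: float = CV_LIMIT_NEAR_LOQ,
) -> AcceptanceFlag:
    """Guideline flags: |ME| strictly above 25%, CV strictly above 15%
    (20% near the LOQ). An nd metric is not evaluable."""
    if is_nd(metric.value):
        return AcceptanceFlag(False, False, near_loq, evaluable=False)
    me_exceeds = (
        metric.metric in SIGNED_METRICS and abs(metric.value) > me_limit
    )
    limit = cv_limit_near_loq if near_loq else cv_limit
    cv_exceeds = metric.cv is not None and metric.cv > limit
    return AcceptanceFlag(me_exceeds=me_exceeds, cv_exceeds=cv_exceeds, near_loq=near_loq)


def ratio_metric(
    metric: Metric,
    numerator_values,
    denominator_values,
    analyte: str,
    arm: str,
    conc: float,
    day_range: tuple[float, float] | None = None,
    surrogate_is: bool | None = None,
) -> MetricResult:
    """Build a :class:`MetricResult` from the raw replicate values of the
    numerator and denominator groups.

    The value is a ratio of group means. The reported CV% is the CV of the
    per-replicate numerator values (scaling them by the constant
    denominator mean leaves the CV unchanged), and n is the numerator
    replicate count.
    """
    from .table import summarize_group  # local import to avoid a cycle

    num = summarize_group(numerator_values)
    den = summarize_group(denominator_values)
    num_mean = ND if is_nd(num) else num.mean
    den_mean = ND if is_nd(den) else den.mean
    n = len([v for v in numerator_values if v is not None])
    cv = None if is_nd(num) else num.cv
    if metric in (Metric.ME, Metric.ME_N):
        value = matrix_effect(num_mean, den_mean)
    elif metric in (Metric.RE, Metric.RE_N):
        value = extraction_recovery(num_mean, den_mean)
    elif metric in (Metric.RA, Metric.RA_N):
        value = process_efficiency(num_mean, den_mean)
    else:
        value = pad_transfer_recovery(num_mean, den_mean)
    return MetricResult(
        metric=metric,
        analyte=analyte,
        arm=arm,
        conc=conc,
        value=value,
        cv=cv,
        n=n,
        numerator_mean=num_mean,
        denominator_mean=den_mean,
        day_range=day_range,
        surrogate_is=surrogate_is,
    )


def round_for_report(value: float | NDType) -> str:
    """Table-style rounding: integer percent, one decimal below 1 in
    magnitude; nd prints as 'nd'."""
    if is_nd(value):
        return "nd"
    if value is None:
        return ""
    if abs(value) < 1.0 and value != 0:
        return f"{value:.1f}"
    return f"{value:.0f}"
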