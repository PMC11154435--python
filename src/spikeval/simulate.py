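"""Seeded generator of spiking-experiment tables, chromatogram traces, and
real-sample time courses with known ground truth.

The generator encodes the mechanisms the validation statistics are meant
to measure, so every downstream number has a closed-form expectation:

* **Matrix enhancement** — injections carrying co-extracted matrix see a
  multiplicative signal gain drawn per injection (GC-MS active-site
  competition is erratic between injections, so the gain is random, with
  CV ``enhancement_cv``). The neat standard (set A) never sees it.
* **Extraction loss** — analytes spiked before SPE (sets C/C_Q) keep only
  ``extraction_efficiency`` of their signal.
* **Pad retention** — polar analytes stick to the collection device's
  absorbent pad. Retained fraction is a decreasing logistic in logP:
  ``1 / (1 + exp(steepness · (logP − midpoint)))``.
* **Buffer interference censoring** — device-arm signals below an area
  threshold report the nd sentinel (censored, not zero).
* **Injection noise** — multiplicative lognormal with unit mean and the
  stated CV (areas are positive; replicate dispersion in such studies is
  relative).

Internal-standard areas are generated at the IS spiking level and run
through the same set-dependent extraction/pad factors as a pre-extraction
spike (the IS is added before processing), but their matrix gain is
``E ** is_coupling`` where ``E`` is the paired analyte's gain in that
injection — ``is_coupling = 1`` models a perfectly co-varying deuterated
analogue, ``0`` an IS blind to the matrix.

Expected area for a target at level ``c`` (response factor ``RF``):

=========  =============================================
set        expected area
=========  =============================================
A          RF·c
B, B_Q     RF·c·E
C          RF·c·E·eff
C_Q        RF·c·E·eff·(1 − retained)
TUBE_A     RF·c·(1 − retained)
TUBE_B     RF·c
=========  =============================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .analytes import (
    Arm,
    AnalytePanel,
    EXTRACTED_SETS,
    MATRIX_SETS,
    PAD_SETS,
    QUANTISAL_ONLY_SETS,
    SetLabel,
    SpikeCondition,
    default_panel,
)
from .calibration import ChromTrace
from .nd import ND, is_nd
from .realsample import TimecoursePoint
from .table import ExperimentTable, PeakMeasurement

__all__ = [
    "TruthParams",
    "DesignSpec",
    "pad_retained_fraction",
    "simulate_experiment",
    "simulate_trace",
    "simulate_tea_timecourse",
    "paper_like_truth",
    "default_design",
]

IS_NOMINAL_NG_ML = 15.0


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the generator.

    The shipped defaults (:func:`paper_like_truth`) form an illustrative
    profile: strong, erratic enhancement for the pyrrolidine alkaloids
    (CUS) and the cinnamoyl ester (t-CIN), mild enhancement elsewhere,
    extraction efficiencies between 0.35 and 0.65, and pad retention that
    effectively removes the polar analytes (EME, CUS) from device-arm
    samples at low levels. They reproduce the qualitative patterns of the
    validation study, not its numbers.
    """

    response_factor: Mapping[str, float]
    matrix_enhancement_mean: Mapping[str, float]
    enhancement_cv: float = 10.0
    extraction_efficiency: Mapping[str, float] = field(default_factory=dict)
    pad_retention_midpoint_logP: float = 1.5
    pad_retention_steepness: float = 4.0
    buffer_interference_censor: float = 0.0
    injection_cv: float = 10.0
    is_coupling: float = 1.0
    seed: int = 0
    # real-sample time-course parameters (per-analyte)
    t0_ratio: Mapping[str, float] = field(default_factory=dict)
    decay_rate_per_min: Mapping[str, float] = field(default_factory=dict)
    detection_ratio: float = 0.01  # ratio at which S/N falls to 3
    # chromatogram-trace parameters
    trace_noise_sd: float = 5.0
    trace_height_per_conc: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.is_coupling <= 1.0:
            raise ValueError("is_coupling must be in [0, 1]")
        for name, eff in self.extraction_efficiency.items():
            if not 0.0 < eff <= 1.0:
                raise ValueError(f"extraction efficiency for {name} must be in (0, 1]")
        for name, enh in self.matrix_enhancement_mean.items():
            if enh < 0:
                raise ValueError(f"matrix enhancement for {name} must be >= 0")
        if self.enhancement_cv < 0 or self.injection_cv < 0:
            raise ValueError("CVs must be >= 0")

    def with_(self, **kwargs) -> "TruthParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DesignSpec:
    """Which cells to generate: analytes × arms × sets × levels × n × days."""

    analytes: tuple[str, ...]
    arms: tuple[Arm, ...] = (Arm.DROOLING, Arm.QUANTISAL)
    sets: tuple[SetLabel, ...] = (
        SetLabel.A_NEAT,
        SetLabel.B_POST_SPIKE,
        SetLabel.C_PRE_SPIKE,
        SetLabel.BQ_POST_SPIKE,
        SetLabel.CQ_PRE_SPIKE,
        SetLabel.TUBE_A_PAD,
        SetLabel.TUBE_B_BUFFER,
    )
    levels: tuple[float, ...] = (10.0, 20.0, 50.0, 500.0)
    replicates: int = 3
    days: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.days < 1:
            raise ValueError("replicates and days are >= 1")
        if not self.analytes:
            raise ValueError("design needs at least one analyte")
        if any(lvl < 0 for lvl in self.levels):
            raise ValueError("levels must be >= 0")


def pad_retained_fraction(logP: float, truth: TruthParams) -> float:
    """Fraction of analyte retained on the device pad: a decreasing
    logistic in logP (polar analytes stick, hydrophobic ones elute)."""
    if not math.isfinite(logP):
        raise ValueError("logP must be finite")
    z = truth.pad_retention_steepness * (logP - truth.pad_retention_midpoint_logP)
    return 1.0 / (1.0 + math.exp(z))


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size=None):
    """Multiplicative noise with mean 1 and the given CV."""
    if cv_pct == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log1p((cv_pct / 100.0) ** 2)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _set_factors(
    set_label: SetLabel,
    analyte: str,
    panel: AnalytePanel,
    truth: TruthParams,
    enhancement: float,
    coupling_power: float = 1.0,
) -> float:
    """Deterministic part of the expected area multiplier for one set,
    excluding RF·c."""
    factor = 1.0
    if set_label in MATRIX_SETS:
        factor *= enhancement ** coupling_power
    if set_label in EXTRACTED_SETS:
        factor *= truth.extraction_efficiency.get(analyte, 1.0)
    if set_label in PAD_SETS:
        factor *= 1.0 - pad_retained_fraction(panel[analyte].logP, truth)
    return factor


def simulate_experiment(
    truth: TruthParams,
    design: DesignSpec,
    panel: AnalytePanel | None = None,
    seed: int | None = None,
) -> tuple[ExperimentTable, dict]:
    """Generate a spiking-experiment table plus a ground-truth sidecar.

    Deterministic under a fixed seed (``seed`` overrides ``truth.seed``).
    The sidecar records every parameter needed to verify downstream
    statistics by parameter recovery.
    """
    panel = panel if panel is not None else default_panel()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records: list[PeakMeasurement] = []
    for analyte in design.analytes:
        spec = panel[analyte]
        rf = truth.response_factor.get(analyte, 1000.0)
        is_name = spec.assigned_is
        rf_is = truth.response_factor.get(is_name, 1000.0) if is_name else None
        enh_mean = truth.matrix_enhancement_mean.get(analyte, 1.0)
        for arm in design.arms:
            for set_label in design.sets:
                if set_label in QUANTISAL_ONLY_SETS and arm is not Arm.QUANTISAL:
                    continue
                if set_label is SetLabel.A_NEAT and arm is not design.arms[0]:
                    continue  # the neat standard is arm-independent; emit once
                if (
                    set_label in (SetLabel.B_POST_SPIKE, SetLabel.C_PRE_SPIKE)
                    and arm is Arm.QUANTISAL
                    and Arm.DROOLING in design.arms
                ):
                    continue  # plain B/C belong to the drooling arm of a two-arm design
                for conc in design.levels:
                    for day in range(1, design.days + 1):
                        for rep in range(1, design.replicates + 1):
                            enhancement = (
                                enh_mean * _lognormal_factor(rng, truth.enhancement_cv)
                                if set_label in MATRIX_SETS
                                else 1.0
                            )
                            area = (
                                rf
                                * conc
                                * _set_factors(set_label, analyte, panel, truth, enhancement)
                                * _lognormal_factor(rng, truth.injection_cv)
                            )
                            is_area = None
                            if is_name is not None:
                                is_area = (
                                    rf_is
                                    * IS_NOMINAL_NG_ML
                                    * _set_factors(
                                        set_label, is_name, panel, truth,
                                        enhancement, truth.is_coupling,
                                    )
                                    * _lognormal_factor(rng, truth.injection_cv)
                                )
                            if (
                                arm is Arm.QUANTISAL
                                and set_label is not SetLabel.A_NEAT
                                and truth.buffer_interference_censor > 0
                            ):
                                if area < truth.buffer_interference_censor:
                                    area = ND
                                if (
                                    is_area is not None
                                    and not is_nd(is_area)
                                    and is_area < truth.buffer_interference_censor
                                ):
                                    is_area = ND
                            records.append(
                                PeakMeasurement(
                                    analyte=analyte,
                                    condition=SpikeCondition(
                                        arm=arm,
                                        set_label=set_label,
                                        nominal_conc=conc,
                                        day=day,
                                        replicate=rep,
                                        enforce_grid=False,
                                    ),
                                    area=area,
                                    is_area=is_area,
                                )
                            )
    sidecar = {
        "response_factor": dict(truth.response_factor),
        "matrix_enhancement_mean": dict(truth.matrix_enhancement_mean),
        "enhancement_cv": truth.enhancement_cv,
        "extraction_efficiency": dict(truth.extraction_efficiency),
        "pad_retention_midpoint_logP": truth.pad_retention_midpoint_logP,
        "pad_retention_steepness": truth.pad_retention_steepness,
        "pad_retained_fraction": {
            a: pad_retained_fraction(panel[a].logP, truth) for a in design.analytes
        },
        "buffer_interference_censor": truth.buffer_interference_censor,
        "injection_cv": truth.injection_cv,
        "is_coupling": truth.is_coupling,
        "seed": truth.seed if seed is None else seed,
        "expected": {
            a: {
                "ME_pct": 100.0 * (truth.matrix_enhancement_mean.get(a, 1.0) - 1.0),
                "RE_pct": 100.0 * truth.extraction_efficiency.get(a, 1.0),
                "RA_pct": 100.0
                * truth.matrix_enhancement_mean.get(a, 1.0)
                * truth.extraction_efficiency.get(a, 1.0),
                "R_pad_pct": 100.0 * (1.0 - pad_retained_fraction(panel[a].logP, truth)),
            }
            for a in design.analytes
        },
    }
    return ExperimentTable(records, panel=panel), sidecar


def simulate_trace(
    conc: float,
    truth: TruthParams,
    arm: Arm | str = Arm.DROOLING,
    analyte: str = "COC",
    panel: AnalytePanel | None = None,
    n_points: int = 400,
    seed: int | None = None,
) -> ChromTrace:
    """A Gaussian peak on a white-noise baseline.

    Peak height is proportional to the expected pre-extraction-spike
    signal for the arm (so device-arm pad losses lower the peak); noise is
    Gaussian with SD ``truth.trace_noise_sd``, clipped at zero. Windows
    are recorded on the trace.
    """
    if conc < 0:
        raise ValueError("conc must be >= 0")
    panel = panel if panel is not None else default_panel()
    arm = Arm(arm)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    height = truth.trace_height_per_conc * conc
    height *= truth.extraction_efficiency.get(analyte, 1.0)
    height *= truth.matrix_enhancement_mean.get(analyte, 1.0)
    if arm is Arm.QUANTISAL:
        height *= 1.0 - pad_retained_fraction(panel[analyte].logP, truth)
    x = np.arange(n_points, dtype=float)
    center, width = 0.75 * n_points, n_points / 80.0
    signal = height * np.exp(-0.5 * ((x - center) / width) ** 2)
    noise = rng.normal(0.0, truth.trace_noise_sd, size=n_points)
    intensities = np.clip(signal + noise + 10.0 * truth.trace_noise_sd, 0.0, None)
    # a tight ±2σ window keeps the max-over-noise bias of the S/N small
    peak_lo = int(center - 2 * width)
    peak_hi = int(center + 2 * width)
    return ChromTrace(
        sampling_interval=0.1,
        intensities=intensities,
        peak_window=(peak_lo, peak_hi),
        noise_window=(0, n_points // 2),
    )


def simulate_tea_timecourse(
    truth: TruthParams,
    times: Sequence[float],
    device_factor: float = 1.0,
    volunteer: int = 1,
    panel: AnalytePanel | None = None,
) -> list[TimecoursePoint]:
    """First-order decay of external-standard-normalized ratios after a
    single coca-tea ingestion, in both collection arms.

    The drooling arm reports ``r0·exp(−k·t)`` per analyte; the device arm
    is attenuated by ``device_factor`` and by pad retention. Ratios whose
    implied S/N falls below 3 (ratio < ``truth.detection_ratio``) are
    censored to nd. Deterministic (no noise): the time course is a design
    template, not a stochastic model.
    """
    panel = panel if panel is not None else default_panel()
    points: list[TimecoursePoint] = []
    for analyte, r0 in truth.t0_ratio.items():
        k = truth.decay_rate_per_min.get(analyte, 0.0)
        for t in times:
            if t < 0:
                raise ValueError("times must be >= 0")
            base = r0 * math.exp(-k * t)
            for arm in (Arm.DROOLING, Arm.QUANTISAL):
                ratio = base
                if arm is Arm.QUANTISAL:
                    ratio *= device_factor * (
                        1.0 - pad_retained_fraction(panel[analyte].logP, truth)
                    )
                points.append(
                    TimecoursePoint(
                        volunteer=volunteer,
                        arm=arm.value,
                        time_min=float(t),
                        analyte=analyte,
                        ratio=ratio if ratio >= truth.detection_ratio else ND,
                    )
                )
    return points


def paper_like_truth(seed: int = 0) -> TruthParams:
    """The illustrative default truth profile (see :class:`TruthParams`)."""
    targets = ("EME", "CUS", "TRO", "COC", "t-CIN", "EME-d3", "COC-d3")
    return TruthParams(
        response_factor={a: 1000.0 for a in targets},
        matrix_enhancement_mean={
            "EME": 1.10,
            "CUS": 2.00,
            "TRO": 1.05,
            "COC": 1.10,
            "t-CIN": 1.35,
            "EME-d3": 1.15,
            "COC-d3": 1.10,
        },
        enhancement_cv=10.0,
        extraction_efficiency={
            "EME": 0.50,
            "CUS": 0.45,
            "TRO": 0.45,
            "COC": 0.45,
            "t-CIN": 0.40,
            "EME-d3": 0.50,
            "COC-d3": 0.45,
        },
        pad_retention_midpoint_logP=1.5,
        pad_retention_steepness=4.0,
        buffer_interference_censor=4000.0,
        injection_cv=10.0,
        is_coupling=1.0,
        seed=seed,
        t0_ratio={"HYG": 0.4, "CUS": 0.6, "EME": 1.2, "TRO": 0.005, "COC": 17.0, "t-CIN": 1.3},
        decay_rate_per_min={
            "HYG": 0.020,
            "CUS": 0.020,
            "EME": 0.018,
            "TRO": 0.030,
            "COC": 0.030,
            "t-CIN": 0.028,
        },
        detection_ratio=0.02,
    )


def default_design(analytes: Sequence[str] | None = None) -> DesignSpec:
    """The full two-arm, seven-set, four-level triplicate design."""
    if analytes is None:
        analytes = ("EME", "CUS", "TRO", "COC", "t-CIN", "EME-d3", "COC-d3")
    return DesignSpec(analytes=tuple(analytes))
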