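"""Long-format peak-area tables for spiking experiments.

One row = one injection of one analyte: its absolute peak area, the area of
its assigned deuterated internal standard measured in the same injection,
and optionally the external-standard area. Areas are floats, the censoring
sentinel :data:`~spikeval.nd.ND`, or ``None`` for a missing cell.

Censoring propagates conservatively: a replicate group containing *any* nd
injection has an nd mean, mirroring how validation reports print whole
cells as nd rather than mixing detected and undetected replicates.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .analytes import AnalytePanel, Arm, SetLabel, SpikeCondition, default_panel
from .nd import ND, NDType, coerce_area, is_nd

__all__ = [
    "PeakMeasurement",
    "ExperimentTable",
    "GroupStats",
    "read_peak_table",
    "write_peak_table",
    "mean_area",
    "PeakTableError",
    "SchemaError",
    "LookupError_",
]

REQUIRED_COLUMNS = (
    "analyte",
    "arm",
    "set",
    "conc_ng_ml",
    "day",
    "replicate",
    "area",
    "is_area",
    "skf_area",
)


class PeakTableError(ValueError):
    """Base error for malformed peak tables."""


class SchemaError(PeakTableError):
    """Structural problem: bad header, unknown label, duplicate key."""


class LookupError_(PeakTableError):
    """A requested replicate group does not exist in the table."""


@dataclass(frozen=True)
class PeakMeasurement:
    """One injection's areas for one analyte under one spiking condition."""

    analyte: str
    condition: SpikeCondition
    area: float | NDType | None
    is_area: float | NDType | None = None
    skf_area: float | NDType | None = None

    def __post_init__(self) -> None:
        for label, value in (("area", self.area), ("is_area", self.is_area),
                             ("skf_area", self.skf_area)):
            if value is not None and not is_nd(value) and value < 0:
                raise ValueError(f"{label} must be nonnegative, got {value}")

    @property
    def key(self) -> tuple:
        return (self.analyte, *self.condition.key)


@dataclass(frozen=True)
class GroupStats:
    """Mean, CV% and replicate count of one replicate group."""

    mean: float
    cv: float | None
    n: int


class ExperimentTable:
    """A validated collection of :class:`PeakMeasurement` records.

    Enforces key uniqueness and known analyte labels against a panel, and
    offers the grouped queries (replicate areas, group means, normalized
    ratios) that the validation statistics consume.
    """

    def __init__(
        self,
        records: Iterable[PeakMeasurement],
        panel: AnalytePanel | None = None,
    ):
        self.panel = panel if panel is not None else default_panel()
        self.records: list[PeakMeasurement] = list(records)
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.analyte not in self.panel:
                raise SchemaError(f"unknown analyte label {rec.analyte!r}")
            if rec.key in seen:
                raise SchemaError(f"duplicate measurement key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # -- queries ---------------------------------------------------------

    def select(
        self,
        analyte: str,
        set_label: SetLabel | str,
        conc: float | None = None,
        arm: Arm | str | None = None,
        day: int | None = None,
    ) -> list[PeakMeasurement]:
        set_label = SetLabel(set_label)
        arm = Arm(arm) if arm is not None else None
        out = []
        for rec in self.records:
            c = rec.condition
            if rec.analyte != analyte or c.set_label is not set_label:
                continue
            if conc is not None and c.nominal_conc != conc:
                continue
            if arm is not None and c.arm is not arm:
                continue
            if day is not None and c.day != day:
                continue
            out.append(rec)
        return out

    def areas(self, analyte, set_label, conc=None, arm=None, day=None) -> list:
        return [r.area for r in self.select(analyte, set_label, conc, arm, day)]

    def normalized_ratios(self, analyte, set_label, conc=None, arm=None, day=None) -> list:
        """Per-injection area / IS-area ratios.

        Injections whose IS area is nd or zero cannot be normalized and are
        dropped; an injection with an nd analyte area keeps the nd (it
        censors the group downstream). Missing IS areas are also dropped.
        """
        ratios = []
        for rec in self.select(analyte, set_label, conc, arm, day):
            if rec.is_area is None or is_nd(rec.is_area) or rec.is_area == 0:
                continue
            if is_nd(rec.area):
                ratios.append(ND)
            elif rec.area is not None:
                ratios.append(rec.area / rec.is_area)
        return ratios

    def days(self, analyte, set_label, conc=None, arm=None) -> list[int]:
        return sorted({r.condition.day for r in self.select(analyte, set_label, conc, arm)})

    @property
    def design_meta(self) -> pd.DataFrame:
        """Replicate counts per (analyte, arm, set, conc, day)."""
        df = self.to_dataframe()
        return (
            df.groupby(["analyte", "arm", "set", "conc_ng_ml", "day"], as_index=False)
            .size()
            .rename(columns={"size": "n"})
        )

    def unnormalizable_targets(self) -> list[PeakMeasurement]:
        """Target records whose IS area is nd (flagged, per the table invariant)."""
        flagged = []
        for rec in self.records:
            spec = self.panel[rec.analyte]
            if spec.assigned_is is not None and is_nd(rec.is_area):
                flagged.append(rec)
        return flagged

    # -- conversion ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            c = rec.condition
            rows.append(
                {
                    "analyte": rec.analyte,
                    "arm": c.arm.value,
                    "set": c.set_label.value,
                    "conc_ng_ml": c.nominal_conc,
                    "day": c.day,
                    "replicate": c.replicate,
                    "area": rec.area,
                    "is_area": rec.is_area,
                    "skf_area": rec.skf_area,
                }
            )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


# -- statistics ----------------------------------------------------------


def summarize_group(values: Sequence) -> GroupStats | NDType:
    """Mean, CV% (sample SD, n−1) and n of one replicate group.

    Any nd value censors the whole group to nd. ``None`` (missing) entries
    are ignored. Raises :class:`LookupError_` on an empty group.
    """
    values = [v for v in values if v is not None]
    if not values:
        raise LookupError_("no matching measurements for the requested group")
    if any(is_nd(v) for v in values):
        return ND
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size > 1:
        sd = float(arr.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else math.inf if sd > 0 else 0.0
    else:
        cv = None
    return GroupStats(mean=mean, cv=cv, n=int(arr.size))


def mean_area(
    table: ExperimentTable,
    analyte: str,
    set_label: SetLabel | str,
    conc: float | None = None,
    arm: Arm | str | None = None,
    day: int | None = None,
) -> GroupStats | NDType:
    """Mean peak area of one replicate group (censored to nd if any
    replicate is nd)."""
    return summarize_group(table.areas(analyte, set_label, conc, arm, day))


# -- CSV I/O -------------------------------------------------------------


def _format_cell(value: float | NDType | None) -> str:
    if value is None:
        return ""
    if is_nd(value):
        return "nd"
    if isinstance(value, float) and math.isnan(value):  # pandas upcast of None
        return ""
    return repr(value)


def read_peak_table(
    path: str | Path | io.TextIOBase,
    panel: AnalytePanel | None = None,
    enforce_grid: bool = True,
) -> ExperimentTable:
    """Read a long-format peak-area CSV into a validated table.

    The header must contain the columns ``analyte, arm, set, conc_ng_ml,
    day, replicate, area, is_area, skf_area``. Area cells may hold a
    number, the token ``nd`` (any case, the censoring sentinel) or be
    blank (missing). Blank is *not* nd.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header
        try:
            arm = Arm(row["arm"].strip())
            set_label = SetLabel(row["set"].strip())
        except ValueError as exc:
            raise SchemaError(f"row {rownum}: unknown label ({exc})") from None
        try:
            condition = SpikeCondition(
                arm=arm,
                set_label=set_label,
                nominal_conc=float(row["conc_ng_ml"]),
                day=int(row["day"]),
                replicate=int(row["replicate"]),
                enforce_grid=enforce_grid,
            )
            records.append(
                PeakMeasurement(
                    analyte=row["analyte"].strip(),
                    condition=condition,
                    area=coerce_area(row["area"]),
                    is_area=coerce_area(row["is_area"]),
                    skf_area=coerce_area(row["skf_area"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise PeakTableError(f"row {rownum}: {exc}") from None
    return ExperimentTable(records, panel=panel)


def write_peak_table(table: ExperimentTable, path: str | Path | io.TextIOBase) -> None:
    """Write the canonical long-format CSV (comma, dot decimal, ``nd`` token,
    blank for missing). Round-trips byte-for-byte with :func:`read_peak_table`."""
    df = table.to_dataframe()
    for col in ("area", "is_area", "skf_area"):
        df[col] = df[col].map(_format_cell)
    df["conc_ng_ml"] = df["conc_ng_ml"].map(repr)
    df.to_csv(path, index=False)
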