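"""The validation study as a model/results pair.

:class:`ValidationStudy` is built from an :class:`~spikeval.table.ExperimentTable`
(or a long-format DataFrame / CSV); ``fit()`` evaluates the requested
validation statistics for every analyte × arm × level cell present in the
data and returns a :class:`ValidationResults` carrying the metric grid,
guideline flags, the consistency-identity residuals, and a ``summary()``
table. Cells whose required sets are absent are marked "not computed" with
a reason rather than silently dropped.

Multi-day cells (the same analyte × set × level replicated on several
days) are evaluated per day and reported as a min–max range; the cell
value is the mean of the per-day values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .analytes import AnalytePanel, Arm, SetLabel, default_panel
from .metrics import (
    Metric,
    MetricResult,
    NORMALIZED_METRICS,
    acceptance_flags,
    matuszewski_identity,
    ratio_metric,
    round_for_report,
)
from .nd import ND, is_nd
from .table import ExperimentTable, LookupError_, read_peak_table

__all__ = ["ValidationStudy", "ValidationResults", "build_validation_report"]

#: metric → (numerator set, denominator set) per arm. Set A (neat standard)
#: is arm-independent and matched ignoring the stored arm.
_SET_MAP = {
    (Metric.ME, Arm.DROOLING): (SetLabel.B_POST_SPIKE, SetLabel.A_NEAT),
    (Metric.ME, Arm.QUANTISAL): (SetLabel.BQ_POST_SPIKE, SetLabel.A_NEAT),
    (Metric.RE, Arm.DROOLING): (SetLabel.C_PRE_SPIKE, SetLabel.B_POST_SPIKE),
    (Metric.RE, Arm.QUANTISAL): (SetLabel.CQ_PRE_SPIKE, SetLabel.BQ_POST_SPIKE),
    (Metric.RA, Arm.DROOLING): (SetLabel.C_PRE_SPIKE, SetLabel.A_NEAT),
    (Metric.RA, Arm.QUANTISAL): (SetLabel.CQ_PRE_SPIKE, SetLabel.A_NEAT),
    (Metric.R_PAD, Arm.QUANTISAL): (SetLabel.TUBE_A_PAD, SetLabel.TUBE_B_BUFFER),
}
_ABS_OF = {
    Metric.ME_N: Metric.ME,
    Metric.RE_N: Metric.RE,
    Metric.RA_N: Metric.RA,
    Metric.R_PAD_N: Metric.R_PAD,
}

DEFAULT_METRICS = (
    Metric.ME,
    Metric.ME_N,
    Metric.RE,
    Metric.RE_N,
    Metric.RA,
    Metric.RA_N,
    Metric.R_PAD,
    Metric.R_PAD_N,
)


def _group_values(table: ExperimentTable, analyte, set_label, conc, arm, day, normalized):
    arm_filter = None if set_label is SetLabel.A_NEAT else arm
    if normalized:
        return table.normalized_ratios(analyte, set_label, conc, arm_filter, day)
    return table.areas(analyte, set_label, conc, arm_filter, day)


def _cell(
    table: ExperimentTable,
    metric: Metric,
    analyte: str,
    arm: Arm,
    conc: float,
    surrogate_is: bool | None,
) -> tuple[MetricResult | None, str | None]:
    """Evaluate one report cell; returns (result, reason-if-not-computed)."""
    base = _ABS_OF.get(metric, metric)
    sets = _SET_MAP.get((base, arm))
    if sets is None:
        return None, f"{metric.value} is not defined for the {arm.value} arm"
    num_set, den_set = sets
    normalized = metric in NORMALIZED_METRICS
    days = sorted(
        set(table.days(analyte, num_set, conc, None if num_set is SetLabel.A_NEAT else arm))
    )
    if not days:
        return None, f"no {num_set.value} records for this cell"
    den_days = table.days(analyte, den_set, conc, None if den_set is SetLabel.A_NEAT else arm)
    if not den_days:
        return None, f"no {den_set.value} records for this cell"

    def _nd_cell() -> MetricResult:
        # the set exists but no injection could be normalized (IS censored):
        # the cell is censored, not missing
        return MetricResult(metric=metric, analyte=analyte, arm=arm.value, conc=conc,
                            value=ND, cv=None, n=0, numerator_mean=ND,
                            denominator_mean=ND, surrogate_is=surrogate_is)

    per_day: list[MetricResult] = []
    for day in days:
        num = _group_values(table, analyte, num_set, conc, arm, day, normalized)
        den_day = day if day in den_days else None
        den = _group_values(table, analyte, den_set, conc, arm, den_day, normalized)
        if not [v for v in num if v is not None] or not [v for v in den if v is not None]:
            if normalized:
                return _nd_cell(), None
            return None, f"no usable {num_set.value}/{den_set.value} values"
        try:
            per_day.append(
                ratio_metric(metric, num, den, analyte, arm.value, conc,
                             surrogate_is=surrogate_is)
            )
        except (ZeroDivisionError, LookupError_) as exc:
            return None, str(exc)
    if len(per_day) == 1:
        return per_day[0], None
    values = [r.value for r in per_day]
    if any(is_nd(v) for v in values):
        value, day_range = ND, None
    else:
        value, day_range = float(np.mean(values)), (min(values), max(values))
    cvs = [r.cv for r in per_day if r.cv is not None]
    pooled = MetricResult(
        metric=metric,
        analyte=analyte,
        arm=arm.value,
        conc=conc,
        value=value,
        cv=max(cvs) if cvs else None,
        n=sum(r.n for r in per_day),
        numerator_mean=per_day[0].numerator_mean,
        denominator_mean=per_day[0].denominator_mean,
        day_range=day_range,
        surrogate_is=surrogate_is,
    )
    return pooled, None


def build_validation_report(
    table: ExperimentTable,
    metrics: Sequence[Metric] = DEFAULT_METRICS,
    analytes: Sequence[str] | None = None,
    near_loq_max_conc: float = 10.0,
) -> pd.DataFrame:
    """Evaluate the requested metrics for every analyte × arm × level cell.

    Returns a long DataFrame with one row per cell: the metric value
    (or nd), CV%, n, the group means, guideline flags, a day range for
    multi-day cells, and — on process-efficiency rows — the residual
    |RA − (1 + ME/100)·RE| of the consistency identity, computed from the
    same three group means.
    """
    panel = table.panel
    if analytes is None:
        analytes = [a for a in panel if panel[a].role.value != "external_standard"]
    df = table.to_dataframe()
    rows = []
    cache: dict[tuple, MetricResult | None] = {}

    def cell(metric, analyte, arm, conc, surrogate):
        key = (metric, analyte, arm, conc)
        if key not in cache:
            cache[key] = _cell(table, metric, analyte, arm, conc, surrogate)
        return cache[key]

    for analyte in analytes:
        spec = panel[analyte]
        surrogate = None
        if spec.assigned_is is not None:
            surrogate = spec.assigned_is != f"{analyte}-d3"
        sub = df[df["analyte"] == analyte]
        if sub.empty:
            continue
        for arm in (Arm.DROOLING, Arm.QUANTISAL):
            concs = sorted(
                set(
                    sub[(sub["arm"] == arm.value) | (sub["set"] == SetLabel.A_NEAT.value)][
                        "conc_ng_ml"
                    ]
                )
            )
            concs = [c for c in concs if c > 0]
            arm_sets = set(sub[sub["arm"] == arm.value]["set"])
            if not arm_sets - {SetLabel.A_NEAT.value}:
                continue
            for conc in concs:
                for metric in metrics:
                    normalized = metric in NORMALIZED_METRICS
                    if normalized and spec.assigned_is is None:
                        continue  # ISs/external standards have no normalized form
                    if (_ABS_OF.get(metric, metric), arm) not in _SET_MAP:
                        continue  # e.g. pad recovery only exists for the device arm
                    result, reason = cell(metric, analyte, arm, conc, surrogate if normalized else None)
                    row = {
                        "metric": metric.value,
                        "analyte": analyte,
                        "arm": arm.value,
                        "conc_ng_ml": conc,
                        "status": "ok" if result is not None else "not computed",
                        "reason": reason,
                        "value": result.value if result is not None else None,
                        "cv_pct": result.cv if result is not None else None,
                        "n": result.n if result is not None else 0,
                        "numerator_mean": result.numerator_mean if result is not None else None,
                        "denominator_mean": result.denominator_mean if result is not None else None,
                        "day_min": result.day_range[0] if result is not None and result.day_range else None,
                        "day_max": result.day_range[1] if result is not None and result.day_range else None,
                        "surrogate_is": result.surrogate_is if result is not None else None,
                        "identity_residual": None,
                    }
                    if result is not None:
                        flags = acceptance_flags(result, near_loq=conc <= near_loq_max_conc)
                        row["me_exceeds"] = flags.me_exceeds if flags.evaluable else None
                        row["cv_exceeds"] = flags.cv_exceeds if flags.evaluable else None
                    else:
                        row["me_exceeds"] = None
                        row["cv_exceeds"] = None
                    if metric in (Metric.RA, Metric.RA_N) and result is not None:
                        pair = (Metric.ME, Metric.RE) if metric is Metric.RA else (Metric.ME_N, Metric.RE_N)
                        me_res, _ = cell(pair[0], analyte, arm, conc, surrogate if normalized else None)
                        re_res, _ = cell(pair[1], analyte, arm, conc, surrogate if normalized else None)
                        if (
                            me_res is not None
                            and re_res is not None
                            and not any(is_nd(v) for v in (me_res.value, re_res.value, result.value))
                            and me_res.day_range is None
                            and re_res.day_range is None
                            and result.day_range is None
                        ):
                            row["identity_residual"] = abs(
                                result.value - matuszewski_identity(me_res.value, re_res.value)
                            )
                    rows.append(row)
    return pd.DataFrame(rows)


class ValidationStudy:
    """Model object for a spiking-experiment validation study.

    Parameters
    ----------
    table : ExperimentTable
        Validated long-format peak-area table covering the sets needed by
        the requested metrics.
    metrics : sequence of Metric, optional
        Statistics to evaluate; defaults to all eight (absolute and
        IS-normalized ME / RE / RA / pad recovery).
    analytes : sequence of str, optional
        Restrict the report to these analytes.
    near_loq_max_conc : float
        Levels at or below this concentration use the relaxed 20% CV
        acceptance limit.
    """

    def __init__(
        self,
        table: ExperimentTable,
        metrics: Sequence[Metric] = DEFAULT_METRICS,
        analytes: Sequence[str] | None = None,
        near_loq_max_conc: float = 10.0,
    ):
        self.table = table
        self.metrics = tuple(metrics)
        self.analytes = tuple(analytes) if analytes is not None else None
        self.near_loq_max_conc = near_loq_max_conc

    @classmethod
    def from_csv(cls, path: str | Path, panel: AnalytePanel | None = None, **kwargs) -> "ValidationStudy":
        return cls(read_peak_table(path, panel=panel), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, panel: AnalytePanel | None = None, **kwargs) -> "ValidationStudy":
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_peak_table(buf, panel=panel), **kwargs)

    def fit(self) -> "ValidationResults":
        grid = build_validation_report(
            self.table,
            metrics=self.metrics,
            analytes=list(self.analytes) if self.analytes is not None else None,
            near_loq_max_conc=self.near_loq_max_conc,
        )
        return ValidationResults(self, grid)


class ValidationResults:
    """Fitted validation grid with flags, residuals and report writers."""

    def __init__(self, model: ValidationStudy, grid: pd.DataFrame):
        self.model = model
        self.grid = grid

    # -- accessors -------------------------------------------------------

    def metric(self, metric: Metric | str, analyte: str, arm: str | Arm, conc: float):
        """The value of one cell (float or the nd sentinel)."""
        metric = Metric(metric)
        arm = Arm(arm).value
        sel = self.grid[
            (self.grid["metric"] == metric.value)
            & (self.grid["analyte"] == analyte)
            & (self.grid["arm"] == arm)
            & (self.grid["conc_ng_ml"] == conc)
        ]
        if sel.empty:
            raise KeyError((metric.value, analyte, arm, conc))
        row = sel.iloc[0]
        if row["status"] != "ok":
            raise LookupError_(f"cell not computed: {row['reason']}")
        return row["value"]

    @property
    def identity_residuals(self) -> pd.DataFrame:
        res = self.grid[self.grid["identity_residual"].notna()]
        return res[["metric", "analyte", "arm", "conc_ng_ml", "identity_residual"]]

    @property
    def flagged(self) -> pd.DataFrame:
        ok = self.grid[self.grid["status"] == "ok"]
        return ok[(ok["me_exceeds"] == True) | (ok["cv_exceeds"] == True)]  # noqa: E712

    # -- rendering -------------------------------------------------------

    def summary(self) -> str:
        """Aligned text grids, one block per arm × metric, analytes as
        columns and levels as rows (table-style rounding)."""
        lines = []
        grid = self.grid
        for arm in sorted(grid["arm"].unique()):
            for metric in [m.value for m in self.model.metrics]:
                sub = grid[(grid["arm"] == arm) & (grid["metric"] == metric)]
                sub = sub[sub["status"] == "ok"]
                if sub.empty:
                    continue
                lines.append(f"== {metric} — {arm} arm ==")
                pivot: dict[float, dict[str, str]] = {}
                analytes = list(dict.fromkeys(sub["analyte"]))
                for _, row in sub.iterrows():
                    text = round_for_report(row["value"])
                    if row["day_min"] is not None and not pd.isna(row["day_min"]):
                        text = f"{round_for_report(row['day_min'])}–{round_for_report(row['day_max'])}"
                    if row["cv_pct"] is not None and not is_nd(row["value"]):
                        text += f" ({row['cv_pct']:.1f}%)"
                    pivot.setdefault(row["conc_ng_ml"], {})[row["analyte"]] = text
                header = ["conc"] + analytes
                widths = [max(len(h), 10) for h in header]
                lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
                for conc in sorted(pivot):
                    cells = [f"{conc:g}"] + [pivot[conc].get(a, "-") for a in analytes]
                    lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
                lines.append("")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        out = self.grid.copy()
        out["value"] = out["value"].map(lambda v: "nd" if is_nd(v) else v)
        out["numerator_mean"] = out["numerator_mean"].map(lambda v: "nd" if is_nd(v) else v)
        out["denominator_mean"] = out["denominator_mean"].map(lambda v: "nd" if is_nd(v) else v)
        out.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        records = []
        for _, row in self.grid.iterrows():
            rec = {k: ("nd" if is_nd(v) else v) for k, v in row.items()}
            rec = {k: (None if isinstance(v, float) and pd.isna(v) else v) for k, v in rec.items()}
            records.append(rec)
        text = json.dumps(records, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text
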