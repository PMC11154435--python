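"""Analyte metadata and the experimental-design vocabulary.

An :class:`AnalyteSpec` describes one compound in the GC-MS panel: its role
(quantified target, deuterated internal standard, or external standard added
just before injection), the SIM ions used to monitor it, its retention-time
group, its octanol/water partition coefficient (logP, which governs how
strongly it is retained on a collection device's absorbent pad), and — for
targets — which deuterated IS normalizes its areas.

A :class:`SpikeCondition` identifies one experimental cell of the classic
three-set matrix-effect/recovery design:

* set A — neat standard in solvent (no matrix, no extraction);
* set B — blank matrix extracted first, spiked *after* extraction
  (matrix present, no extraction loss);
* set C — matrix spiked *before* extraction (matrix and extraction loss);

plus the device counterparts B_Q/C_Q collected through an absorbent-pad
device, the pad-transfer pair (TUBE_A = pad + buffer vs TUBE_B = buffer
only), and REAL for volunteer samples.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Role",
    "Arm",
    "SetLabel",
    "AnalyteSpec",
    "AnalytePanel",
    "SpikeCondition",
    "default_panel",
    "DESIGN_GRID",
]

#: Nominal spiking levels (ng/mL) used across the validation experiments.
DESIGN_GRID = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 2000.0)


class Role(str, enum.Enum):
    TARGET = "target"
    DEUTERATED_IS = "deuterated_IS"
    EXTERNAL_STANDARD = "external_standard"


class Arm(str, enum.Enum):
    """Oral-fluid collection route."""

    DROOLING = "drooling"
    QUANTISAL = "quantisal"


class SetLabel(str, enum.Enum):
    A_NEAT = "A"
    B_POST_SPIKE = "B"
    C_PRE_SPIKE = "C"
    BQ_POST_SPIKE = "B_Q"
    CQ_PRE_SPIKE = "C_Q"
    TUBE_A_PAD = "TUBE_A"
    TUBE_B_BUFFER = "TUBE_B"
    REAL = "REAL"


#: Sets that only exist for the device (Quantisal) arm.
QUANTISAL_ONLY_SETS = frozenset(
    {SetLabel.BQ_POST_SPIKE, SetLabel.CQ_PRE_SPIKE, SetLabel.TUBE_A_PAD, SetLabel.TUBE_B_BUFFER}
)

#: Sets whose signal passed through matrix (co-extracted oral fluid).
MATRIX_SETS = frozenset(
    {SetLabel.B_POST_SPIKE, SetLabel.C_PRE_SPIKE, SetLabel.BQ_POST_SPIKE, SetLabel.CQ_PRE_SPIKE}
)

#: Sets where the analyte (and pre-added IS) went through the SPE extraction.
EXTRACTED_SETS = frozenset({SetLabel.C_PRE_SPIKE, SetLabel.CQ_PRE_SPIKE})

#: Sets where the analyte was loaded onto the device pad.
PAD_SETS = frozenset({SetLabel.CQ_PRE_SPIKE, SetLabel.TUBE_A_PAD})


@dataclass(frozen=True)
class AnalyteSpec:
    """One compound of the panel, with acquisition and normalization metadata."""

    name: str
    role: Role
    logP: float
    quant_ion: int
    qualifier_ions: tuple[int, ...] = ()
    retention_group_start: float | None = None
    assigned_is: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.logP):
            raise ValueError(f"{self.name}: logP must be finite")
        if self.quant_ion not in self.ion_set:
            raise ValueError(f"{self.name}: quant ion {self.quant_ion} not in ion set")
        is_d3 = self.name.endswith("-d3")
        if (self.role is Role.DEUTERATED_IS) != is_d3:
            raise ValueError(
                f"{self.name}: deuterated-IS role must coincide with a '-d3' suffix"
            )
        if self.role is Role.TARGET and not self.assigned_is:
            raise ValueError(f"{self.name}: every target needs an assigned IS")
        if self.role is not Role.TARGET and self.assigned_is:
            raise ValueError(f"{self.name}: only targets carry an assigned IS")

    @property
    def ion_set(self) -> frozenset[int]:
        return frozenset((self.quant_ion, *self.qualifier_ions))


class AnalytePanel(Mapping[str, AnalyteSpec]):
    """Immutable name → :class:`AnalyteSpec` lookup with role helpers."""

    def __init__(self, specs: Iterable[AnalyteSpec]):
        self._specs = {spec.name: spec for spec in specs}
        for spec in self._specs.values():
            if spec.assigned_is is not None and spec.assigned_is not in self._specs:
                raise ValueError(
                    f"{spec.name}: assigned IS {spec.assigned_is!r} not in the panel"
                )

    def __getitem__(self, name: str) -> AnalyteSpec:
        return self._specs[name]

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(n for n, s in self._specs.items() if s.role is Role.TARGET)

    @property
    def internal_standards(self) -> tuple[str, ...]:
        return tuple(n for n, s in self._specs.items() if s.role is Role.DEUTERATED_IS)

    def assigned_is(self, analyte: str) -> str | None:
        return self._specs[analyte].assigned_is


def default_panel() -> AnalytePanel:
    """The packaged coca-leaf alkaloid panel (SIM ions, logP, IS assignments)."""
    raw = yaml.safe_load(
        resources.files("spikeval.data").joinpath("analytes.yaml").read_text()
    )
    specs = []
    for entry in raw["analytes"]:
        specs.append(
            AnalyteSpec(
                name=entry["name"],
                role=Role(entry["role"]),
                logP=float(entry["logP"]),
                quant_ion=int(entry["quant_ion"]),
                qualifier_ions=tuple(int(i) for i in entry.get("qualifier_ions", ())),
                retention_group_start=entry.get("retention_group_start"),
                assigned_is=entry.get("assigned_is"),
            )
        )
    return AnalytePanel(specs)


@dataclass(frozen=True)
class SpikeCondition:
    """One experimental cell: arm × set × nominal level × day × replicate."""

    arm: Arm
    set_label: SetLabel
    nominal_conc: float
    day: int = 1
    replicate: int = 1
    enforce_grid: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.nominal_conc < 0:
            raise ValueError("nominal_conc must be >= 0")
        if self.day < 1 or self.replicate < 1:
            raise ValueError("day and replicate are 1-based")
        if self.set_label in QUANTISAL_ONLY_SETS and self.arm is not Arm.QUANTISAL:
            raise ValueError(
                f"set {self.set_label.value} is defined only for the quantisal arm"
            )
        if (
            self.enforce_grid
            and self.set_label is not SetLabel.REAL
            and self.nominal_conc not in DESIGN_GRID
        ):
            raise ValueError(
                f"nominal_conc {self.nominal_conc} outside the design grid {DESIGN_GRID}"
            )

    @property
    def key(self) -> tuple:
        return (self.arm.value, self.set_label.value, self.nominal_conc, self.day, self.replicate)
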