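import pytest

from spikeval import (
    Arm,
    ExperimentTable,
    PeakMeasurement,
    SetLabel,
    SpikeCondition,
    default_panel,
    paper_like_truth,
)
from spikeval.nd import ND


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def truth():
    return paper_like_truth(seed=0)


def make_record(
    analyte="COC",
    arm=Arm.DROOLING,
    set_label=SetLabel.A_NEAT,
    conc=10.0,
    day=1,
    replicate=1,
    area=100.0,
    is_area=None,
    skf_area=None,
):
    return PeakMeasurement(
        analyte=analyte,
        condition=SpikeCondition(
            arm=arm, set_label=set_label, nominal_conc=conc, day=day, replicate=replicate
        ),
        area=area,
        is_area=is_area,
        skf_area=skf_area,
    )


def make_table(cells, panel=None, is_area=None):
    """Build an ExperimentTable from {(analyte, set_label, conc): [areas]}.

    ``is_area`` may be a constant, or a dict keyed the same way holding
    per-replicate IS areas.
    """
    records = []
    for (analyte, set_label, conc), areas in cells.items():
        set_label = SetLabel(set_label)
        arm = (
            Arm.QUANTISAL
            if set_label
            in (SetLabel.BQ_POST_SPIKE, SetLabel.CQ_PRE_SPIKE, SetLabel.TUBE_A_PAD, SetLabel.TUBE_B_BUFFER)
            else Arm.DROOLING
        )
        for i, area in enumerate(areas, start=1):
            isa = is_area
            if isinstance(is_area, dict):
                isa = is_area[(analyte, set_label.value, conc)][i - 1]
            records.append(
                make_record(
                    analyte=analyte,
                    arm=arm,
                    set_label=set_label,
                    conc=conc,
                    replicate=i,
                    area=area,
                    is_area=isa,
                )
            )
    return ExperimentTable(records, panel=panel)


# Volunteer-1 time course: external-standard ratios in both collection arms
# at 60 and 120 min after a cup of coca tea (published case study; nd =
# signal-to-noise below 3).
VOLUNTEER_1 = {
    ("drooling", 60.0): {"HYG": 0.28, "CUS": 0.43, "EME": 0.85, "TRO": ND, "COC": 11.94, "t-CIN": 0.95},
    ("quantisal", 60.0): {"HYG": ND, "CUS": 0.08, "EME": 0.08, "TRO": ND, "COC": 1.14, "t-CIN": 0.07},
    ("drooling", 120.0): {"HYG": 0.11, "CUS": 0.05, "EME": 0.40, "TRO": ND, "COC": 1.11, "t-CIN": 0.13},
    ("quantisal", 120.0): {"HYG": ND, "CUS": ND, "EME": ND, "TRO": ND, "COC": 0.28, "t-CIN": ND},
}


@pytest.fixture
def volunteer1_points():
    from spikeval import TimecoursePoint

    points = []
    for (arm, t), ratios in VOLUNTEER_1.items():
        for analyte, ratio in ratios.items():
            points.append(
                TimecoursePoint(volunteer=1, arm=arm, time_min=t, analyte=analyte, ratio=ratio)
            )
    return points
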