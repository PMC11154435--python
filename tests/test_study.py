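"""The report layer: grid completeness, dependency logic, normalization
equivalences at table level, and the brute-force oracle comparison."""

import numpy as np
import pytest

from spikeval import (
    Arm,
    DesignSpec,
    Metric,
    SetLabel,
    ValidationStudy,
    paper_like_truth,
    simulate_experiment,
)
from spikeval.nd import is_nd
from spikeval.table import LookupError_

from conftest import make_table


@pytest.fixture(scope="module")
def sim_results():
    truth = paper_like_truth(seed=9)
    design = DesignSpec(
        analytes=("COC", "CUS", "COC-d3", "EME-d3"),
        levels=(10.0, 50.0),
        replicates=3,
    )
    table, _ = simulate_experiment(truth, design, seed=9)
    return ValidationStudy(table).fit()


class TestReportGrid:
    def test_full_design_has_no_not_computed_cells(self, sim_results):
        assert (sim_results.grid["status"] == "ok").all()

    def test_missing_set_a_blocks_me_and_ra_but_not_re(self):
        table = make_table(
            {
                ("COC", "B", 10.0): [130.0, 130.0, 130.0],
                ("COC", "C", 10.0): [65.0, 65.0, 65.0],
            }
        )
        grid = ValidationStudy(table, metrics=(Metric.ME, Metric.RE, Metric.RA)).fit().grid
        status = dict(zip(grid["metric"], grid["status"]))
        assert status["ME"] == "not computed"
        assert status["RA"] == "not computed"
        assert status["RE"] == "ok"

    def test_identity_residual_zero_on_noise_free_table(self):
        truth = paper_like_truth(seed=2).with_(
            injection_cv=0.0, enhancement_cv=0.0, buffer_interference_censor=0.0
        )
        table, _ = simulate_experiment(
            truth,
            DesignSpec(analytes=("COC", "CUS", "COC-d3", "EME-d3"), levels=(10.0, 50.0)),
            seed=2,
        )
        res = ValidationStudy(table).fit()
        assert not res.identity_residuals.empty
        assert res.identity_residuals["identity_residual"].max() < 1e-9

    def test_constant_is_makes_normalized_equal_absolute(self):
        cells = {
            ("COC", "A", 10.0): [100.0, 102.0, 98.0],
            ("COC", "B", 10.0): [130.0, 128.0, 132.0],
            ("COC", "C", 10.0): [64.0, 66.0, 65.0],
        }
        table = make_table(cells, is_area=500.0)
        res = ValidationStudy(table).fit()
        for absolute, normalized in (("ME", "ME_n"), ("RE", "RE_n"), ("RA", "RA_n")):
            assert res.metric(absolute, "COC", "drooling", 10.0) == pytest.approx(
                res.metric(normalized, "COC", "drooling", 10.0)
            )

    def test_report_means_match_brute_force_recomputation(self):
        """Oracle: per-cell mean/CV recomputed directly from the raw
        replicates on a 2-analyte, 2-level toy table."""
        rng = np.random.default_rng(0)
        cells = {}
        for analyte in ("COC", "CUS"):
            for conc in (10.0, 50.0):
                for set_label in ("A", "B", "C"):
                    cells[(analyte, set_label, conc)] = list(rng.uniform(50, 150, size=3))
        table = make_table(cells)
        res = ValidationStudy(table, metrics=(Metric.ME, Metric.RE, Metric.RA)).fit()
        for analyte in ("COC", "CUS"):
            for conc in (10.0, 50.0):
                a = np.mean(cells[(analyte, "A", conc)])
                b = np.mean(cells[(analyte, "B", conc)])
                c = np.mean(cells[(analyte, "C", conc)])
                assert res.metric("ME", analyte, "drooling", conc) == pytest.approx(
                    (b / a - 1) * 100
                )
                assert res.metric("RE", analyte, "drooling", conc) == pytest.approx(100 * c / b)
                assert res.metric("RA", analyte, "drooling", conc) == pytest.approx(100 * c / a)
                row = res.grid[
                    (res.grid["metric"] == "RE")
                    & (res.grid["analyte"] == analyte)
                    & (res.grid["conc_ng_ml"] == conc)
                ].iloc[0]
                creps = cells[(analyte, "C", conc)]
                assert row["cv_pct"] == pytest.approx(
                    100 * np.std(creps, ddof=1) / np.mean(creps)
                )

    def test_scale_invariance_of_the_whole_grid(self):
        cells = {
            ("COC", "A", 10.0): [100.0, 102.0, 98.0],
            ("COC", "B", 10.0): [130.0, 128.0, 132.0],
            ("COC", "C", 10.0): [64.0, 66.0, 65.0],
        }
        res1 = ValidationStudy(make_table(cells, is_area=500.0)).fit()
        scaled = {k: [a * 3.7 for a in v] for k, v in cells.items()}
        res2 = ValidationStudy(make_table(scaled, is_area=500.0 * 3.7)).fit()
        for metric in ("ME", "RE", "RA", "ME_n", "RE_n", "RA_n"):
            assert res1.metric(metric, "COC", "drooling", 10.0) == pytest.approx(
                res2.metric(metric, "COC", "drooling", 10.0), rel=1e-9
            )

    def test_censored_normalization_reports_nd_cell(self):
        """If the IS is nd in every injection of a set, the normalized
        metric is nd (censored), not missing."""
        cells = {
            ("COC", "A", 10.0): [100.0, 100.0, 100.0],
            ("COC", "B", 10.0): [130.0, 130.0, 130.0],
        }
        from spikeval.nd import ND

        table = make_table(
            cells,
            is_area={
                ("COC", "A", 10.0): [500.0, 500.0, 500.0],
                ("COC", "B", 10.0): [ND, ND, ND],
            },
        )
        res = ValidationStudy(table, metrics=(Metric.ME, Metric.ME_N)).fit()
        assert res.metric("ME", "COC", "drooling", 10.0) == pytest.approx(30.0)
        assert is_nd(res.metric("ME_n", "COC", "drooling", 10.0))

    def test_surrogate_is_annotated(self, sim_results):
        grid = sim_results.grid
        cus = grid[(grid["analyte"] == "CUS") & (grid["metric"] == "ME_n")]
        coc = grid[(grid["analyte"] == "COC") & (grid["metric"] == "ME_n")]
        assert cus["surrogate_is"].eq(True).all()  # CUS normalizes via EME-d3
        assert coc["surrogate_is"].eq(False).all()  # COC has its own analogue


class TestResultsObject:
    def test_summary_renders_all_requested_metrics(self, sim_results):
        text = sim_results.summary()
        for metric in ("ME", "RE", "RA", "R_pad"):
            assert f"== {metric} " in text

    def test_metric_accessor_raises_on_unknown_cell(self, sim_results):
        with pytest.raises(KeyError):
            sim_results.metric("ME", "COC", "drooling", 123.0)

    def test_csv_and_json_round_trip_nd_tokens(self, sim_results, tmp_path):
        sim_results.to_csv(tmp_path / "grid.csv")
        text = (tmp_path / "grid.csv").read_text()
        assert "nd" in text  # censored device-arm cells survive as tokens
        payload = sim_results.to_json()
        assert '"nd"' in payload

    def test_day_ranges_reported_for_two_day_cells(self):
        cells = {
            ("COC", "A", 20.0): [100.0, 100.0, 100.0],
        }
        table_records = make_table(cells).records
        from conftest import make_record

        for day, areas in ((1, (110.0, 112.0, 111.0)), (2, (125.0, 124.0, 126.0))):
            for rep, area in enumerate(areas, start=1):
                table_records.append(
                    make_record(
                        analyte="COC", set_label=SetLabel.B_POST_SPIKE, conc=20.0,
                        day=day, replicate=rep, area=area,
                    )
                )
        from spikeval import ExperimentTable

        res = ValidationStudy(
            ExperimentTable(table_records), metrics=(Metric.ME,)
        ).fit()
        row = res.grid.iloc[0]
        assert row["day_min"] == pytest.approx(11.0)
        assert row["day_max"] == pytest.approx(25.0)
        assert row["value"] == pytest.approx(18.0)
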