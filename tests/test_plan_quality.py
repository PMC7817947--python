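import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import random_mask
from kbplan.core_grid import DoseGrid, StructureMask, VoxelGrid
from kbplan.histograms import CumulativeCurve, compute_dvh
from kbplan.phantoms import scoring_reference_case
from kbplan.plan_quality import (
    PlanMetrics,
    ScoreEntry,
    ScoreTableConfig,
    compute_plan_metrics,
    conformity_index,
    conformity_index_from_grids,
    default_score_table,
    extract_index,
    homogeneity_index,
    score_plan,
)


def step_curve(levels, fractions):
    """DVH of discrete dose compartments: `fractions` of volume at `levels`."""
    levels = np.asarray(levels, float)
    fractions = np.asarray(fractions, float)
    edges = np.arange(0.0, levels.max() + 0.2, 0.1)
    ordinate = np.array(
        [100.0 * fractions[levels >= e - 1e-12].sum() for e in edges]
    )
    return CumulativeCurve(abscissa=edges, ordinate=ordinate, kind="dvh")


class TestConformityIndex:
    def test_perfect_conformity_is_one(self):
        assert conformity_index(100.0, 100.0, 100.0) == pytest.approx(1.0)

    def test_zero_coverage_is_zero(self):
        assert conformity_index(0.0, 100.0, 150.0) == 0.0

    def test_hand_evaluated_value(self):
        assert conformity_index(90.0, 100.0, 150.0) == pytest.approx(0.54)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            conformity_index(0.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            conformity_index(0.0, 10.0, 0.0)

    def test_grid_evaluation_equals_volume_formula(self, rng):
        grid = VoxelGrid(shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0))
        target = random_mask(rng, grid, p=0.2, role="target")
        dose = DoseGrid(grid, rng.random(grid.shape) * 80, prescription=60.0)
        vox = grid.voxel_volume_cc
        covered = dose.dose >= 60.0
        expect = conformity_index(
            np.sum(covered & target.occupancy) * vox,
            target.voxel_count * vox,
            np.sum(covered) * vox,
        )
        assert conformity_index_from_grids(target, dose) == pytest.approx(expect)


class TestHomogeneityIndex:
    def test_uniform_dose_is_zero(self):
        curve = step_curve([50.0], [1.0])
        assert homogeneity_index(curve) == pytest.approx(0.0)

    def test_constructed_curve_hand_value(self):
        # piecewise-linear DVH with D2%=74, D98%=68, D50%=70
        curve = CumulativeCurve(
            abscissa=np.array([0.0, 68.0, 70.0, 74.0, 75.0]),
            ordinate=np.array([100.0, 98.0, 50.0, 2.0, 0.0]),
            kind="dvh",
        )
        assert homogeneity_index(curve) == pytest.approx(6.0 / 70.0)

    def test_scale_invariance(self):
        curve = CumulativeCurve(
            abscissa=np.array([0.0, 68.0, 70.0, 74.0, 75.0]),
            ordinate=np.array([100.0, 98.0, 50.0, 2.0, 0.0]),
            kind="dvh",
        )
        doubled = CumulativeCurve(
            abscissa=2.0 * curve.abscissa, ordinate=curve.ordinate, kind="dvh"
        )
        assert homogeneity_index(doubled) == pytest.approx(homogeneity_index(curve))

    def test_degenerate_curve_raises(self):
        curve = CumulativeCurve(
            abscissa=np.array([0.0, 1.0]), ordinate=np.array([0.0, 0.0]), kind="dvh"
        )
        with pytest.raises(ValueError, match="D_50%"):
            homogeneity_index(curve)


class TestExtractIndex:
    def test_uniform_dose_indices_coincide(self, uniform_case):
        mask, dose = uniform_case
        curve = compute_dvh(mask, dose)
        for spec in ("Dmax", "D1%"):
            assert extract_index(curve, spec) == pytest.approx(50.0, abs=1e-9)
        # D_mean integrates the differential histogram at mid-bin, so it is
        # exact only to within half a bin width
        assert extract_index(curve, "Dmean") == pytest.approx(50.0, abs=0.05)

    def test_two_compartment_d1cc_and_v50(self):
        # 2 cc structure: half at 60 Gy, half at 40 Gy
        curve = step_curve([40.0, 60.0], [0.5, 0.5])
        curve.total_volume_cc = 2.0
        assert extract_index(curve, "D1cc") == pytest.approx(60.0)
        assert extract_index(curve, "V50Gy") == pytest.approx(50.0)

    def test_d1cc_small_structure_falls_back_to_dmax(self, caplog):
        curve = step_curve([40.0, 60.0], [0.5, 0.5])
        curve.total_volume_cc = 0.5
        with caplog.at_level("WARNING"):
            v = extract_index(curve, "D1cc")
        assert v == extract_index(curve, "Dmax")
        assert "1 cc" in caplog.text

    def test_dmean_matches_voxel_average(self, rng, unit_grid):
        mask = random_mask(rng, unit_grid)
        dose = DoseGrid(unit_grid, rng.random(unit_grid.shape) * 70, prescription=70)
        bin_width = 0.1
        curve = compute_dvh(mask, dose, bin_width=bin_width)
        expect = dose.dose[mask.occupancy].mean()
        assert abs(extract_index(curve, "Dmean") - expect) <= 0.5 * bin_width

    def test_relative_volume_index_needs_prescription(self):
        curve = step_curve([70.0], [1.0])
        assert extract_index(curve, "V98%", prescription_gy=70.0) == pytest.approx(100.0)
        with pytest.raises(ValueError, match="prescription"):
            extract_index(curve, "V98%")

    def test_unknown_spec_rejected(self):
        curve = step_curve([70.0], [1.0])
        with pytest.raises(ValueError, match="index spec"):
            extract_index(curve, "Q42")


class TestDefaultTable:
    def test_level_best_band_sums_match_published_maxima(self):
        table = default_score_table()
        sums = table.level_best_sums()
        assert sums["targets"] == 100
        assert sums["critical"] == 60
        assert sums["subcritical"] == 25
        assert sums["other"] == 15
        assert sum(sums.values()) == 200

    def test_json_round_trip(self):
        table = default_score_table()
        back = ScoreTableConfig.from_json(table.to_json())
        assert back.level_best_sums() == table.level_best_sums()
        assert len(back.entries) == len(table.entries)
        assert back.entries[0] == table.entries[0]

    def test_malformed_entry_rejected_at_construction(self):
        with pytest.raises(ValueError, match="bands"):
            ScoreEntry("x", "Dmax", (("<", 50.0),), (5, 3), "other")


class TestScorePlan:
    def _metrics(self, **structures):
        return PlanMetrics(values=structures)

    def test_spinal_cord_best_band(self):
        table = default_score_table()
        res = score_plan(self._metrics(spinal_cord={"D1cc": 30.0}), table)
        row = next(r for r in res.rows if r["structure"] == "spinal_cord")
        assert row["points"] == 12

    def test_pgtv_coverage_best_band(self):
        table = default_score_table()
        res = score_plan(self._metrics(pgtv={"V98%": 99.0}), table)
        row = next(r for r in res.rows if r["index"] == "V98%" and r["structure"] == "pgtv")
        assert row["points"] == 10

    def test_threshold_tie_falls_to_worse_band(self):
        table = default_score_table()
        res = score_plan(self._metrics(spinal_cord={"D1cc": 35.0}), table)
        row = next(r for r in res.rows if r["structure"] == "spinal_cord")
        assert row["points"] == 6  # exactly 35 is not <35
        res2 = score_plan(self._metrics(spinal_cord={"D1cc": 50.0}), table)
        row2 = next(r for r in res2.rows if r["structure"] == "spinal_cord")
        assert row2["points"] == 0  # exactly 50: neither <50 nor >50 -> catch-all

    def test_temporal_lobe_dmax_middle_band_is_60_to_65(self):
        table = default_score_table()
        for value, points in [(59.0, 4), (62.0, 2), (66.0, 0)]:
            res = score_plan(self._metrics(temporal_lobe={"Dmax": value}), table)
            row = next(
                r for r in res.rows
                if r["structure"] == "temporal_lobe" and r["index"] == "Dmax"
            )
            assert row["points"] == points

    def test_paired_organ_sides_are_averaged(self):
        table = default_score_table()
        res = score_plan(
            self._metrics(parotid_l={"Dmean": 20.0}, parotid_r={"Dmean": 30.0}), table
        )
        row = next(
            r for r in res.rows if r["structure"] == "parotid" and r["index"] == "Dmean"
        )
        assert row["points"] == pytest.approx(1.0)  # mean of 2 and 0

    def test_worst_side_mode(self):
        table = default_score_table()
        table.paired_mode = "worst"
        res = score_plan(
            self._metrics(parotid_l={"Dmean": 20.0}, parotid_r={"Dmean": 30.0}), table
        )
        row = next(
            r for r in res.rows if r["structure"] == "parotid" and r["index"] == "Dmean"
        )
        assert row["points"] == 0.0

    def test_missing_metric_scores_zero_with_warning(self, caplog):
        table = default_score_table()
        with caplog.at_level("WARNING"):
            res = score_plan(self._metrics(), table)
        assert res.total == 0.0
        assert "no metric" in caplog.text
        table.missing_policy = "error"
        with pytest.raises(ValueError, match="no metric"):
            score_plan(self._metrics(), table)

    def test_total_is_sum_of_subtotals_and_order_independent(self):
        table = default_score_table()
        metrics = self._metrics(
            spinal_cord={"D1cc": 40.0}, pgtv={"V98%": 97.0}, larynx={"Dmean": 44.0}
        )
        res = score_plan(metrics, table)
        assert res.total == pytest.approx(sum(res.subtotals.values()))
        reversed_table = ScoreTableConfig(
            entries=list(reversed(table.entries)), level_maxima=table.level_maxima
        )
        assert score_plan(metrics, reversed_table).total == res.total

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(lo=st.floats(0.0, 80.0), delta=st.floats(0.0, 30.0))
    def test_lower_oar_index_never_scores_fewer_points(self, lo, delta):
        table = default_score_table()
        p_lo = score_plan(PlanMetrics(values={"spinal_cord": {"D1cc": lo}}), table)
        p_hi = score_plan(PlanMetrics(values={"spinal_cord": {"D1cc": lo + delta}}), table)
        row = lambda res: next(r for r in res.rows if r["structure"] == "spinal_cord")
        assert row(p_lo)["points"] >= row(p_hi)["points"]


class TestFullPlanPipeline:
    def test_ideal_reference_plan_scores_maximum(self):
        masks, dose, prescriptions = scoring_reference_case()
        table = default_score_table()
        metrics = compute_plan_metrics(masks, dose, table, prescriptions)
        res = score_plan(metrics, table)
        assert res.total == pytest.approx(200.0)
        assert res.subtotals == pytest.approx(
            {"targets": 100.0, "critical": 60.0, "subcritical": 25.0, "other": 15.0}
        )
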