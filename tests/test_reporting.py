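"""Grades, KIDMAP, Wright map, group ANOVA, and report I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raschkit as rk
from raschkit.model import PersonMeasure
from raschkit.reporting import (
    GradeBands,
    assign_grade,
    compare_groups,
    kidmap,
    wright_map_data,
    write_reports,
)


class TestAssignGrade:
    @pytest.mark.parametrize(
        "theta, grade",
        [
            (4.66, "A"),   # the perfect responder's published measure
            (3.01, "A"),
            (3.0, "B"),
            (1.5, "C"),
            (0.0, "C"),
            (-1.5, "D"),
            (-2.99, "D"),
            (-3.0, "E"),
            (-10.0, "E"),
        ],
    )
    def test_band_assignment(self, theta, grade):
        assert assign_grade(theta) == grade

    @settings(deadline=None)
    @given(theta=st.floats(-50, 50))
    def test_partition_and_monotonicity(self, theta):
        g = assign_grade(theta)
        assert g in "ABCDE"
        # monotone: a higher ability never gets a worse grade
        assert assign_grade(theta + 0.5) <= g

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_grade(np.inf)

    def test_custom_bands_validated(self):
        with pytest.raises(ValueError):
            GradeBands(thresholds=(1.0, 2.0, 3.0, 4.0))
        with pytest.raises(ValueError):
            GradeBands(thresholds=(3.0, 1.5), labels=("A", "B"))


class TestKidmap:
    def _pm(self, calibrated, pid):
        row = calibrated.persons.set_index("person_id").loc[pid]
        return PersonMeasure(pid, row["theta"], row["se"], row["raw_score"])

    def test_expected_matches_model(self, study_data, calibrated):
        pm = self._pm(calibrated, "P001")
        rec = kidmap(pm, study_data, calibrated.items)
        by_item = calibrated.items.set_index("item_id")
        for _, row in rec.rows.iterrows():
            p = rk.dichotomous_probability(
                pm.theta, by_item.loc[row["item_id"], "difficulty"]
            )
            assert row["expected"] == pytest.approx(p, abs=1e-12)
            z = (row["observed"] - p) / np.sqrt(p * (1 - p))
            assert row["z"] == pytest.approx(z, abs=1e-12)

    def test_perfect_responder_has_no_aberrant_items(self, study_data,
                                                     calibrated):
        rec = kidmap(self._pm(calibrated, "GPT301"), study_data,
                     calibrated.items)
        assert (rec.rows["z"].abs() < 2).all()
        assert set(rec.rows["quadrant"]) == {"expected-correct"}
        assert rec.outfit_mnsq < 2.0

    def test_unexpected_correct_far_above_ability(self, study_data, calibrated):
        # correct answer on an item ~5 logits above theta: z > 2
        pm = PersonMeasure("P001", -3.0, 1.0, 5)
        rec = kidmap(pm, study_data, calibrated.items)
        row = rec.rows.iloc[-1]  # hardest item, ~2.5 logits
        if row["observed"] == 1:
            assert row["z"] > 2
            assert row["quadrant"] == "unexpected-correct"

    def test_quadrants_partition_items(self, study_data, calibrated):
        rec = kidmap(self._pm(calibrated, "P150"), study_data, calibrated.items)
        assert sum(rec.quadrant_counts().values()) == study_data.n_items
        assert rec.rows["difficulty"].is_monotonic_increasing

    def test_unknown_person_rejected(self, study_data, calibrated):
        with pytest.raises(ValueError):
            kidmap(PersonMeasure("nobody", 0, 1, 5), study_data,
                   calibrated.items)


class TestWrightMap:
    def test_bins_partition_persons(self, calibrated):
        wm = wright_map_data(calibrated.persons, calibrated.items)
        assert wm["bins"]["total"].sum() == len(calibrated.persons)
        groups = [c for c in wm["bins"].columns
                  if c in ("Female", "Male")]
        if groups:
            assert (wm["bins"][groups].sum(axis=1)
                    == wm["bins"]["total"]).all()

    def test_item_placements_pass_through(self, calibrated):
        wm = wright_map_data(calibrated.persons, calibrated.items)
        np.testing.assert_array_equal(
            wm["items"]["difficulty"].to_numpy(), calibrated.difficulties
        )

    def test_modal_bin_within_item_span(self, calibrated):
        wm = wright_map_data(calibrated.persons, calibrated.items)
        mode = wm["bins"].loc[wm["bins"]["total"].idxmax()]
        assert -2.5 <= (mode["bin_low"] + mode["bin_high"]) / 2 <= 2.5


class TestCompareGroups:
    def test_two_level_f_equals_t_squared(self, calibrated):
        out = compare_groups(calibrated.persons, "group")
        assert out["F"] == pytest.approx(out["t"] ** 2, rel=1e-10)
        assert 0 <= out["p"] <= 1

    def test_identical_groups_give_zero_f(self):
        import pandas as pd

        theta = np.r_[np.linspace(-1, 1, 20), np.linspace(-1, 1, 20)]
        persons = pd.DataFrame(
            {"theta": theta, "group": ["a"] * 20 + ["b"] * 20}
        )
        out = compare_groups(persons)
        assert out["F"] == pytest.approx(0.0, abs=1e-12)

    def test_grade_strata_differ_by_construction(self, calibrated):
        persons = calibrated.persons.copy()
        persons["grade"] = [rk.assign_grade(t) for t in persons["theta"]]
        counts = persons["grade"].value_counts()
        usable = counts[counts >= 2].index
        out = compare_groups(persons[persons["grade"].isin(usable)], "grade")
        assert out["p"] < 0.001

    def test_single_level_rejected(self):
        import pandas as pd

        persons = pd.DataFrame({"theta": [0.1, 0.2], "group": ["a", "a"]})
        with pytest.raises(ValueError):
            compare_groups(persons)


class TestIO:
    def test_round_trip(self, study_data, tmp_path):
        path = tmp_path / "study.csv"
        study_data.to_csv(path)
        back = rk.ResponseMatrix.from_csv(path)
        np.testing.assert_array_equal(back.scores, study_data.scores)
        assert back.person_ids == study_data.person_ids
        assert back.item_ids == study_data.item_ids
        assert back.groups == study_data.groups

    def test_missing_cells_round_trip(self, tmp_path):
        scores = np.array([[1.0, np.nan, 0.0], [0.0, 1.0, np.nan]])
        data = rk.ResponseMatrix(scores, ["a", "b"], ["i1", "i2", "i3"])
        path = tmp_path / "m.csv"
        data.to_csv(path)
        back = rk.ResponseMatrix.from_csv(path)
        np.testing.assert_array_equal(np.isnan(back.scores), np.isnan(scores))
        assert back.raw_person_scores().tolist() == [1.0, 1.0]

    def test_invalid_cell_names_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("person_id,group,item_1,item_2\np1,F,1,2\np2,M,0,1\n")
        with pytest.raises(ValueError, match=r"row 2.*item_2"):
            rk.ResponseMatrix.from_csv(path)

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError):
            rk.ResponseMatrix(np.array([[1.0, 2.0]]), ["p"], ["a", "b"])

    def test_write_reports_and_determinism(self, study_data, calibrated,
                                           tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            files = write_reports(study_data, calibrated, out, plots=False)
            assert all(f.exists() for f in files)
        for name in ("items.tsv", "persons.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_svg_plots_rendered(self, study_data, calibrated, tmp_path):
        pm_row = calibrated.persons.iloc[-1]
        rec = kidmap(
            PersonMeasure(pm_row["person_id"], pm_row["theta"], pm_row["se"],
                          pm_row["raw_score"]),
            study_data,
            calibrated.items,
        )
        files = write_reports(study_data, calibrated, tmp_path / "p",
                              kidmaps=[rec], plots=True)
        svgs = [f for f in files if f.suffix == ".svg"]
        assert {f.name for f in svgs} >= {"did.svg", "wright_map.svg",
                                          "kidmap_GPT301.svg"}
        for f in svgs:
            assert f.read_text().lstrip().startswith("<?xml")
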