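"""Data model, readers/writers and deterministic transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scentsel import (
    ScentMatrix,
    StudyValidationError,
    filter_compounds,
    fruit_set_pct,
    load_study,
    relative_fitness,
    to_relative,
    total_emission,
    write_study,
    z_transform,
)
from scentsel.data import validate_fitness


class TestRoundTrip:
    def test_write_then_load_is_value_identical(self, small_study, tmp_path):
        paths = write_study(small_study, tmp_path)
        reloaded = load_study(
            paths["scent"], paths["descriptors"],
            fitness_path=paths["fitness"], metadata_path=paths["metadata"],
        )
        pd.testing.assert_frame_equal(
            reloaded.scent.values, small_study.scent.values, check_exact=False,
            rtol=1e-9,
        )
        assert reloaded.scent.mode == "absolute"
        assert list(reloaded.samples["population"]) == list(
            small_study.samples["population"]
        )

    def test_write_load_write_is_byte_identical(self, small_study, tmp_path):
        p1 = write_study(small_study, tmp_path / "a")
        reloaded = load_study(
            p1["scent"], p1["descriptors"],
            fitness_path=p1["fitness"], metadata_path=p1["metadata"],
        )
        p2 = write_study(reloaded, tmp_path / "b")
        assert p1["scent"].read_bytes() == p2["scent"].read_bytes()
        assert p1["fitness"].read_bytes() == p2["fitness"].read_bytes()

    def test_fruits_exceeding_flowers_named_in_error(self):
        bad = pd.DataFrame(
            {"sample_id": ["x1", "x2"], "n_fruits": [5, 9], "n_flowers": [10, 6]}
        )
        with pytest.raises(StudyValidationError, match="x2"):
            validate_fitness(bad)

    def test_missing_cells_read_as_zero(self, tmp_path):
        (tmp_path / "scent.csv").write_text("sample_id,c1,c2\ns1,1.5,\ns2,,2.0\n")
        (tmp_path / "desc.csv").write_text(
            "compound_id,name,kri,compound_class,verified\n"
            "c1,indole,1290,nitrogen-bearing,True\nc2,UNK1400,1400,unknown,False\n"
        )
        study = load_study(tmp_path / "scent.csv", tmp_path / "desc.csv")
        assert study.scent.values.loc["s1", "c2"] == 0.0
        assert study.scent.values.loc["s2", "c1"] == 0.0

    def test_undescribed_compound_rejected(self, tmp_path):
        (tmp_path / "scent.csv").write_text("sample_id,mystery\ns1,1.0\n")
        (tmp_path / "desc.csv").write_text(
            "compound_id,name,kri,compound_class,verified\n"
            "c1,indole,1290,nitrogen-bearing,True\n"
        )
        with pytest.raises(StudyValidationError, match="mystery"):
            load_study(tmp_path / "scent.csv", tmp_path / "desc.csv")


class TestFilterCompounds:
    def test_occurrence_and_control_rules(self, toy_matrix):
        # occurrences: c_a=4, c_b=3, c_c=6; c_c also present in one air control
        controls = ScentMatrix(
            pd.DataFrame(
                {"c_a": [0.0], "c_b": [0.0], "c_c": [0.2]},
                index=pd.Index(["air1"], name="sample_id"),
            )
        )
        out = filter_compounds(toy_matrix, controls, min_occurrence=4)
        # brute-force oracle: count nonzero per column, check control hits
        expected = [
            c for c in toy_matrix.compound_ids
            if (toy_matrix.values[c] > 0).sum() >= 4
            and (controls.values[c] == 0).all()
        ]
        assert out.compound_ids == expected == ["c_a"]

    def test_three_occurrences_removed_empty_removed(self, toy_matrix):
        mat = toy_matrix.values.copy()
        mat["c_zero"] = 0.0
        out = filter_compounds(ScentMatrix(mat), None, min_occurrence=4)
        assert "c_b" not in out.compound_ids      # present in only 3 samples
        assert "c_zero" not in out.compound_ids   # present in none

    def test_idempotent(self, small_study):
        infl = small_study.inflorescence()
        once = filter_compounds(infl, None)
        twice = filter_compounds(once, None)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_relative_mode_rejected(self, toy_matrix):
        rel = to_relative(toy_matrix)
        with pytest.raises(StudyValidationError):
            filter_compounds(rel, None)


class TestToRelative:
    def test_hand_computed_rows(self):
        m = ScentMatrix(
            pd.DataFrame({"a": [2.0, 1.0], "b": [2.0, 4.0], "c": [0.0, 5.0]},
                         index=["s1", "s2"])
        )
        rel = to_relative(m)
        assert rel.mode == "relative"
        np.testing.assert_allclose(rel.values.loc["s1"], [50.0, 50.0, 0.0])
        np.testing.assert_allclose(rel.values.loc["s2"], [10.0, 40.0, 50.0])

    def test_rows_sum_to_100(self, small_study):
        rel = to_relative(small_study.scent)
        np.testing.assert_allclose(rel.values.sum(axis=1), 100.0, atol=1e-9)

    def test_commutes_with_column_permutation(self, toy_matrix):
        perm = ["c_c", "c_a", "c_b"]
        a = to_relative(toy_matrix).values[perm]
        b = to_relative(toy_matrix.subset_compounds(perm)).values
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_row_names_sample(self):
        m = ScentMatrix(pd.DataFrame({"a": [1.0, 0.0]}, index=["ok", "empty"]))
        with pytest.raises(StudyValidationError, match="empty"):
            to_relative(m)


class TestTotals:
    def test_totals_match_naive_loop(self, rng):
        vals = pd.DataFrame(rng.uniform(0, 5, size=(5, 4)),
                            index=[f"s{i}" for i in range(5)],
                            columns=list("abcd"))
        vals[vals < 1] = 0.0
        t = total_emission(ScentMatrix(vals))
        for sid in vals.index:
            total = sum(vals.loc[sid])
            rich = sum(1 for v in vals.loc[sid] if v > 0)
            assert t.loc[sid, "total"] == pytest.approx(total)
            assert t.loc[sid, "richness"] == rich

    def test_all_zero_row(self):
        m = ScentMatrix(pd.DataFrame({"a": [0.0, 2.0], "b": [0.0, 2.0]},
                                     index=["z", "s"]))
        t = total_emission(m)
        assert t.loc["z", "total"] == 0 and t.loc["z", "richness"] == 0
        assert t.loc["s", "total"] == 4 and t.loc["s", "richness"] == 2


class TestFruitSet:
    @pytest.mark.parametrize(
        "fruits,flowers,expected", [(30, 60, 50.0), (0, 40, 0.0), (12, 12, 100.0)]
    )
    def test_percentage(self, fruits, flowers, expected):
        assert fruit_set_pct(fruits, flowers) == expected

    def test_zero_flowers_rejected(self):
        with pytest.raises(StudyValidationError):
            fruit_set_pct(0, 0)


class TestRelativeFitness:
    def test_single_population_scaling(self):
        fit = pd.DataFrame({"n_fruits": [2, 4, 6], "n_flowers": [10, 10, 10]},
                           index=["a", "b", "c"])
        pops = pd.Series(["P", "P", "P"], index=fit.index)
        out = relative_fitness(fit, pops)
        np.testing.assert_allclose(out["rel_fruit_set"], [0.5, 1.0, 1.5])

    def test_two_populations_scaled_by_own_mean(self, rng):
        n = 20
        fit = pd.DataFrame(
            {"n_fruits": rng.integers(0, 30, n), "n_flowers": 30},
            index=[f"s{i}" for i in range(n)],
        )
        fit.iloc[0, 0] = max(fit.iloc[0, 0], 1)  # guard nonzero group means
        fit.iloc[10, 0] = max(fit.iloc[10, 0], 1)
        pops = pd.Series(["P1"] * 10 + ["P2"] * 10, index=fit.index)
        out = relative_fitness(fit, pops)
        for p in ("P1", "P2"):
            sub = fit.loc[pops == p, "n_fruits"]
            np.testing.assert_allclose(
                out.loc[pops == p, "rel_fruit_set"], sub / sub.mean()
            )
            assert out.loc[pops == p, "rel_fruit_set"].mean() == pytest.approx(1.0)

    def test_all_zero_group_rejected(self):
        fit = pd.DataFrame({"n_fruits": [0, 0], "n_flowers": [5, 5]},
                           index=["a", "b"])
        with pytest.raises(StudyValidationError):
            relative_fitness(fit, pd.Series(["P", "P"], index=fit.index))


class TestZTransform:
    def test_known_column(self):
        z = z_transform(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_moments(self, rng):
        z = z_transform(pd.DataFrame(rng.normal(2, 7, size=(30, 3)),
                                     columns=list("abc")))
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    def test_positive_affine_invariance(self, a, b):
        x = pd.DataFrame({"x": [0.3, -1.2, 2.5, 0.0, 4.4]})
        np.testing.assert_allclose(
            z_transform(a * x + b)["x"], z_transform(x)["x"], atol=1e-9
        )

    def test_constant_column_named(self):
        with pytest.raises(StudyValidationError, match="flat"):
            z_transform(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))
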