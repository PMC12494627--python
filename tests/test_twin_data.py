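import numpy as np
import pandas as pd
import pytest

import sweetwin as sw
from sweetwin.data import CohortValidationError, StructuralError


class TestReadLongTable:
    def test_round_trip_preserves_values_and_missing(self, small_cohort, tmp_path):
        out = tmp_path / "again.csv"
        sw.write_long_table(small_cohort, out)
        back = sw.read_long_table(out, dict(small_cohort.trait_registry))
        pd.testing.assert_frame_equal(back.data, small_cohort.data)

    def test_identity_shape(self, small_cohort):
        assert small_cohort.n_individuals == 5
        assert small_cohort.n_families == 3
        assert small_cohort.traits == ["liking", "fl_sweet"]
        # NA token became a missing marker
        assert np.isnan(small_cohort.data.loc[2, "fl_sweet"])

    @pytest.mark.parametrize(
        "mutate, err, fragment",
        [
            (lambda d: pd.concat([d, d.iloc[[0]]]), StructuralError, "F001"),
            (lambda d: d.assign(sex=["F", "M", "M", "M", "F"]),
             CohortValidationError, "F001"),
            (lambda d: d.assign(liking=[60, 70, 40, 55, 500]),
             CohortValidationError, "liking"),
            (lambda d: d.assign(age=[30, 30, -1, 25, 28]),
             CohortValidationError, "age"),
            (lambda d: d.assign(sex=["F", "F", "M", "M", "X"]),
             CohortValidationError, "sex"),
            (lambda d: d.assign(zygosity=d["zygosity"].replace("DZ_OS", "??")),
             CohortValidationError, "zygosity"),
        ],
    )
    def test_validation_errors(self, small_cohort, mutate, err, fragment):
        df = mutate(small_cohort.data.copy())
        with pytest.raises(err, match=fragment):
            sw.TwinCohort(df, dict(small_cohort.trait_registry))

    def test_three_rows_one_family_is_structural_error(self, small_cohort):
        df = small_cohort.data.copy()
        extra = df.iloc[[4]].assign(family_id="F001")
        with pytest.raises(StructuralError):
            sw.TwinCohort(pd.concat([df, extra]), {})

    def test_dz_os_equal_sex_rejected(self, small_cohort):
        df = small_cohort.data.copy()
        extra = df.iloc[[4]].assign(twin_order=2, sex="F")
        with pytest.raises(CohortValidationError, match="F003"):
            sw.TwinCohort(pd.concat([df, extra]), {})


class TestPairWide:
    def test_complete_and_singleton_rows(self, small_cohort):
        pt = sw.pair_wide(small_cohort, "liking")
        assert len(pt) == 3
        assert pt.n_complete == 2
        assert not pt.frame.loc[2, "complete"]  # F003 singleton

    def test_both_missing_family_dropped(self, small_cohort):
        pt = sw.pair_wide(small_cohort, "fl_sweet")
        # F003 has fl_sweet observed; F002 has one side; F001 complete
        assert set(pt.frame["family_id"]) == {"F001", "F002", "F003"}
        df = small_cohort.data.copy()
        df.loc[df.family_id == "F002", "fl_sweet"] = np.nan
        pt2 = sw.pair_wide(sw.TwinCohort(df, {}), "fl_sweet")
        assert set(pt2.frame["family_id"]) == {"F001", "F003"}

    def test_empty_cohort(self, small_cohort):
        empty = sw.TwinCohort(small_cohort.data.iloc[:0],
                              dict(small_cohort.trait_registry))
        pt = sw.pair_wide(empty, "liking")
        assert len(pt) == 0

    def test_unknown_trait(self, small_cohort):
        with pytest.raises(KeyError):
            sw.pair_wide(small_cohort, "nope")

    def test_unpair_restores_family_value_multiset(self, small_cohort):
        pt = sw.pair_wide(small_cohort, "liking")
        unpaired = set()
        for _, row in pt.frame.iterrows():
            for j in (1, 2):
                v = row[f"liking_{j}"]
                if np.isfinite(v):
                    unpaired.add((row["family_id"], v))
        original = {
            (r.family_id, r.liking)
            for r in small_cohort.data.itertuples()
            if np.isfinite(r.liking)
        }
        assert unpaired == original

    def test_covariates_attached_with_numeric_sex(self, small_cohort):
        pt = sw.pair_wide(small_cohort, "liking", covariates=("age", "sex"))
        assert pt.frame.loc[0, "sex_1"] == 0.0  # F
        assert pt.frame.loc[1, "sex_2"] == 1.0  # M
        assert pt.frame.loc[0, "age_1"] == 30


class TestCenterCovariates:
    def test_centering(self, small_cohort):
        out = sw.center_covariates(small_cohort)
        assert out.data["age"].mean() == pytest.approx(0.0)
        ages = sorted(out.data["age"].unique())
        assert ages[0] == pytest.approx(25 - small_cohort.data["age"].mean())

    def test_idempotent(self, small_cohort):
        once = sw.center_covariates(small_cohort)
        twice = sw.center_covariates(once)
        assert np.allclose(once.data["age"], twice.data["age"])

    def test_all_missing_ages_error(self, small_cohort):
        df = small_cohort.data.copy()
        df["age"] = np.nan
        with pytest.raises(CohortValidationError):
            sw.center_covariates(sw.TwinCohort(df, {}))


class TestGroupScore:
    @pytest.fixture
    def cohort_with_items(self, small_cohort):
        df = small_cohort.data.copy()
        df["item_a"] = [3.0, 7.0, np.nan, 2.0, 1.0]
        df["item_b"] = [5.0, np.nan, np.nan, 4.0, 7.0]
        reg = dict(small_cohort.trait_registry)
        reg.update({"item_a": (1, 7), "item_b": (1, 7)})
        return sw.TwinCohort(df, reg)

    def test_mean_over_nonmissing(self, cohort_with_items):
        out = sw.group_score(cohort_with_items, ["item_a", "item_b"], "grp")
        assert out.data.loc[0, "grp"] == 4.0        # (3+5)/2
        assert out.data.loc[1, "grp"] == 7.0        # (7, missing)
        assert np.isnan(out.data.loc[2, "grp"])     # all missing
        assert out.trait_registry["grp"] == (1, 7)

    def test_empty_item_list_error(self, cohort_with_items):
        with pytest.raises(ValueError):
            sw.group_score(cohort_with_items, [], "grp")

    def test_mismatched_scales_error(self, cohort_with_items):
        with pytest.raises(ValueError, match="common scale"):
            sw.group_score(cohort_with_items, ["item_a", "liking"], "grp")
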