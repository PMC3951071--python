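import math

import numpy as np
import pytest

from hemrbe.datamodel import (
    BloodCountRecord,
    DataModelError,
    Experiment,
    GroupSummary,
    load_counts_csv,
    normalize_to_fraction,
    percent_change,
    summarize_groups,
    tukey_vs_baseline,
    write_counts_csv,
)
from hemrbe.fixtures import available_cell_types, load_reference_frame, load_reference_summaries

from conftest import make_groups


def _experiment(pre_counts, post, dose=10.0, timepoint="d1", cell_type="WBC"):
    records = []
    for i, c in enumerate(pre_counts):
        records.append(BloodCountRecord("e1", "reference", f"a{i}", 0.0, "pre",
                                        cell_type, count=c))
    for i, c in enumerate(post):
        records.append(BloodCountRecord("e1", "reference", f"a{i}", dose, timepoint,
                                        cell_type, count=c))
    return Experiment("e1", "reference", records)


class TestNormalization:
    def test_fraction_is_count_over_cohort_pre_mean(self):
        exp = normalize_to_fraction(_experiment([10, 12, 8], [5]))
        post = [r for r in exp.records if r.timepoint == "d1"]
        assert post[0].fraction_of_control == pytest.approx(0.5)
        assert exp.baseline["WBC"] == pytest.approx(10.0)

    def test_posts_equal_to_baseline_mean_give_fraction_one(self):
        exp = normalize_to_fraction(_experiment([10, 12, 8], [10, 10, 10]))
        for r in exp.records:
            if r.timepoint == "d1":
                assert r.fraction_of_control == pytest.approx(1.0)

    def test_pre_irradiation_group_mean_is_exactly_one(self):
        exp = normalize_to_fraction(_experiment([9.5, 11.0, 13.2], [5, 6, 7]))
        pre = [g for g in summarize_groups(exp.records) if g.timepoint == "pre"]
        assert pre[0].mean_fraction == pytest.approx(1.0, abs=1e-15)

    def test_idempotent(self):
        exp = normalize_to_fraction(_experiment([10, 12, 8], [5, 6]))
        again = normalize_to_fraction(exp)
        assert [r.fraction_of_control for r in again.records] == [
            r.fraction_of_control for r in exp.records
        ]

    def test_missing_baseline_names_cell_type_and_experiment(self):
        records = [BloodCountRecord("eX", "reference", "a0", 10.0, "d1",
                                    "platelet", count=100.0)]
        with pytest.raises(DataModelError, match="platelet.*eX"):
            normalize_to_fraction(Experiment("eX", "reference", records))


class TestPercentChange:
    @pytest.mark.parametrize("fraction,expected", [(1.0, 0.0), (0.5, -50.0), (1.5, 50.0)])
    def test_sign_convention(self, fraction, expected):
        assert percent_change(fraction) == pytest.approx(expected)

    # Printed "Change (%)" cells were rounded from unrounded means, while the
    # table means themselves are rounded to 2 decimals; agreement is therefore
    # only guaranteed to ~0.5 percentage points.
    @pytest.mark.parametrize("mean,printed", [
        (0.33, -66.6),   # WBC 20 Gy Day 1
        (0.23, -76.7),   # lymphocyte 20 Gy 4 h
        (0.54, -46.3),   # WBC 10 Gy 4 h
        (0.26, -73.6),   # monocyte 20 Gy 4 h
        (0.48, -51.8),   # platelet 20 Gy Day 14
    ])
    def test_matches_printed_change_columns(self, mean, printed):
        assert percent_change(mean) == pytest.approx(printed, abs=0.55)

    def test_rejects_nonpositive(self):
        with pytest.raises(DataModelError):
            percent_change(0.0)


class TestSummarize:
    def test_mean_and_se(self):
        from conftest import make_records
        groups = summarize_groups(make_records({10.0: [0.4, 0.5, 0.6]}))
        g = groups[0]
        assert g.mean_fraction == pytest.approx(0.5)
        assert g.se_fraction == pytest.approx(0.1 / math.sqrt(3), abs=1e-10)
        assert g.n == 3

    def test_single_record_flagged(self):
        from conftest import make_records
        g = summarize_groups(make_records({10.0: [0.7]}))[0]
        assert g.se_fraction == 0.0
        assert not g.se_defined


class TestCSVRoundtrip:
    def test_write_read_preserves_fields(self, tmp_path):
        exp = _experiment([10, 12, 8], [5, 6, 7])
        path = tmp_path / "counts.csv"
        write_counts_csv([exp], path)
        loaded = load_counts_csv(path)
        assert len(loaded) == 1
        assert len(loaded[0].records) == len(exp.records)
        orig = {r.key: r.count for r in exp.records}
        for r in loaded[0].records:
            assert r.count == pytest.approx(orig[r.key])

    def test_duplicate_key_is_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "experiment_id,arm,animal_id,dose_gy,timepoint,cell_type,count,fraction\n"
            "e1,reference,a0,10,d1,WBC,5.0,\n"
            "e1,reference,a0,10,d1,WBC,6.0,\n"
        )
        with pytest.raises(DataModelError, match="duplicate"):
            load_counts_csv(path)

    def test_unknown_cell_type_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "experiment_id,arm,animal_id,dose_gy,timepoint,cell_type,count,fraction\n"
            "e1,reference,a0,10,d1,basophil,5.0,\n"
        )
        with pytest.raises(DataModelError, match="row 2"):
            load_counts_csv(path)

    def test_negative_dose_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(
            "experiment_id,arm,animal_id,dose_gy,timepoint,cell_type,count,fraction\n"
            "e1,reference,a0,-3,d1,WBC,5.0,\n"
        )
        with pytest.raises(DataModelError, match="row 2"):
            load_counts_csv(path)


class TestFixtures:
    def test_all_cell_types_ship(self):
        assert set(available_cell_types()) == {
            "WBC", "lymphocyte", "neutrophil", "monocyte", "eosinophil",
            "platelet", "RBC",
        }

    def test_wbc_table_shape(self):
        df = load_reference_frame("WBC")
        post = df[df.timepoint != "pre"]
        assert sorted(post.dose_gy.unique()) == [5, 7.5, 7.7, 10, 15, 20]
        assert set(post.timepoint) == {"4h", "d1", "d7", "d14", "d30"}
        assert len(post) == 30

    def test_printed_cells(self):
        # lymphocyte 20 Gy 4 h prints as 0.23 +/- 0.02
        gs = load_reference_summaries("lymphocyte")
        g = next(x for x in gs if x.timepoint == "4h" and x.dose == 20)
        assert (g.mean_fraction, g.se_fraction) == (0.23, 0.02)
        assert g.n == 3


class TestTukey:
    def test_no_difference_no_significance(self):
        groups = make_groups({5: 1.0, 10: 1.0, 20: 1.0}, timepoint="4h", se=0.05)
        groups.append(GroupSummary("reference", 0.0, "pre", "WBC", 12, 1.0, 0.05))
        tiers = tukey_vs_baseline(groups)
        assert all(t == "" for t in tiers.values())

    def test_huge_shift_hits_top_tier(self):
        groups = make_groups({5: 1.0, 10: 1.0, 20: 1.0 - 50 * 0.01}, timepoint="4h",
                             se=0.01)
        groups.append(GroupSummary("reference", 0.0, "pre", "WBC", 12, 1.0, 0.01))
        tiers = tukey_vs_baseline(groups)
        assert tiers[(20.0, "4h")] == "***"
        assert tiers[(5.0, "4h")] == ""

    def test_monotone_tiers_from_simulated_effects(self, rng):
        # Large true effect at 20 Gy, none at 5 Gy: tiers must not invert.
        from hemrbe.datamodel import summarize_groups
        from conftest import make_records
        truth = {5.0: 1.0, 10.0: 0.75, 20.0: 0.35}
        fracs = {d: (m * np.exp(rng.normal(0, 0.05, 6))).tolist()
                 for d, m in truth.items()}
        groups = summarize_groups(make_records(fracs, arm="reference",
                                               timepoint="4h"))
        groups.append(GroupSummary("reference", 0.0, "pre", "WBC", 12, 1.0, 0.02))
        tiers = tukey_vs_baseline(groups)
        order = {"": 0, "#": 1, "*": 2, "**": 3, "***": 4}
        assert order[tiers[(20.0, "4h")]] >= order[tiers[(10.0, "4h")]] \
            >= order[tiers[(5.0, "4h")]]
        assert tiers[(20.0, "4h")] == "***"

    def test_single_animal_group_not_testable(self):
        groups = make_groups({5: 0.8, 10: 0.6, 20: 0.4}, timepoint="4h")
        groups.append(GroupSummary("reference", 0.0, "pre", "WBC", 1, 1.0, 0.0,
                                   se_defined=False))
        tiers = tukey_vs_baseline(groups)
        assert all(t == "NT" for t in tiers.values())
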