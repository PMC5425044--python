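import numpy as np
import pandas as pd
import pytest

from fdsee.data_io import (
    Cohort,
    CohortValidationError,
    EEProfile,
    EmptyCohortError,
    IntegrityError,
    SchemaError,
    filter_and_window,
    read_ee_dataset,
    summarize_cohort,
    write_ee_dataset,
)
from fdsee.synthetic import SimulationConfig, simulate_cohort


def _profile(sid="a", group="obese", weight=50.0, T=5, see=None, time=None):
    return EEProfile(
        subject_id=sid,
        group=group,
        weight=weight,
        height=150.0,
        age=12.0,
        sex=0,
        time=np.arange(1, T + 1) if time is None else time,
        see=np.full(T, 1.0) if see is None else see,
    )


def _long_csv(tmp_path, rows):
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "minute", "see", "group", "weight", "height", "age", "sex"],
    )
    path = tmp_path / "data.csv"
    df.to_csv(path, index=False)
    return path


class TestRead:
    def test_long_format_round_trip(self, tmp_path):
        rows = [
            (s, m, 1.0 + 0.1 * m, "obese" if s == "a" else "non-obese", 50.0, 150, 12, 0)
            for s in ("a", "b")
            for m in range(1, 6)
        ]
        cohort = read_ee_dataset(_long_csv(tmp_path, rows))
        assert len(cohort) == 2
        assert all(p.n_minutes == 5 for p in cohort)
        np.testing.assert_allclose(cohort.profiles[0].see, 1.0 + 0.1 * np.arange(1, 6))

    def test_wide_write_read_is_bitwise_identical(self, tmp_path):
        cohort, _ = simulate_cohort(SimulationConfig(n_per_group=(3, 3), T=20), seed=5)
        path = tmp_path / "wide.csv"
        write_ee_dataset(cohort, path, layout="wide")
        back = read_ee_dataset(path, {"format": "wide"})
        # CSV is written with full repr precision, so values survive exactly
        for p, q in zip(cohort, back):
            assert p.subject_id == q.subject_id
            np.testing.assert_array_equal(p.time, q.time)
            np.testing.assert_array_equal(p.see, q.see)
            assert p.weight == q.weight

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"subject_id": ["a"], "minute": [1]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="see"):
            read_ee_dataset(path)

    def test_duplicate_subject_minute_rejected(self, tmp_path):
        rows = [("a", 1, 1.0, "obese", 50.0, 150, 12, 0)] * 2
        with pytest.raises(IntegrityError):
            read_ee_dataset(_long_csv(tmp_path, rows))

    def test_nonpositive_weight_rejected(self, tmp_path):
        rows = [("a", 1, 1.0, "obese", -3.0, 150, 12, 0)]
        with pytest.raises(CohortValidationError):
            read_ee_dataset(_long_csv(tmp_path, rows))

    def test_invalid_see_minutes_recorded_not_dropped_silently(self, tmp_path):
        rows = [
            ("a", 1, 1.0, "obese", 50.0, 150, 12, 0),
            ("a", 2, "oops", "obese", 50.0, 150, 12, 0),
            ("a", 3, 1.2, "obese", 50.0, 150, 12, 0),
        ]
        cohort = read_ee_dataset(_long_csv(tmp_path, rows))
        assert cohort.profiles[0].n_invalid == 1
        assert cohort.profiles[0].n_minutes == 2
        assert any("1 invalid" in line for line in cohort.provenance)


class TestProfileValidation:
    def test_nonpositive_see_rejected(self):
        with pytest.raises(CohortValidationError):
            _profile(see=np.array([1.0, 0.0, 1.0, 1.0, 1.0]))

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(CohortValidationError):
            _profile(time=np.array([1, 3, 2, 4, 5]))

    def test_duplicate_subject_ids_rejected(self):
        with pytest.raises(IntegrityError):
            Cohort([_profile("a"), _profile("a")])


class TestFilterAndWindow:
    def test_short_subjects_removed_and_grid_common(self):
        # 20 simulated subjects, 3 of them at only 300 minutes -> 17 retained
        cfg = SimulationConfig(n_per_group=(9, 8), T=405)
        cohort, _ = simulate_cohort(cfg, seed=2)
        short_cfg = SimulationConfig(n_per_group=(2, 1), T=300)
        short, _ = simulate_cohort(short_cfg, seed=3)
        for i, p in enumerate(short.profiles):
            p.subject_id = f"short{i}"
        merged = Cohort(cohort.profiles + short.profiles)
        assert len(merged) == 20
        out = filter_and_window(merged, 405)
        assert len(out) == 17
        assert np.array_equal(out.common_grid(), np.arange(1, 406))

    def test_exact_length_cohort_unchanged(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_per_group=(3, 3), T=50), seed=1)
        out = filter_and_window(cohort, 50)
        assert len(out) == 6
        for p, q in zip(cohort, out):
            np.testing.assert_array_equal(p.see, q.see)

    def test_idempotent(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_per_group=(4, 4), T=60), seed=7)
        once = filter_and_window(cohort, 50)
        twice = filter_and_window(once, 50)
        for p, q in zip(once, twice):
            np.testing.assert_array_equal(p.see, q.see)
            np.testing.assert_array_equal(p.time, q.time)

    def test_all_removed_raises(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_per_group=(2, 2), T=30), seed=0)
        with pytest.raises(EmptyCohortError):
            filter_and_window(cohort, 100)


class TestSummarize:
    def test_single_subject_group_has_no_sd(self):
        cohort = Cohort([_profile("a", see=np.full(5, 0.9))])
        table = summarize_cohort(cohort)
        assert table.loc["obese", "mean_see_mean"] == pytest.approx(0.9)
        assert np.isnan(table.loc["obese", "mean_see_sd"])

    def test_zero_exponent_equals_raw_summary(self, small_cohort):
        cohort, _ = small_cohort
        raw = summarize_cohort(cohort)
        zero = summarize_cohort(cohort, weight_exponent=0.0)
        pd.testing.assert_frame_equal(raw, zero)

    def test_recovers_simulated_group_levels(self):
        cfg = SimulationConfig(n_per_group=(60, 60), T=200)
        cohort, truth = simulate_cohort(cfg, seed=9)
        table = summarize_cohort(cohort, weight_exponent=0.5)
        # weight-adjusted group levels should sit near the generator's
        # time-averaged means (0.125 obese, 0.130 non-obese) within MC error
        assert table.loc["obese", "mean_see_mean"] == pytest.approx(0.125, abs=0.01)
        assert table.loc["non-obese", "mean_see_mean"] == pytest.approx(0.130, abs=0.01)
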