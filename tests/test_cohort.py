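"""Daily aggregation, three-stage imputation, splits and windowing."""

import numpy as np
import pandas as pd
import pytest

from eigenformer.cohort import (
    PROV_INTERP,
    PROV_LOCF,
    PROV_MISSING,
    PROV_OBSERVED,
    NormStats,
    aggregate_daily,
    build_sequences,
    impute_cohort,
    impute_three_stage,
    prepare_cohort,
    split_patients,
    zscore_normalize,
)


def events_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "variable", "value"])


class TestAggregateDaily:
    def test_single_value_passthrough(self):
        ev = events_frame([("p1", "2020-01-01T08:00", "creatinine", 1.2)])
        (s,) = aggregate_daily(ev, policy="mean")
        assert s.X[0, 0] == 1.2
        assert s.provenance[0, 0] == PROV_OBSERVED

    def test_mean_and_last_policies(self):
        ev = events_frame(
            [
                ("p1", "2020-01-01T08:00", "creatinine", 1.0),
                ("p1", "2020-01-01T16:00", "creatinine", 2.0),
            ]
        )
        assert aggregate_daily(ev, policy="mean")[0].X[0, 0] == 1.5
        assert aggregate_daily(ev, policy="last")[0].X[0, 0] == 2.0

    def test_grid_spans_first_to_last_day_with_missing_mask(self):
        ev = events_frame(
            [
                ("p1", "2020-01-01", "creatinine", 1.0),
                ("p1", "2020-01-04", "creatinine", 2.0),
                ("p1", "2020-01-02", "bun", 30.0),
            ]
        )
        (s,) = aggregate_daily(ev)
        assert s.n_days == 4
        assert s.feature_names == ("bun", "creatinine")
        assert not s.mask[1, s.feature_names.index("creatinine")]
        assert s.mask[1, s.feature_names.index("bun")]

    def test_nonfinite_values_dropped_bad_timestamp_raises(self):
        ev = events_frame(
            [
                ("p1", "2020-01-01", "creatinine", np.inf),
                ("p1", "2020-01-01", "creatinine", 1.0),
            ]
        )
        (s,) = aggregate_daily(ev)
        assert s.X[0, 0] == 1.0
        with pytest.raises(Exception):
            aggregate_daily(events_frame([("p1", "not-a-date", "creatinine", 1.0)]))

    def test_duplicate_rows_deduplicated(self):
        ev = events_frame(
            [
                ("p1", "2020-01-01T08:00", "creatinine", 1.0),
                ("p1", "2020-01-01T08:00", "creatinine", 1.0),
            ]
        )
        assert aggregate_daily(ev, policy="mean")[0].X[0, 0] == 1.0


def make_series(values_by_day, n_days, feature="creatinine"):
    rows = [("p1", f"2020-01-{d + 1:02d}", feature, v) for d, v in values_by_day.items()]
    # anchor the grid length with a second feature observed every day
    rows += [("p1", f"2020-01-{d + 1:02d}", "anchor", 1.0 * d) for d in range(n_days)]
    (s,) = aggregate_daily(events_frame(rows))
    return s


class TestImputation:
    def test_fully_observed_identity(self):
        s = make_series({0: 1.0, 1: 2.0, 2: 3.0}, 3)
        out, violations = impute_three_stage(s)
        assert violations == []
        assert (out.provenance == PROV_OBSERVED).all()
        assert np.array_equal(out.X, s.X)

    def test_short_gap_linear_interpolation(self):
        s = make_series({0: 1.0, 4: 2.0}, 5)
        out, _ = impute_three_stage(s, max_gap_days=7)
        j = out.feature_names.index("creatinine")
        assert np.allclose(out.X[:, j], [1.0, 1.25, 1.5, 1.75, 2.0])
        assert list(out.provenance[1:4, j]) == [PROV_INTERP] * 3
        # interpolated cells record their dependence on the right endpoint
        assert list(out.dep_day[1:4, j]) == [4, 4, 4]

    def test_long_gap_and_trailing_locf(self):
        s = make_series({0: 1.0, 9: 5.0, 10: 6.0}, 13)
        out, _ = impute_three_stage(s, max_gap_days=7)
        j = out.feature_names.index("creatinine")
        assert np.allclose(out.X[1:9, j], 1.0)  # 8-day gap: carried forward
        assert (out.provenance[1:9, j] == PROV_LOCF).all()
        assert np.allclose(out.X[11:, j], 6.0)  # trailing: carried forward
        assert (out.provenance[11:, j] == PROV_LOCF).all()

    def test_leading_gap_stays_missing(self):
        s = make_series({3: 1.0, 4: 2.0, 10: 3.0}, 11)
        out, _ = impute_three_stage(s)
        j = out.feature_names.index("creatinine")
        assert (out.provenance[:3, j] == PROV_MISSING).all()
        assert np.isnan(out.X[:3, j]).all()

    def test_exclusion_over_missing_threshold(self):
        # creatinine first observed on day 4 of 10: 40% missing
        s = make_series({4: 1.0, 9: 2.0}, 10)
        out, violations = impute_three_stage(s, missing_threshold=0.30)
        assert out is None
        (pid, feat, frac) = violations[0]
        assert feat == "creatinine"
        assert frac == pytest.approx(0.4)

    def test_never_observed_feature_is_fully_missing(self):
        rows = [("p1", f"2020-01-{d + 1:02d}", "anchor", 1.0) for d in range(4)]
        rows.append(("p2", "2020-01-01", "creatinine", 1.0))
        rows.append(("p2", "2020-01-02", "anchor", 1.0))
        series = aggregate_daily(events_frame(rows))
        p1 = [s for s in series if s.patient_id == "p1"][0]
        out, violations = impute_three_stage(p1, essential_features=["creatinine"])
        assert out is None
        assert violations[0][2] == 1.0

    def test_cohort_retention_accounting(self):
        good = make_series({0: 1.0, 1: 2.0, 2: 3.0}, 3)
        bad = make_series({4: 1.0}, 10)
        retained, report = impute_cohort([good, bad])
        assert report.n_input == 2
        assert report.n_retained == len(retained) == 1
        assert report.n_retained + len({v[0] for v in report.excluded}) == report.n_input
        # every excluded patient violates the threshold when re-checked
        for pid, feat, frac in report.excluded:
            assert frac > 0.30


class TestNormalization:
    def test_symmetric_three_point(self):
        stats = NormStats(np.array([2.0]), np.array([1.0]), ("f",))
        out = zscore_normalize(np.array([[1.0], [2.0], [3.0]]), stats)
        assert np.allclose(out.ravel(), [-1, 0, 1])

    def test_centering_and_roundtrip(self, rng):
        X = rng.normal(5, 3, size=(20, 2))
        stats = NormStats(X.mean(0), X.std(0, ddof=1), ("a", "b"))
        assert np.allclose(zscore_normalize(np.tile(X.mean(0), (4, 1)), stats), 0.0)
        assert np.abs(stats.inverse(zscore_normalize(X, stats)) - X).max() < 1e-12

    def test_zero_sigma_rejected(self):
        stats = NormStats(np.array([0.0]), np.array([0.0]), ("f",))
        with pytest.raises(ValueError):
            zscore_normalize(np.ones((3, 1)), stats)


class TestSplits:
    def test_ten_patients_8_1_1(self):
        tr, va, te = split_patients([f"p{i}" for i in range(10)], seed=1)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        assert set(tr) | set(va) | set(te) == {f"p{i}" for i in range(10)}

    def test_same_seed_reproducible_different_seed_not(self):
        ids = [f"p{i}" for i in range(1000)]
        a = split_patients(ids, seed=7)
        b = split_patients(ids, seed=7)
        c = split_patients(ids, seed=8)
        assert a == b
        assert a != c
        assert tuple(map(len, a)) == tuple(map(len, c))

    def test_stratified_proportions(self):
        ids = [f"p{i}" for i in range(200)]
        strata = {pid: i % 4 for i, pid in enumerate(ids)}
        tr, va, te = split_patients(ids, seed=3, stratify_by=strata)
        for g in range(4):
            in_train = sum(1 for p in tr if strata[p] == g)
            assert in_train == 40  # 80% of each 50-patient stratum

    def test_tiny_stratum_falls_back_pooled(self):
        ids = [f"p{i}" for i in range(12)]
        strata = {pid: (0 if i < 10 else 1) for i, pid in enumerate(ids)}
        tr, va, te = split_patients(ids, seed=0, stratify_by=strata)
        assert sorted(tr + va + te) == sorted(ids)


class TestBuildSequences:
    def make_full_series(self, T):
        rows = []
        for d in range(T):
            rows.append(("p1", f"2020-01-{d + 1:02d}T09:00", "creatinine", float(d)))
            rows.append(("p1", f"2020-01-{d + 1:02d}T09:00", "bun", 10.0 + d))
        (s,) = aggregate_daily(events_frame(rows))
        out, _ = impute_three_stage(s)
        return out

    def identity_stats(self):
        return NormStats(np.zeros(2), np.ones(2), ("bun", "creatinine"))

    def test_sample_count_formula(self):
        s = self.make_full_series(10)
        samples = build_sequences([s], 7, 1, "creatinine", self.identity_stats())
        assert len(samples) == 10 - 7 - 1 + 1

    def test_window_does_not_fit(self):
        s = self.make_full_series(5)
        assert build_sequences([s], 7, 1, "creatinine", self.identity_stats()) == []

    def test_indexing_contract(self):
        s = self.make_full_series(10)
        samples = build_sequences([s], 7, 2, "creatinine", self.identity_stats())
        first = samples[0]
        assert first.anchor_day == 6
        j = s.feature_names.index("creatinine")
        assert np.allclose(first.x[:, j], np.arange(0, 7))  # rows t-6 .. t
        assert first.y == pytest.approx(8.0)  # target at t + H

    def test_bad_config_rejected(self):
        s = self.make_full_series(10)
        with pytest.raises(ValueError):
            build_sequences([s], 0, 1, "creatinine", self.identity_stats())
        with pytest.raises(ValueError):
            build_sequences([s], 7, 0, "creatinine", self.identity_stats())


class TestPreparedCohort:
    def test_training_matrix_is_exactly_standardized(self, tiny_prepared):
        _, data = tiny_prepared
        M = data["cohort"].training_matrix
        assert np.abs(M.mean(axis=0)).max() < 1e-10
        assert np.abs(M.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_patient_level_leakage(self, tiny_prepared):
        _, data = tiny_prepared
        cohort = data["cohort"]
        ids = {s: {x.patient_id for x in cohort.samples[s]} for s in ("train", "val", "test")}
        assert not (ids["train"] & ids["val"])
        assert not (ids["train"] & ids["test"])
        assert not (ids["val"] & ids["test"])

    def test_no_lookahead_under_truncation(self, tiny_cohort):
        """Deleting all data after a sample's anchor day must leave its
        lookback matrix bit-identical (causal imputation guarantee)."""
        cohort = prepare_cohort(tiny_cohort.events, tiny_cohort.demographics, seed=0)
        ev = tiny_cohort.events.copy()
        ev["timestamp"] = pd.to_datetime(ev["timestamp"])
        checked = 0
        for sample in cohort.samples["test"][:8]:
            pid = sample.patient_id
            pat = ev[ev["patient_id"] == pid]
            start = pat["timestamp"].dt.normalize().min()
            cutoff = start + pd.Timedelta(days=int(sample.anchor_day))
            truncated = pat[pat["timestamp"].dt.normalize() <= cutoff]
            series = aggregate_daily(truncated)
            imputed, _ = impute_cohort(series, essential_features=[])
            # compare the lookback matrix recomputed from truncated data
            s_trunc = imputed[0]
            Xn = zscore_normalize(s_trunc.X, cohort.stats)
            lb = Xn[sample.anchor_day - cohort.lookback + 1 : sample.anchor_day + 1]
            assert np.array_equal(lb, sample.x)
            checked += 1
        assert checked > 0
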