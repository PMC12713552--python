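"""Cohort assignment, two-stage normative tables, sex contrasts, curves."""

import numpy as np
import pandas as pd
import pytest

from myosize.norms import (
    COHORT_IDS,
    COHORTS,
    NormativeTable,
    assign_cohort,
    build_normative_table,
    compare_sexes,
    export_growth_curves,
    load_reference_normative_table,
)
from myosize.samples import BiopsySample
from myosize.synthetic import generate_cohort_samples, make_cohort_params


def _biopsy(sample_id, age, sex, values):
    fibers = pd.DataFrame(
        {"label_id": range(1, len(values) + 1), "area_um2": np.asarray(values) ** 2,
         "minferet_um": values}
    )
    return BiopsySample(sample_id, age, sex, fibers)


class TestAssignCohort:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (0.9, "0-3 months"),
            (3.9, "0-3 months"),
            (4.0, "4-6 months"),
            (12.0, "10-12 months"),
            (13.0, "1 year"),
            (14.0, "1 year"),
            (24.0, "2 years"),
            (119.9, "9 years"),
            (120.0, "10-12 years"),
            (300.0, "22-25 years"),
        ],
    )
    def test_mapping(self, age, expected):
        assert assign_cohort(age) == expected

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 312.0, 1e9, float("nan")):
            with pytest.raises(ValueError):
                assign_cohort(bad)

    def test_partition_covers_study_range_exactly_once(self):
        """Every age on a half-month grid maps to exactly one cohort."""
        for age in np.arange(0, 312, 0.5):
            cid = assign_cohort(float(age))
            hits = [c for c, lo, hi in COHORTS if lo <= age < hi]
            assert hits == [cid]
        # intervals are disjoint and contiguous over [0, 312)
        spans = sorted((lo, hi) for _, lo, hi in COHORTS)
        assert spans[0][0] == 0 and spans[-1][1] == 312
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c


class TestBuildNormativeTable:
    def test_two_identical_biopsies_have_zero_sd(self):
        v = np.linspace(5, 25, 101)
        t = build_normative_table([_biopsy("a", 30, "male", v), _biopsy("b", 31, "male", v)])
        cell = t.cell("2 years", "male")
        assert cell["n_biopsies"] == 2
        for lev in (5, 25, 50, 75, 95):
            assert cell[f"p{lev}_sd"] == 0.0
            assert cell[f"p{lev}_mean"] == pytest.approx(np.percentile(v, lev))

    def test_single_biopsy_reports_no_sd(self):
        t = build_normative_table([_biopsy("solo", 11, "male", np.linspace(5, 20, 50))])
        cell = t.cell("10-12 months", "male")
        assert cell["n_biopsies"] == 1
        assert np.isnan(cell["p50_sd"])

    def test_empty_biopsy_rejected(self):
        empty = BiopsySample("x", 30, "male")
        with pytest.raises(ValueError, match="x"):
            build_normative_table([empty])

    def test_percentile_means_monotone_and_match_generator(self):
        """A synthetic cohort's table percentile means sit near the
        generating distribution's percentiles."""
        p = make_cohort_params("3 years", "female")
        samples = generate_cohort_samples(
            p, n_biopsies=10, n_fibers=20_000, seed=21, age_months=40.0, sex="female"
        )
        t = build_normative_table(samples)
        cell = t.cell("3 years", "female")
        means = [cell[f"p{lev}_mean"] for lev in (5, 25, 50, 75, 95)]
        assert means == sorted(means)
        pooled = np.concatenate([s.minferet for s in samples])
        for lev, m in zip((5, 25, 50, 75, 95), means):
            assert m == pytest.approx(np.percentile(pooled, lev), rel=0.1)
        assert cell["pooled_mean"] == pytest.approx(p.target_mean_minferet, rel=0.1)

    def test_invariant_to_biopsy_and_fiber_ordering(self):
        rng = np.random.default_rng(3)
        vals = [rng.lognormal(3, 0.5, 500) for _ in range(4)]
        samples = [_biopsy(f"s{i}", 40 + i, "female", v) for i, v in enumerate(vals)]
        shuffled = [
            _biopsy(f"s{i}", 40 + i, "female", rng.permutation(v))
            for i, v in enumerate(vals)
        ]
        t1 = build_normative_table(samples)
        t2 = build_normative_table(list(reversed(shuffled)))
        pd.testing.assert_frame_equal(
            t1.cells.reset_index(drop=True), t2.cells.reset_index(drop=True)
        )


class TestCompareSexes:
    def _table_from_pb(self, pb):
        return NormativeTable(cells=pd.DataFrame(), per_biopsy=pb)

    def test_identical_groups_no_difference(self):
        v = np.linspace(10, 30, 200)
        samples = [_biopsy(f"m{i}", 30, "male", v) for i in range(3)]
        samples += [_biopsy(f"f{i}", 30, "female", v) for i in range(3)]
        t = build_normative_table(samples)
        out = compare_sexes(t, "2 years", 50)
        assert out["difference"] == 0.0
        assert out["p_value"] == 1.0

    def test_insufficient_biopsies_not_estimable(self):
        t = build_normative_table(
            [_biopsy("m", 30, "male", np.linspace(5, 20, 50)),
             _biopsy("f1", 30, "female", np.linspace(5, 20, 50)),
             _biopsy("f2", 30, "female", np.linspace(6, 21, 50))]
        )
        with pytest.raises(ValueError, match="not estimable"):
            compare_sexes(t, "2 years", 50)

    def test_reference_table_not_estimable(self):
        t = load_reference_normative_table()
        with pytest.raises(ValueError, match="not estimable"):
            compare_sexes(t, "2 years", 50)

    def test_type_i_error_calibrated(self):
        """Null simulation: same distribution for both sexes, n = 10 per
        sex, 1000 replicates -> rejection rate near 0.05."""
        rng = np.random.default_rng(555)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            rows = []
            for sex, tag in (("male", "m"), ("female", "f")):
                for i in range(10):
                    rows.append(
                        {"sample_id": f"{tag}{i}", "cohort": "2 years", "sex": sex,
                         "level": 50, "value": rng.normal(20, 3)}
                    )
            t = self._table_from_pb(pd.DataFrame(rows))
            if compare_sexes(t, "2 years", 50)["p_value"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_power_against_large_shift(self):
        """Groups shifted by 3 SD, n = 12 per sex -> p < 0.001 in >= 95%
        of replicates."""
        rng = np.random.default_rng(556)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            rows = []
            for sex, tag, mu in (("male", "m", 29.0), ("female", "f", 20.0)):
                for i in range(12):
                    rows.append(
                        {"sample_id": f"{tag}{i}", "cohort": "2 years", "sex": sex,
                         "level": 50, "value": rng.normal(mu, 3)}
                    )
            t = self._table_from_pb(pd.DataFrame(rows))
            if compare_sexes(t, "2 years", 50)["p_value"] < 0.001:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_no_spurious_sex_effect_from_pipeline(self):
        """Both sexes drawn from one distribution: percentile means agree."""
        p = make_cohort_params("2 years", "pooled")
        male = generate_cohort_samples(p, 12, 5000, seed=31, age_months=30, sex="male")
        female = generate_cohort_samples(p, 12, 5000, seed=32, age_months=30, sex="female")
        t = build_normative_table(male + female)
        m = t.cell("2 years", "male")
        f = t.cell("2 years", "female")
        for lev in (5, 25, 50, 75, 95):
            assert m[f"p{lev}_mean"] == pytest.approx(f[f"p{lev}_mean"], rel=0.15)
        assert compare_sexes(t, "2 years", 50)["p_value"] > 0.01


class TestReferenceTableAndCurves:
    def test_reference_table_has_all_cells(self):
        t = load_reference_normative_table()
        assert len(t.cells) == 36
        assert set(t.cells["cohort"]) == set(COHORT_IDS)
        cell = t.cell("22-25 years", "male")
        assert cell["p95_mean"] == pytest.approx(82.59)
        assert cell["pooled_mean"] == pytest.approx(58.19)

    def test_growth_curves_by_sex_roundtrip(self, tmp_path):
        t = load_reference_normative_table()
        curves = export_growth_curves(t, "by-sex")
        path = tmp_path / "curves.csv"
        curves.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(curves, back)
        assert len(curves) == 36 * 5

    def test_pooled_under_2y_merges_sexes(self):
        t = load_reference_normative_table()
        curves = export_growth_curves(t, "pooled-under-2y")
        young = curves[curves["cohort"].isin(
            ["0-3 months", "4-6 months", "7-9 months", "10-12 months", "1 year", "2 years"]
        )]
        assert set(young["group"]) == {"pooled"}
        old = curves[curves["cohort"] == "3 years"]
        assert set(old["group"]) == {"male", "female"}

    def test_empty_table_gives_header_only(self):
        t = NormativeTable(cells=pd.DataFrame(columns=["cohort", "sex", "n_biopsies"]))
        curves = export_growth_curves(t)
        assert curves.empty
        assert list(curves.columns) == ["cohort", "group", "level", "value_um"]
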