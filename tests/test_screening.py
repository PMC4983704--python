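"""Screening statistics: oracles for the fence rule, step-down Sidak,
Spearman matrix, and discovery/validation screening logic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from combiwise.reference import published_screening_table
from combiwise.screening import (
    exclude_outliers,
    one_sample_test,
    relative_change,
    screen_cohort,
    snr,
    spearman_matrix,
    stepdown_sidak,
    z_score,
)
from combiwise.simulate import BiomarkerSpec, generate_screening_panel


class TestRelativeChange:
    def test_basic_percentage(self):
        d, _ = relative_change([50.0], [60.0])
        assert d == pytest.approx([20.0])

    def test_linear_change_doubles_over_two_years(self):
        # a 10%-per-year linear change is 20% after two years
        d1, _ = relative_change([100.0], [110.0])
        d2, _ = relative_change([100.0], [120.0])
        assert d2 == pytest.approx(2 * d1)

    def test_no_change_is_zero(self):
        d, _ = relative_change([7.0], [7.0])
        assert d == pytest.approx([0.0])

    def test_zero_baseline_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero baseline"):
            d, n = relative_change([0.0, 10.0], [5.0, 11.0])
        assert n == 1
        assert d == pytest.approx([10.0])


class TestExcludeOutliers:
    def test_documented_fence_example(self):
        vals = list(range(1, 11)) + [100]
        kept, removed = exclude_outliers(vals)
        # Q1=3.5, Q3=8.5 by linear interpolation, IQR=5 -> upper fence 23.5
        assert list(removed) == [100]
        assert sorted(kept) == list(range(1, 11))

    def test_constant_data_untouched(self):
        kept, removed = exclude_outliers([5.0] * 6)
        assert len(kept) == 6 and len(removed) == 0

    def test_symmetric_inlier_data_is_identity(self):
        x = [-2.0, -1.0, 0.0, 1.0, 2.0]
        kept, removed = exclude_outliers(x)
        assert list(kept) == x

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=20))
    def test_matches_brute_force_oracle(self, values):
        kept, removed = exclude_outliers(values)
        x = np.array(values)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        fence_lo, fence_hi = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
        expect_keep = [v for v in values if fence_lo <= v <= fence_hi]
        assert sorted(kept) == sorted(expect_keep)
        if np.std(expect_keep, ddof=1) > 0 and len(expect_keep) >= 2:
            t, p = one_sample_test(kept)
            ref = stats.ttest_1samp(expect_keep, 0.0)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestOneSampleTest:
    def test_zero_mean_gives_p_one(self):
        t, p = one_sample_test([-1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_composite_row_statistics(self):
        # n=35 sample constructed to have exactly mean 9.10, SD 13.23
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 35)
        x = (x - x.mean()) / x.std(ddof=1) * 13.23 + 9.10
        t, p = one_sample_test(x)
        assert t == pytest.approx(9.10 / (13.23 / np.sqrt(35)), rel=1e-12)
        assert t == pytest.approx(4.07, abs=0.01)
        assert p == pytest.approx(3e-4, abs=2e-4)

    def test_zero_sd_with_nonzero_mean_raises(self):
        with pytest.raises(ValueError):
            one_sample_test([2.0, 2.0, 2.0])


class TestZScore:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(9.10, 13.23, 0.6878), (6.48, 14.15, 0.4580)],
    )
    def test_published_rows(self, mean, sd, expected, rng):
        x = rng.normal(0, 1, 40)
        x = (x - x.mean()) / x.std(ddof=1) * sd + mean
        assert z_score(x) == expected

    def test_zero_mean(self, rng):
        x = rng.normal(0, 1, 10)
        assert z_score(x - x.mean()) == 0.0

    def test_scale_invariant(self, rng):
        x = rng.normal(3, 2, 25)
        assert z_score(10.0 * x) == z_score(x)


class TestStepdownSidak:
    def test_single_p_unchanged(self):
        assert stepdown_sidak([0.2]) == pytest.approx([0.2])

    def test_hand_checked_triple(self):
        adj = stepdown_sidak([0.01, 0.02, 0.03])
        # 1-(1-.01)^3 = .029701; 1-(1-.02)^2 = .0396; 1-.97=.03 -> monotonized
        assert adj == pytest.approx([0.029701, 0.0396, 0.0396])

    def test_all_ones_stay_one(self):
        assert stepdown_sidak([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_permutation_invariant(self, ps):
        adj = stepdown_sidak(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = stepdown_sidak(np.asarray(ps)[perm])
        assert np.allclose(np.sort(adj_perm), np.sort(adj))


class TestSnr:
    def test_identical_populations(self):
        assert snr([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        assert snr([8.0, 6.0], [1.0, 1.0]) == pytest.approx(7.0)

    def test_common_rescaling_invariant(self, rng):
        p = rng.normal(5, 2, 30)
        r = rng.normal(0, 1, 30)
        assert snr(3.3 * p, 3.3 * r) == pytest.approx(snr(p, r))

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            snr([1.0], [0.0, 0.0])


class TestSpearmanMatrix:
    def test_monotone_and_reversed_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [10, 20, 30, 40], "c": [4, 3, 2, 1]})
        rho, _, _ = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0],
                "y": [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0],
            }
        )
        rho, _, _ = spearman_matrix(df)
        rx = stats.rankdata(df["x"])
        ry = stats.rankdata(df["y"])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(oracle)

    def test_constant_column_masked_out(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        rho, _, sig = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])
        assert not sig.loc["a", "b"]

    def test_bonferroni_mask_threshold(self, rng):
        n = 60
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.1, n), "c": rng.normal(0, 1, n)})
        _, pv, sig = spearman_matrix(df, alpha=0.05, m_tests=28)
        assert sig.loc["a", "b"]
        assert bool(sig.loc["a", "c"]) == bool(pv.loc["a", "c"] < 0.05 / 28)


class TestScreenCohort:
    def test_published_discovery_and_validation_counts(self):
        # applying the screening filters to the published summary table:
        # 15 discovery-significant outcomes, 11 validated in the second
        # primary-progressive cohort, and (table-wise) 7 in the
        # secondary-progressive cohort
        tab = published_screening_table()
        passed = tab[tab["p_ippoms1"] < 0.05]
        assert len(passed) == 15
        assert int((passed["p_adj_ippoms2"] < 0.05).sum()) == 11
        assert int((passed["p_adj_rivitalise"] < 0.05).sum()) == 7

    def test_nonsignificant_discovery_not_carried(self):
        panel = generate_screening_panel(
            [BiomarkerSpec("NULL", delta_mean=0.0, delta_sd=10.0)],
            n_subjects=30, cohort="DISC", seed=5,
        )
        panel2 = generate_screening_panel(
            [BiomarkerSpec("NULL", delta_mean=0.0, delta_sd=10.0)],
            n_subjects=30, cohort="VAL", seed=6,
        )
        table = screen_cohort(pd.concat([panel, panel2]), "DISC", ["VAL"])
        row = table[(table.cohort == "DISC") & (table.biomarker == "NULL")].iloc[0]
        if row.p_raw >= 0.05:
            val = table[(table.cohort == "VAL")].iloc[0]
            assert pd.isna(val.p_adjusted)

    def test_strong_effect_discovered_and_validated(self):
        bms = [
            BiomarkerSpec("STRONG", delta_mean=9.0, delta_sd=6.0),
            BiomarkerSpec("NULL1", delta_mean=0.0, delta_sd=12.0),
        ]
        frames = [
            generate_screening_panel(bms, n_subjects=35, cohort=c, seed=s)
            for c, s in (("DISC", 1), ("VAL1", 2), ("VAL2", 3))
        ]
        table = screen_cohort(pd.concat(frames), "DISC", ["VAL1", "VAL2"])
        strong = table[table.biomarker == "STRONG"].set_index("cohort")
        assert strong.loc["DISC", "p_raw"] < 0.05
        assert strong.loc["VAL1", "validated"]
        assert strong.loc["VAL2", "validated"]
        # adjusted p is at least the raw p in the carried family
        assert strong.loc["VAL1", "p_adjusted"] >= strong.loc["VAL1", "p_raw"]

    def test_injected_outlier_removed_by_fences(self):
        panel = generate_screening_panel(
            [BiomarkerSpec("OUT", delta_mean=5.0, delta_sd=3.0,
                           n_outliers=1, outlier_scale=30.0)],
            n_subjects=35, cohort="DISC", seed=9,
        )
        table = screen_cohort(panel, "DISC")
        assert int(table.iloc[0]["n_outliers_removed"]) >= 1

    def test_excessive_outlier_removal_falls_back_to_whole_dataset(self):
        # heavily discretized data: most subjects sit on one step, so the
        # IQR collapses and the fences would delete every mover
        base = np.full(20, 4.0)
        follow = base.copy()
        follow[:3] = 4.5
        rows = []
        for i, (b, f) in enumerate(zip(base, follow)):
            rows.append({"subject_id": f"s{i}", "cohort": "C", "biomarker": "EDSSLIKE",
                         "month": -12, "value": b})
            rows.append({"subject_id": f"s{i}", "cohort": "C", "biomarker": "EDSSLIKE",
                         "month": 0, "value": f})
        table = screen_cohort(pd.DataFrame(rows), "C")
        row = table.iloc[0]
        assert row["outliers_kept_whole"]
        assert row["n_used"] == 20

    def test_removal_fraction_cap_triggers_whole_dataset(self, rng):
        # continuous data with one gross outlier, but a very strict cap
        x = rng.normal(5.0, 1.0, 20)
        x[0] = 60.0
        from combiwise.screening import _cohort_stats

        strict = _cohort_stats(x, "BM", "C", max_outlier_fraction=0.01)
        assert strict.outliers_kept_whole and strict.n_used == 20
        default = _cohort_stats(x, "BM", "C")
        assert not default.outliers_kept_whole
        assert default.n_outliers_removed == 1
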