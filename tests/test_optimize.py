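"""Constrained splits, GA weight search, aggregation and validation."""

import numpy as np
import pandas as pd
import pytest

from combiwise.lmm import fit_random_intercept
from combiwise.optimize import (
    GAConfig,
    aggregate_and_drop,
    assign_strata,
    ga_optimize,
    make_constrained_splits,
    validate_composite,
)
from combiwise.scoring import WeightVector
from combiwise.simulate import generate_weighted_feature_cohort


class TestConstrainedSplits:
    def test_single_stratum_fraction(self):
        strata = {f"s{i}": "no_fail" for i in range(10)}
        plans = make_constrained_splits(strata, 3, 0.7, seed=1)
        assert all(len(p.training_ids) == 7 for p in plans)
        for p in plans:
            assert set(p.training_ids) | set(p.validation_ids) == set(strata)
            assert not set(p.training_ids) & set(p.validation_ids)

    def test_same_seed_reproduces_plans(self):
        strata = {f"s{i}": ("fail_ndh" if i % 3 == 0 else "no_fail") for i in range(20)}
        a = make_constrained_splits(strata, 10, seed=42)
        b = make_constrained_splits(strata, 10, seed=42)
        assert [p.training_ids for p in a] == [p.training_ids for p in b]

    def test_stratum_balance_within_one_subject_over_many_plans(self):
        # 98 subjects spread over 5 failure strata, as in a combined
        # progressive-MS cohort
        sizes = {"no_fail": 55, "fail_ndh": 15, "fail_25fw": 12,
                 "fail_25fw_ndh": 10, "fail_dh": 6}
        strata = {}
        i = 0
        for name, n in sizes.items():
            for _ in range(n):
                strata[f"s{i:03d}"] = name
                i += 1
        plans = make_constrained_splits(strata, 300, 0.7, seed=9)
        n_train_target = round(0.7 * 98)
        for p in plans:
            assert len(p.training_ids) == n_train_target
            for name, n in sizes.items():
                share = p.strata_counts[name]["train"]
                assert abs(share - 0.7 * n) <= 1.0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_constrained_splits({"a": "no_fail"}, 1, train_fraction=1.5)

    def test_strata_assigned_from_baseline_failures(self):
        visits = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "c"],
                "month": [-12, 0, -12, -12],
                "fail25fw_1": [1, 0, 0, 0],
                "fail25fw_2": [0, 0, 0, 0],
                "fail9hpt_nd_1": [1, 0, 0, 0],
                "fail9hpt_nd_2": [0, 0, 0, 0],
                "fail9hpt_d_1": [0, 0, 1, 0],
                "fail9hpt_d_2": [0, 0, 0, 0],
            }
        )
        strata = assign_strata(visits)
        assert strata == {"a": "fail_25fw_ndh", "b": "fail_dh", "c": "no_fail"}


class TestGAOptimize:
    def test_single_feature_recovers_its_own_t(self, rng):
        df = generate_weighted_feature_cohort([1.0], n_subjects=30, seed=5)
        F = df[["f0"]].to_numpy()
        w, t = ga_optimize(
            F, np.array([1.0]), df["subject_id"].to_numpy(),
            df["month"].to_numpy(float), GAConfig(generations=10), rng,
        )
        assert w == pytest.approx([1.0])
        direct = fit_random_intercept(
            df["subject_id"], df["month"].astype(float), df["f0"]
        ).t_stat
        assert t == pytest.approx(direct, rel=1e-6)

    def test_pure_noise_feature_gets_negligible_weight(self):
        # one real feature plus one with no trend: across seeded runs the
        # noise feature's median relative weight stays tiny
        weights = []
        for seed in range(8):
            df = generate_weighted_feature_cohort([1.0], n_subjects=60, seed=seed)
            gen = np.random.default_rng(seed)
            df["noise"] = gen.normal(0, 0.05, len(df))
            F = df[["f0", "noise"]].to_numpy()
            w, _ = ga_optimize(
                F, np.array([1.0, 1.0]), df["subject_id"].to_numpy(),
                df["month"].to_numpy(float),
                GAConfig(population_size=30, generations=40),
                np.random.default_rng(100 + seed),
            )
            weights.append(w[1])
        assert np.median(weights) < 0.05

    def test_known_composite_recovered(self, rng):
        truth = np.array([0.5, 0.3, 0.2])
        df = generate_weighted_feature_cohort(truth, n_subjects=80, noise_sd=0.04, seed=3)
        F = df[["f0", "f1", "f2"]].to_numpy()
        w, _ = ga_optimize(
            F, np.ones(3), df["subject_id"].to_numpy(), df["month"].to_numpy(float),
            GAConfig(generations=60), rng,
        )
        cos = w @ truth / (np.linalg.norm(w) * np.linalg.norm(truth))
        assert cos > 0.9


class TestAggregateAndDrop:
    def test_always_zero_feature_dropped(self):
        W = np.array([[0.6, 0.4, 0.0], [0.7, 0.3, 0.0], [0.5, 0.5, 0.0]])
        mean, dropped = aggregate_and_drop(W, ["a", "b", "c"])
        assert dropped == {"c"}
        assert mean["a"] == pytest.approx(0.6)

    def test_stable_weights_pass_through(self):
        W = np.array([[0.5, 0.5], [0.5, 0.5]])
        mean, dropped = aggregate_and_drop(W, ["a", "b"])
        assert dropped == set()
        assert mean == {"a": 0.5, "b": 0.5}

    def test_dropping_everything_is_an_error(self):
        W = np.array([[1e-5, 1e-5], [1e-5, 1e-5]])
        with pytest.raises(ValueError):
            aggregate_and_drop(W, ["a", "b"], drop_threshold=0.9)

    def test_needs_two_permutations(self):
        with pytest.raises(ValueError):
            aggregate_and_drop(np.array([[1.0, 0.0]]), ["a", "b"])


class TestFullPipeline:
    @pytest.fixture(scope="class")
    def result(self):
        from combiwise.optimize import PipelineConfig, optimize_weights
        from combiwise.simulate import SyntheticSpec, generate_cohort

        visits = generate_cohort(
            SyntheticSpec(n_subjects=24, progression_rate_mean=0.04,
                          hazard_max=0.0, learning_gain=2.0), seed=21,
        )
        cfg = PipelineConfig(
            n_permutations_stage1=6,
            n_permutations_stage2=6,
            ga=GAConfig(population_size=20, generations=25),
        )
        return visits, cfg, optimize_weights(visits, cfg, seed=5)

    def test_learning_effect_scales_are_sign_pinned_and_dropped(self, result):
        # cognitive counts improve with repeat testing, opposite to disease
        # progression: the sign constraint pins them at zero weight
        _, _, res = result
        assert {"pasat", "sdmt"} <= res.dropped

    def test_final_scale_spans_0_to_100(self, result):
        _, _, res = result
        kept = [n for n in res.final.feature_names]
        assert res.dropped.isdisjoint(kept)
        assert sum(res.final.relative_weights) == pytest.approx(1.0)

    def test_pipeline_is_pure_function_of_inputs(self, result):
        from combiwise.optimize import optimize_weights

        visits, cfg, res = result
        res2 = optimize_weights(visits, cfg, seed=5)
        assert res2.final.computing_weights == pytest.approx(res.final.computing_weights)
        pd.testing.assert_frame_equal(res2.stage2_weights, res.stage2_weights)

    def test_validation_report_covers_all_permutations(self, result):
        _, cfg, res = result
        assert len(res.validation.t_table) + res.validation.n_skipped == 6


class TestValidateComposite:
    @pytest.fixture
    def feature_table(self):
        df = generate_weighted_feature_cohort([0.6, 0.4], n_subjects=24, seed=8)
        df = df.rename(columns={"f0": "edss", "f1": "snrs"})
        # orient the snrs-like column the way the real scale runs (down)
        df["snrs"] = -df["snrs"]
        return df

    def test_composite_identical_to_single_scale_never_wins(self, feature_table):
        from combiwise.optimize import make_constrained_splits

        strata = {s: "no_fail" for s in feature_table["subject_id"].unique()}
        splits = make_constrained_splits(strata, 10, seed=2)
        wv = WeightVector(("edss",), (1.0,), 0.0)
        report = validate_composite(wv, feature_table, splits, scale_columns=["edss"])
        assert report.win_fraction["edss"] == 0.0  # ties, strict comparison
        assert report.mean_gain["edss"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seeded_splits(self, feature_table):
        from combiwise.optimize import make_constrained_splits

        strata = {s: "no_fail" for s in feature_table["subject_id"].unique()}
        splits = make_constrained_splits(strata, 5, seed=7)
        wv = WeightVector(("edss", "snrs"), (0.6, -0.4), 0.0)
        r1 = validate_composite(wv, feature_table, splits)
        r2 = validate_composite(wv, feature_table, splits)
        pd.testing.assert_frame_equal(r1.t_table, r2.t_table)

    def test_composite_beats_noisier_scale_on_shared_latent(self, feature_table):
        from combiwise.optimize import make_constrained_splits

        # make one scale much noisier; a balanced composite should beat it
        # in most validation permutations
        noisy = feature_table.copy()
        gen = np.random.default_rng(4)
        noisy["snrs"] = noisy["snrs"] - gen.normal(0, 0.25, len(noisy))
        strata = {s: "no_fail" for s in noisy["subject_id"].unique()}
        splits = make_constrained_splits(strata, 40, seed=3)
        wv = WeightVector(("edss", "snrs"), (1.0, -0.2), 0.0)
        report = validate_composite(wv, noisy, splits)
        assert report.win_fraction["snrs"] > 0.8
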