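"""Derivation of composite weights: constrained train/validation splits, a
real-coded genetic algorithm maximizing the mixed-model slope t-statistic,
weight aggregation with variable dropping, and validation against the
individual clinical scales.

The search space is the simplex direction of non-negative weight
magnitudes on unit-rescaled regressors; the worsening sign of each
regressor is applied outside the search so every candidate composite is
oriented toward disease progression.  Because the fitness (a t-statistic)
is invariant to positive rescaling of the composite, only the weight
direction matters and magnitudes are normalized to sum 1 before
evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import scales
from .lmm import balanced_slope_t, fit_random_intercept
from .scales import FEATURE_NAMES, ScaleSpec, default_scale_specs
from .scoring import WeightVector, rescale_to_0_100

# ---------------------------------------------------------------------------
# Constrained permutation splits

#: Failure strata used to balance train/validation allocation.
STRATA = ("fail_25fw_ndh", "fail_ndh", "fail_25fw", "fail_dh", "no_fail")


@dataclass(frozen=True)
class SplitPlan:
    """One train/validation permutation of the cohort."""

    permutation_id: int
    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    strata_counts: dict
    seed: int


def assign_strata(visits: pd.DataFrame) -> dict[str, str]:
    """Assign each subject to a failure stratum from its baseline visit.

    The baseline is the earliest recorded month; a subject failing both
    the walk and the non-dominant peg test lands in the combined stratum,
    then non-dominant peg only, walk only, dominant peg only, else no-fail.
    """
    strata: dict[str, str] = {}
    for sid, grp in visits.groupby("subject_id", sort=True):
        base = grp.loc[grp["month"].idxmin()]

        def failed(c1: str, c2: str) -> bool:
            return any(
                not pd.isna(base.get(c)) and float(base.get(c)) == 1.0 for c in (c1, c2)
            )

        walk = failed("fail25fw_1", "fail25fw_2")
        ndh = failed("fail9hpt_nd_1", "fail9hpt_nd_2")
        dh = failed("fail9hpt_d_1", "fail9hpt_d_2")
        if walk and ndh:
            strata[str(sid)] = "fail_25fw_ndh"
        elif ndh:
            strata[str(sid)] = "fail_ndh"
        elif walk:
            strata[str(sid)] = "fail_25fw"
        elif dh:
            strata[str(sid)] = "fail_dh"
        else:
            strata[str(sid)] = "no_fail"
    return strata


def _stratum_allocation(sizes: Mapping[str, int], n_train: int) -> dict[str, int]:
    """Largest-remainder allocation of the global training count across
    strata; each stratum's share differs from its exact target by < 1."""
    names = sorted(sizes)
    total = sum(sizes.values())
    exact = {s: n_train * sizes[s] / total for s in names}
    alloc = {s: math.floor(exact[s]) for s in names}
    leftover = n_train - sum(alloc.values())
    by_frac = sorted(names, key=lambda s: (-(exact[s] - alloc[s]), s))
    for s in by_frac[:leftover]:
        alloc[s] += 1
    return alloc


def make_constrained_splits(
    subject_strata: Mapping[str, str],
    n_permutations: int,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> list[SplitPlan]:
    """Generate stratified train/validation permutations.

    Each plan allocates ``round(train_fraction * n)`` subjects to training
    overall, sampling within each failure stratum so the stratum's
    training share differs from the target fraction by at most one
    subject.  Reproducible from ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    members: dict[str, list[str]] = {}
    for sid, stratum in subject_strata.items():
        members.setdefault(stratum, []).append(str(sid))
    for ids in members.values():
        ids.sort()
    sizes = {s: len(ids) for s, ids in members.items() if ids}
    n = sum(sizes.values())
    if n == 0:
        raise ValueError("empty cohort")
    n_train = round(train_fraction * n)
    alloc = _stratum_allocation(sizes, n_train)

    child_seeds = np.random.SeedSequence(seed).spawn(n_permutations)
    plans = []
    for pid, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        train: list[str] = []
        valid: list[str] = []
        counts = {}
        for stratum in sorted(sizes):
            ids = members[stratum]
            chosen = rng.choice(len(ids), size=alloc[stratum], replace=False)
            mask = np.zeros(len(ids), dtype=bool)
            mask[chosen] = True
            train.extend(np.array(ids)[mask])
            valid.extend(np.array(ids)[~mask])
            counts[stratum] = {"train": int(mask.sum()), "valid": int((~mask).sum())}
        plans.append(
            SplitPlan(
                permutation_id=pid,
                training_ids=tuple(sorted(train)),
                validation_ids=tuple(sorted(valid)),
                strata_counts=counts,
                seed=seed,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Genetic algorithm

@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA hyperparameters (search over weight magnitudes in
    [0, 1] per unit-rescaled regressor, normalized to sum 1 for fitness)."""

    population_size: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_sigma: float = 0.1
    elitism_frac: float = 0.05
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.lower < 0 or self.upper <= self.lower:
            raise ValueError("bounds must satisfy 0 <= lower < upper")


class _FitnessEvaluator:
    """Slope-t fitness for a batch of candidate weight directions.

    Uses the vectorized balanced-design path when every subject shares the
    same visit schedule, else falls back to per-candidate REML fits.
    """

    def __init__(
        self,
        features: np.ndarray,
        signs: np.ndarray,
        subjects: np.ndarray,
        months: np.ndarray,
    ):
        order = np.lexsort((months, subjects))
        self.F = features[order] * signs  # worsening-oriented
        self.subjects = subjects[order]
        self.months = months[order]
        uniq, counts = np.unique(self.subjects, return_counts=True)
        self.m = len(uniq)
        self.balanced = False
        if counts.min() == counts.max():
            k = counts[0]
            sched = self.months.reshape(self.m, k)
            if np.all(sched == sched[0]):
                self.balanced = True
                self.k = int(k)
                self.times = sched[0].astype(float)

    def __call__(self, pop: np.ndarray) -> np.ndarray:
        sums = pop.sum(axis=1)
        ok = sums > 0
        W = np.where(ok[:, None], pop, 1.0) / np.where(ok, sums, 1.0)[:, None]
        scores = self.F @ W.T  # (n_obs, P)
        if self.balanced:
            t = balanced_slope_t(scores.reshape(self.m, self.k, -1), self.times)
        else:
            t = np.array(
                [
                    fit_random_intercept(self.subjects, self.months, scores[:, j]).t_stat
                    for j in range(scores.shape[1])
                ]
            )
        t = np.where(ok, t, -np.inf)
        return np.where(np.isfinite(t) | (t == -np.inf), t, -np.inf)


def ga_optimize(
    features: np.ndarray,
    signs: np.ndarray,
    subjects: np.ndarray,
    months: np.ndarray,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Search for the weight direction maximizing the slope t-statistic.

    Parameters
    ----------
    features
        ``(n_obs, d)`` unit-rescaled regressors for the training visits.
    signs
        ``(d,)`` worsening direction of each regressor (+1 or -1).
    subjects, months
        Per-observation subject labels and visit months.

    Returns
    -------
    (weights, fitness)
        Best normalized non-negative weight vector (sum 1) and its t.
    """
    config = config or GAConfig()
    rng = rng or np.random.default_rng()
    d = features.shape[1]
    evaluate = _FitnessEvaluator(features, np.asarray(signs, float), subjects, months)

    P = config.population_size
    n_elite = max(1, math.ceil(config.elitism_frac * P))
    pop = rng.uniform(config.lower, config.upper, size=(P, d))
    fit = evaluate(pop)
    for _ in range(config.generations):
        elite_idx = np.argsort(fit)[::-1][:n_elite]
        elites = pop[elite_idx].copy()
        # tournament selection (size 3)
        n_off = P - n_elite
        contenders = rng.integers(0, P, size=(n_off, 3))
        winners = contenders[np.arange(n_off), np.argmax(fit[contenders], axis=1)]
        offspring = pop[winners].copy()
        # blend (BLX-0.5) crossover on consecutive pairs
        for i in range(0, n_off - 1, 2):
            if rng.random() < config.crossover_prob:
                a, b = offspring[i], offspring[i + 1]
                lo = np.minimum(a, b)
                hi = np.maximum(a, b)
                span = hi - lo
                low = lo - 0.5 * span
                high = hi + 0.5 * span
                offspring[i] = rng.uniform(low, high)
                offspring[i + 1] = rng.uniform(low, high)
        # gaussian mutation, per gene
        mut = rng.random(offspring.shape) < config.mutation_prob
        offspring = offspring + mut * rng.normal(0, config.mutation_sigma, offspring.shape)
        offspring = np.clip(offspring, config.lower, config.upper)
        pop = np.vstack([elites, offspring])
        fit = evaluate(pop)
    best = int(np.argmax(fit))
    w = pop[best]
    total = w.sum()
    if total <= 0:
        raise RuntimeError("GA converged to an all-zero weight vector")
    return w / total, float(fit[best])


# ---------------------------------------------------------------------------
# Aggregation, dropping, validation

def aggregate_and_drop(
    weight_matrix: np.ndarray,
    feature_names: Sequence[str],
    drop_threshold: float = 0.01,
) -> tuple[dict[str, float], set[str]]:
    """Average per-permutation normalized weights and drop dead regressors.

    A regressor is dropped when its median normalized weight is below
    ``drop_threshold`` (a fraction of the total weight).  Returns the mean
    normalized weights over all regressors and the dropped set.
    """
    W = np.asarray(weight_matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a (n_permutations >= 2, d) weight matrix")
    sums = W.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("weight vectors must have positive sum")
    Wn = W / sums
    med = np.median(Wn, axis=0)
    dropped = {n for n, m in zip(feature_names, med) if m < drop_threshold}
    if len(dropped) == len(feature_names):
        raise ValueError("drop threshold removes every feature")
    mean = dict(zip(feature_names, Wn.mean(axis=0)))
    return mean, dropped


@dataclass(frozen=True)
class ValidationReport:
    """Composite vs single-scale t-statistics on validation splits."""

    t_table: pd.DataFrame  # one row per permutation; composite + each scale
    win_fraction: dict[str, float]  # P(composite t > scale t), strict
    mean_gain: dict[str, float]  # mean(composite t - scale t)
    n_skipped: int


def validate_composite(
    weights: WeightVector,
    features: pd.DataFrame,
    splits: Sequence[SplitPlan],
    specs: Mapping[str, ScaleSpec] | None = None,
    scale_columns: Sequence[str] | None = None,
) -> ValidationReport:
    """Compare the fixed composite against each single scale on the
    validation side of every split.

    For each validation set the REML slope t is fitted for the composite
    and for each single scale, both oriented so worsening gives a positive
    slope.  Splits with fewer than two validation subjects are skipped.
    """
    specs = specs or default_scale_specs()
    if scale_columns is None:
        scale_columns = [n for n in weights.feature_names if not n.startswith("fail_")]
    from .scoring import composite_scores_frame

    comp = composite_scores_frame(features, weights)
    rows = []
    skipped = 0
    for plan in splits:
        sub = features["subject_id"].astype(str).isin(plan.validation_ids)
        val = features[sub]
        if val["subject_id"].nunique() < 2:
            skipped += 1
            continue
        row = {"permutation_id": plan.permutation_id}
        subj = val["subject_id"].to_numpy()
        months = val["month"].to_numpy(dtype=float)
        row["composite"] = fit_random_intercept(subj, months, comp[sub].to_numpy()).t_stat
        for col in scale_columns:
            sign = specs[col].worsening_sign
            row[col] = fit_random_intercept(
                subj, months, sign * val[col].to_numpy(dtype=float)
            ).t_stat
        rows.append(row)
    table = pd.DataFrame(rows)
    win, gain = {}, {}
    for col in scale_columns:
        if len(table):
            win[col] = float((table["composite"] > table[col]).mean())
            gain[col] = float((table["composite"] - table[col]).mean())
        else:
            win[col] = gain[col] = float("nan")
    return ValidationReport(table, win, gain, skipped)


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the two-stage weight-derivation pipeline."""

    train_fraction: float = 0.7
    n_permutations_stage1: int = 200
    n_permutations_stage2: int = 500
    drop_threshold: float = 0.01
    ga: GAConfig = field(default_factory=GAConfig)
    features: tuple[str, ...] = FEATURE_NAMES


@dataclass(frozen=True)
class OptimizationResult:
    """Everything produced by the weight-derivation pipeline."""

    stage1_weights: pd.DataFrame  # per-permutation normalized weights, all features
    stage2_weights: pd.DataFrame  # per-permutation normalized weights, kept features
    dropped: set
    mean_relative_weights: dict
    final: WeightVector
    validation: ValidationReport


def optimize_weights(
    visits: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
    specs: Mapping[str, ScaleSpec] | None = None,
) -> OptimizationResult:
    """Run the full derivation: splits -> GA per split -> aggregate/drop ->
    second GA stage on retained regressors -> 0-100 rescaling ->
    validation against single scales.

    A pure function of ``(visits, config, seed)``.
    """
    config = config or PipelineConfig()
    specs = specs or default_scale_specs()
    feats = scales.features_frame(visits)
    feat_cols = list(config.features)
    complete = feats.dropna(subset=feat_cols)
    scaled = scales.rescale_frame(complete, specs)
    strata = assign_strata(visits[visits["subject_id"].astype(str).isin(
        scaled["subject_id"].astype(str))])

    signs_all = np.array([specs[n].worsening_sign for n in feat_cols], dtype=float)
    rng_master = np.random.default_rng(np.random.SeedSequence(seed))

    def run_stage(cols: list[str], n_perm: int, split_seed: int):
        signs = np.array([specs[n].worsening_sign for n in cols], dtype=float)
        splits = make_constrained_splits(
            strata, n_perm, config.train_fraction, seed=split_seed
        )
        W = np.empty((n_perm, len(cols)))
        for i, plan in enumerate(splits):
            tr = scaled[scaled["subject_id"].astype(str).isin(plan.training_ids)]
            w, _ = ga_optimize(
                tr[cols].to_numpy(dtype=float),
                signs,
                tr["subject_id"].to_numpy(),
                tr["month"].to_numpy(dtype=float),
                config.ga,
                np.random.default_rng(rng_master.integers(2**31)),
            )
            W[i] = w
        return splits, W

    seed1, seed2 = (int(s.generate_state(1)[0] % 2**31) for s in
                    np.random.SeedSequence(seed).spawn(2))
    _, W1 = run_stage(feat_cols, config.n_permutations_stage1, seed1)
    _, dropped = aggregate_and_drop(W1, feat_cols, config.drop_threshold)
    kept = [c for c in feat_cols if c not in dropped]

    splits2, W2 = run_stage(kept, config.n_permutations_stage2, seed2)
    mean_kept, _ = aggregate_and_drop(W2, kept, drop_threshold=0.0)
    final = rescale_to_0_100(mean_kept, specs)
    report = validate_composite(final, complete, splits2, specs)
    mean_all = {n: mean_kept.get(n, 0.0) for n in feat_cols}
    return OptimizationResult(
        stage1_weights=pd.DataFrame(W1 / W1.sum(axis=1, keepdims=True), columns=feat_cols),
        stage2_weights=pd.DataFrame(W2 / W2.sum(axis=1, keepdims=True), columns=kept),
        dropped=dropped,
        mean_relative_weights=mean_all,
        final=final,
        validation=report,
    )
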