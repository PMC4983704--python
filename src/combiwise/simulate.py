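"""Synthetic longitudinal cohorts with the statistical structure the
composite-scale methodology assumes.

Every subject carries a latent disability trajectory ``d_i(t) = a_i +
b_i * t`` on an EDSS-equivalent 0-10 scale (t in months).  Each clinical
scale observes this latent trait through its own monotone link plus
scale-specific noise: EDSS is the latent value itself, discretized to the
0.5-step grid; SNRS maps through a decreasing logistic onto 0-100; the
timed tests are log-normal with median increasing exponentially in the
latent trait and capped at the administration limits; outright test
failures are drawn from hazards that rise with latent disability
(zero below an EDSS-equivalent of 4, linear to 0.5 at 7, mirroring the
disability range in which ambulation failure emerges); the cognitive
counts can drift upward with repeat testing (a learning effect)
independently of the latent trait.  Healthy-volunteer mode zeroes the
progression, lowers the latent baseline and shrinks the noise, providing
the stable reference population used for signal-to-noise ratios.

Default magnitudes are chosen to resemble small progressive-MS trial
cohorts: baseline EDSS around 5.5 (SD 1.3) and a mean latent worsening of
0.03 EDSS-equivalents per month (~0.36 points/year, matching a ~6% yearly
relative EDSS change at that baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scales import MIN_TIME, PEG_TIME_CAP, VISIT_COLUMNS, WALK_TIME_CAP


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort generator (units in comments)."""

    n_subjects: int = 35
    visit_months: tuple[int, ...] = (-12, -6, 0)
    cohort: str = "SYNTH"
    latent_baseline_mean: float = 5.5  # EDSS-equivalents
    latent_baseline_sd: float = 1.3
    progression_rate_mean: float = 0.03  # EDSS-equivalents / month
    progression_rate_sd: float = 0.02  # between-subject SD of the rate
    edss_noise_sd: float = 0.35  # pre-discretization noise, EDSS points
    snrs_noise_sd: float = 3.0  # SNRS points
    snrs_center: float = 6.5  # latent value at SNRS 50
    snrs_scale: float = 2.0  # logistic slope of the SNRS link
    walk_base: float = 4.0  # median walk seconds at latent 0
    walk_rate: float = 0.35  # exponential growth per latent unit
    walk_log_sd: float = 0.15  # trial-level log-normal sigma
    peg_base: float = 18.0  # median peg seconds at latent 0
    peg_rate: float = 0.12
    peg_log_sd: float = 0.10
    peg_nd_factor: float = 1.05  # non-dominant hand slower by this factor
    hazard_onset: float = 4.0  # latent value where failures begin
    hazard_max: float = 0.5  # failure probability at hazard_ceiling
    hazard_ceiling: float = 7.0
    peg_hazard_factor: float = 0.5  # peg failures rarer than walk failures
    pasat_base: float = 45.0
    sdmt_base: float = 50.0
    cognitive_slope: float = -2.0  # points per latent unit above 5
    cognitive_noise_sd: float = 4.0
    learning_gain: float = 1.5  # points gained per repeat administration
    healthy_volunteer: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("edss_noise_sd", "snrs_noise_sd", "walk_log_sd", "peg_log_sd",
                     "cognitive_noise_sd", "latent_baseline_sd", "progression_rate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.hazard_max <= 1.0:
            raise ValueError("hazard_max must be in [0, 1]")
        if self.hazard_ceiling <= self.hazard_onset:
            raise ValueError("hazard_ceiling must exceed hazard_onset")


def healthy_volunteer_spec(n_subjects: int = 50, **overrides) -> SyntheticSpec:
    """A stable reference population: no progression, low latent level,
    reduced measurement noise (scan-rescan / yearly-stability analogue)."""
    base = SyntheticSpec(
        n_subjects=n_subjects,
        cohort="HV",
        latent_baseline_mean=0.5,
        latent_baseline_sd=0.4,
        progression_rate_mean=0.0,
        progression_rate_sd=0.0,
        edss_noise_sd=0.15,
        snrs_noise_sd=1.0,
        walk_log_sd=0.05,
        peg_log_sd=0.04,
        cognitive_noise_sd=2.0,
        learning_gain=0.0,
        healthy_volunteer=True,
    )
    return replace(base, **overrides)


def _failure_hazard(latent: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    span = spec.hazard_ceiling - spec.hazard_onset
    h = spec.hazard_max * (latent - spec.hazard_onset) / span
    return np.clip(h, 0.0, spec.hazard_max)


def _round_to_half(x: np.ndarray) -> np.ndarray:
    return np.round(x * 2.0) / 2.0


def generate_cohort(spec: SyntheticSpec, seed: int = 0) -> pd.DataFrame:
    """Generate a visits table following the long-format CSV contract.

    Byte-identical for identical ``(spec, seed)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, months = spec.n_subjects, np.asarray(spec.visit_months, dtype=float)
    k = len(months)
    a = rng.normal(spec.latent_baseline_mean, spec.latent_baseline_sd, n)
    b = rng.normal(spec.progression_rate_mean, spec.progression_rate_sd, n)
    latent = a[:, None] + b[:, None] * months[None, :]  # (n, k)

    edss = _round_to_half(
        np.clip(latent + rng.normal(0, spec.edss_noise_sd, (n, k)), 0.0, 10.0)
    )
    # EDSS 0.5 is not on the conventional step grid; snap it to 1.0
    edss = np.where(np.isclose(edss, 0.5), 1.0, edss)
    snrs_link = 1.0 / (1.0 + np.exp(-(latent - spec.snrs_center) / spec.snrs_scale))
    snrs = np.clip(
        np.round(100.0 * (1.0 - snrs_link) + rng.normal(0, spec.snrs_noise_sd, (n, k))),
        0, 100,
    )

    def timed_trials(base: float, rate: float, log_sd: float, cap: float, factor: float = 1.0):
        med = factor * base * np.exp(rate * latent)
        t1 = np.clip(med * np.exp(rng.normal(0, log_sd, (n, k))), MIN_TIME, cap)
        t2 = np.clip(med * np.exp(rng.normal(0, log_sd, (n, k))), MIN_TIME, cap)
        return np.round(t1, 1), np.round(t2, 1)

    walk1, walk2 = timed_trials(spec.walk_base, spec.walk_rate, spec.walk_log_sd, WALK_TIME_CAP)
    nd1, nd2 = timed_trials(spec.peg_base, spec.peg_rate, spec.peg_log_sd, PEG_TIME_CAP,
                            spec.peg_nd_factor)
    d1, d2 = timed_trials(spec.peg_base, spec.peg_rate, spec.peg_log_sd, PEG_TIME_CAP)

    hz = _failure_hazard(latent, spec)
    walk_fail = rng.random((n, k)) < hz
    nd_fail = rng.random((n, k)) < hz * spec.peg_hazard_factor
    d_fail = rng.random((n, k)) < hz * spec.peg_hazard_factor

    visit_index = np.arange(k)[None, :]
    learn = spec.learning_gain * visit_index
    cog_level = spec.cognitive_slope * (latent - 5.0)
    pasat = np.clip(np.round(
        spec.pasat_base + cog_level + learn + rng.normal(0, spec.cognitive_noise_sd, (n, k))
    ), 0, 60)
    sdmt = np.clip(np.round(
        spec.sdmt_base + cog_level + learn + rng.normal(0, spec.cognitive_noise_sd, (n, k))
    ), 0, 110)

    width = len(str(n))
    rows = []
    for i in range(n):
        sid = f"{spec.cohort}-{i + 1:0{width}d}"
        for j, month in enumerate(spec.visit_months):
            rows.append({
                "subject_id": sid,
                "cohort": spec.cohort,
                "month": int(month),
                "edss": edss[i, j],
                "snrs": snrs[i, j],
                "t25fw_1": np.nan if walk_fail[i, j] else walk1[i, j],
                "t25fw_2": np.nan if walk_fail[i, j] else walk2[i, j],
                "fail25fw_1": 1 if walk_fail[i, j] else 0,
                "fail25fw_2": 0,
                "t9hpt_nd_1": np.nan if nd_fail[i, j] else nd1[i, j],
                "t9hpt_nd_2": np.nan if nd_fail[i, j] else nd2[i, j],
                "fail9hpt_nd_1": 1 if nd_fail[i, j] else 0,
                "fail9hpt_nd_2": 0,
                "t9hpt_d_1": np.nan if d_fail[i, j] else d1[i, j],
                "t9hpt_d_2": np.nan if d_fail[i, j] else d2[i, j],
                "fail9hpt_d_1": 1 if d_fail[i, j] else 0,
                "fail9hpt_d_2": 0,
                "pasat": pasat[i, j],
                "sdmt": sdmt[i, j],
            })
    return pd.DataFrame(rows, columns=list(VISIT_COLUMNS))


# ---------------------------------------------------------------------------
# Feature-level cohorts with a known optimal weight direction

def generate_weighted_feature_cohort(
    loadings: Sequence[float],
    n_subjects: int = 98,
    visit_months: Sequence[int] = (-12, -6, 0),
    noise_sd: float = 0.02,
    latent_baseline_sd: float = 0.15,
    progression_rate_mean: float = 0.004,
    progression_rate_sd: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Unit-scale regressors sharing one latent trend with known loadings.

    Feature ``f_q = loading_q * L_i(t) + noise`` with equal iid noise, so
    the weight direction maximizing the composite's slope t-statistic is
    proportional to the loadings — the ground truth for optimizer
    recovery checks.  The default noise (0.02 on the unit scale against a
    mean latent drift of 0.048/year) is calibrated so the per-feature
    yearly-change sensitivity z-scores span ~0.15-0.5 with a composite
    around 0.7-0.8, matching the hierarchy observed for real clinical
    scales in progressive-MS cohorts.  Returns columns
    ``subject_id, month, f0..f{d-1}``.
    """
    lam = np.asarray(loadings, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    months = np.asarray(visit_months, dtype=float)
    n, k, d = n_subjects, len(months), lam.size
    a = rng.normal(0.5, latent_baseline_sd, n)
    b = rng.normal(progression_rate_mean, progression_rate_sd, n)
    latent = a[:, None] + b[:, None] * months[None, :]
    F = latent[:, :, None] * lam[None, None, :] + rng.normal(0, noise_sd, (n, k, d))
    rows = []
    width = len(str(n))
    for i in range(n):
        for j, m in enumerate(visit_months):
            rows.append({
                "subject_id": f"W-{i + 1:0{width}d}",
                "month": int(m),
                **{f"f{q}": F[i, j, q] for q in range(d)},
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Screening panels

@dataclass(frozen=True)
class BiomarkerSpec:
    """True yearly behaviour of one synthetic candidate biomarker."""

    name: str
    delta_mean: float = 0.0  # true mean relative yearly change, %
    delta_sd: float = 10.0  # between-subject SD of the change, %
    baseline_mean: float = 100.0
    baseline_sd: float = 10.0
    n_outliers: int = 0  # injected gross outliers in the follow-up value
    outlier_scale: float = 10.0  # outlier deltas inflated by this factor


def generate_screening_panel(
    biomarkers: Sequence[BiomarkerSpec],
    n_subjects: int = 35,
    cohort: str = "SYNTH",
    months: tuple[int, int] = (-12, 0),
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format two-time-point panel for screening validation.

    Each subject's follow-up value is ``baseline * (1 + delta/100)`` with
    per-subject ``delta ~ N(delta_mean, delta_sd)``; optional gross
    outliers multiply the drawn delta by ``outlier_scale`` for the first
    ``n_outliers`` subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m0, m1 = months
    width = len(str(n_subjects))
    rows = []
    for bm in biomarkers:
        base = rng.normal(bm.baseline_mean, bm.baseline_sd, n_subjects)
        base = np.where(np.abs(base) < 1e-6, bm.baseline_mean, base)
        delta = rng.normal(bm.delta_mean, bm.delta_sd, n_subjects)
        if bm.n_outliers:
            delta[: bm.n_outliers] *= bm.outlier_scale
        follow = base * (1.0 + delta / 100.0)
        for i in range(n_subjects):
            sid = f"{cohort}-{i + 1:0{width}d}"
            rows.append({"subject_id": sid, "cohort": cohort, "biomarker": bm.name,
                         "month": m0, "value": base[i]})
            rows.append({"subject_id": sid, "cohort": cohort, "biomarker": bm.name,
                         "month": m1, "value": follow[i]})
    return pd.DataFrame(rows)
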