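"""Validation of raw clinical scores and derivation of the scoring regressors.

A visit carries the raw clinical measurements used throughout the package:
EDSS (0-10 in half steps, higher = worse), SNRS (0-100, higher = better),
two timed 25-foot-walk trials, two 9-hole-peg trials per hand (any trial may
instead end in outright failure), and the cognitive counts PASAT and SDMT.

From a visit we derive the ten regressors that composite scales are built
on: EDSS and SNRS as-is, ``log2`` of the mean of the two completed trials
for each timed test (set to 0 with the paired failure indicator set to 1
whenever at least one trial failed), and PASAT/SDMT passed through.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Administration caps for completed timed tests, in seconds.  A completed
#: walk slower than 180 s (peg trial slower than 300 s) is clamped to the
#: cap, which also fixes the log-term denominators used for unit rescaling.
WALK_TIME_CAP = 180.0
PEG_TIME_CAP = 300.0

#: Times below 1 s are physiologically impossible; clamping keeps every log
#: term non-negative.
MIN_TIME = 1.0

FEATURE_NAMES: tuple[str, ...] = (
    "edss",
    "snrs",
    "log25fw",
    "fail_25fw",
    "log_ndh9hpt",
    "fail_ndh",
    "log_dh9hpt",
    "fail_dh",
    "pasat",
    "sdmt",
)

#: +1 when a larger value means more disability, -1 when larger is better.
WORSENING_SIGN: dict[str, int] = {
    "edss": +1,
    "snrs": -1,
    "log25fw": +1,
    "fail_25fw": +1,
    "log_ndh9hpt": +1,
    "fail_ndh": +1,
    "log_dh9hpt": +1,
    "fail_dh": +1,
    "pasat": -1,
    "sdmt": -1,
}

#: Columns of the long-format visits CSV contract.
VISIT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "cohort",
    "month",
    "edss",
    "snrs",
    "t25fw_1",
    "t25fw_2",
    "fail25fw_1",
    "fail25fw_2",
    "t9hpt_nd_1",
    "t9hpt_nd_2",
    "fail9hpt_nd_1",
    "fail9hpt_nd_2",
    "t9hpt_d_1",
    "t9hpt_d_2",
    "fail9hpt_d_1",
    "fail9hpt_d_2",
    "pasat",
    "sdmt",
)


@dataclass(frozen=True)
class Trial:
    """One attempt at a timed test: a time, an outright failure, or missing."""

    time: Optional[float] = None
    failed: bool = False

    @property
    def missing(self) -> bool:
        return self.time is None and not self.failed

    @property
    def completed(self) -> bool:
        return self.time is not None and not self.failed


@dataclass(frozen=True)
class ScaleSpec:
    """Unit-rescaling spec for one regressor.

    ``max_achievable`` is the denominator that maps the regressor into
    [0, 1]; ``worsening_sign`` is +1 when larger values mean more
    disability and -1 otherwise.
    """

    name: str
    max_achievable: float
    worsening_sign: int

    def __post_init__(self) -> None:
        if not self.max_achievable > 0:
            raise ValueError(f"max_achievable must be > 0 for {self.name!r}")
        if self.worsening_sign not in (-1, +1):
            raise ValueError(f"worsening_sign must be -1 or +1 for {self.name!r}")


def default_scale_specs(sdmt_max: float = 110.0) -> dict[str, ScaleSpec]:
    """Default per-regressor rescaling specs.

    Log terms are divided by ``log2`` of the relevant time cap so that a
    test completed exactly at the cap rescales to 1.  SDMT has no
    universally fixed maximum; 110 is used by default and is configurable.
    """
    return {
        "edss": ScaleSpec("edss", 10.0, +1),
        "snrs": ScaleSpec("snrs", 100.0, -1),
        "log25fw": ScaleSpec("log25fw", math.log2(WALK_TIME_CAP), +1),
        "fail_25fw": ScaleSpec("fail_25fw", 1.0, +1),
        "log_ndh9hpt": ScaleSpec("log_ndh9hpt", math.log2(PEG_TIME_CAP), +1),
        "fail_ndh": ScaleSpec("fail_ndh", 1.0, +1),
        "log_dh9hpt": ScaleSpec("log_dh9hpt", math.log2(PEG_TIME_CAP), +1),
        "fail_dh": ScaleSpec("fail_dh", 1.0, +1),
        "pasat": ScaleSpec("pasat", 60.0, -1),
        "sdmt": ScaleSpec("sdmt", sdmt_max, -1),
    }


@dataclass(frozen=True)
class VisitRecord:
    """Raw clinical scores for one subject-visit; any field may be missing."""

    subject_id: str
    cohort: str = ""
    month: int = 0
    edss: Optional[float] = None
    snrs: Optional[float] = None
    walk_trials: tuple[Trial, Trial] = (Trial(), Trial())
    peg_nd_trials: tuple[Trial, Trial] = (Trial(), Trial())
    peg_d_trials: tuple[Trial, Trial] = (Trial(), Trial())
    pasat: Optional[float] = None
    sdmt: Optional[float] = None


@dataclass(frozen=True)
class Violation:
    """One invariant violation found while validating a visit."""

    field: str
    value: object
    rule: str


class VisitValidationError(ValueError):
    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        msg = "; ".join(f"{v.field}={v.value!r}: {v.rule}" for v in violations)
        super().__init__(f"invalid visit: {msg}")


def _check_trials(name: str, trials: Sequence[Trial], out: list[Violation]) -> None:
    for i, tr in enumerate(trials, start=1):
        if tr.time is not None and tr.failed:
            out.append(Violation(f"{name}_{i}", tr, "trial is both timed and failed"))
        if tr.time is not None and not tr.time > 0:
            out.append(Violation(f"{name}_{i}", tr.time, "non-positive time"))


def check_visit(record: VisitRecord) -> list[Violation]:
    """Return the list of invariant violations for a visit (empty = valid).

    EDSS 0.5 is not part of the conventional Kurtzke step set
    ({0} ∪ {1.0, 1.5, ..., 10.0}) but is accepted with a warning.
    """
    out: list[Violation] = []
    if record.edss is not None:
        e = float(record.edss)
        if not (0.0 <= e <= 10.0):
            out.append(Violation("edss", e, "edss outside [0, 10]"))
        elif abs(e * 2 - round(e * 2)) > 1e-9:
            out.append(Violation("edss", e, "edss not multiple of 0.5"))
        elif abs(e - 0.5) < 1e-9:
            warnings.warn(
                "edss 0.5 is outside the conventional step set; accepting",
                stacklevel=2,
            )
    if record.snrs is not None:
        s = float(record.snrs)
        if not (0.0 <= s <= 100.0):
            out.append(Violation("snrs", s, "snrs outside [0, 100]"))
        elif abs(s - round(s)) > 1e-9:
            out.append(Violation("snrs", s, "snrs not an integer"))
    if record.pasat is not None and not (0 <= record.pasat <= 60):
        out.append(Violation("pasat", record.pasat, "pasat outside [0, 60]"))
    if record.sdmt is not None and record.sdmt < 0:
        out.append(Violation("sdmt", record.sdmt, "sdmt negative"))
    _check_trials("t25fw", record.walk_trials, out)
    _check_trials("t9hpt_nd", record.peg_nd_trials, out)
    _check_trials("t9hpt_d", record.peg_d_trials, out)
    return out


def validate_visit(record: VisitRecord) -> VisitRecord:
    """Return the record unchanged if valid, else raise with all violations."""
    violations = check_visit(record)
    if violations:
        raise VisitValidationError(violations)
    return record


@dataclass(frozen=True)
class FeatureVector:
    """The ten derived regressors for one visit; ``None`` marks missing."""

    edss: Optional[float] = None
    snrs: Optional[float] = None
    log25fw: Optional[float] = None
    fail_25fw: Optional[float] = None
    log_ndh9hpt: Optional[float] = None
    fail_ndh: Optional[float] = None
    log_dh9hpt: Optional[float] = None
    fail_dh: Optional[float] = None
    pasat: Optional[float] = None
    sdmt: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _log_feature(trials: Sequence[Trial], cap: float) -> tuple[Optional[float], Optional[float]]:
    """(log term, failure flag) for one pair of timed trials.

    A failure in either trial dominates: the log term is 0 and the flag 1.
    Both trials must be completed to produce a time-based value; otherwise
    the feature is missing.  Completed times are clamped to [1 s, cap].
    """
    if any(t.failed for t in trials):
        return 0.0, 1.0
    if any(t.missing for t in trials):
        return None, None
    times = [min(max(float(t.time), MIN_TIME), cap) for t in trials]
    return math.log2(sum(times) / len(times)), 0.0


def derive_features(record: VisitRecord) -> FeatureVector:
    """Derive the regressor set from a validated visit (deterministic)."""
    log25, f25 = _log_feature(record.walk_trials, WALK_TIME_CAP)
    lognd, fnd = _log_feature(record.peg_nd_trials, PEG_TIME_CAP)
    logd, fd = _log_feature(record.peg_d_trials, PEG_TIME_CAP)
    return FeatureVector(
        edss=None if record.edss is None else float(record.edss),
        snrs=None if record.snrs is None else float(record.snrs),
        log25fw=log25,
        fail_25fw=f25,
        log_ndh9hpt=lognd,
        fail_ndh=fnd,
        log_dh9hpt=logd,
        fail_dh=fd,
        pasat=None if record.pasat is None else float(record.pasat),
        sdmt=None if record.sdmt is None else float(record.sdmt),
    )


def unit_rescale(
    features: FeatureVector | Mapping[str, Optional[float]],
    specs: Mapping[str, ScaleSpec] | None = None,
) -> dict[str, Optional[float]]:
    """Divide each present feature by its maximum achievable value.

    Maps every admissible input into [0, 1] component-wise; missing
    features stay ``None``.  Raises ``KeyError`` naming any feature
    without a spec.
    """
    if specs is None:
        specs = default_scale_specs()
    vals = features.as_dict() if isinstance(features, FeatureVector) else dict(features)
    out: dict[str, Optional[float]] = {}
    for name, value in vals.items():
        if value is None:
            out[name] = None
            continue
        if name not in specs:
            raise KeyError(f"no ScaleSpec for feature {name!r}")
        out[name] = float(value) / specs[name].max_achievable
    return out


# ---------------------------------------------------------------------------
# DataFrame-level helpers (long-format visits CSV contract)

def _trial_from_row(row: pd.Series, tcol: str, fcol: str) -> Trial:
    failed = bool(row.get(fcol)) and not pd.isna(row.get(fcol)) and float(row.get(fcol)) == 1.0
    t = row.get(tcol)
    time = None if t is None or pd.isna(t) else float(t)
    if failed:
        return Trial(time=None, failed=True)
    return Trial(time=time, failed=False)


def record_from_row(row: pd.Series) -> VisitRecord:
    """Build a :class:`VisitRecord` from one row of the visits CSV contract."""

    def opt(col: str) -> Optional[float]:
        v = row.get(col)
        return None if v is None or pd.isna(v) else float(v)

    return VisitRecord(
        subject_id=str(row["subject_id"]),
        cohort=str(row.get("cohort", "")),
        month=int(row["month"]),
        edss=opt("edss"),
        snrs=opt("snrs"),
        walk_trials=(
            _trial_from_row(row, "t25fw_1", "fail25fw_1"),
            _trial_from_row(row, "t25fw_2", "fail25fw_2"),
        ),
        peg_nd_trials=(
            _trial_from_row(row, "t9hpt_nd_1", "fail9hpt_nd_1"),
            _trial_from_row(row, "t9hpt_nd_2", "fail9hpt_nd_2"),
        ),
        peg_d_trials=(
            _trial_from_row(row, "t9hpt_d_1", "fail9hpt_d_1"),
            _trial_from_row(row, "t9hpt_d_2", "fail9hpt_d_2"),
        ),
        pasat=opt("pasat"),
        sdmt=opt("sdmt"),
    )


def features_frame(visits: pd.DataFrame) -> pd.DataFrame:
    """Derive the per-visit regressor table from a visits table.

    Returns a frame indexed like ``visits`` with columns ``subject_id``,
    ``cohort``, ``month`` and the ten regressors (NaN where missing).
    """
    rows = []
    for _, row in visits.iterrows():
        rec = record_from_row(row)
        fv = derive_features(rec)
        d = {k: (np.nan if v is None else v) for k, v in fv.as_dict().items()}
        rows.append({"subject_id": rec.subject_id, "cohort": rec.cohort, "month": rec.month, **d})
    return pd.DataFrame(rows, index=visits.index)


def rescale_frame(
    features: pd.DataFrame, specs: Mapping[str, ScaleSpec] | None = None
) -> pd.DataFrame:
    """Unit-rescale every regressor column of a feature table."""
    if specs is None:
        specs = default_scale_specs()
    out = features.copy()
    for name in FEATURE_NAMES:
        if name in out.columns:
            out[name] = out[name] / specs[name].max_achievable
    return out
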