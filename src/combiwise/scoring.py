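"""Composite disability scales: the published CombiWISE formula and
construction of 0-100 composites from arbitrary weight vectors.

CombiWISE is a linear combination of EDSS, SNRS, log2 walk time, log2
non-dominant-hand peg time and the two paired failure indicators::

    CombiWISE = 33.166 + 3.803*EDSS - 0.407*SNRS + 2.409*log25FW
                + 18.056*FAIL_25FW + 1.305*logNDH9HPT + 10.751*FAIL_NDH

Higher values mean more disability; the published scale is anchored so
that the most disabled admissible configuration scores (essentially) 100.
The raw formula value is returned unclamped so that the score stays a
linear function of its inputs for regression and mixed-model use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scales import FeatureVector, ScaleSpec, default_scale_specs

#: Published computing weights (signed coefficients on raw regressors).
PUBLISHED_INTERCEPT = 33.166
PUBLISHED_COMPUTING_WEIGHTS: dict[str, float] = {
    "edss": 3.803,
    "snrs": -0.407,
    "log25fw": 2.409,
    "fail_25fw": 18.056,
    "log_ndh9hpt": 1.305,
    "fail_ndh": 10.751,
}


@dataclass(frozen=True)
class WeightVector:
    """A composite scale: signed computing weights on raw regressors plus an
    intercept, and the matching non-negative relative weights on
    unit-rescaled regressors (normalized to sum 1) for cross-scale
    comparison of contributions."""

    feature_names: tuple[str, ...]
    computing_weights: tuple[float, ...]
    intercept: float
    relative_weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.computing_weights):
            raise ValueError("feature_names and computing_weights length mismatch")
        if self.relative_weights is not None and len(self.relative_weights) != len(
            self.feature_names
        ):
            raise ValueError("relative_weights length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.computing_weights))


def published_weight_vector(
    specs: Mapping[str, ScaleSpec] | None = None,
) -> WeightVector:
    """The published CombiWISE weights as a :class:`WeightVector`.

    Relative weights are recovered as |computing weight| x maximum
    achievable value (the magnitude each unit-rescaled regressor carries),
    normalized to sum 1.
    """
    if specs is None:
        specs = default_scale_specs()
    names = tuple(PUBLISHED_COMPUTING_WEIGHTS)
    comp = tuple(PUBLISHED_COMPUTING_WEIGHTS[n] for n in names)
    mags = np.array([abs(c) * specs[n].max_achievable for n, c in zip(names, comp)])
    rel = tuple(mags / mags.sum())
    return WeightVector(names, comp, PUBLISHED_INTERCEPT, rel)


def _require(features: FeatureVector | Mapping[str, Optional[float]], names: Sequence[str]) -> dict:
    vals = features.as_dict() if isinstance(features, FeatureVector) else dict(features)
    missing = [n for n in names if vals.get(n) is None or (
        isinstance(vals.get(n), float) and np.isnan(vals[n]))]
    if missing:
        raise ValueError(f"missing contributing features: {missing}")
    return vals


def combiwise_published(features: FeatureVector | Mapping[str, Optional[float]]) -> float:
    """Evaluate the published CombiWISE formula.

    Requires EDSS, SNRS and the walk / non-dominant-peg regressors to be
    present; no imputation is performed.
    """
    vals = _require(features, list(PUBLISHED_COMPUTING_WEIGHTS))
    return PUBLISHED_INTERCEPT + sum(
        w * float(vals[n]) for n, w in PUBLISHED_COMPUTING_WEIGHTS.items()
    )


def composite_score(
    features: FeatureVector | Mapping[str, Optional[float]], weights: WeightVector
) -> float:
    """Evaluate ``intercept + sum(weight_k * feature_k)`` for any composite."""
    vals = _require(features, weights.feature_names)
    return weights.intercept + sum(
        w * float(vals[n]) for n, w in zip(weights.feature_names, weights.computing_weights)
    )


def composite_scores_frame(features: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Vectorized composite score over a feature table (NaN propagates)."""
    score = pd.Series(weights.intercept, index=features.index, dtype=float)
    for name, w in zip(weights.feature_names, weights.computing_weights):
        score = score + w * features[name].astype(float)
    return score


def rescale_to_0_100(
    relative_weights: Mapping[str, float],
    specs: Mapping[str, ScaleSpec] | None = None,
    unit_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> WeightVector:
    """Turn non-negative relative weights into a 0-100 composite scale.

    Each regressor's admissible unit-rescaled range (default [0, 1], from
    the scale caps) together with its worsening direction defines a
    theoretical best and worst configuration; the computing weights and
    intercept are the unique positive affine map sending best -> 0 and
    worst -> 100, so score ordering is preserved and the scale is
    cohort-independent.
    """
    if specs is None:
        specs = default_scale_specs()
    names = tuple(relative_weights)
    w = np.array([float(relative_weights[n]) for n in names])
    if np.any(w < 0):
        raise ValueError("relative weights must be non-negative magnitudes")
    signs = np.array([specs[n].worsening_sign for n in names], dtype=float)
    lo = np.array([(unit_ranges or {}).get(n, (0.0, 1.0))[0] for n in names])
    hi = np.array([(unit_ranges or {}).get(n, (0.0, 1.0))[1] for n in names])
    # score on the unit scale: s(x) = sum sign_k * w_k * x_k
    worst = np.where(signs > 0, hi, lo)
    best = np.where(signs > 0, lo, hi)
    s_worst = float(np.sum(signs * w * worst))
    s_best = float(np.sum(signs * w * best))
    span = s_worst - s_best
    if span <= 0:
        raise ValueError("degenerate composite: zero admissible range")
    a = 100.0 / span
    comp = tuple(a * signs[i] * w[i] / specs[n].max_achievable for i, n in enumerate(names))
    intercept = -a * s_best
    rel = tuple(w / w.sum()) if w.sum() > 0 else None
    return WeightVector(names, comp, intercept, rel)


def regress_on_edss(edss: Sequence[float], scores: Sequence[float]) -> tuple[float, float]:
    """OLS slope (and its SE) of a composite score on EDSS.

    Calibrates composite points per EDSS step; requires at least three
    distinct EDSS values.
    """
    x = np.asarray(edss, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("edss and scores must be 1-D and equal length")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct EDSS values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)
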