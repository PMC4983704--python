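"""Random-intercept linear-change model and its slope t-statistic.

The model is ``y_ij = beta0 + beta1 * t_ij + b_i + eps_ij`` with
``b_i ~ N(0, sigma2_b)`` and ``eps_ij ~ N(0, sigma2_e)``: a common linear
time trend with a subject-specific level.  The t-statistic of the time
slope (``beta1 / SE``) is the longitudinal sensitivity metric used both to
compare outcome measures and as the genetic-algorithm fitness when
optimizing composite weights.

Estimation profiles the likelihood down to the single variance ratio
``lambda = sigma2_b / sigma2_e``: for fixed lambda the GLS solution and the
residual variance are available in closed form (the per-subject covariance
``I + lambda * J`` inverts analytically), so (RE)ML reduces to a robust 1-D
optimization.  The denominator degrees of freedom follow the nlme
convention for a within-subject covariate: ``N_obs - N_subjects - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

#: Guard value returned for t when the fit is exactly noiseless.
DEGENERATE_T = 1e12

_LOG_LAMBDA_BOUNDS = (-30.0, 30.0)


@dataclass(frozen=True)
class LMMFit:
    """Fitted random-intercept model summary."""

    beta0: float
    beta1: float
    se_beta1: float
    t_stat: float
    df: int
    sigma2_b: float
    sigma2_e: float
    method: str
    converged: bool
    degenerate: bool = False

    @property
    def variance_ratio(self) -> float:
        return self.sigma2_b / self.sigma2_e if self.sigma2_e > 0 else np.inf


class _Sufficient:
    """Per-subject sufficient statistics for the profiled objective."""

    def __init__(self, subjects: np.ndarray, times: np.ndarray, values: np.ndarray):
        order = np.argsort(subjects, kind="stable")
        s, t, y = subjects[order], times[order], values[order]
        _, start = np.unique(s, return_index=True)
        self.n_subjects = len(start)
        self.n_obs = len(y)
        bounds = np.append(start, len(y))
        X = np.column_stack([np.ones_like(t), t])
        self.group_n = np.diff(bounds).astype(float)
        # per-group sums of x, x x', x y, y, y^2
        self.Sx = np.add.reduceat(X, bounds[:-1], axis=0)  # (m, 2)
        self.Sxx = np.array(
            [X[a:b].T @ X[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        )  # (m, 2, 2)
        self.Sxy = np.add.reduceat(X * y[:, None], bounds[:-1], axis=0)  # (m, 2)
        self.Sy = np.add.reduceat(y, bounds[:-1])  # (m,)
        self.Syy = np.add.reduceat(y * y, bounds[:-1])  # (m,)

    def gls(self, lam: float) -> tuple[np.ndarray, np.ndarray, float, float]:
        """GLS pieces at variance ratio ``lam``.

        Returns (beta, A = X'V^-1 X, rss = weighted residual SS, logdetV).
        """
        c = lam / (1.0 + self.group_n * lam)  # (m,)
        A = self.Sxx.sum(axis=0) - np.einsum("m,mi,mj->ij", c, self.Sx, self.Sx)
        b = self.Sxy.sum(axis=0) - (c * self.Sy) @ self.Sx
        yVy = self.Syy.sum() - np.sum(c * self.Sy**2)
        beta = np.linalg.solve(A, b)
        rss = max(yVy - b @ beta, 0.0)
        logdet = float(np.sum(np.log1p(self.group_n * lam)))
        return beta, A, rss, logdet


def _neg2ll(suff: _Sufficient, lam: float, method: str) -> float:
    _, A, rss, logdet = suff.gls(lam)
    n, p = suff.n_obs, 2
    if rss <= 0:
        return -1e300  # perfect fit; handled by caller
    if method == "ML":
        return n * np.log(rss / n) + logdet
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(rss / (n - p)) + logdet + logdetA


def fit_random_intercept(
    subjects: Sequence,
    times: Sequence[float],
    values: Sequence[float],
    method: str = "REML",
) -> LMMFit:
    """Fit the random-intercept linear-change model.

    Parameters
    ----------
    subjects, times, values
        Parallel 1-D sequences: subject label, visit time in months, and
        the score at that visit.
    method
        ``"REML"`` (default) or ``"ML"``.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    subj = np.asarray(subjects)
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if not (len(subj) == len(t) == len(y)):
        raise ValueError("subjects, times, values must have equal length")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite times or values")
    suff = _Sufficient(subj, t, y)
    if suff.n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct times (singular design)")

    n, p, m = suff.n_obs, 2, suff.n_subjects
    df = n - m - 1

    res = optimize.minimize_scalar(
        lambda u: _neg2ll(suff, np.exp(u), method),
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [0.0, float(np.exp(res.x))]
    objs = [_neg2ll(suff, lam, method) for lam in candidates]
    lam = candidates[int(np.argmin(objs))]
    converged = bool(res.success)

    beta, A, rss, _ = suff.gls(lam)
    denom = n if method == "ML" else n - p
    sigma2_e = rss / denom
    sigma2_b = lam * sigma2_e
    Ainv = np.linalg.inv(A)
    scale_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    if sigma2_e <= 1e-12 * scale_y:
        warnings.warn("zero residual variance: degenerate fit, t clipped", stacklevel=2)
        t_stat = DEGENERATE_T * np.sign(beta[1]) if abs(beta[1]) > 1e-12 else 0.0
        # residuals are exact subject constants: estimate the intercept
        # variance from subject-mean residuals directly
        resid_means = (suff.Sy - suff.Sx @ beta) / suff.group_n
        ddof = 0 if method == "ML" else 1
        sigma2_b = float(np.var(resid_means, ddof=ddof)) if m > ddof else 0.0
        return LMMFit(
            beta0=float(beta[0]),
            beta1=float(beta[1]),
            se_beta1=0.0,
            t_stat=float(t_stat),
            df=df,
            sigma2_b=float(sigma2_b),
            sigma2_e=float(sigma2_e),
            method=method,
            converged=converged,
            degenerate=True,
        )
    se = float(np.sqrt(sigma2_e * Ainv[1, 1]))
    return LMMFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta1=se,
        t_stat=float(beta[1] / se),
        df=df,
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        method=method,
        converged=converged,
    )


def slope_t_statistic(subjects, times, values) -> float:
    """REML slope t-statistic — the longitudinal sensitivity of a score."""
    return fit_random_intercept(subjects, times, values, method="REML").t_stat


# ---------------------------------------------------------------------------
# Balanced-design fast path (vectorized over many candidate composites)

def balanced_slope_t(values: np.ndarray, times: Sequence[float]) -> np.ndarray:
    """REML slope t for balanced data, vectorized over trailing axes.

    ``values`` has shape ``(m, k, ...)``: m subjects, the same k visit
    times for everyone, and optionally extra axes of candidate scores
    (e.g. a GA population).  For balanced designs the GLS slope is the
    within-subject contrast estimate for every variance ratio, and the
    REML variance components reduce to the classical within/between mean
    squares, so no iteration is needed.  Agrees with
    :func:`fit_random_intercept` (asserted in the test suite).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    m, k = y.shape[0], y.shape[1]
    if k != len(t):
        raise ValueError("values.shape[1] must equal len(times)")
    if m < 2 or np.unique(t).size < 2:
        raise ValueError("need >= 2 subjects and >= 2 distinct times")
    tc = t - t.mean()
    stt = float(np.sum(tc**2))
    n = m * k
    df_resid = n - m - 1
    tc_b = tc.reshape((1, k) + (1,) * (y.ndim - 2))

    beta1 = np.sum(y * tc_b, axis=(0, 1)) / (m * stt)
    subj_mean = y.mean(axis=1, keepdims=True)
    resid_w = y - subj_mean - beta1 * tc_b
    sse_w = np.sum(resid_w**2, axis=(0, 1))
    grand = y.mean(axis=(0, 1))
    ssb = k * np.sum((subj_mean[:, 0] - grand) ** 2, axis=0)
    msw = sse_w / df_resid
    msb = ssb / (m - 1)
    # interior REML: sigma2_b = (MSB - MSW)/k > 0; else boundary (pooled OLS)
    interior = msb > msw
    sigma2_e = np.where(interior, msw, (sse_w + ssb) / (n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2_e / (m * stt))
        t_stat = np.where(se > 0, beta1 / se, np.sign(beta1) * DEGENERATE_T)
    return t_stat
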