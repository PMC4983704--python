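"""Sample-size estimation for 2-year trial designs from 1-year change
statistics.

Both designs assume linear change over time: the untreated 2-year mean
relative change is twice the observed 1-year mean, the SD is held at the
1-year value, and a drug with effect ``e`` shrinks the treated mean by a
factor ``1 - e``.  The effect size is therefore
``d = 2 * mean_1yr * e / sd_1yr``.  Power is computed exactly from the
noncentral t distribution (matching classical trial-design software
output) rather than a normal approximation:

* parallel: two-sample two-tailed t-test, per-arm n, df = 2n - 2,
  noncentrality ``d * sqrt(n/2)``;
* one_group (baseline-versus-treatment): one-sample two-tailed t-test,
  df = n - 1, noncentrality ``d * sqrt(n)``.

By default the standardized effect size is rounded to two decimals before
the iteration — the precision at which effect sizes are conventionally
entered into trial-design software — which is required to reproduce
published per-arm figures computed that way; set
``effect_size_decimals=None`` for the unrounded effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DESIGNS = ("parallel", "one_group")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a sample-size calculation.

    ``mean_1yr`` and ``sd_1yr`` are the observed untreated mean and SD of
    relative percentage change over one year; ``drug_effect`` is the
    assumed fractional reduction of progression (e.g. 0.5, 0.4, 0.3).
    """

    mean_1yr: float
    sd_1yr: float
    drug_effect: float
    alpha: float = 0.05
    power: float = 0.80
    design: str = "parallel"
    effect_size_decimals: int | None = 2

    def __post_init__(self) -> None:
        if not self.sd_1yr > 0:
            raise ValueError("sd_1yr must be > 0")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must be in (0, 1)")
        if not 0.0 < self.drug_effect < 1.0:
            raise ValueError("drug_effect must be in (0, 1)")
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")

    @property
    def effect_size_d(self) -> float:
        """Standardized detectable difference, 2 * mean * effect / sd,
        rounded to ``effect_size_decimals`` when that is set."""
        d = 2.0 * self.mean_1yr * self.drug_effect / self.sd_1yr
        if self.effect_size_decimals is not None:
            d = round(d, self.effect_size_decimals)
        return d


@dataclass(frozen=True)
class PowerResult:
    """Smallest n meeting the power target, with the achieved power."""

    n_per_arm: int
    achieved_power: float
    effect_size_d: float


def power_at_n(spec: PowerSpec, n: int) -> float:
    """Exact two-tailed noncentral-t power of the design at sample size n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    d = abs(spec.effect_size_d)
    if spec.design == "parallel":
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
    else:
        df = n - 1
        nc = d * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(
        stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def required_n(spec: PowerSpec, n_max: int = 1_000_000) -> PowerResult:
    """Smallest integer sample size (per arm) reaching the target power.

    Iterates the exact noncentral-t power function upward from the normal
    approximation; errors when the effect size is zero (infinite n).
    """
    d = abs(spec.effect_size_d)
    if d == 0:
        raise ValueError("zero effect size: required n is infinite")
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    mult = 2.0 if spec.design == "parallel" else 1.0
    n_guess = max(2, int(np.floor(mult * (za + zb) ** 2 / d**2)) - 2)
    n = n_guess
    while n >= 3 and power_at_n(spec, n - 1) >= spec.power:
        n -= 1
    while power_at_n(spec, n) < spec.power:
        n += 1
        if n > n_max:
            raise RuntimeError("required n exceeds n_max")
    return PowerResult(
        n_per_arm=n,
        achieved_power=power_at_n(spec, n),
        effect_size_d=spec.effect_size_d,
    )


def sample_size_table(
    mean_1yr: float,
    sd_1yr: float,
    effects: tuple[float, ...] = (0.5, 0.4, 0.3),
    design: str = "parallel",
    alpha: float = 0.05,
    power: float = 0.80,
) -> dict[float, int]:
    """Per-effect required n for one design; convenience for reports."""
    return {
        e: required_n(
            PowerSpec(mean_1yr, sd_1yr, e, alpha=alpha, power=power, design=design)
        ).n_per_arm
        for e in effects
    }
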