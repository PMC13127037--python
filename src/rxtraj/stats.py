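"""Descriptive-statistics kernel shared by every table-producing module.

Proportions are summarised with Wald 95% confidence intervals and means
with normal-theory intervals (mean ± z·sd/√n); both use z = 1.959964 and
display rounding of exactly one decimal with ties rounded half-up
(57.95 → 58.0).  Unrounded values are retained on the result objects so
downstream computation never accumulates rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

Z_95 = 1.959964


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at `ndigits` decimals.

    Built-in round() uses banker's rounding; printed clinical tables
    round half-up, so 57.95 must become 58.0, not 57.9.
    """
    if math.isnan(x):
        return x
    factor = 10.0 ** ndigits
    # nudge by a relative epsilon so binary representation of .5 ties
    # (e.g. 57.95 stored as 57.94999...) still rounds up
    eps = abs(x) * 1e-12
    return math.floor(abs(x) * factor + 0.5 + eps) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ProportionCI:
    """A proportion k/n with its Wald 95% CI, on the percentage scale."""

    k: int
    n: int
    pct: float  # unrounded, 0..100
    lo: float
    hi: float

    @property
    def display(self) -> tuple[float, float, float]:
        """(pct, lo, hi) rounded half-up to 1 decimal, as printed."""
        return (round_half_up(self.pct), round_half_up(self.lo), round_half_up(self.hi))


@dataclass(frozen=True)
class MeanCI:
    """A mean with SD and normal-theory 95% CI."""

    mean: float
    sd: float
    n: int
    lo: float
    hi: float

    @property
    def display(self) -> tuple[float, float, float]:
        return (round_half_up(self.mean), round_half_up(self.lo), round_half_up(self.hi))


def percentage(k: int, n: int) -> float:
    """100·k/n rounded half-up to 1 decimal, as printed in cohort tables."""
    if n <= 0:
        raise ValueError("percentage undefined for n <= 0")
    return round_half_up(100.0 * k / n)


def wald_proportion_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wald (normal-approximation) CI for a binomial proportion.

    Bounds are pct ± z·100·sqrt(p(1−p)/n), clipped to [0, 100].
    """
    if n < 1:
        raise ValueError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if level != 0.95:
        raise NotImplementedError("only the 95% level is supported")
    p = k / n
    pct = 100.0 * p
    half = Z_95 * 100.0 * math.sqrt(p * (1.0 - p) / n)
    lo = max(0.0, pct - half)
    hi = min(100.0, pct + half)
    return ProportionCI(k=k, n=n, pct=pct, lo=lo, hi=hi)


def normal_mean_ci(mean: float, sd: float, n: int, level: float = 0.95) -> MeanCI:
    """Normal-theory CI for a mean: mean ± z·sd/√n."""
    if n < 1:
        raise ValueError("need n >= 1")
    if sd < 0:
        raise ValueError("need sd >= 0")
    if level != 0.95:
        raise NotImplementedError("only the 95% level is supported")
    half = Z_95 * sd / math.sqrt(n)
    return MeanCI(mean=mean, sd=sd, n=n, lo=mean - half, hi=mean + half)
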