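"""Fixed-N frequentist sample-size machinery.

The efficiency benchmark for the adaptive design: per-arm sample sizes for
the classical two-sample pooled-variance t test, computed by exact
noncentral-t iteration (not the normal approximation), and the cumulative
participant cost of a programme of such fixed-N trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import LeapfrogValidationError

__all__ = ["PowerSpec", "power_two_arm", "sample_size_two_arm", "cumulative_cost"]


@dataclass(frozen=True)
class PowerSpec:
    """Target effect size (Cohen's d), power, and two-sided alpha."""

    d: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.power < 1):
            raise LeapfrogValidationError(f"power must be in (0,1), got {self.power}")
        if not (0 < self.alpha < 1):
            raise LeapfrogValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.d == 0 or not math.isfinite(self.d):
            raise LeapfrogValidationError("effect size d must be nonzero and finite")


def power_two_arm(n_per_arm: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample pooled t test at ``n`` per arm.

    Under effect d the t statistic is noncentral t with df = 2n - 2 and
    noncentrality d * sqrt(n/2); power is the probability of exceeding the
    two-sided critical value in either tail.
    """
    if n_per_arm < 2:
        raise LeapfrogValidationError("n_per_arm must be >= 2")
    df = 2 * n_per_arm - 2
    ncp = d * math.sqrt(n_per_arm / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_two_arm(spec: PowerSpec) -> int:
    """Smallest per-arm n giving the target power (noncentral-t iteration).

    Exact minimality: power(n) >= target and power(n - 1) < target.
    """
    target = spec.power
    lo, hi = 2, 4
    while power_two_arm(hi, spec.d, spec.alpha) < target:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise LeapfrogValidationError(
                "required sample size exceeds 10^7 per arm; check the spec"
            )
    # power is monotone in n: bisect to the smallest adequate n
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_arm(mid, spec.d, spec.alpha) >= target:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def cumulative_cost(arms_per_trial: Sequence[int], per_arm_n: int) -> int:
    """Total participants across a programme of fixed-N trials.

    ``arms_per_trial`` lists the number of arms in each successive trial;
    every arm recruits ``per_arm_n`` participants.
    """
    if per_arm_n < 1 or any(a < 1 for a in arms_per_trial):
        raise LeapfrogValidationError("arm counts and per-arm n must be positive")
    return int(sum(a * per_arm_n for a in arms_per_trial))
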