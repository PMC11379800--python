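"""Pairwise sequential Bayes-factor design analysis.

Simulates accrual of one challenger arm against one comparator arm under a
:class:`TrialDesign`, applies the absorbing Bayes-factor boundaries, and
estimates operating characteristics (cumulative boundary-crossing
probabilities, i.e. power and false-positive rate as functions of accrued
sample size) over a grid of true standardized effects.  A grid search over
candidate designs (:func:`search_parameters`) supports the simulation-first
planning workflow: pick boundaries and sample-size limits so that the design
has the desired power at the target effect and an acceptable false-positive
rate at zero effect.

Outcomes are standardized continuous measures: comparator ~ Normal(mu, sd),
challenger ~ Normal(mu + d*sd, sd), so ``d`` is Cohen's d.

Monte-Carlo replications use one named RNG stream per replication, seeded
from ``(seed, replication_index)``, so every cell is reproducible and the
per-trace and vectorized code paths see identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bayesfactor import PriorSpec, TStat, critical_t, jzs_bf
from .errors import LeapfrogValidationError

__all__ = [
    "TrialDesign",
    "OutcomeModel",
    "PairwiseTrace",
    "OCTable",
    "CandidateResult",
    "simulate_pairwise_trace",
    "estimate_oc",
    "first_look_probabilities",
    "search_parameters",
]

#: Replication chunk size for the vectorized simulator; bounds peak memory
#: at roughly chunk * n_max * 4 doubles.
_CHUNK = 2000


@dataclass(frozen=True)
class TrialDesign:
    """Analysis-parameter bundle for a leapfrog (or pairwise sequential) trial.

    Parameters
    ----------
    n_min, n_max : int
        Per-arm sample size at which sequential analyses start / at which an
        undecided arm is dropped.
    bf_fail, bf_success : float
        Lower and upper absorbing Bayes-factor boundaries (drop / promote).
    prior : PriorSpec
        Cauchy prior scale and direction of the superiority hypothesis.
    step : int
        Analysis cadence: participants per arm between successive looks.
        The first look is at ``n_min``; a final look always happens at
        ``n_max`` even if the cadence does not land on it exactly.
    allocation_ratio : (int, int)
        Challenger:comparator accrual pattern.  The operating-characteristic
        machinery assumes the 1:1 interleaved accrual of the reference
        design; other integer ratios are honoured by the per-trace simulator.
    """

    n_min: int = 150
    n_max: int = 450
    bf_fail: float = 1 / 5
    bf_success: float = 3.0
    prior: PriorSpec = field(default_factory=PriorSpec)
    step: int = 1
    allocation_ratio: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if not (0 < self.bf_fail < 1 < self.bf_success):
            raise LeapfrogValidationError(
                f"boundaries must satisfy 0 < bf_fail < 1 < bf_success "
                f"(got bf_fail={self.bf_fail}, bf_success={self.bf_success})"
            )
        if not (2 <= self.n_min <= self.n_max):
            raise LeapfrogValidationError(
                f"need 2 <= n_min <= n_max (got n_min={self.n_min}, n_max={self.n_max})"
            )
        if self.step < 1:
            raise LeapfrogValidationError(f"step must be >= 1, got {self.step}")
        a, b = self.allocation_ratio
        if not (isinstance(a, int) and isinstance(b, int) and a >= 1 and b >= 1):
            raise LeapfrogValidationError(
                f"allocation_ratio must be a pair of positive integers, "
                f"got {self.allocation_ratio!r}"
            )
        if self.prior.direction == "two_sided":
            raise LeapfrogValidationError(
                "sequential boundaries require a directional prior "
                "(the two-sided BF is not monotone in t)"
            )

    def look_schedule(self) -> np.ndarray:
        """Per-arm n values at which the BF is evaluated."""
        ns = np.arange(self.n_min, self.n_max + 1, self.step)
        if ns[-1] != self.n_max:
            ns = np.append(ns, self.n_max)
        return ns


@dataclass(frozen=True)
class OutcomeModel:
    """True outcome-generating model for one challenger/comparator pair."""

    effect: float = 0.0  # Cohen's d of challenger vs comparator
    sd: float = 1.0
    comparator_mean: float = 0.0

    def __post_init__(self):
        if not (self.sd > 0):
            raise LeapfrogValidationError(f"sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class PairwiseTrace:
    """One simulated sequential comparison: BF path and stopping event."""

    looks: tuple[tuple[int, float], ...]  # (n per arm at look, BF)
    stop_reason: str  # 'fail' | 'success' | 'nmax'
    stop_n: int  # per-arm challenger n at stopping


@dataclass(frozen=True)
class OCTable:
    """Cumulative boundary-crossing probabilities by true effect and n.

    ``p_fail[i, j]`` / ``p_success[i, j]`` are the percentages of
    replications at ``effect_grid[i]`` absorbed at the corresponding
    boundary by a per-arm sample size of ``checkpoints[j]``.  ``mc_se_*``
    hold the binomial Monte-Carlo standard error of each cell (percent).
    ``expected_stop_n[i]`` is the mean per-arm sample size at stopping
    (arms stopped by the cap count ``n_max``).
    """

    effect_grid: tuple[float, ...]
    checkpoints: tuple[int, ...]
    p_fail: np.ndarray
    p_success: np.ndarray
    mc_se_fail: np.ndarray
    mc_se_success: np.ndarray
    expected_stop_n: np.ndarray
    n_reps: int
    design: TrialDesign
    seed: int

    def __post_init__(self):
        for name in ("p_fail", "p_success", "mc_se_fail", "mc_se_success",
                     "expected_stop_n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    def to_long_frame(self):
        """Tidy long format: one row per (effect, checkpoint, boundary)."""
        import pandas as pd

        rows = []
        for i, d in enumerate(self.effect_grid):
            for j, cp in enumerate(self.checkpoints):
                rows.append((d, cp, "fail", self.p_fail[i, j], self.mc_se_fail[i, j]))
                rows.append((d, cp, "success", self.p_success[i, j],
                             self.mc_se_success[i, j]))
        return pd.DataFrame(rows, columns=["effect", "checkpoint_n", "boundary",
                                           "probability_pct", "mc_se_pct"])

    def to_wide_frame(self):
        """Wide report layout: one row per effect, one column block per
        boundary x checkpoint."""
        import pandas as pd

        data = {"effect": list(self.effect_grid)}
        for j, cp in enumerate(self.checkpoints):
            data[f"fail_{cp}"] = self.p_fail[:, j]
        for j, cp in enumerate(self.checkpoints):
            data[f"success_{cp}"] = self.p_success[:, j]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Replication streams

def _replication_rng(seed: int, rep: int) -> np.random.Generator:
    """The named RNG stream for one replication."""
    return np.random.default_rng((int(seed), int(rep)))


def _draw_pair(design: TrialDesign, model: OutcomeModel, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replication's outcome sequences in accrual order.

    Accrual interleaves challenger and comparator following
    ``allocation_ratio`` (challenger first), drawing from a single stream in
    allocation order so the accrual pattern is part of the reproducible
    state.  Returns (challenger, comparator) outcome arrays; the challenger
    array has ``n_max`` entries.
    """
    a, b = design.allocation_ratio
    n_ch = design.n_max
    n_co = int(math.ceil(n_ch / a) * b)
    z = rng.standard_normal(n_ch + n_co)
    block = a + b
    order = np.tile(np.r_[np.zeros(a, bool), np.ones(b, bool)],
                    (n_ch + n_co) // block + 1)[: n_ch + n_co]
    ch = z[~order][:n_ch] * model.sd + model.comparator_mean + model.effect * model.sd
    co = z[order][:n_co] * model.sd + model.comparator_mean
    return ch, co


def _comparator_n(design: TrialDesign, n_challenger: int) -> int:
    """Comparator count accrued by the time the challenger has n."""
    a, b = design.allocation_ratio
    return int(math.ceil(n_challenger / a) * b)


# ---------------------------------------------------------------------------
# Per-trace simulation (records actual Bayes factors)

def simulate_pairwise_trace(design: TrialDesign, model: OutcomeModel,
                            seed: int, rep: int = 0) -> PairwiseTrace:
    """Simulate one challenger-vs-comparator sequential comparison.

    Outcomes accrue in allocation-ratio order; the JZS BF is evaluated by
    quadrature at every look; boundaries are absorbing.  ``rep`` selects the
    replication stream ``(seed, rep)``, matching the vectorized
    :func:`estimate_oc` path replication-for-replication.
    """
    ch, co = _draw_pair(design, model, _replication_rng(seed, rep))
    looks = []
    for n in design.look_schedule():
        n = int(n)
        m = _comparator_n(design, n)
        ts = TStat(t=_pooled_t(ch[:n], co[:m]), n1=n, n2=m)
        bf = jzs_bf(ts, design.prior).bf
        looks.append((n, bf))
        if bf <= design.bf_fail:
            return PairwiseTrace(tuple(looks), "fail", n)
        if bf >= design.bf_success:
            return PairwiseTrace(tuple(looks), "success", n)
    return PairwiseTrace(tuple(looks), "nmax", int(design.n_max))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = a.size, b.size
    pv = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (n1 + n2 - 2)
    return float((a.mean() - b.mean()) / math.sqrt(pv * (1 / n1 + 1 / n2)))


# ---------------------------------------------------------------------------
# Vectorized operating characteristics

_BOUNDS_CACHE: dict[tuple, tuple] = {}


def _critical_bounds(design: TrialDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map the BF boundaries to per-look critical t values.

    Valid because the directional BF is strictly monotone in t.  Roots are
    tracked along n with a warm-started bracket.  Unreachable boundaries
    map to -inf / +inf.  Tables are cached per design (they are the costly
    part of the vectorized simulator).
    """
    from scipy import optimize

    key = (design.n_min, design.n_max, design.step, design.allocation_ratio,
           design.bf_fail, design.bf_success, design.prior)
    if key in _BOUNDS_CACHE:
        return _BOUNDS_CACHE[key]

    ns = design.look_schedule()
    greater = design.prior.direction == "greater"
    out = []
    for threshold, unreachable in ((design.bf_fail,
                                    -np.inf if greater else np.inf),
                                   (design.bf_success,
                                    np.inf if greater else -np.inf)):
        log_th = math.log(threshold)
        sign = 1.0 if design.prior.direction == "greater" else -1.0
        vals = np.empty(ns.size)
        prev = None
        for i, n in enumerate(ns):
            n = int(n)
            m = _comparator_n(design, n)

            def f(t):
                bf = jzs_bf(TStat(t=sign * t, n1=n, n2=m), design.prior).bf
                return math.log(bf) - log_th

            if prev is None:
                root = critical_t(n, m, design.prior, threshold)
                if root is None:
                    vals[i] = unreachable
                    continue
                prev = sign * root
            else:
                lo, hi = prev - 0.05, prev + 0.05
                tries = 0
                while f(lo) * f(hi) > 0 and tries < 12:
                    lo -= 0.1
                    hi += 0.1
                    tries += 1
                if tries == 12:
                    root = critical_t(n, m, design.prior, threshold)
                    prev = sign * root if root is not None else None
                    vals[i] = sign * prev if prev is not None else unreachable
                    continue
                prev = optimize.brentq(f, lo, hi, xtol=1e-7)
            vals[i] = sign * prev
        out.append(vals)
    t_fail, t_success = out
    _BOUNDS_CACHE[key] = (ns, t_fail, t_success)
    return ns, t_fail, t_success


def _simulate_stops(design: TrialDesign, effect: float, n_reps: int, seed: int,
                    sd: float = 1.0, comparator_mean: float = 0.0):
    """Stop n and stop reason (0=nmax, 1=fail, 2=success) for each replication."""
    if design.allocation_ratio != (1, 1):
        # General accrual ratios take the per-trace route.
        stop_n = np.empty(n_reps, int)
        stop_r = np.empty(n_reps, int)
        model = OutcomeModel(effect=effect, sd=sd, comparator_mean=comparator_mean)
        code = {"nmax": 0, "fail": 1, "success": 2}
        for rep in range(n_reps):
            tr = simulate_pairwise_trace(design, model, seed, rep)
            stop_n[rep] = tr.stop_n
            stop_r[rep] = code[tr.stop_reason]
        return stop_n, stop_r

    ns, t_lo, t_hi = _critical_bounds(design)
    look_idx = ns - 1
    n_max = design.n_max
    stop_n = np.empty(n_reps, int)
    stop_r = np.empty(n_reps, int)
    count = np.arange(1, n_max + 1, dtype=float)
    for start in range(0, n_reps, _CHUNK):
        m = min(_CHUNK, n_reps - start)
        X = np.empty((m, n_max))
        Y = np.empty((m, n_max))
        for j in range(m):
            z = _replication_rng(seed, start + j).standard_normal(2 * n_max)
            X[j] = z[0::2] * sd + comparator_mean + effect * sd
            Y[j] = z[1::2] * sd + comparator_mean
        mx = X.cumsum(1) / count
        my = Y.cumsum(1) / count
        ssx = (X**2).cumsum(1) - count * mx**2
        ssy = (Y**2).cumsum(1) - count * my**2
        nn = count[look_idx]
        pooled = (ssx[:, look_idx] + ssy[:, look_idx]) / (2 * nn - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = (mx[:, look_idx] - my[:, look_idx]) / np.sqrt(pooled * 2.0 / nn)
        if design.prior.direction == "greater":
            fail = tt <= t_lo
            succ = tt >= t_hi
        else:  # BF decreasing in t: boundary inequalities flip
            fail = tt >= t_lo
            succ = tt <= t_hi
        crossed = fail | succ
        first = np.argmax(crossed, axis=1)
        hit = crossed.any(axis=1)
        stop_n[start:start + m] = np.where(hit, ns[first], n_max)
        stop_r[start:start + m] = np.where(
            ~hit, 0, np.where(succ[np.arange(m), first], 2, 1)
        )
    return stop_n, stop_r


def estimate_oc(design: TrialDesign, effect_grid: Sequence[float],
                checkpoints: Sequence[int], n_reps: int, seed: int,
                sd: float = 1.0, comparator_mean: float = 0.0) -> OCTable:
    """Estimate cumulative boundary-crossing probabilities by Monte Carlo.

    For each true effect, ``n_reps`` independent sequential comparisons are
    simulated; each cell reports the percentage absorbed at the given
    boundary by the given per-arm n (boundaries are absorbing, so rows are
    nondecreasing across checkpoints), together with its binomial standard
    error.
    """
    checkpoints = [int(c) for c in checkpoints]
    if n_reps < 100:
        raise LeapfrogValidationError(f"n_reps must be >= 100, got {n_reps}")
    for c in checkpoints:
        if not (design.n_min <= c <= design.n_max):
            raise LeapfrogValidationError(
                f"checkpoint {c} outside [n_min={design.n_min}, n_max={design.n_max}]"
            )
    effect_grid = [float(d) for d in effect_grid]
    shape = (len(effect_grid), len(checkpoints))
    p_fail = np.empty(shape)
    p_success = np.empty(shape)
    expected_stop = np.empty(len(effect_grid))
    cps = np.asarray(checkpoints)
    for i, d in enumerate(effect_grid):
        stop_n, stop_r = _simulate_stops(design, d, n_reps, seed,
                                         sd=sd, comparator_mean=comparator_mean)
        p_fail[i] = 100.0 * np.mean(
            (stop_r[:, None] == 1) & (stop_n[:, None] <= cps), axis=0)
        p_success[i] = 100.0 * np.mean(
            (stop_r[:, None] == 2) & (stop_n[:, None] <= cps), axis=0)
        expected_stop[i] = stop_n.mean()
    se = lambda p: 100.0 * np.sqrt(p / 100 * (1 - p / 100) / n_reps)
    return OCTable(
        effect_grid=tuple(effect_grid), checkpoints=tuple(checkpoints),
        p_fail=p_fail, p_success=p_success,
        mc_se_fail=se(p_fail), mc_se_success=se(p_success),
        expected_stop_n=expected_stop, n_reps=n_reps, design=design, seed=seed,
    )


def first_look_probabilities(design: TrialDesign, model: OutcomeModel,
                             n_reps: int, seed: int) -> tuple[float, float]:
    """(p_fail, p_success) in percent at the first look (n = n_min per arm).

    Fast path: a single t statistic per replication compared against the
    critical t values that the BF boundaries map to at ``n_min``.  Equals
    the ``n_min`` checkpoint of :func:`estimate_oc` for the same seed.
    """
    if n_reps < 100:
        raise LeapfrogValidationError(f"n_reps must be >= 100, got {n_reps}")
    single = replace(design, n_max=design.n_min)
    stop_n, stop_r = _simulate_stops(single, model.effect, n_reps, seed,
                                     sd=model.sd,
                                     comparator_mean=model.comparator_mean)
    return (100.0 * float(np.mean(stop_r == 1)),
            100.0 * float(np.mean(stop_r == 2)))


# ---------------------------------------------------------------------------
# Parameter search

@dataclass(frozen=True)
class CandidateResult:
    """One candidate design's operating characteristics at the search points."""

    design: TrialDesign
    power: float  # % absorbed at success by n_max, at the target effect
    false_positive: float  # % absorbed at success by n_max, at d = 0
    expected_n_at_target: float  # mean per-arm stopping n at the target effect


def search_parameters(target_d: float, power_floor: float, alpha_ceiling: float,
                      candidate_grid: Sequence[TrialDesign], n_reps: int,
                      seed: int) -> list[CandidateResult]:
    """Rank candidate designs by efficiency subject to error-rate constraints.

    Each candidate is simulated at the target effect (power) and at zero
    effect (false-positive rate), both assessed at ``n_max``.  Candidates
    with power >= ``power_floor`` and false-positive rate <= ``alpha_ceiling``
    (both fractions) survive and are ranked by expected per-arm sample size
    at the target effect, smallest first.  An empty surviving set returns an
    empty list.
    """
    if not candidate_grid:
        raise LeapfrogValidationError("candidate_grid must be non-empty")
    survivors = []
    for design in candidate_grid:
        oc = estimate_oc(design, [0.0, target_d], [design.n_max], n_reps, seed)
        fp = float(oc.p_success[0, 0])
        power = float(oc.p_success[1, 0])
        if power >= 100.0 * power_floor and fp <= 100.0 * alpha_ceiling:
            survivors.append(CandidateResult(
                design=design, power=power, false_positive=fp,
                expected_n_at_target=float(oc.expected_stop_n[1]),
            ))
    return sorted(survivors, key=lambda r: r.expected_n_at_target)
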