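"""Multi-arm leapfrog trial orchestration.

Runs the full adaptive-platform bookkeeping: permuted-block randomization
across the active arms, sequential directional Bayes-factor evaluation of
every challenger against the *contemporaneously randomized* subset of the
current comparator, arm dropping (failure boundary or sample-size cap),
promotion of successful challengers to comparator ("leapfrogging"),
mid-trial entry of scheduled arms, and an event log from which the whole
trajectory can be audited or replayed.

Decision rules
--------------
* A challenger is analysed once it and its contemporaneous comparator
  subset both hold at least ``n_min`` participants, on the design's cadence.
* BF <= bf_fail  -> the challenger is dropped (``dropped_fail``).
* BF >= bf_success -> the challenger is promoted to comparator; the old
  comparator is retired.  Remaining challengers face the new comparator
  from their next look onwards.
* A challenger reaching ``n_max`` undecided is dropped (``dropped_nmax``).
  The sitting comparator is exempt from the cap by default.
* Scheduled arms enter at trial start, at an explicit global randomization
  index, or on the next arm drop (the default; one queued arm per drop).

The contemporaneous subset of the comparator for a challenger is every
comparator-arm participant whose global randomization index is at or after
the challenger's entry index — including participants the comparator
accrued while it was itself still a challenger.  This is the reading under
which the reference five-method trajectory totals 1,250 participants; it is
switchable via ``contemporaneous_includes_prepromotion``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .bayesfactor import jzs_bf, two_sample_t
from .calibration import TrialDesign
from .errors import LeapfrogValidationError, ScriptError

__all__ = [
    "ArmRecord",
    "ArmSpec",
    "ArmSchedule",
    "TrialEvent",
    "TrialHistory",
    "ReplayDecision",
    "ReplayScript",
    "run_trial",
    "contemporaneous_subset",
    "replay_scenario",
]

EntryTrigger = Literal["start", "on_drop"] | int
Status = Literal["active", "dropped_fail", "dropped_nmax", "promoted", "retired"]

TERMINAL = {"dropped_fail", "dropped_nmax", "retired"}


@dataclass
class ArmRecord:
    """Bookkeeping record for one trial arm."""

    arm_id: str
    role: Literal["comparator", "challenger"]
    entry_index: int  # first global randomization index the arm was eligible for
    true_effect: float = 0.0  # arm's true mean on the standardized outcome scale
    indices: list[int] = field(default_factory=list)
    outcomes: list[float] = field(default_factory=list)
    status: Status = "active"
    last_look_n: int = 0

    @property
    def n(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ArmSpec:
    """One scheduled arm: identity, true effect, and entry trigger."""

    arm_id: str
    true_effect: float = 0.0
    entry: EntryTrigger = "on_drop"


@dataclass(frozen=True)
class ArmSchedule:
    """Ordered arm roster.  The first ``start`` arm is the initial comparator."""

    arms: tuple[ArmSpec, ...]

    def __init__(self, arms: Sequence[ArmSpec]):
        object.__setattr__(self, "arms", tuple(arms))
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise LeapfrogValidationError("arm_ids must be unique")
        starters = [a for a in self.arms if a.entry == "start"]
        if len(starters) < 2:
            raise LeapfrogValidationError(
                "schedule must supply a comparator and at least one challenger "
                "at trial start"
            )
        for a in self.arms:
            if not (a.entry in ("start", "on_drop") or isinstance(a.entry, int)):
                raise LeapfrogValidationError(
                    f"arm {a.arm_id!r}: invalid entry trigger {a.entry!r}"
                )


@dataclass(frozen=True)
class TrialEvent:
    index: int  # global randomization index (total allocated) at the event
    kind: Literal["arm_entered", "look_evaluated", "arm_dropped_fail",
                  "arm_dropped_nmax", "arm_promoted", "comparator_retired"]
    arm_id: str
    bf: float | None = None


@dataclass(frozen=True)
class TrialHistory:
    """Event-ordered record of a completed leapfrog trial."""

    events: tuple[TrialEvent, ...]
    arms: dict[str, ArmRecord]
    final_comparator: str

    @property
    def per_arm_n(self) -> dict[str, int]:
        return {aid: arm.n for aid, arm in self.arms.items()}

    @property
    def total_n(self) -> int:
        return sum(arm.n for arm in self.arms.values())


def contemporaneous_subset(comparator: ArmRecord, challenger: ArmRecord) -> np.ndarray:
    """Comparator outcomes randomized at or after the challenger's entry.

    Participants the comparator accrued while still a challenger count,
    provided their randomization index is >= the challenger's entry index.
    """
    idx = np.asarray(comparator.indices)
    out = np.asarray(comparator.outcomes)
    return out[idx >= challenger.entry_index]


class _Engine:
    """Shared allocation/decision loop for simulation and replay."""

    def __init__(self, design: TrialDesign, schedule: ArmSchedule,
                 rng: np.random.Generator | None,
                 comparator_nmax_exempt: bool = True,
                 contemporaneous_includes_prepromotion: bool = True):
        self.design = design
        self.rng = rng
        self.comparator_nmax_exempt = comparator_nmax_exempt
        self.include_prepromotion = contemporaneous_includes_prepromotion
        self.arms: dict[str, ArmRecord] = {}
        self.entry_order: list[str] = []
        self.events: list[TrialEvent] = []
        self.total = 0
        self.comparator_id: str | None = None
        self.block: list[str] = []
        self.carryover: list[str] = []
        self.pending = [a for a in schedule.arms if a.entry != "start"]
        for spec in schedule.arms:
            if spec.entry == "start":
                self._enter(spec)

    # -- arm lifecycle ----------------------------------------------------

    def _enter(self, spec: ArmSpec):
        role = "comparator" if self.comparator_id is None else "challenger"
        arm = ArmRecord(arm_id=spec.arm_id, role=role,
                        entry_index=self.total + 1, true_effect=spec.true_effect)
        self.arms[spec.arm_id] = arm
        self.entry_order.append(spec.arm_id)
        if role == "comparator":
            self.comparator_id = spec.arm_id
        self.events.append(TrialEvent(self.total, "arm_entered", spec.arm_id))
        self._reset_block()

    def _active(self) -> list[str]:
        return [aid for aid in self.entry_order
                if self.arms[aid].status == "active"
                or (self.arms[aid].status == "promoted" and aid == self.comparator_id)]

    def _challengers(self) -> list[str]:
        return [aid for aid in self._active() if aid != self.comparator_id]

    def _fire_drop_trigger(self):
        for i, spec in enumerate(self.pending):
            if spec.entry == "on_drop":
                self.pending.pop(i)
                self._enter(spec)
                return

    def _fire_index_triggers(self):
        fired = [s for s in self.pending
                 if isinstance(s.entry, int) and s.entry <= self.total + 1]
        for spec in fired:
            self.pending.remove(spec)
            self._enter(spec)

    def _drop(self, arm_id: str, kind: str):
        self.arms[arm_id].status = ("dropped_fail" if kind == "arm_dropped_fail"
                                    else "dropped_nmax")
        self.events.append(TrialEvent(self.total, kind, arm_id))
        self._reset_block()
        self._fire_drop_trigger()

    def _promote(self, arm_id: str, bf: float | None):
        old = self.comparator_id
        self.arms[old].status = "retired"
        self.events.append(TrialEvent(self.total, "comparator_retired", old))
        self.arms[arm_id].status = "promoted"
        self.arms[arm_id].role = "comparator"
        self.comparator_id = arm_id
        self.events.append(TrialEvent(self.total, "arm_promoted", arm_id, bf))
        self._reset_block()

    # -- allocation -------------------------------------------------------

    def _reset_block(self):
        # Randomized runs re-form the permuted block whenever the active set
        # changes.  The unfilled remainder of the abandoned block is kept:
        # if the trial ends here, those participants are already concurrently
        # randomized and the still-active arms receive their slots.
        # Deterministic replay instead keeps the running round-robin cycle
        # (terminal arms are simply skipped; new arms join the next cycle),
        # matching lockstep per-arm accrual within each phase.
        if self.rng is not None:
            self.carryover = self.block
            self.block = []

    def _next_arm(self) -> str:
        active = self._active()
        if self.rng is None:
            while True:
                if not self.block:
                    self.block = list(active)
                aid = self.block.pop(0)
                if aid in active:
                    return aid
        if not self.block:
            self.block = [active[k] for k in self.rng.permutation(len(active))]
        return self.block.pop(0)

    def _allocate(self, arm_id: str, outcome: float):
        self.total += 1
        arm = self.arms[arm_id]
        arm.indices.append(self.total)
        arm.outcomes.append(outcome)

    # -- history ----------------------------------------------------------

    def history(self) -> TrialHistory:
        assert self.comparator_id is not None
        return TrialHistory(events=tuple(self.events), arms=self.arms,
                            final_comparator=self.comparator_id)


def run_trial(design: TrialDesign, schedule: ArmSchedule, seed: int,
              comparator_nmax_exempt: bool = True,
              contemporaneous_includes_prepromotion: bool = True) -> TrialHistory:
    """Simulate a complete multi-arm leapfrog trial.

    Participants are allocated one at a time by permuted-block randomization
    over the active arms (block size = number of active arms, blocks
    re-formed whenever the active set changes); outcomes are drawn from
    Normal(arm true effect, 1) on the standardized scale.  After each
    allocation the allocated challenger is analysed if it sits on a look
    point; boundary crossings trigger drops and promotions immediately.
    The trial ends when no challenger remains and the schedule is exhausted.
    """
    rng = np.random.default_rng((int(seed), 0))
    eng = _Engine(design, schedule, rng,
                  comparator_nmax_exempt=comparator_nmax_exempt,
                  contemporaneous_includes_prepromotion=contemporaneous_includes_prepromotion)
    n_min, n_max, step = design.n_min, design.n_max, design.step

    guard = 0
    limit = (len(schedule.arms) + 1) * n_max * 4 + 1000
    while True:
        guard += 1
        if guard > limit:  # defensive: the rules guarantee termination
            raise RuntimeError("trial failed to terminate")
        eng._fire_index_triggers()
        while not eng._challengers() and eng.pending:
            # No drops can occur with no challengers left; admit the next
            # scheduled arm so the roster is exhausted, not stranded.
            spec = eng.pending.pop(0)
            eng._enter(spec)
        if not eng._challengers():
            break

        arm_id = eng._next_arm()
        arm = eng.arms[arm_id]
        eng._allocate(arm_id, float(rng.normal(arm.true_effect, 1.0)))

        if arm_id == eng.comparator_id:
            if not comparator_nmax_exempt and arm.n >= n_max:
                # Cap applies to the comparator too: retiring it ends the trial.
                eng.carryover = []
                break
            continue

        # Challenger look on the cadence.
        on_look = arm.n >= n_min and (arm.n - n_min) % step == 0
        if not on_look and arm.n >= n_max:
            on_look = True  # final mandatory look at the cap
        decided = False
        if on_look:
            comp = eng.arms[eng.comparator_id]
            if eng.include_prepromotion:
                subset = contemporaneous_subset(comp, arm)
            else:
                idx = np.asarray(comp.indices)
                subset = np.asarray(comp.outcomes)[
                    (idx >= arm.entry_index) & (idx >= comp.entry_index)]
            if subset.size >= n_min:
                ts = two_sample_t(arm.outcomes, subset)
                bf = jzs_bf(ts, design.prior).bf
                eng.events.append(TrialEvent(eng.total, "look_evaluated",
                                             arm_id, bf))
                arm.last_look_n = arm.n
                if bf <= design.bf_fail:
                    eng._drop(arm_id, "arm_dropped_fail")
                    decided = True
                elif bf >= design.bf_success:
                    eng._promote(arm_id, bf)
                    decided = True
        if not decided and arm.n >= n_max:
            eng._drop(arm_id, "arm_dropped_nmax")

    # Participants in the block in progress at the final decision are
    # concurrently randomized: the still-active arms (the comparator)
    # receive their remaining slots, so a 2-arm trial running to the cap
    # accrues the full 2 * n_max.
    for aid in eng.carryover:
        if aid in eng._active():
            a = eng.arms[aid]
            eng._allocate(aid, float(rng.normal(a.true_effect, 1.0)))
    return eng.history()


# ---------------------------------------------------------------------------
# Deterministic replay

@dataclass(frozen=True)
class ReplayDecision:
    """A forced boundary event: the arm hits ``decision`` at per-arm ``n``."""

    arm_id: str
    decision: Literal["fail", "success"]
    n: int


@dataclass(frozen=True)
class ReplayScript:
    """A scripted trajectory: design, roster, and forced boundary events.

    The replay reproduces the engine's allocation and bookkeeping exactly
    (deterministic round-robin allocation in entry order, no outcome
    simulation) with decisions imposed by the script; it exists to audit
    per-arm totals and the event sequence of a narrated scenario.
    """

    design: TrialDesign
    schedule: ArmSchedule
    decisions: tuple[ReplayDecision, ...]

    def __init__(self, design, schedule, decisions):
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "schedule", schedule)
        object.__setattr__(self, "decisions", tuple(decisions))
        known = {a.arm_id for a in schedule.arms}
        seen = set()
        for dec in self.decisions:
            if dec.arm_id in seen:
                raise ScriptError(f"arm {dec.arm_id!r} has more than one decision")
            seen.add(dec.arm_id)
            if dec.arm_id not in known:
                raise ScriptError(f"decision for unknown arm {dec.arm_id!r}")
            if not (design.n_min <= dec.n <= design.n_max):
                raise ScriptError(
                    f"{dec.arm_id}: scripted {dec.decision} at n={dec.n} outside "
                    f"[n_min={design.n_min}, n_max={design.n_max}]"
                )


def replay_scenario(script: ReplayScript) -> TrialHistory:
    """Replay a scripted trial deterministically.

    Allocation cycles through the active arms in entry order.  When a
    challenger reaches the per-arm n of its scripted decision, that boundary
    event is applied — after checking it is feasible under the decision
    rules (analyses require n_min per arm and n_min contemporaneous
    comparator participants; nothing can be decided beyond n_max).
    Unscripted challengers reaching n_max are dropped by the cap.

    Raises
    ------
    ScriptError
        Naming the offending step, if any scripted event is infeasible or
        never happens.
    """
    design = script.design
    eng = _Engine(design, script.schedule, rng=None)
    by_arm = {d.arm_id: d for d in script.decisions}
    applied = set()
    guard = 0
    limit = (len(script.schedule.arms) + 1) * design.n_max * 4 + 1000
    while True:
        guard += 1
        if guard > limit:
            raise ScriptError("script does not lead to trial termination")
        eng._fire_index_triggers()
        while not eng._challengers() and eng.pending:
            eng._enter(eng.pending.pop(0))
        if not eng._challengers():
            break

        arm_id = eng._next_arm()
        arm = eng.arms[arm_id]
        eng._allocate(arm_id, math.nan)

        if arm_id == eng.comparator_id:
            continue
        dec = by_arm.get(arm_id)
        if dec is not None and arm.n == dec.n:
            comp = eng.arms[eng.comparator_id]
            subset_n = int(np.sum(np.asarray(comp.indices) >= arm.entry_index))
            if subset_n < design.n_min:
                raise ScriptError(
                    f"{arm_id}: scripted {dec.decision} at n={dec.n} but the "
                    f"contemporaneous comparator subset holds only {subset_n} "
                    f"(< n_min={design.n_min}) participants"
                )
            eng.events.append(TrialEvent(eng.total, "look_evaluated", arm_id))
            if dec.decision == "fail":
                eng._drop(arm_id, "arm_dropped_fail")
            else:
                eng._promote(arm_id, None)
            applied.add(arm_id)
        elif arm.n >= design.n_max:
            eng._drop(arm_id, "arm_dropped_nmax")

    missing = set(by_arm) - applied
    if missing:
        raise ScriptError(
            f"scripted decisions never occurred for arms: {sorted(missing)} "
            "(arm terminal or trial ended before the scripted n)"
        )
    return eng.history()
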