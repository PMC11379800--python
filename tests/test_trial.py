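"""Multi-arm leapfrog engine: bookkeeping oracle, invariants, replay."""

import numpy as np
import pytest

from leapfrog.bayesfactor import PriorSpec, jzs_bf, two_sample_t
from leapfrog.calibration import OutcomeModel, TrialDesign, _simulate_stops
from leapfrog.errors import LeapfrogValidationError, ScriptError
from leapfrog.trial import (
    ArmSchedule,
    ArmSpec,
    ReplayDecision,
    ReplayScript,
    contemporaneous_subset,
    replay_scenario,
    run_trial,
)

TOY = TrialDesign(n_min=4, n_max=8, bf_fail=1 / 3, bf_success=3,
                  prior=PriorSpec(0.5, "greater"), step=1)


def naive_leapfrog(design, schedule, seed):
    """Independent flat re-enactment of the decision rules.

    Deliberately structured as plain sequential bookkeeping (lists and one
    loop, no engine abstractions) so it can serve as a brute-force oracle
    for ``run_trial`` on small instances.  Consumes randomness in the same
    documented order: one block permutation whenever the block refills, one
    normal draw per allocation.
    """
    rng = np.random.default_rng((int(seed), 0))
    arms = {}  # arm_id -> dict(n, idx, out, status, entry, effect)
    order = []
    events = []
    pending = [a for a in schedule.arms if a.entry != "start"]
    comparator = None
    total = 0

    def enter(spec):
        nonlocal comparator
        arms[spec.arm_id] = dict(n=0, idx=[], out=[], status="active",
                                 entry=total + 1, effect=spec.true_effect)
        order.append(spec.arm_id)
        if comparator is None:
            comparator = spec.arm_id
        events.append((total, "arm_entered", spec.arm_id, None))

    for spec in schedule.arms:
        if spec.entry == "start":
            enter(spec)

    block, carry = [], []

    def active():
        return [a for a in order
                if arms[a]["status"] == "active"
                or (arms[a]["status"] == "promoted" and a == comparator)]

    def challengers():
        return [a for a in active() if a != comparator]

    while True:
        for spec in [s for s in pending
                     if isinstance(s.entry, int) and s.entry <= total + 1]:
            pending.remove(spec)
            enter(spec)
            carry, block = block, []
        while not challengers() and pending:
            enter(pending.pop(0))
            carry, block = block, []
        if not challengers():
            break
        if not block:
            act = active()
            block = [act[k] for k in rng.permutation(len(act))]
        aid = block.pop(0)
        a = arms[aid]
        total += 1
        a["idx"].append(total)
        a["out"].append(float(rng.normal(a["effect"], 1.0)))
        a["n"] += 1
        if aid == comparator:
            continue
        decided = False
        on_look = (a["n"] >= design.n_min
                   and (a["n"] - design.n_min) % design.step == 0)
        if not on_look and a["n"] >= design.n_max:
            on_look = True
        if on_look:
            comp = arms[comparator]
            sub = [o for i, o in zip(comp["idx"], comp["out"])
                   if i >= a["entry"]]
            if len(sub) >= design.n_min:
                bf = jzs_bf(two_sample_t(a["out"], sub), design.prior).bf
                events.append((total, "look_evaluated", aid, bf))
                if bf <= design.bf_fail:
                    a["status"] = "dropped_fail"
                    events.append((total, "arm_dropped_fail", aid, None))
                    carry, block = block, []
                    nxt = next((s for s in pending if s.entry == "on_drop"), None)
                    if nxt is not None:
                        pending.remove(nxt)
                        enter(nxt)
                        carry, block = block, []
                    decided = True
                elif bf >= design.bf_success:
                    arms[comparator]["status"] = "retired"
                    events.append((total, "comparator_retired", comparator, None))
                    a["status"] = "promoted"
                    comparator = aid
                    events.append((total, "arm_promoted", aid, bf))
                    carry, block = block, []
                    decided = True
        if not decided and a["n"] >= design.n_max:
            a["status"] = "dropped_nmax"
            events.append((total, "arm_dropped_nmax", aid, None))
            carry, block = block, []
            nxt = next((s for s in pending if s.entry == "on_drop"), None)
            if nxt is not None:
                pending.remove(nxt)
                enter(nxt)
                carry, block = block, []

    for aid in carry:
        if aid in active():
            a = arms[aid]
            total += 1
            a["idx"].append(total)
            a["out"].append(float(rng.normal(a["effect"], 1.0)))
            a["n"] += 1
    return events, {k: v["n"] for k, v in arms.items()}, total, comparator


class TestRunTrialOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_bookkeeping_three_arms(self, seed):
        """Full event-by-event agreement with the flat oracle."""
        sched = ArmSchedule([ArmSpec("C", 0.0, "start"),
                             ArmSpec("A", -0.8, "start"),
                             ArmSpec("B", 1.2, "start"),
                             ArmSpec("D", 0.0, "on_drop")])
        hist = run_trial(TOY, sched, seed)
        ev, per_arm, total, comp = naive_leapfrog(TOY, sched, seed)
        got = [(e.index, e.kind, e.arm_id, e.bf) for e in hist.events]
        assert got == ev
        assert hist.per_arm_n == per_arm
        assert hist.total_n == total
        assert hist.final_comparator == comp

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_naive_with_explicit_index_entry(self, seed):
        sched = ArmSchedule([ArmSpec("C", 0.0, "start"),
                             ArmSpec("A", 0.5, "start"),
                             ArmSpec("E", 0.5, 10)])
        hist = run_trial(TOY, sched, seed)
        ev, per_arm, total, comp = naive_leapfrog(TOY, sched, seed)
        assert [(e.index, e.kind, e.arm_id, e.bf) for e in hist.events] == ev
        assert hist.per_arm_n == per_arm


class TestRunTrialBehaviour:
    def test_forced_nmax_path(self):
        d = TrialDesign(n_min=5, n_max=12, bf_fail=1e-12, bf_success=1e12)
        sched = ArmSchedule([ArmSpec("C", 0.0, "start"),
                             ArmSpec("X", 0.0, "start")])
        hist = run_trial(d, sched, seed=2)
        assert hist.arms["X"].status == "dropped_nmax"
        assert hist.per_arm_n == {"C": 12, "X": 12}
        assert hist.total_n == 2 * d.n_max

    def test_deterministic(self):
        sched = ArmSchedule([ArmSpec("C", 0.0, "start"),
                             ArmSpec("A", 0.3, "start"),
                             ArmSpec("B", -0.3, "start")])
        h1 = run_trial(TOY, sched, 33)
        h2 = run_trial(TOY, sched, 33)
        assert h1.events == h2.events
        assert h1.per_arm_n == h2.per_arm_n

    def test_schedule_without_comparator_rejected(self):
        with pytest.raises(LeapfrogValidationError):
            ArmSchedule([ArmSpec("only", 0.0, "start")])
        with pytest.raises(LeapfrogValidationError):
            ArmSchedule([ArmSpec("a", 0.0, "on_drop"),
                         ArmSpec("b", 0.0, "on_drop")])

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_single_comparator_fuzz(self, seed):
        """Randomized scenarios: participant conservation, one comparator at
        every event, and no resurrection of terminal arms."""
        rng = np.random.default_rng(seed + 400)
        n_min = int(rng.integers(3, 6))
        design = TrialDesign(
            n_min=n_min, n_max=n_min + int(rng.integers(2, 6)),
            bf_fail=1 / 3, bf_success=3.0, step=int(rng.integers(1, 3)))
        specs = [ArmSpec("C", 0.0, "start"), ArmSpec("a0", 0.0, "start")]
        for k in range(int(rng.integers(1, 4))):
            entry = ["start", "on_drop"][int(rng.integers(0, 2))]
            specs.append(ArmSpec(f"x{k}", float(rng.normal(0, 1)), entry))
        hist = run_trial(design, ArmSchedule(specs), seed)

        assert hist.total_n == sum(hist.per_arm_n.values())
        alloc_events = max((e.index for e in hist.events), default=0)
        assert hist.total_n >= alloc_events
        # replay the event log: exactly one comparator at all times, and
        # terminal arms never act again
        comparator = None
        terminal = set()
        for ev in hist.events:
            assert ev.arm_id not in terminal
            if ev.kind == "arm_entered" and comparator is None:
                comparator = ev.arm_id
            elif ev.kind == "comparator_retired":
                assert ev.arm_id == comparator
                terminal.add(ev.arm_id)
                comparator = None
            elif ev.kind == "arm_promoted":
                assert comparator is None
                comparator = ev.arm_id
            elif ev.kind in ("arm_dropped_fail", "arm_dropped_nmax"):
                terminal.add(ev.arm_id)
        assert comparator == hist.final_comparator
        # every drop/promotion is preceded by a crossing look or the cap
        looks = {}
        for ev in hist.events:
            if ev.kind == "look_evaluated":
                looks[ev.arm_id] = ev.bf
            elif ev.kind == "arm_dropped_fail":
                assert looks[ev.arm_id] <= design.bf_fail
            elif ev.kind == "arm_promoted":
                assert looks[ev.arm_id] >= design.bf_success
            elif ev.kind == "arm_dropped_nmax":
                assert hist.arms[ev.arm_id].n == design.n_max

    def test_reduces_to_pairwise_simulator(self):
        """With one challenger and no scheduled entries the multi-arm engine
        reproduces the pairwise design analysis within Monte-Carlo error."""
        design = TrialDesign(n_min=10, n_max=25, bf_fail=1 / 3, bf_success=3,
                             step=3)
        effect = 0.4
        n_trials = 150
        sched = ArmSchedule([ArmSpec("C", 0.0, "start"),
                             ArmSpec("X", effect, "start")])
        succ = stops = 0
        for seed in range(n_trials):
            h = run_trial(design, sched, seed)
            succ += h.arms["X"].status == "promoted"
            stops += h.arms["X"].n
        stop_n, stop_r = _simulate_stops(design, effect, 4000, seed=777)
        p_engine = succ / n_trials
        p_pair = float(np.mean(stop_r == 2))
        se = np.sqrt(p_pair * (1 - p_pair) / n_trials
                     + p_pair * (1 - p_pair) / 4000)
        assert abs(p_engine - p_pair) <= 3.5 * se
        mean_engine = stops / n_trials
        mean_pair = float(stop_n.mean())
        se_n = np.sqrt(stop_n.var() / n_trials + stop_n.var() / 4000)
        assert abs(mean_engine - mean_pair) <= 3.5 * se_n

    def test_better_arm_usually_promoted(self):
        """Two challengers at d = 0 and d = 0.5: the real improvement wins
        the promotion in a clear majority of trials."""
        design = TrialDesign(n_min=20, n_max=60, bf_fail=1 / 5, bf_success=3,
                             step=10)
        sched = ArmSchedule([ArmSpec("C", 0.0, "start"),
                             ArmSpec("null_arm", 0.0, "start"),
                             ArmSpec("good_arm", 0.5, "start")])
        promoted = sum(
            run_trial(design, sched, seed).arms["good_arm"].status == "promoted"
            for seed in range(500))
        assert promoted > 250


class TestContemporaneousSubset:
    def _arm(self, arm_id, entry, idx, out=None, role="challenger"):
        from leapfrog.trial import ArmRecord

        return ArmRecord(arm_id=arm_id, role=role, entry_index=entry,
                         indices=list(idx),
                         outcomes=list(out if out is not None
                                       else np.zeros(len(idx))))

    def test_full_overlap_from_start(self):
        comp = self._arm("C", 1, range(1, 11), np.arange(10.0),
                         role="comparator")
        chal = self._arm("X", 1, [])
        assert contemporaneous_subset(comp, chal).size == 10

    def test_late_entry_filters_strictly(self):
        comp = self._arm("C", 1, range(1, 11), np.arange(10.0),
                         role="comparator")
        chal = self._arm("X", 6, [])
        sub = contemporaneous_subset(comp, chal)
        assert sub.size == 5
        assert list(sub) == [5.0, 6.0, 7.0, 8.0, 9.0]

    def test_entry_after_all_comparator_data(self):
        comp = self._arm("C", 1, range(1, 11), role="comparator")
        chal = self._arm("X", 99, [])
        assert contemporaneous_subset(comp, chal).size == 0


class TestReplay:
    def _design(self):
        return TrialDesign(n_min=150, n_max=450, bf_fail=1 / 5, bf_success=3)

    def test_five_method_trajectory(self):
        """Scripted multi-arm trajectory: three challengers at start, two
        entering on drops, two successive promotions; audited totals."""
        sched = ArmSchedule([
            ArmSpec("C", entry="start"), ArmSpec("arm1", entry="start"),
            ArmSpec("arm2", entry="start"), ArmSpec("arm3", entry="start"),
            ArmSpec("arm4", entry="on_drop"), ArmSpec("arm5", entry="on_drop"),
        ])
        script = ReplayScript(self._design(), sched, [
            ReplayDecision("arm1", "fail", 150),
            ReplayDecision("arm3", "success", 200),
            ReplayDecision("arm2", "fail", 200),
            ReplayDecision("arm4", "success", 200),
            ReplayDecision("arm5", "fail", 150),
        ])
        hist = replay_scenario(script)
        assert hist.total_n == 1250
        assert hist.per_arm_n == {"C": 200, "arm1": 150, "arm2": 200,
                                  "arm3": 350, "arm4": 200, "arm5": 150}
        assert hist.final_comparator == "arm4"
        kinds = [(e.kind, e.arm_id) for e in hist.events
                 if e.kind not in ("look_evaluated",)]
        assert ("arm_promoted", "arm3") in kinds
        assert ("comparator_retired", "C") in kinds
        assert ("arm_promoted", "arm4") in kinds

    def test_single_immediate_failure(self):
        sched = ArmSchedule([ArmSpec("C", entry="start"),
                             ArmSpec("X", entry="start")])
        script = ReplayScript(self._design(), sched,
                              [ReplayDecision("X", "fail", 150)])
        hist = replay_scenario(script)
        assert hist.total_n == 2 * 150

    def test_unscripted_arm_hits_cap(self):
        d = TrialDesign(n_min=4, n_max=8, bf_fail=1 / 3, bf_success=3)
        sched = ArmSchedule([ArmSpec("C", entry="start"),
                             ArmSpec("X", entry="start")])
        hist = replay_scenario(ReplayScript(d, sched, []))
        assert hist.arms["X"].status == "dropped_nmax"
        assert hist.per_arm_n["X"] == 8

    def test_promotion_before_nmin_rejected(self):
        sched = ArmSchedule([ArmSpec("C", entry="start"),
                             ArmSpec("X", entry="start")])
        with pytest.raises(ScriptError, match="X"):
            ReplayScript(self._design(), sched,
                         [ReplayDecision("X", "success", 100)])

    def test_decision_for_unknown_arm_rejected(self):
        sched = ArmSchedule([ArmSpec("C", entry="start"),
                             ArmSpec("X", entry="start")])
        with pytest.raises(ScriptError, match="ghost"):
            ReplayScript(self._design(), sched,
                         [ReplayDecision("ghost", "fail", 150)])

    def test_unreachable_decision_rejected(self):
        # arm2's decision sits beyond the trial's natural end
        d = TrialDesign(n_min=4, n_max=8, bf_fail=1 / 3, bf_success=3)
        sched = ArmSchedule([ArmSpec("C", entry="start"),
                             ArmSpec("X", entry="start")])
        script = ReplayScript(d, sched, [ReplayDecision("X", "fail", 4),
                                         ReplayDecision("C", "fail", 8)])
        with pytest.raises(ScriptError):
            replay_scenario(script)

    def test_no_challenger_schedule_rejected(self):
        with pytest.raises(LeapfrogValidationError):
            ArmSchedule([])
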