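# leapfrog-trial

A design-analysis and simulation toolkit for **leapfrog trials** — a
simplified adaptive platform trial (APT) design for continuous treatment
development, aimed at trialists and methodologists in psychological
treatment research and similar settings where realistic improvements are
small (Cohen's *d* ≈ 0.2) and classical fixed-N trials are prohibitively
large.

## The design

One or more *challenger* arms are compared against the current *comparator*
arm (e.g. treatment as usual) on a continuous primary outcome, with
participants randomized across active arms. Once a challenger and its
contemporaneously randomized comparator subset both reach a minimum per-arm
sample size N_min, a **directional sequential Bayes factor** is computed at
every analysis:

    BF = ∫ f(t | ν, δ√n_eff) π(δ) dδ  /  f(t | ν, 0)

where *t* is the pooled-variance two-sample t statistic, ν = n₁+n₂−2,
n_eff = n₁n₂/(n₁+n₂), and π is a Cauchy(0, *rscale*) prior on the
standardized effect δ truncated to δ > 0 (the JZS default Bayes factor with
a one-sided alternative). The boundaries are absorbing:

* **BF ≤ BF_fail** — the challenger is dropped;
* **BF ≥ BF_success** — the challenger is *promoted*: it leapfrogs the
  comparator and becomes the new benchmark, the old comparator retires;
* **n = N_max undecided** — the challenger is dropped at the cap.

New arms can enter an ongoing trial (at start, at a chosen randomization
index, or on the next arm drop). Because weak arms are dropped quickly and
strong arms replace the benchmark, a programme that would classically need
a series of fixed-N RCTs collapses into one continuously running trial.

The toolkit provides:

* `leapfrog.bayesfactor` — directional/two-sided JZS Bayes factors by
  adaptive quadrature, with a Monte-Carlo prior-integration oracle and
  BF-boundary ↔ critical-t inversion;
* `leapfrog.calibration` — pairwise sequential design analysis: simulated
  BF trajectories, operating characteristics (power / false-positive rate
  as a function of accrued n) over a grid of true effects, and a candidate
  design search;
* `leapfrog.trial` — the multi-arm engine: permuted-block allocation,
  contemporaneous comparisons, drops/promotions/mid-trial entries, full
  event logging, plus deterministic replay of scripted trajectories;
* `leapfrog.power` — the classical fixed-N benchmark (exact noncentral-t
  sample sizes);
* a `leapfrog` CLI (`power`, `oc`, `run`, `replay`, `calibrate`) driven by
  YAML/JSON configs.

## Worked example

The reference design analyses start at 150/arm, cap at 450/arm, with
boundaries BF_fail = 1/5 and BF_success = 3 and prior scale 0.5:

```python
from leapfrog import (TrialDesign, PriorSpec, OutcomeModel, TStat, jzs_bf,
                      first_look_probabilities, estimate_oc, run_trial,
                      ArmSchedule, ArmSpec)

bf = jzs_bf(TStat(t=2.5, n1=200, n2=200), PriorSpec(0.5, "greater"))
print(round(bf.bf, 3))                      # 5.622

design = TrialDesign()                      # the reference parameters
pf, ps = first_look_probabilities(design, OutcomeModel(effect=0.0),
                                  n_reps=10_000, seed=1)
print(f"{pf:.1f}% {ps:.1f}%")               # 57.1% 1.4%
```

With no true effect (d = 0), the very first analysis at 150/arm already
drops the challenger 57% of the time, and wrongly promotes it only 1.4% of
the time. Cumulative operating characteristics over accrual:

```python
oc = estimate_oc(design, effect_grid=[0.0, 0.2], checkpoints=[200, 450],
                 n_reps=10_000, seed=1)
print(oc.to_wide_frame().round(1).to_string(index=False))
```

```
 effect  fail_200  fail_450  success_200  success_450
    0.0      74.3      90.0          3.0          5.1
    0.2      10.6      13.3         52.6         80.4
```

Reading the `success` block: the design wrongly promotes a null challenger
by the cap about 5% of the time (the pairwise false-positive rate), while a
true d = 0.2 challenger is promoted with ~80% probability by 450/arm —
the classical fixed-N trial for the same effect needs 394 per arm
(`leapfrog power --d 0.2` → `n_per_arm: 394`), every time, with no early
stopping.

A three-arm trial in which one personalization attempt is useless and one
carries the hoped-for d = 0.2:

```python
sched = ArmSchedule([ArmSpec("standard", 0.0, "start"),
                     ArmSpec("personalized_v1", 0.0, "start"),
                     ArmSpec("personalized_v2", 0.2, "start")])
hist = run_trial(design, sched, seed=11)
print(hist.total_n, hist.final_comparator)  # 452 personalized_v2
print(hist.per_arm_n)
# {'standard': 150, 'personalized_v1': 151, 'personalized_v2': 151}
```

In this run both decisions fell at the first look: the null arm was dropped
and the effective arm was promoted to become the new standard of care, after
452 randomized participants in total. (Sequential sample sizes are random;
this run was decided unusually early.)

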