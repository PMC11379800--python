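"""Configuration loading and report writing.

Configs are YAML or JSON.  A full run configuration bundles the trial
design with exactly what the command needs: an operating-characteristics
grid, a multi-arm schedule, a replay script, or a candidate grid for
calibration.  Validation happens at load time and reports the offending
field path; a seed is mandatory for every stochastic command (there are no
silent defaults — reproducibility is part of the contract).

Reports: the OC table is written as a wide CSV mirroring the published
table layout (rows = true effect, column blocks = fail/success boundary by
checkpoint), a tidy long CSV, and a JSON metadata sidecar recording the
design, replication count, seed and Monte-Carlo standard errors so any
report can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayesfactor import PriorSpec
from .calibration import OCTable, TrialDesign
from .errors import LeapfrogValidationError
from .trial import ArmSchedule, ArmSpec, ReplayDecision, ReplayScript, TrialHistory

__all__ = [
    "RunConfig",
    "load_config",
    "write_oc_report",
    "read_oc_long",
    "write_history",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; sections are present as the command needs."""

    design: TrialDesign
    seed: int | None = None
    n_reps: int | None = None
    effect_grid: tuple[float, ...] | None = None
    checkpoints: tuple[int, ...] | None = None
    schedule: ArmSchedule | None = None
    replay: ReplayScript | None = None
    calibration: dict | None = None

    def require_seed(self) -> int:
        if self.seed is None:
            raise LeapfrogValidationError(
                "seed: a seed is required for stochastic commands (no default)"
            )
        return int(self.seed)


def _get(mapping, key, path, required=False, default=None):
    if key not in mapping:
        if required:
            raise LeapfrogValidationError(f"{path}{key}: missing required field")
        return default
    return mapping[key]


def _parse_design(raw, path="design.") -> TrialDesign:
    if not isinstance(raw, dict):
        raise LeapfrogValidationError("design: must be a mapping")
    known = {"n_min", "n_max", "bf_fail", "bf_success", "rscale", "direction",
             "step", "allocation_ratio"}
    unknown = set(raw) - known
    if unknown:
        raise LeapfrogValidationError(
            f"design: unknown fields {sorted(unknown)} (expected {sorted(known)})"
        )
    prior = PriorSpec(rscale=float(raw.get("rscale", 0.5)),
                      direction=raw.get("direction", "greater"))
    kwargs = {}
    for key, cast in (("n_min", int), ("n_max", int),
                      ("bf_fail", float), ("bf_success", float), ("step", int)):
        if key in raw:
            try:
                kwargs[key] = cast(raw[key])
            except (TypeError, ValueError) as exc:
                raise LeapfrogValidationError(f"{path}{key}: {exc}") from exc
    if "allocation_ratio" in raw:
        ratio = raw["allocation_ratio"]
        if not (isinstance(ratio, (list, tuple)) and len(ratio) == 2):
            raise LeapfrogValidationError(
                f"{path}allocation_ratio: expected a pair, got {ratio!r}"
            )
        kwargs["allocation_ratio"] = (int(ratio[0]), int(ratio[1]))
    try:
        return TrialDesign(prior=prior, **kwargs)
    except LeapfrogValidationError as exc:
        raise LeapfrogValidationError(f"design: {exc}") from exc


def _parse_schedule(raw, path="schedule") -> ArmSchedule:
    if not isinstance(raw, list) or not raw:
        raise LeapfrogValidationError(f"{path}: must be a non-empty list of arms")
    specs = []
    for i, item in enumerate(raw):
        p = f"{path}[{i}]."
        arm_id = str(_get(item, "arm_id", p, required=True))
        entry = _get(item, "entry", p, default="on_drop")
        if isinstance(entry, str) and entry not in ("start", "on_drop"):
            raise LeapfrogValidationError(
                f"{p}entry: expected 'start', 'on_drop' or an integer index, "
                f"got {entry!r}"
            )
        specs.append(ArmSpec(arm_id=arm_id,
                             true_effect=float(_get(item, "effect", p, default=0.0)),
                             entry=entry if isinstance(entry, str) else int(entry)))
    return ArmSchedule(specs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise LeapfrogValidationError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise LeapfrogValidationError("config root must be a mapping")

    design = _parse_design(_get(raw, "design", "", required=True))
    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)
    n_reps = raw.get("n_reps")
    if n_reps is not None:
        n_reps = int(n_reps)

    effect_grid = checkpoints = None
    if "oc" in raw:
        oc = raw["oc"]
        effect_grid = tuple(float(d) for d in _get(oc, "effect_grid", "oc.",
                                                   required=True))
        checkpoints = tuple(int(c) for c in _get(oc, "checkpoints", "oc.",
                                                 required=True))

    schedule = _parse_schedule(raw["schedule"]) if "schedule" in raw else None

    replay = None
    if "replay" in raw:
        rep = raw["replay"]
        sched = _parse_schedule(_get(rep, "schedule", "replay.", required=True),
                                path="replay.schedule")
        decisions = []
        for i, d in enumerate(_get(rep, "decisions", "replay.", required=True)):
            p = f"replay.decisions[{i}]."
            decision = _get(d, "decision", p, required=True)
            if decision not in ("fail", "success"):
                raise LeapfrogValidationError(
                    f"{p}decision: expected 'fail' or 'success', got {decision!r}"
                )
            decisions.append(ReplayDecision(
                arm_id=str(_get(d, "arm_id", p, required=True)),
                decision=decision,
                n=int(_get(d, "n", p, required=True))))
        replay = ReplayScript(design, sched, decisions)

    calibration = None
    if "calibrate" in raw:
        cal = raw["calibrate"]
        candidates = [_parse_design(c, path=f"calibrate.candidates[{i}].")
                      for i, c in enumerate(_get(cal, "candidates", "calibrate.",
                                                 required=True))]
        calibration = {
            "target_d": float(_get(cal, "target_d", "calibrate.", required=True)),
            "power_floor": float(_get(cal, "power_floor", "calibrate.",
                                      default=0.80)),
            "alpha_ceiling": float(_get(cal, "alpha_ceiling", "calibrate.",
                                        default=0.05)),
            "candidates": candidates,
        }

    return RunConfig(design=design, seed=seed, n_reps=n_reps,
                     effect_grid=effect_grid, checkpoints=checkpoints,
                     schedule=schedule, replay=replay, calibration=calibration)


# ---------------------------------------------------------------------------
# Reports

def _check_overwrite(path: Path, force: bool):
    if path.exists() and not force:
        raise LeapfrogValidationError(
            f"refusing to overwrite existing output {path} (use force)"
        )


def write_oc_report(oc: OCTable, outdir, force: bool = False) -> dict[str, Path]:
    """Write wide CSV, tidy long CSV and JSON metadata for an OC table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wide": outdir / "oc_wide.csv",
        "long": outdir / "oc_long.csv",
        "meta": outdir / "oc_meta.json",
    }
    for p in paths.values():
        _check_overwrite(p, force)
    oc.to_wide_frame().to_csv(paths["wide"], index=False)
    oc.to_long_frame().to_csv(paths["long"], index=False)
    design = dataclasses.asdict(oc.design)
    meta = {
        "design": design,
        "n_reps": oc.n_reps,
        "seed": oc.seed,
        "effect_grid": list(oc.effect_grid),
        "checkpoints": list(oc.checkpoints),
        "expected_stop_n": [float(x) for x in oc.expected_stop_n],
        "mc_se_fail": np.asarray(oc.mc_se_fail).tolist(),
        "mc_se_success": np.asarray(oc.mc_se_success).tolist(),
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_oc_long(long_csv, meta_json) -> OCTable:
    """Rebuild an OCTable from its long CSV + metadata (exact round-trip)."""
    df = pd.read_csv(long_csv)
    meta = json.loads(Path(meta_json).read_text())
    effects = meta["effect_grid"]
    cps = meta["checkpoints"]
    p = {b: np.empty((len(effects), len(cps))) for b in ("fail", "success")}
    for (eff, cp, boundary), grp in df.groupby(["effect", "checkpoint_n",
                                                "boundary"]):
        i = effects.index(eff)
        j = cps.index(cp)
        p[boundary][i, j] = grp["probability_pct"].iloc[0]
    draw = dict(meta["design"])
    prior = PriorSpec(**draw.pop("prior"))
    draw["allocation_ratio"] = tuple(draw["allocation_ratio"])
    design = TrialDesign(prior=prior, **draw)
    return OCTable(
        effect_grid=tuple(effects), checkpoints=tuple(cps),
        p_fail=p["fail"], p_success=p["success"],
        mc_se_fail=np.asarray(meta["mc_se_fail"]),
        mc_se_success=np.asarray(meta["mc_se_success"]),
        expected_stop_n=np.asarray(meta["expected_stop_n"]),
        n_reps=meta["n_reps"], design=design, seed=meta["seed"],
    )


def write_history(history: TrialHistory, outdir, force: bool = False) -> dict[str, Path]:
    """Serialize a trial history: JSONL event log + per-arm summary CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"events": outdir / "events.jsonl", "arms": outdir / "arms.csv"}
    for p in paths.values():
        _check_overwrite(p, force)
    with paths["events"].open("w") as fh:
        for ev in history.events:
            fh.write(json.dumps({"index": ev.index, "kind": ev.kind,
                                 "arm_id": ev.arm_id, "bf": ev.bf}) + "\n")
    rows = [
        {"arm_id": aid, "role": arm.role, "entry_index": arm.entry_index,
         "true_effect": arm.true_effect, "n": arm.n, "status": arm.status}
        for aid, arm in history.arms.items()
    ]
    pd.DataFrame(rows).to_csv(paths["arms"], index=False)
    return paths
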