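"""End-to-end wiring: simulate a trial, stream guidance over the logs,
analyze the outcomes, and write a reproducible artifact directory."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import feedback as fb
from . import simulate as sim
from . import tracker_io
from . import trial_stats as ts
from .errors import ConfigError, StageError

__all__ = ["RunConfig", "run_end_to_end", "make_fixtures", "analyze_dataset"]

STAGES = ("simulate", "logs", "guide", "summarize", "tests")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Loadable from a single YAML file with sections ``feedback``,
    ``phantom``, ``operator``, ``design`` (each optional, defaults apply)
    plus ``master_seed`` and ``outdir``.  The master seed is recorded in
    every output; referenced input files must exist at load time.
    """

    outdir: Path = Path("run_output")
    master_seed: int = 0
    feedback: fb.FeedbackConfig = field(default_factory=fb.FeedbackConfig)
    phantom: sim.PhantomConfig = field(default_factory=sim.PhantomConfig)
    operator: sim.OperatorModel = field(default_factory=sim.OperatorModel)
    design: sim.TrialDesign = field(default_factory=sim.TrialDesign)
    write_logs: bool = True
    verbosity: int = 1

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        try:
            kwargs = {}
            if "feedback" in raw:
                kwargs["feedback"] = fb.FeedbackConfig.from_mapping(raw.pop("feedback"))
            if "phantom" in raw:
                kwargs["phantom"] = sim.PhantomConfig(**raw.pop("phantom"))
            if "operator" in raw:
                kwargs["operator"] = sim.OperatorModel(**raw.pop("operator"))
            if "design" in raw:
                design = raw.pop("design")
                if "modalities" in design:
                    design["modalities"] = tuple(design["modalities"])
                kwargs["design"] = sim.TrialDesign(**design)
            if "outdir" in raw:
                kwargs["outdir"] = Path(raw.pop("outdir"))
            for key in ("master_seed", "write_logs", "verbosity"):
                if key in raw:
                    kwargs[key] = raw.pop(key)
            if raw:
                raise ConfigError(f"{path}: unknown config keys {sorted(raw)}")
            kwargs.update(overrides)
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def analyze_dataset(df, outdir: Path) -> None:
    """Write the three summary tables and the test/robustness results for a
    trial dataframe (one row per attempt)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    df["guidance"] = df["guided"].map({True: "GUIDED", False: "UNGUIDED"})

    trace_lines: list[str] = []
    test_records = []
    for outcome in ts.OUTCOMES:
        # Staff-group comparison across all modalities (two-group, rank-sum).
        staff = ts.summarize(
            df, outcome, "staff_group",
            diff_between=("LABORATORY", "HOSPITAL"), test="wilcoxon",
        )
        staff.to_csv(outdir / f"summary_staff_{outcome}.csv", index=False,
                     float_format="%.6f")
        # Guided vs unguided (type-III ANOVA on the unbalanced 120/40 split).
        guided = ts.summarize(
            df, outcome, "guidance",
            diff_between=("UNGUIDED", "GUIDED"), test="anova",
        )
        guided.to_csv(outdir / f"summary_guidance_{outcome}.csv", index=False,
                      float_format="%.6f")
        # Per-modality summary, omnibus, pairwise, robustness.
        modal = ts.summarize(df, outcome, "modality")
        modal.to_csv(outdir / f"summary_modality_{outcome}.csv", index=False,
                     float_format="%.6f")
        omni = ts.omnibus(df, outcome, "modality")
        test_records.append({"outcome": outcome, **omni.to_record()})
        pw = ts.pairwise(df, outcome, "modality")
        pw.insert(0, "outcome", outcome)
        pw.to_csv(outdir / f"pairwise_{outcome}.csv", index=False,
                  float_format="%.6g")
        robust, trace = ts.robustness(df, outcome, "modality")
        robust.insert(0, "outcome", outcome)
        robust.to_csv(outdir / f"robustness_{outcome}.csv", index=False)
        trace_lines.append(f"== {outcome} ==")
        trace_lines.extend(trace)

    import pandas as pd

    pd.DataFrame(test_records).to_csv(outdir / "omnibus_tests.csv", index=False)
    (outdir / "decision_trace.txt").write_text("\n".join(trace_lines) + "\n")


def run_end_to_end(config: RunConfig) -> Path:
    """Run simulate → logs → guide → summarize → tests and write everything
    plus a manifest into ``config.outdir``.  Byte-identical outputs for
    identical config + seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stages": {},
        "config": {
            "feedback": dataclasses.asdict(config.feedback),
            "phantom": dataclasses.asdict(config.phantom),
            "operator": dataclasses.asdict(config.operator),
            "design": dataclasses.asdict(config.design),
        },
    }

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        manifest["stages"][name] = {
            "status": "complete",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        if config.verbosity > 0:
            print(f"[{name}] complete ({manifest['stages'][name]['seconds']} s)")
        return result

    dataset = _run_stage(
        "simulate",
        lambda: sim.simulate_trial(
            design=config.design,
            operator=config.operator,
            phantom_cfg=config.phantom,
            feedback_cfg=config.feedback,
            master_seed=config.master_seed,
            keep_logs=config.write_logs,
        ),
    )
    df = dataset.to_dataframe()

    def _write_logs():
        if not config.write_logs:
            return
        logdir = outdir / "logs"
        logdir.mkdir(exist_ok=True)
        for outcome, log in zip(dataset.outcomes, dataset.logs):
            name = f"{outcome.participant_id}_a{outcome.order_index}_{outcome.modality}"
            tracker_io.write_log(log, logdir / f"{name}.csv")

    _run_stage("logs", _write_logs)

    def _guide():
        if not config.write_logs:
            return
        streamdir = outdir / "guidance"
        streamdir.mkdir(exist_ok=True)
        for outcome, log in zip(dataset.outcomes, dataset.logs):
            states = fb.guidance_stream(log, config.feedback)
            name = f"{outcome.participant_id}_a{outcome.order_index}_{outcome.modality}"
            fb.write_states(states, streamdir / f"{name}.jsonl")

    _run_stage("guide", _guide)

    _run_stage("summarize", lambda: dataset.to_csv(outdir / "trial.csv"))
    _run_stage("tests", lambda: analyze_dataset(df, outdir / "analysis"))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def make_fixtures(seed: int = 0, outdir: Path = Path("fixtures")) -> Path:
    """Generate a tiny deterministic dataset for tests and documentation:
    a 2-participant trial (one per staff group) with per-attempt tracker
    logs and the trial CSV."""
    config = RunConfig(
        outdir=Path(outdir),
        master_seed=seed,
        design=sim.TrialDesign(n_participants_per_group=1),
        verbosity=0,
    )
    return run_end_to_end(config)
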