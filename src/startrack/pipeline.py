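"""End-to-end pipeline: simulate (or ingest) -> score -> analyze -> report.

A run writes, under the output directory: the trials and scored-trials
CSVs, analysis reports as JSON and text tables, and a run manifest
recording the seed, package version, configuration and SHA-256 digests
of every artifact.  Identical configuration and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .integrated_measure import integrated_measures, write_scored_trials
from .randomization import generate_schedule, write_schedule
from .report import render_reliability, render_validity, result_to_json
from .reliability import analyze_retest
from .synthetic_data import (
    SimulationConfig,
    simulate_retest_study,
    simulate_validity_study,
)
from .trial_model import read_trials, write_trials
from .validity import analyze_validity

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("startrack")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full synthetic-study pipeline run."""

    out_dir: Path
    seed: int = 0
    n_validity_subjects: int = 20
    n_retest_subjects: int = 11
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    #: read trials from this CSV instead of simulating (phase inferred)
    trials_csv: Path | None = None
    adjust_ci: bool = True
    latin_square: bool = False

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text(encoding="utf-8"))
        sim = data.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline keys in {path}: {sorted(unknown)}")
        if "out_dir" in data:
            data["out_dir"] = Path(data["out_dir"])
        if data.get("trials_csv"):
            data["trials_csv"] = Path(data["trials_csv"])
        data["simulation"] = SimulationConfig(**sim)
        data.update(overrides)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the manifest dictionary.

    Stages: randomize -> simulate (or ingest) -> score -> analyze ->
    render.  Any stage error is re-raised annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d out=%s", config.seed, out)
    artifacts: dict[str, str] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.trials_csv is not None:
        trials = _stage("ingest", lambda: read_trials(config.trials_csv))
        phases = {t.phase for t in trials}
        studies = {p: [t for t in trials if t.phase == p] for p in phases}
    else:
        sim_validity = dataclasses.replace(
            config.simulation, n_subjects=config.n_validity_subjects, seed=config.seed
        )
        sim_retest = dataclasses.replace(
            config.simulation, n_subjects=config.n_retest_subjects, seed=config.seed + 1
        )
        schedule = _stage(
            "randomize",
            lambda: generate_schedule(
                config.n_validity_subjects, config.seed, config.latin_square
            ),
        )
        write_schedule(schedule, out / "schedule.csv")
        artifacts["schedule.csv"] = _sha256(out / "schedule.csv")
        studies = {
            "validity": _stage(
                "simulate", lambda: simulate_validity_study(sim_validity, schedule)
            ),
            "retest": _stage("simulate", lambda: simulate_retest_study(sim_retest)),
        }

    results: dict[str, dict] = {}
    for phase, trials in sorted(studies.items()):
        write_trials(trials, out / f"trials_{phase}.csv")
        artifacts[f"trials_{phase}.csv"] = _sha256(out / f"trials_{phase}.csv")
        scored = _stage("score", lambda t=trials: integrated_measures(list(t)))
        write_scored_trials(scored, out / f"scored_{phase}.csv")
        artifacts[f"scored_{phase}.csv"] = _sha256(out / f"scored_{phase}.csv")
        if phase == "validity":
            result = _stage(
                "analyze",
                lambda t=trials: analyze_validity(t, adjust_ci=config.adjust_ci),
            )
            text = render_validity(result)
        else:
            result = _stage("analyze", lambda t=trials: analyze_retest(t))
            text = render_reliability(result)
        (out / f"report_{phase}.json").write_text(
            result_to_json(result) + "\n", encoding="utf-8"
        )
        (out / f"report_{phase}.txt").write_text(text + "\n", encoding="utf-8")
        artifacts[f"report_{phase}.json"] = _sha256(out / f"report_{phase}.json")
        artifacts[f"report_{phase}.txt"] = _sha256(out / f"report_{phase}.txt")
        results[phase] = result.to_dict()
        log.info("analyzed %s study (%d trials)", phase, len(trials))

    manifest = {
        "package": "startrack",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "n_validity_subjects": config.n_validity_subjects,
            "n_retest_subjects": config.n_retest_subjects,
            "adjust_ci": config.adjust_ci,
            "latin_square": config.latin_square,
            "simulation": dataclasses.asdict(config.simulation),
            "trials_csv": str(config.trials_csv) if config.trials_csv else None,
        },
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info("pipeline done: %d artifacts", len(artifacts))
    return {"manifest": manifest, "results": results}
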