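"""End-to-end orchestration: generate/load -> fit -> census -> MIS -> report.

A :class:`RunConfig` collects every knob of the analysis (paths,
fitting, simulation, and intervention blocks, plus one master seed).
:func:`run_pipeline` executes the stages in order, writes all tabular
outputs as CSV/TSV into the output directory, and finishes with a JSON
manifest echoing the configuration, per-stage wall-clock timings, and a
content digest for every output file.  The master seed deterministically
derives one sub-seed per stage, so a fixed (config, seed) pair always
produces identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .dynamics import attractor_census_frame, sample_attractors
from .fitting import (
    CandidateModels,
    alignment_error,
    error_report_frame,
    fit_network,
    models_to_frame,
    per_trajectory_error,
)
from .intervention import consensus_interventions
from .network import (
    Domains,
    LogicNetwork,
    NetworkValidationError,
    load_adherence_fixture,
    parse_network,
    write_parameters,
)
from .synthetic import (
    generate_ground_truth,
    read_trajectories,
    simulate_cohort,
    write_sidecar,
    write_trajectories,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "PipelineError",
    "UnsatisfiableFitError",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class UnsatisfiableFitError(PipelineError):
    """No candidate model met the coverage threshold."""


@dataclass
class FittingConfig:
    K: int = 1
    coverage_min: float = 0.75
    max_models: int = 200
    theta_domain: tuple[int, ...] | None = None
    weight_domain: tuple[int, ...] = (1, 2)

    def domains(self) -> Domains:
        theta = tuple(self.theta_domain) if self.theta_domain is not None else None
        return Domains(theta=theta, weight=tuple(self.weight_domain))


@dataclass
class SimulationConfig:
    n_inits: int = 1000
    max_steps: int = 50


@dataclass
class InterventionConfig:
    max_size: int = 2
    hold_steps: int = 5
    noise_prob: float = 0.05
    n_replicates: int = 100
    consensus_models: int | None = None  # cap on models entering consensus


@dataclass
class SyntheticConfig:
    n_participants: int = 82
    n_assessments: tuple[int, int] = (3, 7)
    noise_rate: float = 0.0
    missing_rate: float = 0.0
    steps_between: int = 1


@dataclass
class RunConfig:
    """Full run configuration; round-trips through YAML unchanged."""

    output_dir: str = "results"
    network: str = "fixture"  # path to a network TSV, or the packaged circuit
    trajectories: str | None = None  # CSV path; None -> synthetic generation
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    intervention: InterventionConfig = field(default_factory=InterventionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.fitting.K < 1:
            raise NetworkValidationError("fitting.K must be >= 1")
        if not 0 < self.fitting.coverage_min <= 1:
            raise NetworkValidationError("fitting.coverage_min must lie in (0, 1]")
        if self.fitting.max_models < 1:
            raise NetworkValidationError("fitting.max_models must be >= 1")
        if self.simulation.n_inits < 1 or self.simulation.max_steps < 1:
            raise NetworkValidationError("simulation sizes must be >= 1")
        if self.intervention.max_size < 1 or self.intervention.hold_steps < 1:
            raise NetworkValidationError("intervention sizes must be >= 1")
        if not 0 <= self.intervention.noise_prob < 1:
            raise NetworkValidationError("intervention.noise_prob must lie in [0, 1)")
        sy = self.synthetic
        if not (0 <= sy.noise_rate < 1 and 0 <= sy.missing_rate < 1):
            raise NetworkValidationError("synthetic rates must lie in [0, 1)")
        if self.network != "fixture" and not Path(self.network).exists():
            raise NetworkValidationError(f"network file not found: {self.network}")
        if self.trajectories is not None and not Path(self.trajectories).exists():
            raise NetworkValidationError(
                f"trajectory file not found: {self.trajectories}"
            )

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "output_dir": self.output_dir,
            "network": self.network,
            "trajectories": self.trajectories,
            "synthetic": convert(self.synthetic),
            "fitting": convert(self.fitting),
            "simulation": convert(self.simulation),
            "intervention": convert(self.intervention),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        def build(factory, block):
            block = dict(block or {})
            for key in ("n_assessments", "theta_domain", "weight_domain"):
                if key in block and isinstance(block[key], list):
                    block[key] = tuple(block[key])
            return factory(**block)

        return cls(
            output_dir=data.get("output_dir", "results"),
            network=data.get("network", "fixture"),
            trajectories=data.get("trajectories"),
            synthetic=build(SyntheticConfig, data.get("synthetic")),
            fitting=build(FittingConfig, data.get("fitting")),
            simulation=build(SimulationConfig, data.get("simulation")),
            intervention=build(InterventionConfig, data.get("intervention")),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Counts and paths summarizing one pipeline run."""

    output_dir: str
    n_models: int
    best_coverage: float
    n_attractors: int
    n_nonadherent: int
    n_rescued: int
    unanimous_strategies: list[str]
    true_model_recovered: bool | None
    files: dict[str, str]
    timings: dict[str, float]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_network(spec: str) -> LogicNetwork:
    if spec == "fixture":
        return load_adherence_fixture()
    return parse_network(spec)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write results under ``config.output_dir``.

    Stage order: network -> trajectories (load or synthesize) -> fit ->
    attractor census -> consensus MIS -> manifest.  Any stage failure
    raises :class:`PipelineError` naming the stage; an empty candidate
    set raises :class:`UnsatisfiableFitError` with the best achievable
    coverage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    files: dict[str, Path] = {}
    seed_seq = np.random.SeedSequence(config.seed)
    s_truth, s_cohort, s_census, s_consensus = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(4)
    )

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Timer()

    with stage("network"):
        net = load_network(config.network)

    true_params = None
    with stage("trajectories"):
        if config.trajectories is not None:
            trajs = read_trajectories(config.trajectories, net)
        else:
            sy = config.synthetic
            true_params = generate_ground_truth(
                net, seed=s_truth, domains=config.fitting.domains()
            )
            trajs = simulate_cohort(
                net,
                true_params,
                n_participants=sy.n_participants,
                n_assessments=sy.n_assessments,
                noise_rate=sy.noise_rate,
                missing_rate=sy.missing_rate,
                seed=s_cohort,
                steps_between=sy.steps_between,
            )
            files["trajectories"] = out / "trajectories.csv"
            write_trajectories(trajs, net, files["trajectories"])
            files["true_parameters"] = out / "true_parameters.tsv"
            write_parameters(net, true_params, files["true_parameters"])
            files["trajectories_sidecar"] = out / "trajectories.meta.yaml"
            write_sidecar(
                files["trajectories_sidecar"],
                {
                    "n_participants": sy.n_participants,
                    "n_assessments": list(sy.n_assessments)
                    if isinstance(sy.n_assessments, tuple)
                    else sy.n_assessments,
                    "noise_rate": sy.noise_rate,
                    "missing_rate": sy.missing_rate,
                    "steps_between": sy.steps_between,
                    "seed": config.seed,
                },
            )

    with stage("fit"):
        candidates = fit_network(
            net,
            trajs,
            K=config.fitting.K,
            domains=config.fitting.domains(),
            coverage_min=config.fitting.coverage_min,
            max_models=config.fitting.max_models,
        )
        if not candidates.models:
            raise UnsatisfiableFitError(
                "fit",
                f"no model reached coverage {config.fitting.coverage_min:.2f}; "
                f"best achievable coverage {candidates.best_coverage:.3f}",
            )
        files["models"] = out / "models.tsv"
        models_to_frame(net, candidates).to_csv(files["models"], sep="\t", index=False)
        best = candidates.models[0]
        err = alignment_error(net, best, trajs, K=config.fitting.K)
        files["error_report"] = out / "error_report.csv"
        error_report_frame(err).to_csv(files["error_report"], index=False)
        balance = per_trajectory_error(net, best, trajs, K=config.fitting.K)
        files["trajectory_error"] = out / "per_trajectory_error.csv"
        with open(files["trajectory_error"], "wt", encoding="utf-8") as fh:
            fh.write("participant_id,error,n_scored\n")
            for pid, (e, n) in sorted(balance.items()):
                fh.write(f"{pid},{e},{n}\n")
        recovered = (
            candidates.admits(net, true_params) if true_params is not None else None
        )

    with stage("attractors"):
        n_consensus = config.intervention.consensus_models
        consensus_pool = candidates.models[: n_consensus or len(candidates.models)]
        census_frames = []
        attractors_by_model = []
        census_seeds = np.random.SeedSequence(s_census).spawn(len(consensus_pool))
        for m_i, params in enumerate(consensus_pool):
            sample = sample_attractors(
                net,
                params,
                n_inits=config.simulation.n_inits,
                max_steps=config.simulation.max_steps,
                seed=np.random.default_rng(census_seeds[m_i]),
            )
            attractors_by_model.append(sample.attractors)
            frame = attractor_census_frame(net, sample.attractors)
            frame.insert(0, "model_id", m_i)
            frame["unconverged_fraction"] = sample.unconverged_fraction
            census_frames.append(frame)
        import pandas as pd

        census = pd.concat(census_frames, ignore_index=True)
        files["attractors"] = out / "attractor_census.csv"
        census.to_csv(files["attractors"], index=False)
        distinct = {a.key() for atts in attractors_by_model for a in atts}
        nonadh = {
            a.key()
            for atts in attractors_by_model
            for a in atts
            if a.adherent is False
        }

    with stage("mis"):
        consensus = consensus_interventions(
            net,
            consensus_pool,
            seed=s_consensus,
            n_inits=config.simulation.n_inits,
            max_steps=config.simulation.max_steps,
            max_size=config.intervention.max_size,
            hold_steps=config.intervention.hold_steps,
            attractors_by_model=attractors_by_model,
        )
        files["mis_table"] = out / "mis_table.csv"
        consensus.table.to_csv(files["mis_table"], index=False)

    files["config"] = out / "config.yaml"
    config.to_yaml(files["config"])
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
        "counts": {
            "n_models": candidates.n_models,
            "best_coverage": candidates.best_coverage,
            "n_attractors": len(distinct),
            "n_nonadherent": len(nonadh),
            "n_rescued": consensus.n_rescued_states,
        },
        "files": {name: _digest(path) for name, path in files.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return RunReport(
        output_dir=str(out),
        n_models=candidates.n_models,
        best_coverage=candidates.best_coverage,
        n_attractors=len(distinct),
        n_nonadherent=len(nonadh),
        n_rescued=consensus.n_rescued_states,
        unanimous_strategies=consensus.unanimous_strategies,
        true_model_recovered=recovered,
        files={name: str(path) for name, path in files.items()},
        timings=timings,
    )
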