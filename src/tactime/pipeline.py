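"""Pipeline orchestration: configuration, stage execution and reporting.

A :class:`RunConfig` carries the stage list, output directory, seed and
per-module overrides; every numeric default equals the design value used
throughout the package (10-ms fit bins, 1-ms PSTH steps, 25-ms smoothing
sigma, 2.2-STD onset threshold, 1000 resamples, G = 5 mixture classes with
concentration 1e-6, tau regularization weight 0.01 centered at 600 ms,
5000-neuron populations with 100 proxies at full scale, 200 neurons at desk
scale).  ``run_pipeline`` executes the requested stages in dependency order,
logging the seed and wall time of each, and all outputs are plain CSV/JSON
that round-trip through the package's own readers.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import recovery, synthetic
from .lnp import Condition
from .percept import LeakyIntegratorObserver, neurometric_curve
from .psychometrics import bias_measure, congruence_accuracy, fit_psychometric
from .stimuli import (
    build_trial_matrix,
    duration_levels,
    generate_seed_set,
    stimulus_to_frame,
    trials_to_frame,
)

STAGES = (
    "simulate-stimuli",
    "simulate-behavior",
    "fit-percept",
    "analyze-behavior",
    "analyze-neural",
    "recover",
)


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "tactime_out"
    seed: int = 0
    population_size: int = synthetic.DESK_POPULATION_SIZE
    n_trials_per_cell: int = synthetic.DESK_TRIALS_PER_CELL
    coupling: float = synthetic.DEFAULT_COUPLING
    n_stimulus_seeds: int = 10
    options: dict = field(default_factory=dict)

    def validate(self):
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid stages are {STAGES}")
        if self.population_size < 1 or self.n_trials_per_cell < 1:
            raise ValueError("population_size and n_trials_per_cell must be >= 1")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text)).validate()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    to ``report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = dict(config=dataclasses.asdict(config), stages={})
    gt = synthetic.GroundTruth(
        coupling=config.coupling,
        population_size=config.population_size,
        population_seed=config.seed + 1,
    )
    table = None
    observer_fit = None
    for stage in config.stages:
        t0 = time.perf_counter()
        entry = dict(seed=config.seed)
        if stage == "simulate-stimuli":
            stims = generate_seed_set(
                sigma=64.0 / float(np.sqrt(2.0 / np.pi)),  # nominal intensity 64 mm/s
                duration_ms=334.0,
                n_seeds=config.n_stimulus_seeds,
                base_seed=config.seed,
            )
            frame = stimulus_to_frame(stims[0])
            frame.to_csv(out / "example_stimulus.csv", index=False)
            trials_to_frame(build_trial_matrix()).to_csv(
                out / "trial_matrix.csv", index=False
            )
            entry["outputs"] = ["example_stimulus.csv", "trial_matrix.csv"]
        elif stage == "simulate-behavior":
            table = synthetic.make_behavior_session(
                gt, config.n_trials_per_cell, rng=config.seed
            )
            table.to_csv(out / "behavior.csv", index=False)
            entry["outputs"] = ["behavior.csv"]
        elif stage == "fit-percept":
            if table is None:
                table = synthetic.make_behavior_session(
                    gt, config.n_trials_per_cell, rng=config.seed
                )
            cells = recovery.percept_cells_from_truth(gt, table)
            observer_fit = LeakyIntegratorObserver(random_state=config.seed).fit(cells)
            (out / "percept_params.json").write_text(
                json.dumps(observer_fit.params_.to_dict(), indent=2)
            )
            entry["outputs"] = ["percept_params.json"]
            entry["params"] = observer_fit.params_.to_dict()
        elif stage == "analyze-behavior":
            if table is None:
                table = synthetic.make_behavior_session(
                    gt, config.n_trials_per_cell, rng=config.seed
                )
            fit = fit_psychometric(table[table.light == "none"])
            bias = bias_measure(table[table.light == "none"])
            cong = congruence_accuracy(table[table.light == "none"], rng=config.seed)
            results = dict(psychometric=fit.params(), congruence=cong)
            (out / "behavior_analysis.json").write_text(json.dumps(results, indent=2))
            bias.to_csv(out / "bias_by_delta_i.csv")
            entry["outputs"] = ["behavior_analysis.json", "bias_by_delta_i.csv"]
        elif stage == "analyze-neural":
            if observer_fit is None:
                params = gt.observer
            else:
                params = observer_fit.params_
            profiles = {}
            for T in duration_levels():
                for light in ("none", "excite_stim2"):
                    opto = 1.0 if light == "excite_stim2" else 0.0
                    profiles[(float(T), light)] = gt.drive(float(T), 64.0, opto)
            profiles[(334.0, "none")] = gt.drive(334.0, 64.0, 0.0)
            design = build_trial_matrix(
                intensities=[64.0], light_conditions=("none", "excite_stim2")
            )
            curve = neurometric_curve(profiles, params, design)
            curve.to_csv(out / "neurometric_curve.csv", index=False)
            entry["outputs"] = ["neurometric_curve.csv"]
        elif stage == "recover":
            rec = synthetic.recovery_experiment(dict(seed=config.seed))
            (out / "recovery_report.json").write_text(json.dumps(rec, indent=2))
            entry["outputs"] = ["recovery_report.json"]
            entry["all_passed"] = rec["all_passed"]
        entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = entry
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
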