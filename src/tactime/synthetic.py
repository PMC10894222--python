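"""Ground-truth generators emulating the study's data structures.

Everything downstream of the recording hardware is reproducible here with
known parameters: behavioral sessions are drawn from a leaky-integrator
observer reading a known surrogate vS1 population, and spike rasters are
drawn from known LNP neuron parameters, under light-off and light-on
conditions.  Each generator is deterministic under a fixed seed and fully
described by its serialized :class:`GroundTruth` record, so every fitting
stage can be tested for parameter recovery without the deposited recordings.

The irrelevant-feature coupling (intensity biasing perceived duration) is
realized as an intensity-dependent gain on the vibrissal drive: a stimulus
of intensity I scales the mechanoreceptor currents by ``(I / I_ref) **
coupling``.  Stronger vibrations then drive more spikes into the integrator
and feel longer — the mechanism under test — with ``coupling`` a scalar
knob (0 disables the bias).

Default desk-scale conditions: a 200-neuron population sampled from a
three-class mixture (transient/light-sensitive, sustained, weakly
responsive), 100 trials per stimulus cell, the 7 x 7 psychometric design,
observer tau = 500 ms with lapse rate 0.1.  The background noise variance is
set so that no-light accuracy on non-easy comparisons is in the high-70s
percent range, matching trained-rat performance; the full-scale population
(5000 neurons, 100 proxies) is available through the size arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lnp import Condition, NeuronParams, SpikeRaster, simulate_spikes
from .percept import (
    PerceptParams,
    choice_probability,
    integrate_percept,
)
from .population import NeuronPopulationMixture, population_rate
from .stimuli import (
    DEFAULT_I1_MMS,
    DEFAULT_T1_MS,
    TrialSpec,
    build_trial_matrix,
    trials_to_frame,
)

DESK_POPULATION_SIZE = 200
DESK_TRIALS_PER_CELL = 100
DEFAULT_COUPLING = 0.10

_DEFAULT_WEIGHTS = (0.35, 0.45, 0.20)
# rows: (i0, i1_ss, i1_peak, i2_ss, i2_peak, i3_peak, lambda_max, upsilon)
_DEFAULT_MEANS = (
    (-0.6, 0.30, 1.6, 0.08, 0.25, -0.12, 0.060, 1.2),  # transient, light-driven
    (-0.4, 0.45, 1.1, 0.02, 0.07, 0.00, 0.080, 0.8),  # sustained sensory
    (-1.0, 0.10, 0.4, 0.01, 0.04, 0.00, 0.030, 1.0),  # weakly responsive
)
_DEFAULT_SDS = (
    (0.15, 0.08, 0.25, 0.06, 0.12, 0.08, 0.015, 0.25),
    (0.12, 0.10, 0.20, 0.03, 0.05, 0.03, 0.020, 0.18),
    (0.20, 0.05, 0.12, 0.02, 0.03, 0.02, 0.008, 0.20),
)


def default_mixture() -> NeuronPopulationMixture:
    """Three-class ground-truth mixture over the eight free LNP parameters."""
    covs = np.stack([np.diag(np.square(s)) for s in np.asarray(_DEFAULT_SDS)])
    return NeuronPopulationMixture.from_components(
        np.asarray(_DEFAULT_WEIGHTS), np.asarray(_DEFAULT_MEANS), covs
    )


def default_percept_params() -> PerceptParams:
    """Observer constants for the desk-scale population (see module notes)."""
    return PerceptParams(tau=500.0, mu_b=1.0, sigma2_b=5e4, p_l=0.1, b_l=0.5)


@dataclass
class GroundTruth:
    """Everything needed to regenerate a synthetic data set bit-for-bit."""

    observer: PerceptParams = field(default_factory=default_percept_params)
    coupling: float = DEFAULT_COUPLING
    mixture: NeuronPopulationMixture = field(default_factory=default_mixture)
    design: list[TrialSpec] = field(default_factory=build_trial_matrix)
    population_size: int = DESK_POPULATION_SIZE
    population_seed: int = 42
    reference_i: float = DEFAULT_I1_MMS

    _population: list[NeuronParams] | None = field(default=None, repr=False)
    _rate_cache: dict = field(default_factory=dict, repr=False)

    @property
    def population(self) -> list[NeuronParams]:
        if self._population is None:
            self._population = self.mixture.sample_neurons(
                self.population_size, rng=self.population_seed
            )
        return self._population

    def mechano_gain(self, intensity: float) -> float:
        return float((intensity / self.reference_i) ** self.coupling)

    def condition(
        self, duration_ms: float, intensity: float, opto_gain: float = 0.0, **kw
    ) -> Condition:
        return Condition(
            duration_ms,
            mechano_gain=self.mechano_gain(intensity),
            opto_gain=opto_gain,
            **kw,
        )

    def drive(self, duration_ms: float, intensity: float, opto_gain: float = 0.0):
        """Cached mean population rate profile over [0, T] (spikes/ms)."""
        key = (round(duration_ms, 6), round(intensity, 6), opto_gain)
        if key not in self._rate_cache:
            cond = self.condition(duration_ms, intensity, opto_gain)
            self._rate_cache[key] = population_rate(self.population, cond)[1]
        return self._rate_cache[key]

    def choice_probability(self, trial: TrialSpec) -> float:
        o1 = 1.0 if trial.light == "excite_stim1" else 0.0
        o2 = {"excite_stim2": 1.0, "inhibit_stim2": -1.0}.get(trial.light, 0.0)
        f1 = self.drive(trial.t1_ms, trial.i1, o1)
        f2 = self.drive(trial.t2_ms, trial.i2, o2)
        p1 = integrate_percept(f1, self.observer, trial.t1_ms)
        p2 = integrate_percept(f2, self.observer, trial.t2_ms)
        return choice_probability(p1, p2, self.observer)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            dict(
                observer=self.observer.to_dict(),
                coupling=self.coupling,
                mixture=json.loads(self.mixture.to_json()),
                design=trials_to_frame(self.design)[
                    ["T1", "T2", "I1", "I2", "light", "task"]
                ].to_dict("records"),
                population_size=self.population_size,
                population_seed=self.population_seed,
                reference_i=self.reference_i,
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        mix = NeuronPopulationMixture.from_components(
            d["mixture"]["weights"], d["mixture"]["means"], d["mixture"]["covariances"]
        )
        design = [
            TrialSpec(r["T1"], r["T2"], r["I1"], r["I2"], r["light"], r["task"])
            for r in d["design"]
        ]
        return cls(
            observer=PerceptParams(**d["observer"]),
            coupling=d["coupling"],
            mixture=mix,
            design=design,
            population_size=d["population_size"],
            population_seed=d["population_seed"],
            reference_i=d["reference_i"],
        )


def make_behavior_session(
    ground_truth: GroundTruth,
    n_trials_per_cell: int = DESK_TRIALS_PER_CELL,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a choice table from the observer's closed-form probabilities.

    One row per design cell with Binomial(n, p) "stimulus 2 greater" counts;
    the generating probability is kept in ``p_true``.
    """
    if len(ground_truth.design) == 0:
        raise ValueError("trial design is empty")
    rng = np.random.default_rng(rng)
    rows = []
    for trial in ground_truth.design:
        p = ground_truth.choice_probability(trial)
        k = int(rng.binomial(n_trials_per_cell, p))
        rows.append(
            dict(
                delta_t=trial.delta_t,
                delta_i=trial.delta_i,
                light=trial.light,
                n_trials=n_trials_per_cell,
                n_chose2=k,
                T1=trial.t1_ms,
                T2=trial.t2_ms,
                I1=trial.i1,
                I2=trial.i2,
                congruence=trial.congruence,
                task=trial.task,
                p_true=p,
            )
        )
    return pd.DataFrame(rows)


def make_raster_set(
    population: list[NeuronParams],
    conditions: dict,
    n_trials: int = DESK_TRIALS_PER_CELL,
    rng: int | np.random.Generator = 0,
) -> dict:
    """Per-neuron Poisson rasters for each labeled condition.

    ``conditions`` maps labels (e.g. ``(duration, intensity, light)``) to
    :class:`Condition` objects; at least one light-off condition must be
    included.  Returns label -> list of SpikeRaster (one per neuron).
    """
    if not any(not c.light_on for c in conditions.values()):
        raise ValueError("conditions must include at least one light-off condition")
    rng = np.random.default_rng(rng)
    out = {}
    for label, cond in conditions.items():
        out[label] = [
            simulate_spikes(p, cond, n_trials, rng) for p in population
        ]
    return out


def summed_raster(rasters: list[SpikeRaster]) -> SpikeRaster:
    """Population-summed raster (counts added across neurons per trial)."""
    counts = np.sum([r.counts for r in rasters], axis=0)
    r0 = rasters[0]
    return SpikeRaster(counts, r0.t_start_ms, r0.bin_ms, r0.condition)


def recovery_experiment(config: dict | None = None) -> dict:
    """End-to-end generate -> fit -> compare harness.

    ``config`` selects stages (default all) and scales; each stage reports
    the true and recovered quantities and a pass flag against its stated
    tolerance.  Stage failures surface with the stage name.
    """
    from . import recovery as _rec

    config = dict(config or {})
    stages = config.pop("stages", ("lnp", "mixture", "percept", "psychometric"))
    seed = config.pop("seed", 0)
    report = {}
    runners = dict(
        lnp=_rec.recover_lnp,
        mixture=_rec.recover_mixture,
        percept=_rec.recover_percept,
        psychometric=_rec.recover_psychometric,
    )
    for stage in stages:
        if stage not in runners:
            raise ValueError(f"unknown recovery stage {stage!r}")
        try:
            report[stage] = runners[stage](seed=seed, **config.get(stage, {}))
        except Exception as exc:  # surface the failing stage by name
            raise RuntimeError(f"recovery stage {stage!r} failed: {exc}") from exc
    report["all_passed"] = all(r.get("passed", False) for r in report.values())
    return report
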