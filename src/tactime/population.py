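"""Mixture model over neuron parameters and surrogate population drive.

Fitted neuron-parameter vectors (the eight free LNP parameters) are treated
as draws from a Dirichlet-process-like Gaussian mixture: a variational
Bayesian mixture with a Dirichlet weight prior, truncated at G = 5 classes
with concentration 1e-6, so that only as many classes as the data support
receive appreciable weight.  Sampling the fitted mixture yields arbitrarily
large surrogate populations (5000 neurons at full scale); the summed Poisson
spiking of the population under a stimulation condition is the drive
f_vS1(t) fed to the downstream integrator.

The decay constants and current onsets are population-level constants and are
excluded from the mixture space.  Gaussian draws that violate positivity of
lambda_max or upsilon are rejected and redrawn, with the rejection count kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.mixture import BayesianGaussianMixture

from .lnp import (
    FREE_PARAM_NAMES,
    Condition,
    NeuronParams,
    rate_profile,
)

DEFAULT_N_CLASSES = 5
DEFAULT_ALPHA = 1e-6
DEFAULT_POPULATION_SIZE = 5000
DEFAULT_N_PROXIES = 100

_LAMBDA_IDX = FREE_PARAM_NAMES.index("lambda_max")
_UPSILON_IDX = FREE_PARAM_NAMES.index("upsilon")


class NeuronPopulationMixture(BaseEstimator):
    """Variational Bayesian Gaussian mixture over 8-d neuron parameters.

    Attributes (after ``fit`` or ``from_components``)
    -------------------------------------------------
    weights_, means_, covariances_ : mixture components over the free
        parameter space (I0, I1_ss, I1_peak, I2_ss, I2_peak, I3_peak,
        lambda_max, upsilon).
    n_rejected_ : int
        Constraint-violating Gaussian draws discarded by the last ``sample``.
    """

    def __init__(
        self,
        n_classes: int = DEFAULT_N_CLASSES,
        alpha: float = DEFAULT_ALPHA,
        covariance_type: str = "full",
        max_iter: int = 500,
        n_init: int = 10,
        reg_covar: float = 1e-4,
        random_state: int = 0,
    ):
        self.n_classes = n_classes
        self.alpha = alpha
        self.covariance_type = covariance_type
        self.max_iter = max_iter
        self.n_init = n_init
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_neurons, n_params)")
        if X.shape[0] < self.n_classes + 1:
            raise ValueError(
                f"need at least n_classes + 1 = {self.n_classes + 1} parameter "
                f"vectors, got {X.shape[0]}; reduce n_classes"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter
            model = BayesianGaussianMixture(
                n_components=self.n_classes,
                weight_concentration_prior_type="dirichlet_process",
                weight_concentration_prior=self.alpha,
                covariance_type=self.covariance_type,
                max_iter=self.max_iter,
                n_init=self.n_init,
                reg_covar=self.reg_covar,
                random_state=self.random_state,
            ).fit(X)
        self.model_ = model
        self.weights_ = model.weights_
        self.means_ = model.means_
        self.covariances_ = self._full_covariances(model)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _full_covariances(model) -> np.ndarray:
        cov = model.covariances_
        if model.covariance_type == "full":
            return cov
        if model.covariance_type == "diag":
            return np.stack([np.diag(c) for c in cov])
        if model.covariance_type == "tied":
            return np.stack([cov] * model.n_components)
        raise ValueError(f"unsupported covariance type {model.covariance_type}")

    @classmethod
    def from_components(cls, weights, means, covariances) -> "NeuronPopulationMixture":
        """Build a mixture directly from known components (ground truth)."""
        weights = np.asarray(weights, dtype=float)
        if not np.all(weights >= 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        obj = cls(n_classes=len(weights))
        obj.weights_ = weights
        obj.means_ = np.asarray(means, dtype=float)
        obj.covariances_ = np.asarray(covariances, dtype=float)
        obj.n_features_in_ = obj.means_.shape[1]
        return obj

    def predict(self, X):
        """Most probable class per parameter vector (fitted mixtures only)."""
        return self.model_.predict(np.asarray(X, dtype=float))

    def sample_parameters(
        self, n: int, rng: int | np.random.Generator = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw n parameter vectors (with class labels) by rejection.

        Positivity of lambda_max and upsilon is enforced by redrawing
        violating vectors; the number of rejected draws is stored in
        ``n_rejected_``.
        """
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n!r}")
        rng = np.random.default_rng(rng)
        chol = [np.linalg.cholesky(c) for c in self.covariances_]
        out = np.empty((n, self.n_features_in_))
        labels = np.empty(n, dtype=int)
        filled, rejected = 0, 0
        while filled < n:
            todo = n - filled
            ks = rng.choice(len(self.weights_), size=todo, p=self.weights_)
            z = rng.standard_normal((todo, self.n_features_in_))
            draws = np.stack(
                [self.means_[k] + chol[k] @ z[j] for j, k in enumerate(ks)]
            )
            ok = (draws[:, _LAMBDA_IDX] > 0) & (draws[:, _UPSILON_IDX] > 0)
            keep = int(ok.sum())
            out[filled : filled + keep] = draws[ok]
            labels[filled : filled + keep] = ks[ok]
            filled += keep
            rejected += todo - keep
        self.n_rejected_ = rejected
        return out, labels

    def sample_neurons(
        self,
        n: int = DEFAULT_POPULATION_SIZE,
        rng: int | np.random.Generator = 0,
        **fixed,
    ) -> list[NeuronParams]:
        """Sample a surrogate population, attaching the fixed time constants."""
        vecs, _ = self.sample_parameters(n, rng)
        return [NeuronParams.from_free_vector(v, **fixed) for v in vecs]

    def to_json(self) -> str:
        return json.dumps(
            dict(
                weights=self.weights_.tolist(),
                means=self.means_.tolist(),
                covariances=self.covariances_.tolist(),
                param_names=list(FREE_PARAM_NAMES),
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "NeuronPopulationMixture":
        d = json.loads(text)
        return cls.from_components(d["weights"], d["means"], d["covariances"])


def fit_mixture(param_vectors, **kwargs) -> NeuronPopulationMixture:
    """Fit the Dirichlet-weighted Gaussian mixture to fitted neuron vectors."""
    return NeuronPopulationMixture(**kwargs).fit(np.asarray(param_vectors))


def sample_population(
    mixture: NeuronPopulationMixture,
    n: int = DEFAULT_POPULATION_SIZE,
    rng: int | np.random.Generator = 0,
) -> list[NeuronParams]:
    return mixture.sample_neurons(n, rng)


@dataclass
class PopulationDrive:
    """Summed spike count of the population per 1-ms bin, per trial."""

    counts: np.ndarray  # (n_trials, n_bins) summed over neurons
    t_start_ms: float
    bin_ms: float
    condition: Condition

    @property
    def times(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.counts.shape[1]) * self.bin_ms

    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)


def population_rate(
    population: list[NeuronParams], condition: Condition, bin_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Expected summed rate (spikes/ms) across the population."""
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    edges, total = None, None
    for p in population:
        edges, r = rate_profile(p, condition, bin_ms)
        total = r if total is None else total + r
    return edges, total


def population_drive(
    population: list[NeuronParams],
    condition: Condition,
    rng: int | np.random.Generator = 0,
    n_trials: int = 1,
    bin_ms: float = 1.0,
) -> PopulationDrive:
    """Sample the summed Poisson drive f_vS1(t) of the population.

    The sum of independent Poisson counts is Poisson with the summed rate, so
    the drive is drawn directly from the population rate profile.
    """
    rng = np.random.default_rng(rng)
    edges, total = population_rate(population, condition, bin_ms)
    counts = rng.poisson(total * bin_ms, size=(n_trials, total.size))
    return PopulationDrive(counts, condition.t_start_ms, bin_ms, condition)
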