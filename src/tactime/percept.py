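"""Leaky-integrator percept of elapsed stimulus duration and the choice model.

The percept Y obeys dY/dt = -Y/tau + f(t), where f(t) is the summed vS1
drive plus a Gaussian background xi with stationary mean mu_b and variance
sigma2_b.  With Poisson drive of mean rate f_vS1(t), Y(t) is Gaussian with

    E[Y(t)]   = E[Y(0)] e^{-t/tau} + mu_b (1 - e^{-t/tau})
                + sum_{t'} e^{-(t - t')/tau} f_vS1(t') dt'
    Var[Y(t)] = Var[Y(0)] e^{-2t/tau} + sigma2_b (1 - e^{-2t/tau})
                + sum_{t'} e^{-2(t - t')/tau} f_vS1(t') dt'

(the Poisson drive contributes its rate to both moments; the sums run over
1-ms steps).  Y at each stimulus's offset is the perceived duration; the
probability of judging stimulus 2 longer is

    P(T2 > T1) = p_L b_L + (1 - p_L) [1/2 + 1/2 erf(d')],
    d' = (E[Y(T2)] - E[Y(T1)]) / sqrt(2 (Var[Y(T1)] + Var[Y(T2)]))

with lapse probability p_L and lapse bias b_L.  ``LeakyIntegratorObserver``
fits (tau, mu_b, sigma2_b, p_L, b_L) to choice counts by maximum likelihood
with an L2 pull on tau (weight 0.01, center 600 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erf, expit, logit
from sklearn.base import BaseEstimator

DEFAULT_REG_WEIGHT = 0.01
DEFAULT_REG_CENTER_MS = 600.0


@dataclass(frozen=True)
class PerceptParams:
    """Integrator and lapse parameters."""

    tau: float  # integrator time constant, ms
    mu_b: float = 0.0  # stationary mean of the background component
    sigma2_b: float = 0.0  # stationary variance of the background component
    p_l: float = 0.0  # lapse probability
    b_l: float = 0.5  # lapse choice bias toward "stimulus 2 longer"

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")
        if self.sigma2_b < 0:
            raise ValueError(f"sigma2_b must be >= 0, got {self.sigma2_b!r}")
        for name in ("p_l", "b_l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PerceptDistribution:
    """Gaussian distribution of Y at stimulus offset."""

    mean: float
    variance: float
    duration_ms: float

    def __post_init__(self):
        if self.variance < -1e-9:
            raise ValueError(f"variance must be >= 0, got {self.variance!r}")


def integrate_percept(
    drive_rate: np.ndarray,
    params: PerceptParams,
    duration_ms: float | None = None,
    y0_mean: float = 0.0,
    y0_var: float = 0.0,
    dt_ms: float = 1.0,
) -> PerceptDistribution:
    """Closed-form mean and variance of Y at stimulus offset.

    ``drive_rate`` is the mean summed vS1 rate in spikes/ms on a 1-ms grid
    covering [0, T]; the exponential-kernel integrals are evaluated as
    discrete sums at the bin centers.
    """
    f = np.asarray(drive_rate, dtype=float)
    if duration_ms is None:
        duration_ms = f.size * dt_ms
    n = int(round(duration_ms / dt_ms))
    f = f[:n]
    tau = params.tau
    t = duration_ms
    centers = (np.arange(f.size) + 0.5) * dt_ms
    k1 = np.exp(-(t - centers) / tau)
    mean = (
        y0_mean * np.exp(-t / tau)
        + params.mu_b * (1.0 - np.exp(-t / tau))
        + float(np.sum(k1 * f)) * dt_ms
    )
    var = (
        y0_var * np.exp(-2.0 * t / tau)
        + params.sigma2_b * (1.0 - np.exp(-2.0 * t / tau))
        + float(np.sum(k1 * k1 * f)) * dt_ms
    )
    return PerceptDistribution(mean, var, duration_ms)


def choice_probability(
    percept1: PerceptDistribution,
    percept2: PerceptDistribution,
    params: PerceptParams,
) -> float:
    """P(judged stimulus 2 longer) with lapses."""
    total_var = percept1.variance + percept2.variance
    if total_var <= 0:
        raise ValueError("degenerate comparison: both percept variances are zero")
    dprime = (percept2.mean - percept1.mean) / np.sqrt(2.0 * total_var)
    attended = 0.5 + 0.5 * erf(dprime)
    return float(params.p_l * params.b_l + (1.0 - params.p_l) * attended)


def simulate_percept_trials(
    drive_counts: np.ndarray,
    params: PerceptParams,
    rng: int | np.random.Generator = 0,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Stepwise simulation of the integrator on sampled spike-count drives.

    Independent Monte-Carlo oracle for the closed-form moments: per 1-ms
    step, Y decays by exp(-dt/tau), gains the summed spike count of the step
    (entered at the bin midpoint, i.e. with a half-step of decay) and a
    Gaussian background increment whose stationary mean and variance are
    (mu_b, sigma2_b).  Returns Y at the final step for each trial.
    """
    rng = np.random.default_rng(rng)
    counts = np.atleast_2d(np.asarray(drive_counts, dtype=float))
    n_trials, n_bins = counts.shape
    d = np.exp(-dt_ms / params.tau)
    d_half = np.exp(-0.5 * dt_ms / params.tau)
    # background increment sized so its stationary moments equal (mu_b, sigma2_b)
    bg_mu = params.mu_b * (1.0 - d) / d_half
    bg_sd = np.sqrt(params.sigma2_b * (1.0 - d * d)) / d_half
    y = np.zeros(n_trials)
    for b in range(n_bins):
        xi = rng.normal(bg_mu, bg_sd, size=n_trials) if bg_sd > 0 else bg_mu
        y = y * d + (counts[:, b] + xi) * d_half
    return y


class LeakyIntegratorObserver(BaseEstimator):
    """MLE of the percept parameters from drive profiles and choices.

    The observer is fit to aggregated choice cells: each cell supplies the
    mean drive profiles of the two stimuli, the number of trials and the
    number of "stimulus 2 longer" choices.  When several population proxies
    are supplied the log-likelihood is summed over proxies (a common
    parameter set across proxies).

    Parameters
    ----------
    reg_weight, reg_center_ms : float
        L2 pull on tau, applied as ``reg_weight * ((tau - center)/center)**2``
        (the center also sets the penalty scale).
    n_starts : int
        Optimization restarts over (log tau, mu_b, log sigma2_b, logit p_L,
        logit b_L).

    Attributes
    ----------
    params_ : PerceptParams
    loglik_ : float (penalty excluded)
    converged_ : bool
    """

    def __init__(
        self,
        reg_weight: float = DEFAULT_REG_WEIGHT,
        reg_center_ms: float = DEFAULT_REG_CENTER_MS,
        n_starts: int = 6,
        random_state: int = 0,
        tau_bounds: tuple[float, float] = (20.0, 5000.0),
    ):
        self.reg_weight = reg_weight
        self.reg_center_ms = reg_center_ms
        self.n_starts = n_starts
        self.random_state = random_state
        self.tau_bounds = tau_bounds

    # cells: list of dicts with keys drive1, drive2, t1_ms, t2_ms, n, k
    @staticmethod
    def _validate_cells(cells):
        out = []
        for c in cells:
            d1 = np.asarray(c["drive1"], dtype=float)
            d2 = np.asarray(c["drive2"], dtype=float)
            out.append(
                dict(
                    drive1=d1,
                    drive2=d2,
                    t1_ms=float(c.get("t1_ms", d1.size)),
                    t2_ms=float(c.get("t2_ms", d2.size)),
                    n=int(c["n"]),
                    k=int(c["k"]),
                )
            )
        return out

    def _theta_to_params(self, theta) -> PerceptParams:
        return PerceptParams(
            tau=float(np.exp(theta[0])),
            mu_b=float(theta[1]),
            sigma2_b=float(np.exp(theta[2])),
            p_l=float(expit(theta[3])),
            b_l=float(expit(theta[4])),
        )

    def _cell_probability(self, cell, params: PerceptParams) -> float:
        p1 = integrate_percept(cell["drive1"], params, cell["t1_ms"])
        p2 = integrate_percept(cell["drive2"], params, cell["t2_ms"])
        return choice_probability(p1, p2, params)

    def _nll(self, theta, cells):
        params = self._theta_to_params(theta)
        nll = 0.0
        for cell in cells:
            p = np.clip(self._cell_probability(cell, params), 1e-9, 1.0 - 1e-9)
            nll -= cell["k"] * np.log(p) + (cell["n"] - cell["k"]) * np.log(1.0 - p)
        nll += self.reg_weight * ((params.tau - self.reg_center_ms) / self.reg_center_ms) ** 2
        return nll

    def fit(self, cells, y=None):
        """Fit to choice cells (flat list, or list of lists over proxies)."""
        if len(cells) == 0:
            raise ValueError("need at least one choice cell")
        if isinstance(cells[0], (list, tuple)):
            flat = [c for proxy in cells for c in proxy]
        else:
            flat = list(cells)
        flat = self._validate_cells(flat)

        rng = np.random.default_rng(self.random_state)
        lo_t, hi_t = np.log(self.tau_bounds[0]), np.log(self.tau_bounds[1])
        # seed sigma2_b near the drive-integral scale so d' starts O(1)
        scale = float(
            np.median([np.sum(c["drive2"]) + np.sum(c["drive1"]) for c in flat])
        )
        base = np.array(
            [np.log(self.reg_center_ms), 0.0, np.log(max(scale, 1e-3)), logit(0.05), 0.0]
        )
        starts = [base]
        for _ in range(self.n_starts - 1):
            s = base + rng.normal(0.0, [0.7, 1.0, 1.5, 1.0, 0.7])
            s[0] = np.clip(s[0], lo_t, hi_t)
            starts.append(s)

        bounds = [
            (lo_t, hi_t),
            (-1e4, 1e4),
            (np.log(1e-6), np.log(1e12)),
            (logit(1e-4), logit(0.5)),
            (logit(1e-3), logit(1.0 - 1e-3)),
        ]
        best, best_val, any_ok = None, np.inf, False
        for s in starts:
            res = minimize(
                self._nll,
                s,
                args=(flat,),
                method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=800),
            )
            any_ok = any_ok or bool(res.success)
            if res.fun < best_val:
                best, best_val = res, res.fun
        if not any_ok:
            warnings.warn("percept fit did not converge; returning best candidate")
        self.converged_ = any_ok
        self.theta_ = best.x
        self.params_ = self._theta_to_params(best.x)
        self.loglik_ = -(best_val - self.reg_weight * (
            (self.params_.tau - self.reg_center_ms) / self.reg_center_ms
        ) ** 2)
        self._cells_ = flat
        return self

    def predict_proba(self, cells) -> np.ndarray:
        """Predicted P(chose stimulus 2 longer) per cell."""
        cells = self._validate_cells(cells)
        return np.array([self._cell_probability(c, self.params_) for c in cells])


def fit_percept_params(
    cells,
    reg_weight: float = DEFAULT_REG_WEIGHT,
    reg_center_ms: float = DEFAULT_REG_CENTER_MS,
    **kwargs,
) -> LeakyIntegratorObserver:
    """Functional wrapper over :class:`LeakyIntegratorObserver`."""
    return LeakyIntegratorObserver(
        reg_weight=reg_weight, reg_center_ms=reg_center_ms, **kwargs
    ).fit(cells)


def neurometric_curve(
    drive_profiles: dict,
    params: PerceptParams,
    design,
) -> pd.DataFrame:
    """Predicted P(T2 > T1) per delta_T level and light condition.

    ``drive_profiles`` maps (duration_ms, light_label) to a mean drive
    profile over [0, T]; ``design`` is a list of TrialSpec-like objects with
    t1_ms, t2_ms, delta_t and light attributes.  Light applies to the
    stimulus named by the label; stimulus 1 uses the no-light profile unless
    the condition targets it.
    """
    rows = []
    for trial in design:
        light = getattr(trial, "light", "none")
        l1 = light if light == "excite_stim1" else "none"
        l2 = light if light in ("excite_stim2", "inhibit_stim2") else "none"
        d1 = drive_profiles[(trial.t1_ms, l1)]
        d2 = drive_profiles[(trial.t2_ms, l2)]
        p1 = integrate_percept(d1, params, trial.t1_ms)
        p2 = integrate_percept(d2, params, trial.t2_ms)
        rows.append(
            dict(
                delta_t=trial.delta_t,
                light_condition=light,
                p_choice=choice_probability(p1, p2, params),
            )
        )
    frame = pd.DataFrame(rows)
    return (
        frame.groupby(["delta_t", "light_condition"], as_index=False)["p_choice"]
        .mean()
        .sort_values(["light_condition", "delta_t"], ignore_index=True)
    )
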