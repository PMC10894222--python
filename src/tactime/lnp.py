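"""Linear-nonlinear-Poisson model of barrel-cortex neurons.

Each neuron receives a constant background current I0, a mechanoreceptor
current gated by a logistic window over the vibration epoch

    I_M(t) = [I1_ss + (I1_peak - I1_ss) exp(-(t - t0_M)/tau_M)] W(t, T, t0_M)
    W(t, T, t0) = expit(t - t0) * expit(-(t - T - t0))        (t in ms)

and, on light-on trials, an optogenetic current with the same window over the
light epoch plus a post-light-offset term (positive rebound or negative
suppression)

    I_O(t) = [I2_ss + (I2_peak - I2_ss) exp(-(t - t0_O)/tau_O)] W(t, T, t0_O)
             + I3_peak exp(-(t - T - t0_O)/tau_I) expit(t - T - t0_O).

The total current I = I0 + I_M + I_O passes through a generalized sigmoid I/F
curve

    rate = lambda_max * [1 - expit(-10 I)^(1/upsilon)] + 1e-4

giving the firing rate in spikes per 1-ms bin; spikes are emitted as
independent Poisson counts per bin.  ``LNPNeuron`` fits the eight free
parameters (currents, lambda_max, upsilon) to PSTHs binned at 10 ms by
penalized Poisson maximum likelihood; the decay constants are fixed at the
population medians tau_M = 48 ms, tau_O = 49 ms, tau_I = 28 ms by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

RATE_FLOOR = 1e-4  # spikes per ms, stabilizes very low-firing neurons
CURRENT_SCALE = 10.0  # constant scaling inside the I/F sigmoid

DEFAULT_TAU_M = 48.0
DEFAULT_TAU_O = 49.0
DEFAULT_TAU_I = 28.0

FREE_PARAM_NAMES = (
    "i0",
    "i1_ss",
    "i1_peak",
    "i2_ss",
    "i2_peak",
    "i3_peak",
    "lambda_max",
    "upsilon",
)

CURRENT_BOUND = 5.0  # a.u. bound on every current parameter
LAMBDA_BOUNDS = (1e-4, 1.0)  # spikes/ms (0.1 .. 1000 spikes/s)
UPSILON_BOUNDS = (0.05, 20.0)


@dataclass(frozen=True)
class NeuronParams:
    """The 12-parameter single-neuron model.

    Currents are in arbitrary units; ``lambda_max`` is the maximum firing
    rate in spikes per 1-ms bin; time constants and onsets are in ms.
    """

    i0: float = 0.0
    i1_ss: float = 0.0
    i1_peak: float = 0.0
    i2_ss: float = 0.0
    i2_peak: float = 0.0
    i3_peak: float = 0.0
    lambda_max: float = 0.05
    upsilon: float = 1.0
    tau_m: float = DEFAULT_TAU_M
    tau_o: float = DEFAULT_TAU_O
    tau_i: float = DEFAULT_TAU_I
    t0_m: float = 0.0
    t0_o: float = 0.0

    def __post_init__(self):
        if not self.lambda_max > 0:
            raise ValueError(f"lambda_max must be > 0, got {self.lambda_max!r}")
        if not self.upsilon > 0:
            raise ValueError(f"upsilon must be > 0, got {self.upsilon!r}")
        for name in ("tau_m", "tau_o", "tau_i"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")

    @property
    def lambda_max_hz(self) -> float:
        """Maximum rate in spikes/s (reporting convenience)."""
        return self.lambda_max * 1000.0

    def free_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FREE_PARAM_NAMES], dtype=float)

    @classmethod
    def from_free_vector(cls, vec, **fixed) -> "NeuronParams":
        kw = dict(zip(FREE_PARAM_NAMES, map(float, vec)))
        kw.update(fixed)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Condition:
    """Stimulation condition for one trial type.

    ``mechano_gain`` scales the vibrissal currents (unit gain at the
    reference intensity); ``opto_gain`` scales the optogenetic currents
    (0 = light off, 1 = photoexcitation; a negative value flips the light
    currents, a crude photoinhibition).  The light window defaults to the
    stimulus window but may be shifted (e.g. 50 ms early light onset).
    ``t_start_ms``/``t_stop_ms`` bound the simulated epoch; pre-stimulus
    baseline and post-offset dynamics are included by widening them.
    """

    duration_ms: float
    mechano_gain: float = 1.0
    opto_gain: float = 0.0
    light_start_ms: float | None = None
    light_stop_ms: float | None = None
    t_start_ms: float = 0.0
    t_stop_ms: float | None = None

    def __post_init__(self):
        if not self.duration_ms > 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms!r}")

    @property
    def light_on(self) -> bool:
        return self.opto_gain != 0.0

    @property
    def light_window(self) -> tuple[float, float]:
        a = 0.0 if self.light_start_ms is None else self.light_start_ms
        b = self.duration_ms if self.light_stop_ms is None else self.light_stop_ms
        return a, b

    @property
    def stop_ms(self) -> float:
        return self.duration_ms if self.t_stop_ms is None else self.t_stop_ms

    def key(self) -> tuple:
        return (self.duration_ms, self.mechano_gain, self.opto_gain, self.light_window)


def window(t, duration_ms, t0=0.0):
    """Logistic gate over the stimulation epoch, ~1 ms transition scale."""
    t = np.asarray(t, dtype=float)
    return expit(t - t0) * expit(-(t - duration_ms - t0))


def mechano_current(t, params: NeuronParams, duration_ms: float, gain: float = 1.0):
    """Adapting vibrissal drive: exponential decay from the onset peak toward
    steady state, gated by the stimulus window."""
    t = np.asarray(t, dtype=float)
    dt = t - params.t0_m
    decay = np.exp(-np.clip(dt, 0.0, None) / params.tau_m)
    # before onset the window is ~0; clipping dt avoids overflow only
    bracket = params.i1_ss + (params.i1_peak - params.i1_ss) * decay
    return gain * bracket * window(t, duration_ms, params.t0_m)


def opto_current(
    t,
    params: NeuronParams,
    light_start_ms: float = 0.0,
    light_stop_ms: float | None = None,
    duration_ms: float | None = None,
    gain: float = 1.0,
):
    """Optogenetic drive plus post-light-offset term.

    The in-light term mirrors the mechanoreceptor current over the light
    window; after light offset a current of amplitude ``i3_peak`` (negative
    for post-stimulation suppression) decays with ``tau_i``.
    """
    if light_stop_ms is None:
        light_stop_ms = duration_ms
    t = np.asarray(t, dtype=float)
    t0 = params.t0_o + light_start_ms
    light_len = light_stop_ms - light_start_ms
    dt = t - t0
    decay = np.exp(-np.clip(dt, 0.0, None) / params.tau_o)
    in_light = (params.i2_ss + (params.i2_peak - params.i2_ss) * decay) * window(
        t, light_len, t0
    )
    dt_off = t - light_stop_ms - params.t0_o
    post = (
        params.i3_peak
        * np.exp(-np.clip(dt_off, 0.0, None) / params.tau_i)
        * expit(dt_off)
    )
    return gain * (in_light + post)


def total_current(t, params: NeuronParams, condition: Condition):
    """Background + vibrissal + optogenetic current at time(s) t."""
    i = params.i0 + mechano_current(
        t, params, condition.duration_ms, condition.mechano_gain
    )
    if condition.light_on:
        a, b = condition.light_window
        i = i + opto_current(t, params, a, b, gain=condition.opto_gain)
    return i


def rate_from_current(current, lambda_max: float, upsilon: float):
    """Generalized-sigmoid I/F curve, spikes per 1-ms bin.

    The current is scaled by 10 inside the sigmoid and a 1e-4 floor is always
    added.
    """
    current = np.asarray(current, dtype=float)
    return lambda_max * (1.0 - expit(-CURRENT_SCALE * current) ** (1.0 / upsilon)) + RATE_FLOOR


def rate_profile(
    params: NeuronParams, condition: Condition, bin_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Expected firing rate per ms on the condition's time grid.

    Returns (bin left edges in ms, rate in spikes/ms at bin centers).
    """
    edges = np.arange(condition.t_start_ms, condition.stop_ms, bin_ms)
    centers = edges + bin_ms / 2.0
    current = total_current(centers, params, condition)
    return edges, rate_from_current(current, params.lambda_max, params.upsilon)


@dataclass
class SpikeRaster:
    """Poisson spike counts per trial and 1-ms bin for one condition."""

    counts: np.ndarray  # (n_trials, n_bins) integer counts
    t_start_ms: float
    bin_ms: float
    condition: Condition | None = None

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin left edges in ms relative to stimulus onset."""
        return self.t_start_ms + np.arange(self.n_bins) * self.bin_ms

    def mean_rate(self) -> np.ndarray:
        """Trial-averaged rate in spikes/ms per bin."""
        return self.counts.mean(axis=0) / self.bin_ms

    def mean_rate_hz(self) -> np.ndarray:
        return self.mean_rate() * 1000.0

    def spike_times(self) -> list[np.ndarray]:
        """Per-trial event times (bin centers, repeated by count)."""
        t = self.times + self.bin_ms / 2.0
        return [np.repeat(t, trial) for trial in self.counts]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for k, times in enumerate(self.spike_times()):
            for tt in times:
                rows.append((k, tt))
        return pd.DataFrame(rows, columns=["trial", "time_ms"])

    def rebin(self, new_bin_ms: float) -> "SpikeRaster":
        """Aggregate counts into wider bins (new width must be a multiple)."""
        factor = int(round(new_bin_ms / self.bin_ms))
        n = (self.n_bins // factor) * factor
        counts = self.counts[:, :n].reshape(self.n_trials, -1, factor).sum(axis=2)
        return SpikeRaster(counts, self.t_start_ms, new_bin_ms, self.condition)


def simulate_spikes(
    params: NeuronParams,
    condition: Condition,
    n_trials: int,
    rng: int | np.random.Generator = 0,
    bin_ms: float = 1.0,
) -> SpikeRaster:
    """Emit independent Poisson counts per 1-ms bin at the model rate."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    rng = np.random.default_rng(rng)
    edges, rate = rate_profile(params, condition, bin_ms)
    counts = rng.poisson(rate * bin_ms, size=(n_trials, rate.size))
    return SpikeRaster(counts, condition.t_start_ms, bin_ms, condition)


def _invert_if_curve(rate, lambda_max, upsilon):
    """Invert the I/F curve; rate in spikes/ms, clipped into the open range."""
    r = np.clip((rate - RATE_FLOOR) / lambda_max, 1e-6, 1.0 - 1e-6)
    inner = (1.0 - r) ** (-upsilon) - 1.0
    return np.log(np.clip(inner, 1e-12, None)) / CURRENT_SCALE


class LNPNeuron(BaseEstimator):
    """Penalized maximum-likelihood fit of the LNP neuron to binned PSTHs.

    Parameters
    ----------
    fix_taus : bool
        Freeze the decay constants at the population medians (48/49/28 ms);
        when False they are fitted alongside the eight free parameters.
    fit_bin_ms : float
        Width of the PSTH bins used for fitting (10 ms by convention).
    ridge : float
        Weight of a small L2 penalty on the stimulus/light current parameters
        that settles directions the likelihood leaves flat (e.g. a flat PSTH
        puts no constraint on the gated currents).
    n_starts : int
        Number of optimization restarts (heuristic start + random
        perturbations).

    Attributes
    ----------
    params_ : NeuronParams
        Best-fitting parameter set.
    loglik_ : float
        Poisson log-likelihood at the optimum (penalty excluded).
    converged_ : bool
        True if at least one start converged; otherwise the best candidate is
        returned and a warning is issued.
    param_se_ : dict
        Approximate standard errors from the inverse numerical Hessian
        (NaN where the Hessian is not invertible).
    """

    def __init__(
        self,
        fix_taus: bool = True,
        fit_bin_ms: float = 10.0,
        ridge: float = 0.1,
        n_starts: int = 8,
        random_state: int = 0,
        t0_m: float = 0.0,
        t0_o: float = 0.0,
    ):
        self.fix_taus = fix_taus
        self.fit_bin_ms = fit_bin_ms
        self.ridge = ridge
        self.n_starts = n_starts
        self.random_state = random_state
        self.t0_m = t0_m
        self.t0_o = t0_o

    # -- model expectation ------------------------------------------------
    def _expected_counts(self, theta, conditions):
        """Expected spike count per fit bin per trial for each condition."""
        taus = {}
        if not self.fix_taus:
            taus = dict(tau_m=theta[8], tau_o=theta[9], tau_i=theta[10])
        params = NeuronParams.from_free_vector(
            theta[:8], t0_m=self.t0_m, t0_o=self.t0_o, **taus
        )
        out = []
        for cond in conditions:
            _, rate = rate_profile(params, cond, bin_ms=1.0)
            factor = int(round(self.fit_bin_ms))
            n = (rate.size // factor) * factor
            out.append(rate[:n].reshape(-1, factor).sum(axis=1))
        return out

    def _nll(self, theta, conditions, total_counts, n_trials):
        nll = 0.0
        for mu_bin, k, n in zip(
            self._expected_counts(theta, conditions), total_counts, n_trials
        ):
            m = min(mu_bin.size, k.size)
            mu = np.clip(mu_bin[:m] * n, 1e-12, None)
            nll += float(np.sum(mu - k[:m] * np.log(mu)))
        # ridge on the gated currents only; I0 is pinned by the baseline rate
        nll += self.ridge * float(np.sum(np.square(theta[1:6])))
        return nll

    # -- initialization ---------------------------------------------------
    def _heuristic_start(self, conditions, total_counts, n_trials):
        rates = []  # observed per-ms rates per condition
        for cond, k, n in zip(conditions, total_counts, n_trials):
            rates.append(k / (n * self.fit_bin_ms))
        peak = max(float(np.max(r)) for r in rates)
        lam = float(np.clip(peak * 1.3 + 1e-3, *LAMBDA_BOUNDS))
        ups = 1.0

        def seg_rate(cond, r, lo, hi):
            t = cond.t_start_ms + np.arange(r.size) * self.fit_bin_ms
            m = (t >= lo) & (t < hi)
            return float(np.mean(r[m])) if m.any() else np.nan

        base, on_peak, on_ss, off_peak, off_ss = [], [], [], [], []
        for cond, r in zip(conditions, rates):
            T = cond.duration_ms
            b = seg_rate(cond, r, cond.t_start_ms, 0.0)
            if not np.isnan(b):
                base.append(b)
            tgt = on_peak if cond.light_on else off_peak
            tgt_ss = on_ss if cond.light_on else off_ss
            p = seg_rate(cond, r, 0.0, 60.0)
            s = seg_rate(cond, r, T / 2.0, T)
            if not np.isnan(p):
                tgt.append(p)
            if not np.isnan(s):
                tgt_ss.append(s)

        def inv(vals, default):
            if not vals:
                return default
            return float(_invert_if_curve(np.mean(vals), lam, ups))

        i0 = inv(base, -0.5)
        i1p = inv(off_peak, 0.5) - i0
        i1 = inv(off_ss, 0.2) - i0
        i2p = (inv(on_peak, 0.5) - i0 - i1p) if on_peak else 0.0
        i2 = (inv(on_ss, 0.2) - i0 - i1) if on_ss else 0.0
        theta = [i0, i1, i1p, i2, i2p, 0.0, lam, ups]
        if not self.fix_taus:
            theta += [DEFAULT_TAU_M, DEFAULT_TAU_O, DEFAULT_TAU_I]
        lo, hi = self._bounds_arrays()
        return np.clip(theta, lo, hi)

    def _bounds(self):
        b = [(-CURRENT_BOUND, CURRENT_BOUND)] * 6 + [LAMBDA_BOUNDS, UPSILON_BOUNDS]
        if not self.fix_taus:
            b += [(5.0, 300.0)] * 3
        return b

    def _bounds_arrays(self):
        b = np.array(self._bounds())
        return b[:, 0], b[:, 1]

    # -- fitting ----------------------------------------------------------
    def fit(self, conditions, rasters, n_trials=None):
        """Fit to one raster (or binned total counts) per condition.

        Parameters
        ----------
        conditions : list of Condition
            Must include at least one light-off condition; include a light-on
            condition to constrain the optogenetic currents.
        rasters : list of SpikeRaster or list of 1-d arrays
            Either rasters (rebinned internally to ``fit_bin_ms``) or total
            spike counts per fit bin summed across trials.
        n_trials : list of int, required when passing raw count arrays.
        """
        if len(conditions) == 0:
            raise ValueError("need at least one condition")
        total_counts, ns = [], []
        for k, obj in enumerate(rasters):
            if isinstance(obj, SpikeRaster):
                rb = obj.rebin(self.fit_bin_ms) if obj.bin_ms != self.fit_bin_ms else obj
                total_counts.append(rb.counts.sum(axis=0).astype(float))
                ns.append(obj.n_trials)
            else:
                if n_trials is None:
                    raise ValueError("n_trials required with raw count arrays")
                total_counts.append(np.asarray(obj, dtype=float))
                ns.append(int(n_trials[k]))

        bounds = self._bounds()
        lo, hi = self._bounds_arrays()
        rng = np.random.default_rng(self.random_state)
        start0 = self._heuristic_start(conditions, total_counts, ns)
        starts = [start0]
        # the nonlinearity scale has shallow, nearly degenerate basins:
        # seed it explicitly across its plausible range
        for ups in (0.5, 2.0, 4.0):
            s = start0.copy()
            s[7] = ups
            starts.append(s)
        while len(starts) < self.n_starts:
            pert = start0 + rng.normal(0.0, 0.3, size=start0.size) * (
                np.abs(start0) + 0.3
            )
            starts.append(np.clip(pert, lo, hi))

        best, best_val, any_ok = None, np.inf, False
        for s in starts:
            res = minimize(
                self._nll,
                s,
                args=(conditions, total_counts, ns),
                method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=500),
            )
            any_ok = any_ok or bool(res.success)
            if res.fun < best_val:
                best, best_val = res, res.fun
        if not any_ok:
            warnings.warn("LNP fit did not converge; returning best candidate")
        self.converged_ = any_ok
        theta = best.x
        taus = {}
        if not self.fix_taus:
            taus = dict(tau_m=theta[8], tau_o=theta[9], tau_i=theta[10])
        self.params_ = NeuronParams.from_free_vector(
            theta[:8], t0_m=self.t0_m, t0_o=self.t0_o, **taus
        )
        self.theta_ = theta
        self.loglik_ = -self._nll_unpenalized(theta, conditions, total_counts, ns)
        self.param_se_ = self._standard_errors(theta, conditions, total_counts, ns)
        self.fit_quality_ = self._fit_quality(theta, conditions, total_counts, ns)
        return self

    def _nll_unpenalized(self, theta, conditions, total_counts, n_trials):
        ridge, self.ridge = self.ridge, 0.0
        try:
            return self._nll(theta, conditions, total_counts, n_trials)
        finally:
            self.ridge = ridge

    def _fit_quality(self, theta, conditions, total_counts, ns):
        """Fraction of PSTH variance explained by the fitted rate."""
        obs, pred = [], []
        for mu, k, n in zip(self._expected_counts(theta, conditions), total_counts, ns):
            m = min(mu.size, k.size)
            obs.append(k[:m] / n)
            pred.append(mu[:m])
        obs = np.concatenate(obs)
        pred = np.concatenate(pred)
        denom = float(np.sum((obs - obs.mean()) ** 2))
        if denom == 0:
            return np.nan
        return 1.0 - float(np.sum((obs - pred) ** 2)) / denom

    def _standard_errors(self, theta, conditions, total_counts, ns, eps=1e-4):
        n = theta.size
        H = np.zeros((n, n))
        f0 = self._nll(theta, conditions, total_counts, ns)

        def f(x):
            return self._nll(x, conditions, total_counts, ns)

        for a in range(n):
            for b in range(a, n):
                ea = np.zeros(n)
                eb = np.zeros(n)
                ea[a] = eps * max(1.0, abs(theta[a]))
                eb[b] = eps * max(1.0, abs(theta[b]))
                H[a, b] = H[b, a] = (
                    f(theta + ea + eb) - f(theta + ea) - f(theta + eb) + f0
                ) / (ea[a] * eb[b])
        names = list(FREE_PARAM_NAMES) + (
            [] if self.fix_taus else ["tau_m", "tau_o", "tau_i"]
        )
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        return dict(zip(names, se))

    def predict_rate(self, condition: Condition, bin_ms: float = 1.0):
        """Fitted rate profile (spikes/ms) for a condition."""
        return rate_profile(self.params_, condition, bin_ms)


def fit_neuron(
    observed_rasters,
    conditions,
    fixed_taus: bool = True,
    **kwargs,
) -> LNPNeuron:
    """Functional wrapper over :class:`LNPNeuron`."""
    return LNPNeuron(fix_taus=fixed_taus, **kwargs).fit(conditions, observed_rasters)
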