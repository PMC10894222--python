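"""Parameter-recovery harnesses: generate from known ground truth, fit,
compare.  Shared by the test suite, ``synthetic.recovery_experiment`` and
the acceptance script so that every consumer exercises the same pipeline.
"""

from __future__ import annotations

import numpy as np

from .lnp import Condition, LNPNeuron, NeuronParams, simulate_spikes
from .percept import LeakyIntegratorObserver
from .population import NeuronPopulationMixture
from .psychometrics import PsychometricCurve, logistic4
from .synthetic import GroundTruth, make_behavior_session

LNP_TOL = 0.20  # relative error per free parameter at 200 trials/condition
MIXTURE_MIN_ACCURACY = 0.95
PERCEPT_TAU_TOL = 0.20
PERCEPT_PL_TOL = 0.05

#: an adapting, light-responsive neuron with post-light rebound used for the
#: recovery experiments; every parameter visibly shapes the PSTH, so all are
#: statistically identifiable at the harness sample sizes
LNP_TRUE = NeuronParams(
    i0=-0.5,
    i1_ss=0.6,
    i1_peak=1.5,
    i2_ss=0.3,
    i2_peak=0.8,
    i3_peak=0.6,
    lambda_max=0.08,  # spikes/ms (80 spikes/s ceiling)
    upsilon=1.0,
)


def lnp_conditions(
    durations=(334.0, 694.0), mechano_gains=(0.7, 1.3)
) -> list[Condition]:
    """Light-off and light-on conditions with pre/post epochs for fitting.

    Conditions at scaled vibrissal gain (different stimulus intensities)
    probe the I/F curve at distinct operating points and pin down the
    nonlinearity scale upsilon.
    """
    conds = []
    for T in durations:
        for opto in (0.0, 1.0):
            conds.append(
                Condition(T, opto_gain=opto, t_start_ms=-200.0, t_stop_ms=T + 300.0)
            )
    for g in mechano_gains:
        conds.append(
            Condition(
                durations[0],
                mechano_gain=g,
                t_start_ms=-200.0,
                t_stop_ms=durations[0] + 300.0,
            )
        )
    # light without vibration isolates the optogenetic currents
    conds.append(
        Condition(
            durations[0],
            mechano_gain=0.0,
            opto_gain=1.0,
            t_start_ms=-200.0,
            t_stop_ms=durations[0] + 300.0,
        )
    )
    return conds


def recover_lnp(
    seed: int = 0,
    n_trials: int = 200,
    true_params: NeuronParams = LNP_TRUE,
    n_starts: int = 8,
    mechano_gains=(0.4, 0.7, 1.3, 1.6),
) -> dict:
    """Simulate a neuron under light-off/on conditions and refit it."""
    rng = np.random.default_rng(seed)
    conds = lnp_conditions(mechano_gains=mechano_gains)
    rasters = [simulate_spikes(true_params, c, n_trials, rng) for c in conds]
    fit = LNPNeuron(n_starts=n_starts, random_state=seed).fit(conds, rasters)
    truth = true_params.free_vector()
    est = fit.params_.free_vector()
    rel = np.abs(est - truth) / np.abs(truth)
    return dict(
        true=truth.tolist(),
        estimated=est.tolist(),
        relative_errors=rel.tolist(),
        max_relative_error=float(rel.max()),
        tolerance=LNP_TOL,
        passed=bool(rel.max() <= LNP_TOL),
        converged=fit.converged_,
    )


def two_cluster_vectors(
    seed: int = 0, n_per_cluster: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Two well-separated synthetic neuron classes in the 8-d space."""
    rng = np.random.default_rng(seed)
    mu_a = np.array([-0.6, 0.3, 1.6, 0.1, 0.3, -0.1, 0.06, 1.2])
    mu_b = np.array([-1.5, 1.2, 0.4, 0.8, 1.5, 0.3, 0.25, 0.4])
    sd = 0.05 * np.maximum(np.abs(mu_a), 0.2)
    a = mu_a + rng.standard_normal((n_per_cluster, 8)) * sd
    b = mu_b + rng.standard_normal((n_per_cluster, 8)) * sd
    X = np.vstack([a, b])
    labels = np.r_[np.zeros(n_per_cluster), np.ones(n_per_cluster)].astype(int)
    return X, labels


def recover_mixture(seed: int = 0, n_per_cluster: int = 60) -> dict:
    """Fit the G = 5 mixture to two separated clusters; measure how often
    vectors from the same generator class land in the same fitted class."""
    X, labels = two_cluster_vectors(seed, n_per_cluster)
    mix = NeuronPopulationMixture(random_state=seed).fit(X)
    pred = mix.predict(X)
    # map each true class to its majority fitted class
    correct = 0
    for c in np.unique(labels):
        sub = pred[labels == c]
        correct += int(np.max(np.bincount(sub, minlength=mix.n_classes)))
    accuracy = correct / labels.size
    dominant = np.sort(mix.weights_)[::-1]
    return dict(
        assignment_accuracy=float(accuracy),
        dominant_weights=dominant[:2].tolist(),
        tolerance=MIXTURE_MIN_ACCURACY,
        passed=bool(accuracy >= MIXTURE_MIN_ACCURACY),
    )


def percept_cells_from_truth(gt: GroundTruth, table) -> list[dict]:
    """Choice cells (drive profiles + counts) for the observer fit, using
    the ground-truth population's drive profiles as the proxy."""
    cells = []
    for row in table.itertuples():
        o1 = 1.0 if row.light == "excite_stim1" else 0.0
        o2 = {"excite_stim2": 1.0, "inhibit_stim2": -1.0}.get(row.light, 0.0)
        cells.append(
            dict(
                drive1=gt.drive(row.T1, row.I1, o1),
                drive2=gt.drive(row.T2, row.I2, o2),
                t1_ms=row.T1,
                t2_ms=row.T2,
                n=row.n_trials,
                k=row.n_chose2,
            )
        )
    return cells


def recover_percept(
    seed: int = 0,
    n_trials_per_cell: int = 204,  # ~1e4 trials over the 7 x 7 design
    population_size: int = 200,
    observer=None,
) -> dict:
    """Generate ~1e4 choices from a known observer and refit tau and p_L."""
    gt = GroundTruth(population_size=population_size, population_seed=seed + 1)
    if observer is not None:
        gt.observer = observer
    table = make_behavior_session(gt, n_trials_per_cell, rng=seed)
    cells = percept_cells_from_truth(gt, table)
    fit = LeakyIntegratorObserver(random_state=seed).fit(cells)
    true, est = gt.observer, fit.params_
    tau_err = abs(est.tau - true.tau) / true.tau
    pl_err = abs(est.p_l - true.p_l)
    return dict(
        true=true.to_dict(),
        estimated=est.to_dict(),
        tau_relative_error=float(tau_err),
        p_l_absolute_error=float(pl_err),
        n_trials=int(table.n_trials.sum()),
        passed=bool(tau_err <= PERCEPT_TAU_TOL and pl_err <= PERCEPT_PL_TOL),
    )


PSYCHO_TRUE = dict(gamma=0.05, lam=0.05, u=0.0, nu=0.1)


def recover_psychometric(
    seed: int = 0,
    n_per_level: int = 500,
    n_boot: int = 1000,
    true_params: dict | None = None,
) -> dict:
    """Choices from a known logistic; parameters must land inside their 95%
    bootstrap confidence intervals."""
    truth = dict(true_params or PSYCHO_TRUE)
    rng = np.random.default_rng(seed)
    from .stimuli import delta_t, duration_levels

    levels = np.array([delta_t(334.0, t2) for t2 in duration_levels()])
    p = logistic4(levels, truth["gamma"], truth["lam"], truth["u"], truth["nu"])
    k = rng.binomial(n_per_level, p)
    prop = k / n_per_level
    w = np.full_like(prop, n_per_level)
    fit = PsychometricCurve(random_state=seed).fit(levels, prop, w)

    boot = np.empty((n_boot, 4))
    bfit = PsychometricCurve(n_starts=3, random_state=seed)
    for i in range(n_boot):
        kb = rng.binomial(n_per_level, prop)
        bfit.fit(levels, kb / n_per_level, w)
        boot[i] = (bfit.gamma_, bfit.lambda_, bfit.u_, bfit.nu_)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    names = ("gamma", "lam", "u", "nu")
    true_vec = np.array([truth[n] for n in names])
    inside = (true_vec >= lo) & (true_vec <= hi)
    return dict(
        true=truth,
        estimated=dict(zip(names, (fit.gamma_, fit.lambda_, fit.u_, fit.nu_))),
        ci_low=dict(zip(names, lo.tolist())),
        ci_high=dict(zip(names, hi.tolist())),
        inside_ci=dict(zip(names, map(bool, inside))),
        pse=fit.pse_,
        passed=bool(inside.all()),
    )
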