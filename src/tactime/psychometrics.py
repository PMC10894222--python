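"""Behavioral analysis: logistic psychometric fits, bias and resampling stats.

Choice data are aggregated into a *choice table*: one row per stimulus cell
with columns ``delta_t``, ``delta_i``, ``light``, ``n_trials``,
``n_chose2`` (trials on which stimulus 2 was judged greater).  The
psychometric curve along the relevant axis is the four-parameter logistic

    P(delta) = gamma + (1 - lambda - gamma) / (1 + exp(-(delta - u) / nu))

with lower asymptote gamma, upper-asymptote deficit lambda, inflection u and
inverse-slope scale nu; the point of subjective equality (PSE) is the delta
at which the *fitted* curve crosses 50%.  The irrelevant-feature bias, the
one-sided resampling test between conditions, the SVM separation of
bootstrap clouds and the congruent/incongruent accuracy comparison follow
the same trial-level resampling conventions throughout (1000 iterations by
default, easy trials at the design extremes excluded).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

CHOICE_COLUMNS = ("delta_t", "delta_i", "light", "n_trials", "n_chose2")

#: just below the nominal design extremes (|dT| = 0.35, |dI| = 0.3)
EASY_THRESHOLDS = {"duration": 0.34, "intensity": 0.29}
DELTA_COLUMN = {"duration": "delta_t", "intensity": "delta_i"}


def validate_choice_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CHOICE_COLUMNS if c not in table.columns and c != "light"]
    if missing:
        raise ValueError(f"choice table missing columns {missing}")
    if "light" not in table.columns:
        table = table.assign(light="none")
    if ((table.n_chose2 < 0) | (table.n_chose2 > table.n_trials)).any():
        raise ValueError("n_chose2 must lie in [0, n_trials]")
    return table


def read_choice_table(path) -> pd.DataFrame:
    """Read a session CSV; tolerates per-trial (long) layouts with a 0/1
    ``chose2`` column by aggregating to per-cell counts."""
    frame = pd.read_csv(path)
    if "chose2" in frame.columns and "n_trials" not in frame.columns:
        keys = [c for c in ("delta_t", "delta_i", "light") if c in frame.columns]
        grouped = frame.groupby(keys)["chose2"].agg(["count", "sum"]).reset_index()
        frame = grouped.rename(columns={"count": "n_trials", "sum": "n_chose2"})
    return validate_choice_table(frame)


def logistic4(delta, gamma, lam, u, nu):
    """Four-parameter logistic on the normalized-difference axis."""
    return gamma + (1.0 - lam - gamma) * expit((np.asarray(delta, float) - u) / nu)


def pse_from_params(gamma, lam, u, nu):
    """Delta where the fitted curve crosses 0.5 (undefined outside the
    asymptote range)."""
    s = (0.5 - gamma) / (1.0 - lam - gamma)
    if not 0.0 < s < 1.0:
        return np.nan
    return u + nu * logit(s)


class PsychometricCurve(BaseEstimator):
    """Nonlinear least-squares fit of the four-parameter logistic.

    ``fit(X, y, sample_weight)`` takes delta values, observed choice
    proportions (0..1 scale) and per-level trial counts.  Asymptote
    parameters are bounded in [0, 0.5]; multiple starts guard against local
    minima.  Degenerate data (all-0 or all-1 proportions) produce a fit
    flagged via ``degenerate_``.

    Attributes: ``gamma_``, ``lambda_``, ``u_``, ``nu_``, ``pse_``,
    ``slope_`` (= 1/nu).
    """

    def __init__(self, n_starts: int = 6, random_state: int = 0, max_nu: float = 10.0):
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_nu = max_nu

    def fit(self, X, y, sample_weight=None):
        delta = np.asarray(X, dtype=float).ravel()
        prop = np.asarray(y, dtype=float).ravel()
        if delta.size != prop.size:
            raise ValueError("X and y must have the same length")
        if np.unique(delta).size < 4:
            raise ValueError("need at least 4 distinct delta levels")
        w = (
            np.ones_like(prop)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        sw = np.sqrt(w / w.mean())

        self.degenerate_ = bool(np.all(prop <= 0.0) or np.all(prop >= 1.0))

        def residuals(theta):
            return sw * (logistic4(delta, *theta) - prop)

        span = max(delta.max() - delta.min(), 1e-3)
        bounds = (
            [0.0, 0.0, delta.min() - span, 1e-3],
            [0.5, 0.5, delta.max() + span, self.max_nu],
        )
        rng = np.random.default_rng(self.random_state)
        starts = [np.array([0.02, 0.02, float(np.median(delta)), span / 4.0])]
        for _ in range(self.n_starts - 1):
            starts.append(
                np.array(
                    [
                        rng.uniform(0.0, 0.2),
                        rng.uniform(0.0, 0.2),
                        rng.uniform(delta.min(), delta.max()),
                        rng.uniform(span / 20.0, span),
                    ]
                )
            )
        best, best_cost = None, np.inf
        for s in starts:
            s = np.clip(s, bounds[0], bounds[1])
            try:
                res = least_squares(residuals, s, bounds=bounds)
            except ValueError:
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
        gamma, lam, u, nu = best.x
        self.gamma_, self.lambda_, self.u_, self.nu_ = map(
            float, (gamma, lam, u, nu)
        )
        self.pse_ = float(pse_from_params(gamma, lam, u, nu))
        self.slope_ = 1.0 / self.nu_
        self.cost_ = float(best_cost)
        return self

    def predict_proba(self, X):
        return logistic4(np.asarray(X, dtype=float), self.gamma_, self.lambda_, self.u_, self.nu_)

    def params(self) -> dict:
        return dict(
            gamma=self.gamma_,
            lambda_=self.lambda_,
            u=self.u_,
            nu=self.nu_,
            pse=self.pse_,
            slope=self.slope_,
        )


def fit_psychometric(
    table: pd.DataFrame, axis: str = "duration", **kwargs
) -> PsychometricCurve:
    """Fit the logistic along the relevant axis of a choice table (cells
    pooled over the irrelevant feature)."""
    table = validate_choice_table(table)
    col = DELTA_COLUMN[axis]
    grouped = table.groupby(col)[["n_trials", "n_chose2"]].sum().reset_index()
    prop = grouped.n_chose2 / grouped.n_trials
    return PsychometricCurve(**kwargs).fit(grouped[col], prop, grouped.n_trials)


def exclude_easy(
    table: pd.DataFrame, relevant: str = "duration", threshold: float | None = None
) -> pd.DataFrame:
    """Drop trials at the relevant-feature design extremes, where the
    irrelevant feature cannot flip the choice."""
    col = DELTA_COLUMN[relevant]
    if threshold is None:
        threshold = EASY_THRESHOLDS[relevant]
    return table[np.abs(table[col]) < threshold]


def bias_measure(
    table: pd.DataFrame,
    relevant: str = "duration",
    normalize: bool = True,
) -> pd.Series:
    """Irrelevant-feature bias: % judged "stimulus 2 greater" per irrelevant
    delta level, relevant levels pooled, easy trials excluded, normalized by
    subtracting the level where the irrelevant delta is zero (skipped with a
    warning if that level is absent)."""
    table = validate_choice_table(table)
    table = exclude_easy(table, relevant)
    irrelevant_col = DELTA_COLUMN["intensity" if relevant == "duration" else "duration"]
    grouped = table.groupby(irrelevant_col)[["n_trials", "n_chose2"]].sum()
    pct = 100.0 * grouped.n_chose2 / grouped.n_trials
    if normalize:
        # the log-spaced design's middle level sits within rounding of zero
        zero = pct.index[np.isclose(pct.index.to_numpy(dtype=float), 0.0, atol=0.02)]
        if len(zero):
            pct = pct - pct.loc[zero[0]]
        else:
            warnings.warn("no zero level of the irrelevant feature; bias not normalized")
    pct.name = "bias_pct"
    return pct


def _resample_cells(table: pd.DataFrame, rng, n_iter: int) -> np.ndarray:
    """Trial-level bootstrap within each cell: per iteration, redraw each
    cell's choice count as Binomial(n, k/n); returns the per-iteration mean
    percent choice across cells."""
    n = table.n_trials.to_numpy()
    p = table.n_chose2.to_numpy() / n
    draws = rng.binomial(n[None, :], p[None, :], size=(n_iter, n.size))
    return 100.0 * np.mean(draws / n[None, :], axis=1)


def permutation_bias_test(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    n_iter: int = 1000,
    relevant: str = "duration",
    rng: int | np.random.Generator = 0,
    exclude_easy_trials: bool = True,
) -> tuple[float, np.ndarray]:
    """One-sided resampling test of condition A choosing less than B.

    At each of ``n_iter`` iterations both tables are resampled at the trial
    level with replacement, easy trials excluded, and the difference of mean
    percent choice (A - B) is recorded; the p-value is the fraction of
    iterations with a difference >= 0.  Returns (p, bias samples).
    """
    rng = np.random.default_rng(rng)
    a = validate_choice_table(table_a)
    b = validate_choice_table(table_b)
    if exclude_easy_trials:
        a = exclude_easy(a, relevant)
        b = exclude_easy(b, relevant)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("choice tables are empty after easy-trial exclusion")
    bias = _resample_cells(a, rng, n_iter) - _resample_cells(b, rng, n_iter)
    p = float(np.mean(bias >= 0.0))
    return p, bias


def bootstrap_fit_cloud(
    table: pd.DataFrame,
    axis: str = "duration",
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bootstrap cloud of (PSE, mean % choice) pairs from refitting the
    logistic on trial-level resamples (cell sizes preserved)."""
    rng = np.random.default_rng(rng)
    table = validate_choice_table(table)
    col = DELTA_COLUMN[axis]
    grouped = table.groupby(col)[["n_trials", "n_chose2"]].sum().reset_index()
    n = grouped.n_trials.to_numpy()
    p = grouped.n_chose2.to_numpy() / n
    delta = grouped[col].to_numpy()
    out = np.empty((n_boot, 2))
    fitter = PsychometricCurve(n_starts=3)
    for i in range(n_boot):
        k = rng.binomial(n, p)
        prop = k / n
        fitter.fit(delta, prop, n)
        out[i] = (fitter.pse_, 100.0 * np.mean(prop))
    return out


def svm_separation(
    points_a: np.ndarray,
    points_b: np.ndarray,
    n_folds: int = 10,
    C: float = 1.0,
    rng: int = 0,
) -> float:
    """10-fold cross-validated error of a linear SVM separating two clouds
    of (PSE, mean % choice) points; ~0.5 for identical clouds, ~0 for fully
    separated ones."""
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    if len(points_a) < 20 or len(points_b) < 20:
        raise ValueError("need at least 20 points per cloud")
    X = np.vstack([points_a, points_b])
    y = np.r_[np.zeros(len(points_a)), np.ones(len(points_b))]
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng)
    scores = cross_val_score(SVC(kernel="linear", C=C), X, y, cv=cv)
    return float(1.0 - scores.mean())


def congruence_accuracy(
    table: pd.DataFrame,
    relevant: str = "duration",
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> dict:
    """Accuracy on congruent versus incongruent trials.

    The correct answer is the sign of the relevant delta; trials with zero
    relevant delta or neutral congruence are excluded.  Spread is the STD of
    a trial-level bootstrap; the one-sided p-value tests congruent <=
    incongruent by permuting cell congruence labels weighted by trial count.
    """
    rng = np.random.default_rng(rng)
    table = validate_choice_table(table).copy()
    if "congruence" not in table.columns:
        from .stimuli import congruence_label

        table["congruence"] = [
            congruence_label(r.delta_t, r.delta_i) for r in table.itertuples()
        ]
    col = DELTA_COLUMN[relevant]
    table = table[table.congruence.isin(["congruent", "incongruent"])]
    table = table[np.abs(table[col]) > 1e-12]
    if table.congruence.nunique() < 2:
        raise ValueError("need both congruent and incongruent trials")
    correct = np.where(table[col] > 0, table.n_chose2, table.n_trials - table.n_chose2)
    table = table.assign(n_correct=correct)

    def acc(sub):
        return 100.0 * sub.n_correct.sum() / sub.n_trials.sum()

    cong = table[table.congruence == "congruent"]
    incg = table[table.congruence == "incongruent"]
    result = dict(congruent_pct=acc(cong), incongruent_pct=acc(incg))

    # bootstrap spread (binomial resampling per cell)
    def boot(sub):
        n = sub.n_trials.to_numpy()
        p = sub.n_correct.to_numpy() / n
        draws = rng.binomial(n[None, :], p[None, :], size=(n_boot, n.size))
        return 100.0 * draws.sum(axis=1) / n.sum()

    result["congruent_std"] = float(np.std(boot(cong)))
    result["incongruent_std"] = float(np.std(boot(incg)))

    # one-sided permutation of congruence labels across cells
    observed = result["congruent_pct"] - result["incongruent_pct"]
    labels = (table.congruence == "congruent").to_numpy()
    n_corr = table.n_correct.to_numpy()
    n_tr = table.n_trials.to_numpy()
    count = 0
    for _ in range(n_boot):
        perm = rng.permutation(labels)
        a = 100.0 * n_corr[perm].sum() / n_tr[perm].sum()
        b = 100.0 * n_corr[~perm].sum() / n_tr[~perm].sum()
        if a - b >= observed:
            count += 1
    result["p_value"] = count / n_boot
    return result
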