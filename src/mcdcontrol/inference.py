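"""Per-subject parameter estimation, out-of-sample prediction and recovery.

The estimation target is the posterior mode of the core log-parameters
(log alpha, log beta, log gamma, log kR, log kAlpha) under
weakly-informative Gaussian priors, with the importance weight R fixed to
1 for identifiability (its scale trades off against alpha and the affine
output maps).  The affine nuisance maps and Gaussian noise SDs of the
continuous observables are concentrated out of the objective: given the
latent predictions implied by the core parameters, their conditional
maximum is a per-variable least-squares fit, so the search runs in six
dimensions (the five core log-parameters plus the certainty-gain slope,
which must be estimated jointly because it multiplies beta's latent
output).  A Laplace approximation at the mode supplies the
posterior covariance and an approximate log model evidence.

Fitting may use any non-empty subset of the six dependent variables;
held-out variables are predicted afterwards from the fitted core
parameters alone, and compared to data by within-subject Pearson
correlation, which no affine map can change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .core import MCDParams, optimal_effort_batch
from . import core as _core
from .observation import (
    ALL_VARS,
    CONTINUOUS_VARS,
    DECISION_VARS,
    EFFORT_VARS,
    AffineMap,
    ObservationParams,
)
from .analysis import observed_frame

__all__ = [
    "PriorSpec",
    "FitResult",
    "fit_subject",
    "fit_all_subjects",
    "predict_out_of_sample",
    "latent_predictions",
    "parameter_recovery",
    "permutation_chance_level",
]

_PARAM_NAMES = ("alpha", "beta", "gamma", "kR", "kAlpha")
_THETA_NAMES = _PARAM_NAMES + ("gain_slope",)
_COM_CLAMP = 1e-6
_SLOPE_FLOOR = 1e-6
_NOISE_FLOOR = 1e-3


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior moments for all fitted parameters.

    Core parameters are parameterised on the log scale.  The certainty-gain
    slope is the one nuisance estimated jointly (it multiplies beta*z, so
    beta is only identified to the extent this slope is constrained; its
    prior encodes what is known about the rating-scale units).  The
    remaining nuisance moments (affine intercepts, other log slopes, log
    noise SDs) are part of the declared model but are treated as flat by
    the concentrated objective, which profiles them at their conditional
    maximum.
    """

    core_loc: Mapping[str, float] = field(
        default_factory=lambda: {n: 0.0 for n in _PARAM_NAMES}
    )
    core_scale: Mapping[str, float] = field(
        default_factory=lambda: {n: 2.0 for n in _PARAM_NAMES}
    )
    gain_slope_loc: float = 0.0
    gain_slope_scale: float = 2.0
    intercept_loc: float = 0.0
    intercept_scale: float = 10.0
    log_slope_loc: float = 0.0
    log_slope_scale: float = 2.0
    log_noise_loc: float = -1.0
    log_noise_scale: float = 2.0

    def __post_init__(self) -> None:
        for n in _PARAM_NAMES:
            if not self.core_scale[n] > 0:
                raise ValueError(f"prior scale for {n} must be > 0")
        if not self.gain_slope_scale > 0:
            raise ValueError("gain_slope_scale must be > 0")

    def logpdf(self, theta: np.ndarray) -> float:
        loc = np.array([self.core_loc[n] for n in _PARAM_NAMES] + [self.gain_slope_loc])
        scale = np.array(
            [self.core_scale[n] for n in _PARAM_NAMES] + [self.gain_slope_scale]
        )
        return float(np.sum(stats.norm.logpdf(theta, loc, scale)))


@dataclass
class FitResult:
    """Posterior-mode estimate for one subject."""

    subject: str
    params: MCDParams
    obs_params: ObservationParams
    theta: np.ndarray                 # posterior mode on the log scale
    cov: np.ndarray                   # Laplace covariance (5x5)
    log_evidence: float
    fitted_vars: frozenset
    postdictions: pd.DataFrame        # per-trial predicted observables
    n_restarts: int
    best_objective: float
    converged: bool
    prior: PriorSpec

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "theta_names": list(_THETA_NAMES),
            "theta": self.theta.tolist(),
            "params": {n: getattr(self.params, n) for n in ("alpha", "beta", "gamma", "R", "kR", "kAlpha")},
            "maps": {
                v: {"intercept": m.intercept, "slope": m.slope}
                for v, m in self.obs_params.maps.items()
            },
            "noise_sd": dict(self.obs_params.noise_sd),
            "cov": self.cov.tolist(),
            "log_evidence": self.log_evidence,
            "fitted_vars": sorted(self.fitted_vars),
            "n_restarts": self.n_restarts,
            "best_objective": self.best_objective,
            "converged": self.converged,
        }


def _subject_arrays(trials: pd.DataFrame, epsilon: float) -> dict:
    """Per-trial model inputs and observed dependent variables."""
    obs = observed_frame(trials)
    dmu0 = (trials["vr0_a"] - trials["vr0_b"]).to_numpy(float)
    vcr0 = 0.5 * (trials["vcr0_a"] + trials["vcr0_b"]).to_numpy(float)
    sigma0 = 1.0 / np.maximum(vcr0, epsilon)
    cond = trials["condition"].to_numpy()
    return {
        "dmu0": dmu0,
        "sigma0": sigma0,
        "consequential": cond == "consequential",
        "penalized": cond == "penalized",
        "observed": {v: obs[v].to_numpy(float) for v in ALL_VARS},
        "index": trials.index,
    }


def _latents_from_theta(theta: np.ndarray, arr: dict, z_max: float, n_grid: int) -> dict:
    alpha, beta, gamma, kR, kAlpha = np.exp(theta[:5])
    r_eff = np.where(arr["consequential"], kR, 1.0)
    a_eff = np.where(arr["penalized"], alpha + kAlpha, alpha)
    z = optimal_effort_batch(
        arr["dmu0"], arr["sigma0"], r_eff, a_eff, beta, gamma, z_max=z_max, n_grid=n_grid
    )
    return {
        "z_opt": z,
        "confidence": _core.expected_confidence(arr["dmu0"], arr["sigma0"], beta, gamma, z),
        "soa": _core.expected_soa(arr["dmu0"], gamma, z),
        "gain": _core.certainty_gain(beta, z),
        "log_rt": z,
        "effort": z,
        "com": _core.change_of_mind_prob(arr["dmu0"], gamma, z),
    }


def _profile_affine(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Conditional ML affine map and noise SD for one continuous variable.

    Least squares of y on x with the slope clipped at a small positive
    value (the model constrains slopes to be positive); degenerate latent
    predictions collapse to an intercept-only fit.
    """
    vx = np.var(x)
    if vx < 1e-12:
        slope = _SLOPE_FLOOR
    else:
        slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
        slope = max(slope, _SLOPE_FLOOR)
    intercept = float(np.mean(y) - slope * np.mean(x))
    resid = y - (intercept + slope * x)
    sd = max(float(np.sqrt(np.mean(resid**2))), _NOISE_FLOOR)
    return intercept, slope, sd


def _profile_intercept_only(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Conditional ML intercept and noise SD with the slope fixed at 1."""
    return _profile_fixed_slope(x, y, 1.0)


def _profile_fixed_slope(x: np.ndarray, y: np.ndarray, slope: float) -> Tuple[float, float, float]:
    """Conditional ML intercept and noise SD at a given slope."""
    intercept = float(np.mean(y) - slope * np.mean(x))
    resid = y - (intercept + slope * x)
    sd = max(float(np.sqrt(np.mean(resid**2))), _NOISE_FLOOR)
    return intercept, slope, sd


def _gauge_var(fitted_vars: frozenset) -> Optional[str]:
    """Observable whose affine slope is pinned to 1 to fix the effort unit.

    The model has an exact scale symmetry: rescaling (alpha, beta, gamma)
    by a common factor while shrinking z by the same factor leaves every
    observable distribution unchanged, because the affine output maps
    absorb the unit of z.  Measuring resources in log-RT units (slope of
    the log-RT map fixed at 1; subjective effort as a fallback when RT is
    not fitted) removes the redundancy.  Purely decision-related fits
    retain the symmetry, which is harmless there: their evaluation metrics
    are scale-invariant.
    """
    if "log_rt" in fitted_vars:
        return "log_rt"
    if "effort" in fitted_vars:
        return "effort"
    return None


def _concentrated_negloglik(
    theta: np.ndarray, arr: dict, fitted_vars: frozenset, prior: PriorSpec,
    z_max: float, n_grid: int, profile_gain: bool = False,
) -> float:
    if np.any(np.abs(theta) > 20):
        return 1e10
    lat = _latents_from_theta(theta, arr, z_max, n_grid)
    gauge = _gauge_var(fitted_vars)
    ll = 0.0
    for var in fitted_vars:
        y = arr["observed"][var]
        ok = np.isfinite(y)
        if var == "com":
            q = np.clip(lat["com"][ok], _COM_CLAMP, 1.0 - _COM_CLAMP)
            yy = y[ok]
            ll += float(np.sum(yy * np.log(q) + (1.0 - yy) * np.log1p(-q)))
        else:
            x = lat[var][ok]
            yy = y[ok]
            if len(yy) < 3:
                continue
            if var == gauge:
                intercept, slope, sd = _profile_intercept_only(x, yy)
            elif var == "gain" and not profile_gain:
                intercept, slope, sd = _profile_fixed_slope(x, yy, float(np.exp(theta[5])))
            else:
                intercept, slope, sd = _profile_affine(x, yy)
            r = (yy - intercept - slope * x) / sd
            ll += float(-0.5 * np.sum(r**2) - len(yy) * (np.log(sd) + 0.5 * np.log(2 * np.pi)))
    return -(ll + prior.logpdf(theta))


def _profiled_gain_slope(theta: np.ndarray, arr: dict, z_max: float, n_grid: int) -> float:
    """Freely profiled gain slope at a parameter point (start-value heuristic)."""
    lat = _latents_from_theta(theta, arr, z_max, n_grid)
    y = arr["observed"]["gain"]
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return 0.0
    _, slope, _ = _profile_affine(lat["gain"][ok], y[ok])
    return float(np.log(np.clip(slope, 1e-3, 1e3)))


def _finite_difference_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * step**2)
    return 0.5 * (H + H.T)


_DEFAULT_STARTS = np.log(
    [
        [0.05, 0.5, 0.02, 1.0, 0.1],
        [0.02, 0.2, 0.05, 1.2, 0.05],
        [0.1, 1.0, 0.005, 1.0, 0.3],
        [0.3, 2.0, 0.1, 1.5, 0.02],
    ]
)


def _grid_starts(objective_profiled, gain_slope_at, n_best: int = 3) -> list:
    """Coarse global scan over (alpha, beta, gamma) for starting points.

    Condition modifiers start neutral (kR = 1, kAlpha = alpha).  Scoring
    profiles the gain slope freely; the selected points then carry their
    profiled slope as the starting value of the jointly fitted slope.
    The scan covers several decades of each rate parameter, which is what
    makes the subsequent local searches reliable on this multi-plateau
    surface.
    """
    la_grid = np.log(np.geomspace(0.01, 1.0, 7))
    lb_grid = np.log(np.geomspace(0.05, 5.0, 6))
    lg_grid = np.log(np.geomspace(0.005, 2.0, 6))
    scored = []
    for la in la_grid:
        for lb in lb_grid:
            for lg in lg_grid:
                x = np.array([la, lb, lg, 0.0, la, 0.0])
                scored.append((objective_profiled(x), x))
    scored.sort(key=lambda t: t[0])
    starts = []
    for _, x in scored[:n_best]:
        x = x.copy()
        x[5] = gain_slope_at(x)
        starts.append(x)
    return starts


def fit_subject(
    trials: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    fitted_vars: Iterable[str] = ALL_VARS,
    n_restarts: int = 8,
    seed: int = 0,
    epsilon: float = 0.01,
    z_max: float = 20.0,
    n_grid: int = 385,
    maxiter: int = 400,
) -> FitResult:
    """MAP + Laplace fit of one subject's trial table.

    Multi-start Nelder-Mead on the concentrated log-joint:
    a fixed fan of starting points covering plausible behavioural scales,
    topped up with seeded jitter, keeping the best mode.  Non-convergence
    of every restart is flagged on the result, not raised.
    """
    priors = priors or PriorSpec()
    fitted = frozenset(fitted_vars)
    if not fitted:
        raise ValueError("fitted_vars must not be empty")
    if not fitted <= set(ALL_VARS):
        raise ValueError(f"unknown fitted variables: {sorted(fitted - set(ALL_VARS))}")
    if len(trials) < 10:
        raise ValueError(f"need >= 10 trials to fit, got {len(trials)}")
    subject = str(trials["subject"].iloc[0]) if "subject" in trials else "?"

    arr = _subject_arrays(trials, epsilon)
    rng = np.random.default_rng(seed)

    def objective(theta):
        return _concentrated_negloglik(theta, arr, fitted, priors, z_max, n_grid)

    def objective_profiled(theta):
        return _concentrated_negloglik(
            theta, arr, fitted, priors, z_max, n_grid, profile_gain=True
        )

    def gain_slope_at(theta):
        if "gain" not in fitted:
            return priors.gain_slope_loc
        return _profiled_gain_slope(theta, arr, z_max, n_grid)

    starts = _grid_starts(objective_profiled, gain_slope_at)
    for s in _DEFAULT_STARTS[:2]:
        s6 = np.concatenate([s, [0.0]])
        s6[5] = gain_slope_at(s6)
        starts.append(s6)
    while len(starts) < n_restarts:
        starts.append(starts[len(starts) % 3] + 0.5 * rng.standard_normal(6))
    starts = starts[:max(n_restarts, 3)]

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # polish: restarted simplexes escape premature collapse on flat ridges
    for _ in range(3):
        res = minimize(
            objective, best.x, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-6},
        )
        improved = res.fun < best.fun - 1e-6
        if res.fun < best.fun:
            best = res
        if not improved:
            break
    theta = np.asarray(best.x, dtype=float)

    # Laplace covariance at the mode
    H = _finite_difference_hessian(objective, theta)
    try:
        eigval, eigvec = np.linalg.eigh(H)
        eigval = np.clip(eigval, 1e-8, None)
        cov = (eigvec / eigval) @ eigvec.T
        log_det_H = float(np.sum(np.log(eigval)))
    except np.linalg.LinAlgError:
        cov = np.full((len(theta), len(theta)), np.nan)
        log_det_H = np.nan
    log_evidence = float(-best.fun + 0.5 * len(theta) * np.log(2 * np.pi) - 0.5 * log_det_H)

    # profiled nuisances and postdictions at the mode
    lat = _latents_from_theta(theta, arr, z_max, n_grid)
    gauge = _gauge_var(fitted)
    maps = {}
    noise = {}
    post = {}
    for var in CONTINUOUS_VARS:
        y = arr["observed"][var]
        ok = np.isfinite(y)
        if var in fitted and ok.sum() >= 3:
            if var == gauge:
                intercept, slope, sd = _profile_intercept_only(lat[var][ok], y[ok])
            elif var == "gain":
                intercept, slope, sd = _profile_fixed_slope(
                    lat[var][ok], y[ok], float(np.exp(theta[5]))
                )
            else:
                intercept, slope, sd = _profile_affine(lat[var][ok], y[ok])
        else:
            intercept, slope, sd = 0.0, 1.0, 1.0
        maps[var] = AffineMap(intercept=intercept, slope=max(slope, _SLOPE_FLOOR))
        noise[var] = max(sd, _NOISE_FLOOR)
        post[var] = maps[var](lat[var])
    post["com"] = lat["com"]
    post["z_opt"] = lat["z_opt"]

    alpha, beta, gamma, kR, kAlpha = np.exp(theta[:5])
    return FitResult(
        subject=subject,
        params=MCDParams(alpha=alpha, beta=beta, gamma=gamma, R=1.0, kR=kR, kAlpha=kAlpha),
        obs_params=ObservationParams(maps=maps, noise_sd=noise),
        theta=theta,
        cov=cov,
        log_evidence=log_evidence,
        fitted_vars=fitted,
        postdictions=pd.DataFrame(post, index=arr["index"]),
        n_restarts=len(starts),
        best_objective=float(best.fun),
        converged=any_converged,
        prior=priors,
    )


def fit_all_subjects(
    trials: pd.DataFrame, fitted_vars: Iterable[str] = ALL_VARS, **kwargs
) -> Dict[str, FitResult]:
    """Independent per-subject fits over a multi-subject trial table."""
    return {
        str(subj): fit_subject(grp, fitted_vars=fitted_vars, **kwargs)
        for subj, grp in trials.groupby("subject", sort=True)
    }


def latent_predictions(
    fit: FitResult, trials: pd.DataFrame,
    variables: Sequence[str] = ALL_VARS,
    epsilon: float = 0.01, z_max: float = 20.0, n_grid: int = 385,
) -> pd.DataFrame:
    """Latent model outputs for arbitrary trials under fitted core parameters."""
    arr = _subject_arrays(trials, epsilon)
    lat = _latents_from_theta(fit.theta, arr, z_max, n_grid)
    return pd.DataFrame({v: lat[v] for v in variables}, index=arr["index"])


def predict_out_of_sample(
    fit: FitResult, trials: pd.DataFrame, held_out_vars: Iterable[str], **kwargs
) -> pd.DataFrame:
    """Out-of-sample latent predictions for variables absent from the fit.

    Raises if a requested variable was used during fitting.  Predictions
    are latent (unmapped): their evaluation metric, within-subject Pearson
    correlation, is invariant to the missing affine rescaling.
    """
    held = frozenset(held_out_vars)
    overlap = held & fit.fitted_vars
    if overlap:
        raise ValueError(f"held-out variables were fitted: {sorted(overlap)}")
    return latent_predictions(fit, trials, variables=sorted(held), **kwargs)


def parameter_recovery(
    config=None, n_rep: int = 20, seed: int = 0,
    fitted_vars: Iterable[str] = ALL_VARS, n_restarts: int = 6,
    truth_spread: Optional[float] = 0.4, **fit_kwargs
) -> pd.DataFrame:
    """Simulate subjects, refit them, and score parameter recovery.

    Ground-truth core parameters are drawn log-normally around the
    configured population medians with log-scale ``truth_spread`` (default
    0.4): a recovery study should probe the estimator across the plausible
    parameter range, which is wider than the within-study population
    spread but still confined to behaviourally sensible regimes (very
    small unitary costs give ceiling-level effort on every trial, very
    large ones give none; both are uninformative about the efficacies).
    Pass ``truth_spread=None`` to keep the configured spread.
    Returns one row per core parameter with the truth-vs-estimate Spearman
    rank correlation, mean bias and RMSE on the log scale (the bias
    includes the effort-unit conversion implied by the fitting gauge).
    """
    from .simulate import SimConfig, simulate_experiment
    from dataclasses import replace as _dc_replace

    if n_rep < 10:
        raise ValueError("need n_rep >= 10 for a meaningful recovery study")
    config = config or SimConfig()
    config = _dc_replace(config, n_subjects=n_rep, seed=seed)
    if truth_spread is not None:
        scale = dict(config.param_scale)
        scale.update(alpha=truth_spread, beta=truth_spread, gamma=truth_spread)
        config = _dc_replace(config, param_scale=scale)

    # well-specified setting: priors match the generating population,
    # expressed in the fitting gauge (log-RT units of z)
    lam = 1.0 / config.map_loc["log_rt"][1]
    loc = {
        "alpha": float(np.log(config.param_loc["alpha"] * lam)),
        "beta": float(np.log(config.param_loc["beta"] * lam)),
        "gamma": float(np.log(config.param_loc["gamma"] * lam)),
        "kR": float(np.log(config.param_loc["kR"])),
        "kAlpha": float(np.log(config.param_loc["kAlpha"] * lam)),
    }
    spread = truth_spread if truth_spread is not None else 0.4
    scale = {n: spread for n in ("alpha", "beta", "gamma")}
    scale["kR"] = max(config.param_scale["kR"], 0.1)
    scale["kAlpha"] = max(config.param_scale["kAlpha"], 0.1)
    priors = fit_kwargs.pop(
        "priors",
        PriorSpec(
            core_loc=loc,
            core_scale=scale,
            gain_slope_loc=float(np.log(config.map_loc["gain"][1])),
            gain_slope_scale=max(config.map_scale["gain"][1], 0.05),
        ),
    )
    trials, truth = simulate_experiment(config)
    fits = fit_all_subjects(
        trials, fitted_vars=fitted_vars, n_restarts=n_restarts, seed=seed,
        priors=priors, **fit_kwargs
    )
    truth = truth.set_index("subject")
    rows = []
    for i, name in enumerate(_PARAM_NAMES):
        lt = np.log(truth[name].to_numpy(float))
        le = np.array([fits[s].theta[i] for s in truth.index])
        rho = stats.spearmanr(lt, le).statistic if np.std(lt) > 0 else np.nan
        rows.append(
            {
                "param": name,
                "rank_corr": float(rho),
                "bias_log": float(np.mean(le - lt)),
                "rmse_log": float(np.sqrt(np.mean((le - lt) ** 2))),
                "n": n_rep,
            }
        )
    return pd.DataFrame(rows).set_index("param")


def permutation_chance_level(
    obs: pd.DataFrame,
    predictions: pd.DataFrame,
    variables: Sequence[str] = ALL_VARS,
    n_perm: int = 500,
    seed: int = 0,
) -> pd.Series:
    """95th percentile of group-average correlations under the null.

    For each permutation, predicted values are shuffled across trials
    within each subject, breaking the trial alignment while preserving
    both marginals; the group-average observed-predicted correlation is
    recorded, and the 95th percentile over permutations is the chance
    level for each variable.
    """
    if n_perm < 200:
        raise ValueError("need n_perm >= 200 for a stable 95th percentile")
    rng = np.random.default_rng(seed)
    groups = []
    for _, grp in obs.groupby("subject", sort=True):
        idx = grp.index
        groups.append(
            {
                v: (grp[v].to_numpy(float), predictions[v].reindex(idx).to_numpy(float))
                for v in variables
            }
        )
    null = {v: np.empty(n_perm) for v in variables}
    for p in range(n_perm):
        for v in variables:
            rs = []
            for g in groups:
                y, yhat = g[v]
                ok = np.isfinite(y) & np.isfinite(yhat)
                if ok.sum() < 3:
                    continue
                ys, yh = y[ok], yhat[ok]
                if np.std(ys) == 0 or np.std(yh) == 0:
                    continue
                rs.append(np.corrcoef(ys, rng.permutation(yh))[0, 1])
            null[v][p] = np.mean(rs) if rs else np.nan
    return pd.Series(
        {v: float(np.nanpercentile(null[v], 95)) for v in variables}, name="chance_95"
    )
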