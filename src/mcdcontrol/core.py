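"""Closed-form equations of the metacognitive control of decisions (MCD) model.

The model describes a controller that decides how much cognitive resource
``z`` to invest in a two-alternative value-based choice.  Each option carries
a probabilistic value representation summarised by a mode ``mu`` and a
variance ``sigma`` (``sigma`` is a VARIANCE everywhere in this package, not a
standard deviation).  Investing resources has two effects:

* type #1 efficacy ``beta``: precision of the value representations grows
  linearly with ``z`` (``1/sigma(z) = 1/sigma0 + beta*z``);
* type #2 efficacy ``gamma``: the modes are stochastically perturbed, with
  per-option perturbations ``delta_i ~ Normal(0, gamma*z)`` so the mode
  difference receives ``ddelta ~ Normal(0, 2*gamma*z)``.

The controller selects ``z`` maximising the expected value of control
``R' * Pc_bar(z) - alpha' * z``, where ``Pc_bar`` is the anticipated choice
confidence, ``R'`` weighs decision importance (boosted by ``kR`` on
consequential trials) and ``alpha'`` is the unitary effort cost (raised by
``kAlpha`` on penalized trials).

All moment formulas use the same logistic-sigmoid moment-matching
approximation of the Gaussian CDF (``Phi(x) ~ s(pi*x/sqrt(3))``); their
accuracy is enforced by Monte-Carlo oracle tests rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "Condition",
    "ValueBelief",
    "TrialInputs",
    "MCDParams",
    "EffortAllocation",
    "MCDPrediction",
    "confidence_given_belief",
    "posterior_variance",
    "expected_abs_dmu",
    "variance_abs_dmu",
    "expected_confidence",
    "evc",
    "optimize_z",
    "optimal_effort_batch",
    "change_of_mind_prob",
    "expected_soa",
    "certainty_gain",
    "predict_trial",
]

ArrayLike = Union[float, np.ndarray]


class Condition(str, Enum):
    """Experimental condition of one choice trial."""

    NEUTRAL = "neutral"
    CONSEQUENTIAL = "consequential"
    PENALIZED = "penalized"


@dataclass(frozen=True)
class ValueBelief:
    """Probabilistic value representation of one option (mode and variance)."""

    mu: float
    sigma: float  # variance, not SD

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be a positive variance, got {self.sigma}")


@dataclass(frozen=True)
class TrialInputs:
    """Prior decision state: mode difference, shared prior variance, condition."""

    dmu0: float
    sigma0: float  # shared prior variance of both value representations
    condition: Condition = Condition.NEUTRAL

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be a positive variance, got {self.sigma0}")
        object.__setattr__(self, "condition", Condition(self.condition))


@dataclass(frozen=True)
class MCDParams:
    """Subject-level core parameters of the resource-allocation controller.

    alpha   -- effort unitary cost (>0)
    beta    -- type #1 efficacy: precision gained per unit resource (>=0)
    gamma   -- type #2 efficacy: mode-perturbation variance per unit resource (>=0)
    R       -- decision importance weight on neutral trials (>0)
    kR      -- multiplicative boost of R on consequential trials (>0)
    kAlpha  -- additive extra unitary cost on penalized trials (>=0)
    """

    alpha: float
    beta: float
    gamma: float
    R: float = 1.0
    kR: float = 1.0
    kAlpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0 or self.gamma < 0 or self.kAlpha < 0:
            raise ValueError("beta, gamma and kAlpha must be >= 0")
        if not (self.R > 0 and self.kR > 0):
            raise ValueError("R and kR must be > 0")

    def effective_R(self, condition: Condition) -> float:
        """Importance weight after the condition modifier."""
        if Condition(condition) is Condition.CONSEQUENTIAL:
            return self.R * self.kR
        return self.R

    def effective_alpha(self, condition: Condition) -> float:
        """Unitary effort cost after the condition modifier."""
        if Condition(condition) is Condition.PENALIZED:
            return self.alpha + self.kAlpha
        return self.alpha


@dataclass(frozen=True)
class EffortAllocation:
    """Resource allocation returned by the optimizer (z and the optimum z^)."""

    z: float
    z_opt: float
    evc_opt: float = float("nan")

    def __post_init__(self) -> None:
        if self.z < 0 or self.z_opt < 0:
            raise ValueError("allocated resources must be >= 0")


@dataclass(frozen=True)
class MCDPrediction:
    """Latent model outputs evaluated at the optimal allocation z^."""

    z_opt: float
    confidence: float        # Pc_bar(z^)
    q_change: float          # Q(z^), probability of changing one's mind
    soa_expected: float      # expected spreading of alternatives
    certainty_gain: float    # precision gain beta * z^
    sigma_post: float        # posterior variance sigma(z^)
    e_abs_dmu: float         # E[|dmu| | z^]
    v_abs_dmu: float         # V[|dmu| | z^]


def _sigmoid(x: ArrayLike) -> ArrayLike:
    return expit(x)


def confidence_given_belief(dmu: ArrayLike, sigma1: ArrayLike, sigma2: ArrayLike) -> ArrayLike:
    """Choice confidence given a belief state.

    Probability that the option with the larger mode truly has the larger
    value, under independent Gaussian value beliefs with variances
    ``sigma1`` and ``sigma2``:
    ``s(pi * |dmu| / sqrt(3 * (sigma1 + sigma2)))``.

    Equals 0.5 when ``dmu == 0`` and lies in (0.5, 1) otherwise.
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma1 <= 0) or np.any(sigma2 <= 0):
        raise ValueError("variances must be positive")
    x = np.pi * np.abs(dmu) / np.sqrt(3.0 * (sigma1 + sigma2))
    out = _sigmoid(x)
    return float(out) if np.isscalar(dmu) or np.ndim(out) == 0 else out


def posterior_variance(sigma0: ArrayLike, beta: float, z: ArrayLike) -> ArrayLike:
    """Variance of a value representation after investing ``z`` resources.

    Bayesian precision update: ``1 / (1/sigma0 + beta*z)``; never exceeds
    the prior variance ``sigma0``.
    """
    sigma0 = np.asarray(sigma0, dtype=float)
    if np.any(sigma0 <= 0):
        raise ValueError("sigma0 must be positive")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if np.any(np.asarray(z) < 0):
        raise ValueError("z must be >= 0")
    out = 1.0 / (1.0 / sigma0 + beta * np.asarray(z, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def expected_abs_dmu(dmu0: ArrayLike, gamma: float, z: ArrayLike) -> ArrayLike:
    """First moment of the post-effort absolute mode difference.

    |dmu0 + ddelta| with ddelta ~ Normal(0, 2*gamma*z) follows a folded
    normal; its mean (with the sigmoid moment-matched Gaussian CDF) is

        2*sqrt(gamma*z/pi)*exp(-dmu0^2/(4*gamma*z))
        + dmu0*(2*s(pi*dmu0/sqrt(6*gamma*z)) - 1)

    and reduces to |dmu0| when ``gamma*z == 0``.  Always >= |dmu0|.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    dmu0 = np.asarray(dmu0, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0")
    gz = gamma * z
    with np.errstate(divide="ignore", invalid="ignore"):
        bell = 2.0 * np.sqrt(gz / np.pi) * np.exp(-(dmu0**2) / (4.0 * gz))
        tail = dmu0 * (2.0 * _sigmoid(np.pi * dmu0 / np.sqrt(6.0 * gz)) - 1.0)
        out = np.where(gz > 0, bell + tail, np.abs(dmu0))
    return float(out) if np.ndim(out) == 0 else out


def variance_abs_dmu(dmu0: ArrayLike, gamma: float, z: ArrayLike) -> ArrayLike:
    """Second central moment of the post-effort absolute mode difference.

    ``2*gamma*z + dmu0^2 - E[|dmu| | z]^2``; zero at ``z == 0`` and clipped
    at zero against roundoff.
    """
    dmu0 = np.asarray(dmu0, dtype=float)
    z = np.asarray(z, dtype=float)
    e1 = expected_abs_dmu(dmu0, gamma, z)
    out = np.maximum(2.0 * gamma * z + dmu0**2 - np.square(e1), 0.0)
    return float(out) if np.ndim(out) == 0 else out


def expected_confidence(
    dmu0: ArrayLike, sigma0: ArrayLike, beta: float, gamma: float, z: ArrayLike
) -> ArrayLike:
    """Anticipated choice confidence Pc_bar(z) after investing ``z``.

    Combines the precision update and folded-normal moments:
    ``s(pi * E[|dmu||z] / sqrt(6 * (sigma(z) + V[|dmu||z]/2)))``.
    At ``z == 0`` this equals :func:`confidence_given_belief` at the prior.
    Strictly increasing in ``z`` whenever ``beta`` or ``gamma`` is nonzero.
    """
    e1 = expected_abs_dmu(dmu0, gamma, z)
    v1 = variance_abs_dmu(dmu0, gamma, z)
    sig = posterior_variance(sigma0, beta, z)
    out = _sigmoid(np.pi * e1 / np.sqrt(6.0 * (sig + 0.5 * v1)))
    return float(out) if np.ndim(out) == 0 else out


def change_of_mind_prob(dmu0: ArrayLike, gamma: float, z: ArrayLike) -> ArrayLike:
    """Probability Q(z) that the post-effort preference sign flips.

    ``s(-pi*|dmu0| / sqrt(6*gamma*z))`` for ``gamma*z > 0``; defined as 0 at
    ``gamma*z == 0`` (no perturbation, no reversal).  Never exceeds 0.5.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    dmu0 = np.asarray(dmu0, dtype=float)
    z = np.asarray(z, dtype=float)
    gz = gamma * z
    with np.errstate(divide="ignore", invalid="ignore"):
        q = _sigmoid(-np.pi * np.abs(dmu0) / np.sqrt(6.0 * gz))
        out = np.where(gz > 0, q, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def expected_soa(dmu0: ArrayLike, gamma: float, z: ArrayLike) -> ArrayLike:
    """Expected spreading of alternatives after investing ``z``.

    Mean of the chosen-minus-unchosen value-difference increase induced by
    the mode perturbation (a truncated-normal first moment):
    ``2*sqrt(gamma*z/pi) * exp(-dmu0^2/(4*gamma*z))``; 0 at ``gamma*z == 0``.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    dmu0 = np.asarray(dmu0, dtype=float)
    z = np.asarray(z, dtype=float)
    gz = gamma * z
    with np.errstate(divide="ignore", invalid="ignore"):
        soa = 2.0 * np.sqrt(gz / np.pi) * np.exp(-(dmu0**2) / (4.0 * gz))
        out = np.where(gz > 0, soa, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def certainty_gain(beta: float, z: ArrayLike) -> ArrayLike:
    """Precision gained by investing ``z`` resources: ``beta * z``."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    out = beta * np.asarray(z, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def evc(z: ArrayLike, inputs: TrialInputs, params: MCDParams) -> ArrayLike:
    """Expected value of control ``R' * Pc_bar(z) - alpha' * z``.

    ``R'`` and ``alpha'`` are the condition-adjusted importance weight and
    unitary cost (consequential trials multiply R by kR; penalized trials
    add kAlpha to alpha).
    """
    r_eff = params.effective_R(inputs.condition)
    a_eff = params.effective_alpha(inputs.condition)
    pc = expected_confidence(inputs.dmu0, inputs.sigma0, params.beta, params.gamma, z)
    out = r_eff * pc - a_eff * np.asarray(z, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def optimize_z(
    inputs: TrialInputs,
    params: MCDParams,
    z_max: float = 20.0,
    n_grid: int = 512,
    xatol: float = 1e-7,
) -> EffortAllocation:
    """MCD-optimal resource allocation z^ on ``[0, z_max]``.

    Uniform grid scan followed by bounded scalar refinement around the best
    grid point; ties within tolerance resolve to the smallest allocation.
    Emits a warning when the optimum sits at the upper bound (``z_max``
    probably truncates the problem).
    """
    if not z_max > 0:
        raise ValueError("z_max must be > 0")
    if params.beta == 0 and params.gamma == 0:
        # benefit is flat in z, cost strictly increasing: optimum is zero
        return EffortAllocation(z=0.0, z_opt=0.0, evc_opt=float(evc(0.0, inputs, params)))

    grid = np.linspace(0.0, z_max, n_grid)
    values = evc(grid, inputs, params)
    # smallest grid argmax among near-ties
    best = values.max()
    i = int(np.flatnonzero(values >= best - 1e-12)[0])

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda t: -evc(t, inputs, params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    z_hat, v_hat = float(res.x), float(-res.fun)
    # prefer the smaller of grid point and refined point on (near-)ties,
    # and never return a worse value than the scan found
    if v_hat < best or (abs(v_hat - best) <= 1e-12 and grid[i] < z_hat):
        z_hat, v_hat = float(grid[i]), float(best)
    v0 = float(evc(0.0, inputs, params))
    if v0 >= v_hat - 1e-12:
        z_hat, v_hat = 0.0, v0
    if z_hat >= z_max - max(1e-6, xatol):
        warnings.warn(
            f"optimal allocation {z_hat:.6g} hit the search bound z_max={z_max}; "
            "the optimum may be truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    return EffortAllocation(z=z_hat, z_opt=z_hat, evc_opt=v_hat)


def optimal_effort_batch(
    dmu0: np.ndarray,
    sigma0: np.ndarray,
    r_eff: np.ndarray,
    alpha_eff: np.ndarray,
    beta: float,
    gamma: float,
    z_max: float = 20.0,
    n_grid: int = 513,
) -> np.ndarray:
    """Vectorised z^ for many trials at once (grid + parabolic refinement).

    Used on the hot path of model fitting, where a smooth approximation of
    the argmax matters more than the last decimal; the scalar
    :func:`optimize_z` remains the reference implementation.
    """
    dmu0 = np.atleast_1d(np.asarray(dmu0, dtype=float))
    sigma0 = np.atleast_1d(np.asarray(sigma0, dtype=float))
    r_eff = np.broadcast_to(np.asarray(r_eff, dtype=float), dmu0.shape)
    alpha_eff = np.broadcast_to(np.asarray(alpha_eff, dtype=float), dmu0.shape)
    if beta == 0 and gamma == 0:
        return np.zeros_like(dmu0)

    grid = np.linspace(0.0, z_max, n_grid)
    pc = expected_confidence(dmu0[:, None], sigma0[:, None], beta, gamma, grid[None, :])
    values = r_eff[:, None] * pc - alpha_eff[:, None] * grid[None, :]
    i = np.argmax(values, axis=1)

    # parabolic (three-point) refinement of each interior argmax
    i_in = np.clip(i, 1, n_grid - 2)
    y0 = np.take_along_axis(values, (i_in - 1)[:, None], axis=1)[:, 0]
    y1 = np.take_along_axis(values, i_in[:, None], axis=1)[:, 0]
    y2 = np.take_along_axis(values, (i_in + 1)[:, None], axis=1)[:, 0]
    denom = y0 - 2.0 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = grid[1] - grid[0]
    z_hat = grid[i_in] + shift * h
    z_hat = np.where((i == 0) | (i == n_grid - 1), grid[i], z_hat)
    return np.clip(z_hat, 0.0, z_max)


def predict_trial(
    inputs: TrialInputs,
    params: MCDParams,
    z_max: float = 20.0,
    n_grid: int = 512,
) -> MCDPrediction:
    """All latent MCD outputs of one trial at the optimal allocation z^."""
    alloc = optimize_z(inputs, params, z_max=z_max, n_grid=n_grid)
    z = alloc.z_opt
    return MCDPrediction(
        z_opt=z,
        confidence=float(
            expected_confidence(inputs.dmu0, inputs.sigma0, params.beta, params.gamma, z)
        ),
        q_change=float(change_of_mind_prob(inputs.dmu0, params.gamma, z)),
        soa_expected=float(expected_soa(inputs.dmu0, params.gamma, z)),
        certainty_gain=float(certainty_gain(params.beta, z)),
        sigma_post=float(posterior_variance(inputs.sigma0, params.beta, z)),
        e_abs_dmu=float(expected_abs_dmu(inputs.dmu0, params.gamma, z)),
        v_abs_dmu=float(variance_abs_dmu(inputs.dmu0, params.gamma, z)),
    )
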