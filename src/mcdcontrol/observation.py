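"""Mapping between the latent MCD model and observed behavioural variables.

Pre-choice value ratings and value-certainty ratings (both on [0,1] scales)
proxy the prior decision state: the rating difference stands for the prior
mode difference and the inverse mean certainty rating for the prior
variance.  In the other direction, five continuous observables (choice
confidence, spreading of alternatives, certainty gain, log response time,
subjective effort rating) are affine transforms of the corresponding latent
model quantities — two nuisance parameters (intercept, positive slope) plus
a Gaussian noise SD each — while the binary change-of-mind observable is
Bernoulli with the model's unmapped reversal probability Q(z^).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .core import (
    Condition,
    MCDParams,
    MCDPrediction,
    TrialInputs,
    predict_trial,
)

__all__ = [
    "CONTINUOUS_VARS",
    "ALL_VARS",
    "DECISION_VARS",
    "EFFORT_VARS",
    "AffineMap",
    "ObservationParams",
    "TrialRecord",
    "proxy_inputs",
    "predict_observables",
    "latent_for_variable",
    "trial_loglik",
]

#: continuous observables, each with its own affine map and noise SD
CONTINUOUS_VARS = ("confidence", "soa", "gain", "log_rt", "effort")
ALL_VARS = CONTINUOUS_VARS + ("com",)
#: the out-of-sample split used throughout: decision- vs effort-related
DECISION_VARS = frozenset({"confidence", "com", "soa", "gain"})
EFFORT_VARS = frozenset({"log_rt", "effort"})

_COM_CLAMP = 1e-6


@dataclass(frozen=True)
class AffineMap:
    """Linear rescaling ``y = intercept + slope * x`` with positive slope."""

    intercept: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _default_maps() -> dict:
    return {v: AffineMap() for v in CONTINUOUS_VARS}


def _default_noise() -> dict:
    return {v: 0.1 for v in CONTINUOUS_VARS}


@dataclass(frozen=True)
class ObservationParams:
    """Per-variable affine nuisance maps and Gaussian noise SDs."""

    maps: Mapping[str, AffineMap] = field(default_factory=_default_maps)
    noise_sd: Mapping[str, float] = field(default_factory=_default_noise)

    def __post_init__(self) -> None:
        for v in CONTINUOUS_VARS:
            if v not in self.maps:
                raise ValueError(f"missing affine map for '{v}'")
            if v not in self.noise_sd or not self.noise_sd[v] > 0:
                raise ValueError(f"noise_sd for '{v}' must be > 0")


@dataclass(frozen=True)
class TrialRecord:
    """One observed experimental trial (ratings, choice, RT, confidence, effort).

    Post-choice fields are optional so that pre-only (simulator input or
    choice-only dataset) records can be represented.
    """

    subject: str
    trial: int
    condition: Condition
    vr0_a: float
    vr0_b: float
    vcr0_a: float
    vcr0_b: float
    choice: Optional[str] = None          # "a" or "b"
    rt: Optional[float] = None            # seconds
    confidence_obs: Optional[float] = None
    effort_obs: Optional[float] = None
    vr1_a: Optional[float] = None
    vr1_b: Optional[float] = None
    vcr1_a: Optional[float] = None
    vcr1_b: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        for name in ("vr0_a", "vr0_b", "vcr0_a", "vcr0_b",
                     "confidence_obs", "effort_obs",
                     "vr1_a", "vr1_b", "vcr1_a", "vcr1_b"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside the [0, 1] rating scale")
        if self.rt is not None and not self.rt > 0:
            raise ValueError(f"rt must be positive, got {self.rt}")
        if self.choice is not None and self.choice not in ("a", "b"):
            raise ValueError(f"choice must be 'a' or 'b', got {self.choice!r}")

    @property
    def has_post(self) -> bool:
        return None not in (self.vr1_a, self.vr1_b, self.vcr1_a, self.vcr1_b)


def proxy_inputs(record: TrialRecord, epsilon: float = 0.01) -> TrialInputs:
    """Prior decision state proxied from the pre-choice ratings.

    dmu0 = vr0_a - vr0_b; sigma0 = 1 / max(mean certainty rating, epsilon)
    (the floor avoids an infinite prior variance for all-zero certainty
    reports).  The condition label passes through unchanged.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    vcr0 = 0.5 * (record.vcr0_a + record.vcr0_b)
    return TrialInputs(
        dmu0=record.vr0_a - record.vr0_b,
        sigma0=1.0 / max(vcr0, epsilon),
        condition=record.condition,
    )


def latent_for_variable(pred: MCDPrediction, var: str) -> float:
    """Latent model quantity standing behind one observable."""
    latents = {
        "confidence": pred.confidence,
        "soa": pred.soa_expected,
        "gain": pred.certainty_gain,
        "log_rt": pred.z_opt,
        "effort": pred.z_opt,
        "com": pred.q_change,
    }
    try:
        return latents[var]
    except KeyError:
        raise KeyError(f"unknown observable '{var}'") from None


def predict_observables(pred: MCDPrediction, obs: ObservationParams) -> dict:
    """Affinely rescaled observables for one latent prediction.

    Continuous outputs are not clipped here; clipping to rating scales is
    the simulator's business.  The change-of-mind probability is the
    unmapped ``Q(z^)``.
    """
    out = {v: float(obs.maps[v](latent_for_variable(pred, v))) for v in CONTINUOUS_VARS}
    out["com"] = pred.q_change
    return out


def _observed_value(record: TrialRecord, var: str) -> float:
    """Observed counterpart of one fitted variable (may require post ratings)."""
    from . import analysis  # local import: analysis depends on this module too

    if var == "confidence":
        if record.confidence_obs is None:
            raise ValueError("record lacks a confidence report")
        return record.confidence_obs
    if var == "log_rt":
        if record.rt is None:
            raise ValueError("record lacks a response time")
        return float(np.log(record.rt))
    if var == "effort":
        if record.effort_obs is None:
            raise ValueError("record lacks an effort report")
        return record.effort_obs
    if var == "soa":
        return analysis.observed_soa(record)
    if var == "gain":
        return analysis.observed_certainty_gain(record)
    raise KeyError(f"unknown continuous observable '{var}'")


def trial_loglik(
    record: TrialRecord,
    core: MCDParams,
    obs: ObservationParams,
    fitted_vars: Iterable[str],
    epsilon: float = 0.01,
    z_max: float = 20.0,
) -> float:
    """Log-likelihood of one trial's observations under the model.

    Sums, over the fitted variables, Gaussian log-densities of the observed
    continuous values against their affine predictions (log-RT is the
    modelled quantity for response times) and a Bernoulli log-mass for the
    change-of-mind class, with the success probability clamped away from 0
    and 1 so that a structural-zero prediction (gamma = 0) meets an observed
    reversal with a finite penalty.
    """
    from . import analysis

    fitted = set(fitted_vars)
    if not fitted:
        raise ValueError("fitted_vars must not be empty")
    unknown = fitted - set(ALL_VARS)
    if unknown:
        raise ValueError(f"unknown fitted variables: {sorted(unknown)}")

    pred = predict_trial(proxy_inputs(record, epsilon), core, z_max=z_max)
    hat = predict_observables(pred, obs)

    ll = 0.0
    for var in fitted:
        if var == "com":
            label = analysis.classify_change_of_mind(record)
            if label == "excluded_tie":
                continue
            y = 1.0 if label == "change_of_mind" else 0.0
            q = min(max(hat["com"], _COM_CLAMP), 1.0 - _COM_CLAMP)
            ll += y * np.log(q) + (1.0 - y) * np.log1p(-q)
        else:
            y = _observed_value(record, var)
            sd = obs.noise_sd[var]
            r = (y - hat[var]) / sd
            ll += -0.5 * r * r - np.log(sd) - 0.5 * np.log(2.0 * np.pi)
    return float(ll)
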