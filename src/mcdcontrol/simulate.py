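"""Generative simulator of the two-alternative rating/choice experiment.

Emulates the study design end to end: a population of subjects with
heterogeneous control parameters, 74 trials each (60 neutral, 7
consequential, 7 penalized, randomly interleaved), pre-choice value and
certainty ratings on [0, 1] scales, and the six dependent variables
produced by the MCD generative process — the optimal allocation z^ drives
response time and effort reports, the mode perturbations drive choices,
changes of mind, spreading of alternatives and post-choice ratings, and
the precision gain drives post-choice certainty.

Population and observation-noise defaults were chosen once so that the
simulated group statistics land in the empirically reported ranges
(change-of-mind rate near 15%, mean spreading of alternatives a few
hundredths of the rating scale, mean certainty gain around 0.1, response
times of a few seconds); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    Condition,
    MCDParams,
    TrialInputs,
    confidence_given_belief,
    predict_trial,
)
from .observation import (
    CONTINUOUS_VARS,
    AffineMap,
    ObservationParams,
    TrialRecord,
    proxy_inputs,
)

__all__ = [
    "PerturbationDraw",
    "SimConfig",
    "sample_subject_params",
    "sample_trial_inputs",
    "simulate_trial",
    "simulate_latents",
    "simulate_experiment",
    "value_to_rating",
]


@dataclass(frozen=True)
class PerturbationDraw:
    """Realised per-option mode perturbations and their difference.

    delta_a and delta_b are independent Normal(0, gamma*z) draws, so the
    mode-difference perturbation ddelta = delta_a - delta_b is
    Normal(0, 2*gamma*z).
    """

    delta_a: float
    delta_b: float

    @property
    def ddelta(self) -> float:
        return self.delta_a - self.delta_b


def _default_param_loc() -> Dict[str, float]:
    # natural-scale medians of the log-normal population
    return {"alpha": 0.02, "beta": 0.2, "gamma": 0.025, "R": 1.0, "kR": 1.3, "kAlpha": 0.1}


def _default_param_scale() -> Dict[str, float]:
    # log-scale SDs; R degenerate at 1 (its scale is absorbed by alpha and
    # the affine output maps, mirroring the fitting convention)
    return {"alpha": 0.2, "beta": 0.2, "gamma": 0.2, "R": 0.0, "kR": 0.15, "kAlpha": 0.3}


def _default_map_loc() -> Dict[str, Tuple[float, float]]:
    # (intercept, slope) population centres per observable
    return {
        "confidence": (0.0, 1.0),
        "soa": (0.0, 1.0),
        "gain": (0.0, 0.1),
        "log_rt": (0.0, 0.25),
        "effort": (0.1, 0.1),
    }


def _default_map_scale() -> Dict[str, Tuple[float, float]]:
    # (intercept SD, log-slope SD)
    return {
        "confidence": (0.0, 0.0),
        "soa": (0.0, 0.0),
        "gain": (0.02, 0.2),
        "log_rt": (0.15, 0.1),
        "effort": (0.05, 0.1),
    }


def _default_noise() -> Dict[str, float]:
    return {"confidence": 0.08, "soa": 0.05, "gain": 0.05, "log_rt": 0.25, "effort": 0.08}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated experiment."""

    n_subjects: int = 41
    n_neutral: int = 60
    n_consequential: int = 7
    n_penalized: int = 7
    value_rating_beta: Tuple[float, float] = (2.0, 2.0)
    certainty_rating_beta: Tuple[float, float] = (1.2, 1.2)
    param_loc: Dict[str, float] = field(default_factory=_default_param_loc)
    param_scale: Dict[str, float] = field(default_factory=_default_param_scale)
    map_loc: Dict[str, Tuple[float, float]] = field(default_factory=_default_map_loc)
    map_scale: Dict[str, Tuple[float, float]] = field(default_factory=_default_map_scale)
    noise_sd: Dict[str, float] = field(default_factory=_default_noise)
    epsilon: float = 0.01
    z_max: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_subjects, self.n_neutral, self.n_consequential, self.n_penalized):
            if n < 0:
                raise ValueError("counts must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_neutral + self.n_consequential + self.n_penalized

    def subject_rng(self, subject_index: int) -> np.random.Generator:
        """Independent per-subject stream derived from the global seed."""
        return np.random.default_rng([self.seed, subject_index])


def value_to_rating(value: np.ndarray) -> np.ndarray:
    """Map latent value units onto the [0, 1] rating scale.

    The identity-plus-clip read-out: latent values and ratings share the
    same scale, and the bounded rating is the clipped latent value.  This
    is the one place to swap in a different read-out model.
    """
    return np.clip(value, 0.0, 1.0)


def sample_subject_params(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[MCDParams, ObservationParams]:
    """Draw one subject's core and observation parameters.

    Core parameters and affine slopes are log-normal (positivity by
    construction); affine intercepts are Gaussian.
    """
    core_kwargs = {}
    for name in ("alpha", "beta", "gamma", "R", "kR", "kAlpha"):
        loc = config.param_loc[name]
        scale = config.param_scale[name]
        core_kwargs[name] = float(loc * np.exp(scale * rng.standard_normal())) if scale > 0 else float(loc)
    core = MCDParams(**core_kwargs)

    maps = {}
    for var in CONTINUOUS_VARS:
        ic_loc, sl_loc = config.map_loc[var]
        ic_sd, sl_sd = config.map_scale[var]
        intercept = float(ic_loc + ic_sd * rng.standard_normal()) if ic_sd > 0 else float(ic_loc)
        slope = float(sl_loc * np.exp(sl_sd * rng.standard_normal())) if sl_sd > 0 else float(sl_loc)
        maps[var] = AffineMap(intercept=intercept, slope=slope)
    obs = ObservationParams(maps=maps, noise_sd=dict(config.noise_sd))
    return core, obs


def sample_trial_inputs(
    config: SimConfig, rng: np.random.Generator, subject: str = "s01"
) -> list:
    """Pre-choice trial records for one subject.

    Value ratings are iid Beta draws (default Beta(2,2): broad, centred),
    certainty ratings iid Beta(1.2, 1.2) (nearly flat: reported certainty
    spans the scale), and the condition labels are the fixed 60/7/7
    multiset in shuffled order.
    """
    a_v, b_v = config.value_rating_beta
    a_c, b_c = config.certainty_rating_beta
    labels = (
        [Condition.NEUTRAL] * config.n_neutral
        + [Condition.CONSEQUENTIAL] * config.n_consequential
        + [Condition.PENALIZED] * config.n_penalized
    )
    order = rng.permutation(len(labels))
    records = []
    for t, idx in enumerate(order):
        records.append(
            TrialRecord(
                subject=subject,
                trial=t,
                condition=labels[idx],
                vr0_a=float(rng.beta(a_v, b_v)),
                vr0_b=float(rng.beta(a_v, b_v)),
                vcr0_a=float(rng.beta(a_c, b_c)),
                vcr0_b=float(rng.beta(a_c, b_c)),
            )
        )
    return records


def simulate_trial(
    record: TrialRecord,
    core: MCDParams,
    obs: ObservationParams,
    rng: np.random.Generator,
    epsilon: float = 0.01,
    z_max: float = 20.0,
) -> TrialRecord:
    """Complete one pre-choice record with all simulated outcomes.

    Runs the controller to get z^, draws the per-option mode perturbations,
    lets the choice follow the sign of the post-effort mode difference
    (exact ties break uniformly at random), and emits the observed
    variables through the subject's affine maps plus Gaussian noise.
    Ratings are clipped to [0, 1]; response time is exp(log-RT), hence
    positive.
    """
    inputs = proxy_inputs(record, epsilon)
    pred = predict_trial(inputs, core, z_max=z_max)
    z = pred.z_opt

    sd_delta = float(np.sqrt(core.gamma * z))
    draw = PerturbationDraw(
        delta_a=float(sd_delta * rng.standard_normal()),
        delta_b=float(sd_delta * rng.standard_normal()),
    )
    dmu_post = inputs.dmu0 + draw.ddelta
    if dmu_post > 0:
        choice = "a"
    elif dmu_post < 0:
        choice = "b"
    else:
        choice = "a" if rng.random() < 0.5 else "b"

    conf_latent = confidence_given_belief(dmu_post, pred.sigma_post, pred.sigma_post)
    conf = obs.maps["confidence"](conf_latent) + obs.noise_sd["confidence"] * rng.standard_normal()
    log_rt = obs.maps["log_rt"](z) + obs.noise_sd["log_rt"] * rng.standard_normal()
    effort = obs.maps["effort"](z) + obs.noise_sd["effort"] * rng.standard_normal()

    vr1_a = value_to_rating(record.vr0_a + draw.delta_a)
    vr1_b = value_to_rating(record.vr0_b + draw.delta_b)
    gain_latent = obs.maps["gain"](pred.certainty_gain)
    vcr1_a = np.clip(
        record.vcr0_a + gain_latent + obs.noise_sd["gain"] * rng.standard_normal(), 0.0, 1.0
    )
    vcr1_b = np.clip(
        record.vcr0_b + gain_latent + obs.noise_sd["gain"] * rng.standard_normal(), 0.0, 1.0
    )

    return replace(
        record,
        choice=choice,
        rt=float(np.exp(log_rt)),
        confidence_obs=float(np.clip(conf, 0.0, 1.0)),
        effort_obs=float(np.clip(effort, 0.0, 1.0)),
        vr1_a=float(vr1_a),
        vr1_b=float(vr1_b),
        vcr1_a=float(vcr1_a),
        vcr1_b=float(vcr1_b),
    )


def simulate_latents(
    inputs: TrialInputs,
    core: MCDParams,
    n_trials: int,
    rng: np.random.Generator,
    z_max: float = 20.0,
) -> pd.DataFrame:
    """Latent generative draws at fixed inputs, for theory-consistency checks.

    Repeats the perturbation process ``n_trials`` times at the single z^
    implied by ``inputs`` and returns the realised |dmu|, change-of-mind
    indicator and spreading of alternatives — the quantities whose
    population moments the closed forms predict.
    """
    pred = predict_trial(inputs, core, z_max=z_max)
    z = pred.z_opt
    sd = np.sqrt(core.gamma * z)
    delta_a = sd * rng.standard_normal(n_trials)
    delta_b = sd * rng.standard_normal(n_trials)
    dmu_post = inputs.dmu0 + delta_a - delta_b
    ddelta = delta_a - delta_b
    com = np.sign(dmu_post) != np.sign(inputs.dmu0)
    # piecewise spreading of alternatives on the latent modes
    soa = np.where(ddelta > -inputs.dmu0, ddelta, -ddelta) if inputs.dmu0 >= 0 else np.where(
        ddelta < -inputs.dmu0, -ddelta, ddelta
    )
    return pd.DataFrame(
        {
            "abs_dmu": np.abs(dmu_post),
            "com": com.astype(float),
            "soa": soa,
            "z_opt": z,
        }
    )


def _record_to_row(rec: TrialRecord) -> dict:
    return {
        "subject": rec.subject,
        "trial": rec.trial,
        "condition": rec.condition.value,
        "vr0_a": rec.vr0_a,
        "vr0_b": rec.vr0_b,
        "vcr0_a": rec.vcr0_a,
        "vcr0_b": rec.vcr0_b,
        "choice": rec.choice,
        "rt_s": rec.rt,
        "confidence": rec.confidence_obs,
        "effort": rec.effort_obs,
        "vr1_a": rec.vr1_a,
        "vr1_b": rec.vr1_b,
        "vcr1_a": rec.vcr1_a,
        "vcr1_b": rec.vcr1_b,
    }


def simulate_experiment(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full multi-subject experiment.

    Returns the trial table (io schema) and the ground-truth parameter
    table for recovery studies.  Byte-identical under a fixed seed: each
    subject has an independent stream derived from (seed, subject index).
    """
    rows = []
    truth_rows = []
    for s in range(config.n_subjects):
        subject = f"s{s + 1:02d}"
        rng = config.subject_rng(s)
        core, obs = sample_subject_params(config, rng)
        truth = {
            "subject": subject,
            **{k: getattr(core, k) for k in ("alpha", "beta", "gamma", "R", "kR", "kAlpha")},
        }
        for var in CONTINUOUS_VARS:
            truth[f"{var}_intercept"] = obs.maps[var].intercept
            truth[f"{var}_slope"] = obs.maps[var].slope
        truth_rows.append(truth)

        for rec in sample_trial_inputs(config, rng, subject=subject):
            done = simulate_trial(
                rec, core, obs, rng, epsilon=config.epsilon, z_max=config.z_max
            )
            rows.append(_record_to_row(done))
    trials = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth_rows)
    trials.attrs["pre_only"] = False
    return trials, truth_df
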