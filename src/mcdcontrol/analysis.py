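"""Model-free statistics on trial tables.

Builds the observed dependent variables from the ratings (change-of-mind
classification, spreading of alternatives, certainty gain), runs the
within-subject standardized regressions of each variable on the absolute
pre-choice rating difference |dVR0| and the mean certainty rating VCR0,
summarises regression weights with group-level random-effects t-tests, and
produces median-split / binned tables and prediction-accuracy reports.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .observation import ALL_VARS, TrialRecord

__all__ = [
    "classify_change_of_mind",
    "observed_soa",
    "observed_certainty_gain",
    "observed_frame",
    "standardized_regression",
    "subject_regressions",
    "group_random_effects",
    "median_split_summary",
    "prediction_accuracy_report",
]

_CONDITION_DUMMIES = ("consequential", "penalized")


def _pre_post(record: TrialRecord):
    if not record.has_post:
        raise ValueError("record lacks post-choice ratings")
    if record.choice is None:
        raise ValueError("record lacks a recorded choice")


def classify_change_of_mind(record: TrialRecord) -> str:
    """Classify one choice against pre- and post-choice rating preferences.

    ``change_of_mind``: the choice contradicts the pre-choice rating
    preference but agrees with the post-choice one; ``error``: it
    contradicts both; ``consistent``: it agrees with the pre-choice
    preference.  Exactly tied ratings on the deciding comparison yield
    ``excluded_tie``.
    """
    _pre_post(record)
    pre = np.sign(record.vr0_a - record.vr0_b)
    if pre == 0:
        return "excluded_tie"
    chose = 1.0 if record.choice == "a" else -1.0
    if chose == pre:
        return "consistent"
    post = np.sign(record.vr1_a - record.vr1_b)
    if post == 0:
        return "excluded_tie"
    return "change_of_mind" if chose == post else "error"


def observed_soa(record: TrialRecord) -> float:
    """Spreading of alternatives in rating units.

    (post chosen - post unchosen) - (pre chosen - pre unchosen);
    antisymmetric under swapping the chosen/unchosen labels.
    """
    _pre_post(record)
    if record.choice == "a":
        return (record.vr1_a - record.vr1_b) - (record.vr0_a - record.vr0_b)
    return (record.vr1_b - record.vr1_a) - (record.vr0_b - record.vr0_a)


def observed_certainty_gain(record: TrialRecord, agg: str = "mean") -> float:
    """Post-minus-pre certainty rating change, averaged over the two items.

    ``agg="sum"`` switches to the summed (rather than averaged) gain.
    """
    if None in (record.vcr1_a, record.vcr1_b):
        raise ValueError("record lacks post-choice certainty ratings")
    d = (record.vcr1_a - record.vcr0_a) + (record.vcr1_b - record.vcr0_b)
    if agg == "mean":
        return 0.5 * d
    if agg == "sum":
        return d
    raise ValueError(f"agg must be 'mean' or 'sum', got {agg!r}")


def observed_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial observed variables and regressors from a trial table.

    Returns a frame indexed like ``trials`` with columns ``dvr0_abs``,
    ``vcr0``, the six dependent variables (``confidence``, ``soa``,
    ``gain``, ``log_rt``, ``effort``, ``com``) and the change-of-mind class
    label.  ``com`` is 1 for a change of mind, 0 for consistent or error
    choices, and NaN for tie-excluded trials; variables whose source
    columns are absent come out as NaN.
    """
    out = pd.DataFrame(index=trials.index)
    out["subject"] = trials["subject"]
    out["condition"] = trials["condition"]
    out["dvr0_abs"] = (trials["vr0_a"] - trials["vr0_b"]).abs()
    out["vcr0"] = 0.5 * (trials["vcr0_a"] + trials["vcr0_b"])
    out["confidence"] = trials.get("confidence", np.nan)
    out["effort"] = trials.get("effort", np.nan)
    out["log_rt"] = np.log(trials["rt_s"]) if "rt_s" in trials else np.nan

    has_post = all(c in trials for c in ("vr1_a", "vr1_b", "vcr1_a", "vcr1_b", "choice"))
    if has_post:
        from .io import row_to_record

        labels, soa, gain = [], [], []
        for _, row in trials.iterrows():
            rec = row_to_record(row)
            labels.append(classify_change_of_mind(rec))
            soa.append(observed_soa(rec))
            gain.append(observed_certainty_gain(rec))
        out["com_class"] = labels
        out["soa"] = soa
        out["gain"] = gain
        out["com"] = [
            np.nan if lab == "excluded_tie" else float(lab == "change_of_mind")
            for lab in labels
        ]
    else:
        out["com_class"] = None
        out["soa"] = np.nan
        out["gain"] = np.nan
        out["com"] = np.nan
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - np.mean(x)) / sd


def standardized_regression(
    subject_obs: pd.DataFrame,
    outcome: str,
    regressors: Sequence[str] = ("dvr0_abs", "vcr0"),
    include_conditions: bool = False,
) -> pd.Series:
    """Within-subject standardized regression of one dependent variable.

    The outcome and the continuous regressors are z-scored within subject;
    condition dummies (consequential, penalized) enter as raw 0/1 columns
    when requested.  Returns the OLS weights (intercept first).  Requires
    at least 10 usable trials and a full-rank design.  A constant outcome
    (e.g. a subject with no change of mind at all) has no variance to
    explain and yields all-zero weights rather than an error.
    """
    if outcome not in ALL_VARS:
        raise ValueError(f"unknown outcome '{outcome}'")
    cols = [outcome, *regressors]
    df = subject_obs.dropna(subset=cols)
    if len(df) < 10:
        raise ValueError(f"need >= 10 usable trials, got {len(df)}")

    names = ["const", *regressors]
    if include_conditions:
        names += list(_CONDITION_DUMMIES)
    y_raw = df[outcome].to_numpy(float)
    if np.std(y_raw, ddof=1) == 0:
        return pd.Series(np.zeros(len(names)), index=names, name=outcome)
    y = _zscore(y_raw)
    X = np.column_stack([_zscore(df[r].to_numpy(float)) for r in regressors])
    if include_conditions:
        for cond in _CONDITION_DUMMIES:
            X = np.column_stack([X, (df["condition"] == cond).to_numpy(float)])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return pd.Series(fit.params, index=names, name=outcome)


def subject_regressions(
    obs: pd.DataFrame,
    outcome: str,
    regressors: Sequence[str] = ("dvr0_abs", "vcr0"),
    include_conditions: bool = False,
) -> pd.DataFrame:
    """One standardized-regression weight vector per subject (rows)."""
    rows = {}
    for subj, grp in obs.groupby("subject", sort=True):
        rows[subj] = standardized_regression(
            grp, outcome, regressors, include_conditions=include_conditions
        )
    return pd.DataFrame(rows).T


def group_random_effects(
    weights: pd.DataFrame,
    sidedness: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Group-level random-effects summary of per-subject regression weights.

    One-sample t-tests of each weight column against zero.  ``sidedness``
    maps a column to ``"two-sided"``, ``"less"`` or ``"greater"``
    (default two-sided).  Returns mean, SEM, t, dof and p per column.
    """
    if len(weights) < 3:
        raise ValueError("need >= 3 subjects for a random-effects test")
    sidedness = dict(sidedness or {})
    rows = []
    for col in weights.columns:
        x = weights[col].to_numpy(float)
        alt = sidedness.get(col, "two-sided")
        t = stats.ttest_1samp(x, 0.0, alternative=alt)
        rows.append(
            {
                "term": col,
                "mean": float(np.mean(x)),
                "sem": float(stats.sem(x)),
                "t": float(t.statistic),
                "dof": len(x) - 1,
                "p": float(t.pvalue),
                "alternative": alt,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def median_split_summary(
    obs: pd.DataFrame,
    predictions: Optional[pd.DataFrame],
    variable: str,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Binned observed (and predicted) means, median-split by certainty.

    Within each subject, trials are split at the median of VCR0 (low/high)
    and cut into ``n_bins`` quantile bins of |dVR0|; cell means are then
    averaged across subjects (± SEM across subjects).  ``predictions`` may
    carry any number of columns aligned to ``obs`` (e.g. postdicted and
    out-of-sample predicted values); each gets its own mean/SEM columns.
    """
    value_cols = {variable: obs[variable]}
    if predictions is not None:
        for col in predictions.columns:
            value_cols[col] = predictions[col].reindex(obs.index)

    per_subject = []
    for subj, grp in obs.groupby("subject", sort=True):
        med = grp["vcr0"].median()
        vcr_half = np.where(grp["vcr0"] <= med, "low", "high")
        try:
            dbin = pd.qcut(grp["dvr0_abs"], n_bins, labels=False, duplicates="drop")
        except ValueError:
            continue
        cell = pd.DataFrame(
            {
                "vcr_half": vcr_half,
                "dvr_bin": dbin,
                **{k: v.loc[grp.index].to_numpy(float) for k, v in value_cols.items()},
            }
        )
        g = cell.groupby(["vcr_half", "dvr_bin"], observed=True).mean()
        g["subject"] = subj
        per_subject.append(g.reset_index())

    stacked = pd.concat(per_subject, ignore_index=True)
    agg = stacked.groupby(["vcr_half", "dvr_bin"], observed=True).agg(
        **{
            f"{k}_{stat}": (k, fn)
            for k in value_cols
            for stat, fn in (("mean", "mean"), ("sem", stats.sem))
        },
        n_subjects=("subject", "nunique"),
    )
    return agg.reset_index()


def _within_subject_correlations(
    obs: pd.DataFrame, pred: pd.DataFrame, variables: Iterable[str]
) -> pd.DataFrame:
    rows = {}
    for subj, grp in obs.groupby("subject", sort=True):
        r = {}
        for var in variables:
            y = grp[var].to_numpy(float)
            yhat = pred[var].reindex(grp.index).to_numpy(float)
            ok = np.isfinite(y) & np.isfinite(yhat)
            if ok.sum() >= 3 and np.std(y[ok]) > 0 and np.std(yhat[ok]) > 0:
                r[var] = float(np.corrcoef(y[ok], yhat[ok])[0, 1])
            else:
                r[var] = np.nan
        rows[subj] = r
    return pd.DataFrame(rows).T


def prediction_accuracy_report(
    obs: pd.DataFrame,
    protocol_predictions: Mapping[str, pd.DataFrame],
    variables: Sequence[str] = ALL_VARS,
    chance_levels: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Observed-vs-predicted correlation accuracy per variable and protocol.

    For each protocol (e.g. ``full``, ``decision_only``, ``effort_only``)
    and each dependent variable, reports the group mean ± SEM of the
    within-subject across-trial Pearson correlation between observed data
    and model output, alongside an optional permutation chance level.
    """
    rows = []
    for protocol, pred in protocol_predictions.items():
        avail = [v for v in variables if v in pred.columns]
        corr = _within_subject_correlations(obs, pred, avail)
        for var in avail:
            x = corr[var].dropna().to_numpy(float)
            rows.append(
                {
                    "protocol": protocol,
                    "variable": var,
                    "mean_r": float(np.mean(x)) if len(x) else np.nan,
                    "sem_r": float(stats.sem(x)) if len(x) > 1 else np.nan,
                    "n_subjects": len(x),
                    "chance_95": (chance_levels or {}).get(var, np.nan),
                }
            )
    return pd.DataFrame(rows)
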