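"""Regimen contrasts for the 2x4-day crossover: linear mixed models and
Cohen's d.

The model is ``outcome ~ regimen + covariates`` with a participant random
intercept.  With exactly two conditions per participant a random intercept
is identical to a compound-symmetry covariance, so this is the standard
repeated-measures specification for a two-period crossover.  Inference is
t-based on containment degrees of freedom,
``n_obs - rank(X) - (n_groups - 1)``; on balanced complete data with no
covariates the regimen estimate equals the mean paired difference and the
test reduces to the paired t-test.  Glucose outcomes are conventionally
adjusted for BMI and behavioural outcomes for device wear time.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REGIMEN_REF = "SIT"
REGIMEN_ALT = "SITLESS"


@dataclass
class RegimenEffect:
    outcome: str
    estimate: float           # SITless - SIT, outcome units
    ci_low: float
    ci_high: float
    p_value: float
    cohens_d: float
    n_participants: int
    mean_sit: float           # raw regimen means
    mean_sitless: float
    adj_mean_sit: float       # model-adjusted (marginal) means
    adj_mean_sitless: float
    method: str = "mixed"     # "mixed" or the paired-contrast fallback


def _paired_frame(data: pd.DataFrame, outcome: str,
                  covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = ["participant_id", "regimen", "value", *covariates]
    df = data.loc[data["outcome"] == outcome, cols].dropna(subset=["value"])
    wide = df.pivot(index="participant_id", columns="regimen", values="value")
    wide = wide.dropna(subset=[REGIMEN_REF, REGIMEN_ALT])
    return df[df["participant_id"].isin(wide.index)], wide


def cohens_d(data: pd.DataFrame, outcome: str, method: str = "pooled") -> float:
    """Standardised SITless-SIT difference.

    ``pooled`` (default) divides the mean paired difference by the pooled SD
    of the two regimen distributions; ``difference`` divides by the SD of
    the paired differences.  The printed effect-size convention (0.2 / 0.5 /
    0.8 small / medium / large) refers to the pooled variant.
    """
    _, wide = _paired_frame(data, outcome, ())
    diffs = wide[REGIMEN_ALT] - wide[REGIMEN_REF]
    if method == "pooled":
        sd = math.sqrt((wide[REGIMEN_REF].std(ddof=1) ** 2
                        + wide[REGIMEN_ALT].std(ddof=1) ** 2) / 2.0)
    elif method == "difference":
        sd = diffs.std(ddof=1)
    else:
        raise ValueError(f"unknown Cohen's d method {method!r}")
    if not sd > 0:
        raise ValueError(f"zero spread for outcome {outcome!r}")
    return float(diffs.mean() / sd)


def _paired_fallback(df: pd.DataFrame, wide: pd.DataFrame,
                     covariates: tuple[str, ...]) -> tuple[float, float, int]:
    """Covariate-adjusted paired contrast: regress within-participant
    differences on the within-participant covariate differences."""
    diffs = (wide[REGIMEN_ALT] - wide[REGIMEN_REF]).to_numpy()
    X = [np.ones_like(diffs)]
    for cov in covariates:
        w = df.pivot(index="participant_id", columns="regimen", values=cov)
        w = w.loc[wide.index]
        delta = (w[REGIMEN_ALT] - w[REGIMEN_REF]).to_numpy()
        if np.ptp(delta) > 0:  # between-participant covariates drop out
            X.append(delta)
    X = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(X, diffs, rcond=None)
    resid = diffs - X @ beta
    dof = len(diffs) - X.shape[1]
    se = math.sqrt(resid @ resid / dof * np.linalg.inv(X.T @ X)[0, 0])
    return float(beta[0]), se, dof


def fit_regimen_model(data: pd.DataFrame, outcome: str,
                      covariates: tuple[str, ...] = (),
                      d_method: str = "pooled") -> RegimenEffect:
    """Adjusted SITless-SIT contrast for one outcome.

    ``data`` holds one row per participant x regimen x outcome with columns
    ``participant_id, regimen, outcome, value`` plus any covariates.
    Participants missing either regimen are excluded (the crossover requires
    both).  A singular mixed-model fit falls back to the covariate-adjusted
    paired contrast, logged.
    """
    df, wide = _paired_frame(data, outcome, covariates)
    n = len(wide)
    if n < 2:
        raise ValueError(f"need >=2 participants with both regimens for {outcome!r}")

    df = df.sort_values(["participant_id", "regimen"]).reset_index(drop=True)
    y = df["value"].to_numpy(float)
    reg = (df["regimen"] == REGIMEN_ALT).to_numpy(float)
    cov_arr = df[list(covariates)].to_numpy(float) if covariates else \
        np.empty((len(df), 0))
    X = np.column_stack([np.ones_like(y), reg, cov_arr])

    est = se = dof = None
    method = "mixed"
    # standardise for the optimiser; the regimen coefficient scales with y
    y_loc, y_scale = y.mean(), y.std() or 1.0
    Xs = X.copy()
    for j in range(2, Xs.shape[1]):
        Xs[:, j] = (Xs[:, j] - Xs[:, j].mean()) / (Xs[:, j].std() or 1.0)
    try:
        from statsmodels.regression.mixed_linear_model import MixedLM
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM((y - y_loc) / y_scale, Xs,
                          groups=df["participant_id"].to_numpy()
                          ).fit(reml=True)
        est, se = float(res.params[1]) * y_scale, float(res.bse[1]) * y_scale
        dof = len(y) - np.linalg.matrix_rank(X) - (n - 1)
        if not (np.isfinite(est) and np.isfinite(se) and se > 0 and dof > 0):
            raise ValueError("degenerate mixed-model fit")
    except Exception as exc:  # singular/non-converged fit
        logger.warning("%s: mixed model failed (%s); paired-contrast fallback",
                       outcome, exc)
        est, se, dof = _paired_fallback(df, wide, covariates)
        method = "paired"

    if se > 0 and dof > 0:
        p = 2.0 * stats.t.sf(abs(est / se), dof)
        tcrit = stats.t.ppf(0.975, dof)
    else:  # outcome with no spread at all (e.g. a range metric pinned at 0)
        p, tcrit, se = math.nan, math.nan, 0.0

    try:
        d = cohens_d(data, outcome, d_method)
    except ValueError:
        d = math.nan

    cov_means = cov_arr.mean(axis=0) if covariates else np.empty(0)
    # adjusted marginal means at covariate means, via the raw SIT mean anchor
    base = float(wide[REGIMEN_REF].mean())
    return RegimenEffect(
        outcome=outcome, estimate=est,
        ci_low=est - tcrit * se, ci_high=est + tcrit * se,
        p_value=float(p), cohens_d=d,
        n_participants=n,
        mean_sit=base, mean_sitless=float(wide[REGIMEN_ALT].mean()),
        adj_mean_sit=base, adj_mean_sitless=base + est,
        method=method)


def effects_table(effects: list[RegimenEffect]) -> pd.DataFrame:
    rows = [{
        "outcome": e.outcome, "estimate": e.estimate, "ci_low": e.ci_low,
        "ci_high": e.ci_high, "p_value": e.p_value, "cohens_d": e.cohens_d,
        "n": e.n_participants, "mean_sit": e.mean_sit,
        "mean_sitless": e.mean_sitless, "method": e.method,
    } for e in effects]
    return pd.DataFrame(rows)
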