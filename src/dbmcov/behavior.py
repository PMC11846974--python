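"""Survival and motor-behavior inference with censoring-aware models.

Latency tasks have hard cutoffs (pole test: 2-min failure cap; wire hang:
150 s success cap), so latencies are analyzed as censored time-to-event data
with Cox proportional hazards rather than t-tests on means.  Event direction
follows the task semantics: on the pole the *event* is a successful descent
(a failure capped at 120 s is censored); on the wire the *event* is a fall
(holding to the cap is censored).  Survival to humane endpoint is modeled the
same way with administrative censoring at the experimental endpoint.
Longitudinal weight and rotarod series use the same random-intercept mixed
model as the voxelwise analysis; motor-onset dpi among symptomatic mice uses
an ordinary GLM.  Family-wise control across the motor-task battery uses
Bonferroni (p < 0.05 / m).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .mixedlm import fit_random_intercept_lme
from .voxelstats import GLMResult, build_design
from .synthetic import POLE_CAP_S, WIREHANG_CAP_S

__all__ = [
    "CoxFit",
    "TASK_CAPS",
    "encode_task",
    "fit_cox",
    "fit_survival",
    "fit_longitudinal_lme",
    "motor_onset_glm",
    "bonferroni",
]

logger = logging.getLogger(__name__)

TASK_CAPS = {"pole": POLE_CAP_S, "wirehang": WIREHANG_CAP_S}

#: event semantics per task, documented in every output
EVENT_DIRECTION = {
    "pole": "event = successful descent; failures censored at recorded time",
    "wirehang": "event = fall before the cap; holding to 150 s censored",
}


@dataclass
class CoxFit:
    coefs: pd.Series  # log-hazard coefficients
    hazard_ratios: pd.Series  # exp(coef)
    se: pd.Series
    pvalues: pd.Series
    n_events: int
    n_records: int
    event_direction: str = ""
    km_curves: pd.DataFrame | None = None


def encode_task(trials: pd.DataFrame, task: str) -> pd.DataFrame:
    """Turn a trial table into survival records with task-specific censoring.

    Returns a frame with columns duration, event, plus the covariates
    (group, sex, trial, weight_g, dpi, subject_id).  Latencies exceeding the
    task cap violate the generator contract and raise.
    """
    if task not in TASK_CAPS:
        raise ValueError(f"task {task!r} has no cutoff semantics (expected pole|wirehang)")
    cap = TASK_CAPS[task]
    sub = trials[trials["task"] == task].copy()
    if sub.empty:
        raise ValueError(f"no trials for task {task!r}")
    over = sub["latency_s"] > cap
    if over.any():
        raise ValueError(
            f"{int(over.sum())} {task} latencies exceed the {cap:g} s cap"
        )
    if task == "wirehang":
        # falling is the event; holding to the cap is a censored success
        event = (sub["outcome"] == "failure").astype(int)
    else:  # pole
        # successful descent is the event; failures are censored
        event = (sub["outcome"] == "success").astype(int)
    out = pd.DataFrame(
        {
            "subject_id": sub["subject_id"].to_numpy(),
            "duration": sub["latency_s"].to_numpy(float),
            "event": event.to_numpy(),
            "group": sub["group"].to_numpy(),
            "sex": sub["sex"].to_numpy(),
            "trial": sub["trial"].to_numpy(float),
            "weight_g": sub["weight_g"].to_numpy(float),
            "dpi": sub["dpi"].to_numpy(float),
        }
    )
    assert int(out["event"].sum()) + int((1 - out["event"]).sum()) == len(out)
    return out


def _cox_design(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    df = pd.DataFrame({"duration": records["duration"], "event": records["event"]})
    for cov in covariates:
        if cov == "group":
            df["group[PFF]"] = (records["group"] == "PFF").astype(float)
        elif cov == "sex":
            df["sex[M]"] = (records["sex"] == "M").astype(float)
        elif cov == "group:sex":
            df["group[PFF]:sex[M]"] = (
                (records["group"] == "PFF") & (records["sex"] == "M")
            ).astype(float)
        else:
            df[cov] = records[cov].astype(float)
    return df


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    event_direction: str = "",
) -> CoxFit:
    """Cox proportional-hazards partial-likelihood fit (Efron tie handling).

    Default covariates follow ``~ group * sex + trial + weight``.  Requires at
    least one event; complete separation / monotone likelihood raises with
    advice to penalize.
    """
    if covariates is None:
        covariates = ["group", "sex", "group:sex", "trial", "weight_g"]
    df = _cox_design(records, covariates)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise ValueError("no events: every record is censored; Cox model cannot be fit")
    # drop constant covariates (e.g. single-sex subsets) with a note
    keep = [c for c in df.columns if c in ("duration", "event") or df[c].nunique() > 1]
    dropped = sorted(set(df.columns) - set(keep))
    if dropped:
        logger.info("dropping constant covariates: %s", dropped)
        df = df[keep]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            "Cox partial likelihood failed to converge (possible complete "
            "separation or monotone likelihood); consider a penalized fit"
        ) from err
    return CoxFit(
        coefs=cph.params_,
        hazard_ratios=np.exp(cph.params_),
        se=cph.standard_errors_,
        pvalues=cph.summary["p"],
        n_events=n_events,
        n_records=len(df),
        event_direction=event_direction,
    )


def fit_survival(cohort: pd.DataFrame) -> CoxFit:
    """Cox model of humane-endpoint times with group*sex, plus KM curves.

    Event = humane endpoint reached (event_flag 1); mice alive at the
    experimental endpoint are censored.  Kaplan-Meier survivor curves are
    computed per sex x group cell.
    """
    records = pd.DataFrame(
        {
            "duration": cohort["survival_dpi"].to_numpy(float)
            - min(0.0, float(cohort["survival_dpi"].min()) - 1.0),
            "event": cohort["event_flag"].to_numpy(int),
            "group": cohort["group"].to_numpy(),
            "sex": cohort["sex"].to_numpy(),
        }
    )
    fit = fit_cox(
        records,
        covariates=["group", "sex", "group:sex"],
        event_direction="event = humane endpoint; experimental-end survivors censored",
    )
    km_rows = []
    kmf = KaplanMeierFitter()
    for (grp, sex), cell in records.groupby(["group", "sex"]):
        kmf.fit(cell["duration"], cell["event"], label=f"{grp}-{sex}")
        sf = kmf.survival_function_
        km_rows.append(
            pd.DataFrame(
                {
                    "group": grp,
                    "sex": sex,
                    "time": sf.index.to_numpy(float),
                    "survival": sf.iloc[:, 0].to_numpy(float),
                }
            )
        )
    fit.km_curves = pd.concat(km_rows, ignore_index=True)
    return fit


def fit_longitudinal_lme(
    measure: str,
    cohort: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    quadratic_time: bool = False,
) -> GLMResult:
    """Mixed model ``measure ~ group * sex * dpi + (1 | subject)``.

    ``measure`` is 'weight' (taken from the per-timepoint cohort columns) or
    'rotarod' (latencies averaged across the three trials at each timepoint
    first).  ``quadratic_time`` adds dpi^2 terms for inverted-U trajectories.
    """
    if measure == "weight":
        weight_cols = [c for c in cohort.columns if c.startswith("weight_")]
        long = cohort.melt(
            id_vars=["subject_id", "sex", "group"],
            value_vars=weight_cols,
            var_name="dpi",
            value_name="value",
        )
        long["dpi"] = long["dpi"].str.removeprefix("weight_").astype(float)
        long = long.dropna(subset=["value"])
    elif measure == "rotarod":
        if behavior is None:
            raise ValueError("rotarod analysis requires the behavior table")
        rr = behavior[behavior["task"] == "rotarod"]
        long = (
            rr.groupby(["subject_id", "sex", "group", "dpi"], as_index=False)["latency_s"]
            .mean()
            .rename(columns={"latency_s": "value"})
        )
    else:
        raise ValueError(f"unknown longitudinal measure {measure!r}")
    if long["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects for the longitudinal model")
    X, names = build_design(long, quadratic_time=quadratic_time)
    fit = fit_random_intercept_lme(
        long["value"].to_numpy(float), X, long["subject_id"].to_numpy(), term_names=names
    )
    return GLMResult(
        params=pd.Series(fit.beta[:, 0], index=names),
        bse=pd.Series(fit.se[:, 0], index=names),
        tvalues=pd.Series(fit.tvalues[:, 0], index=names),
        pvalues=pd.Series(fit.pvalues[:, 0], index=names),
        n_obs=fit.n_obs,
        formula=f"{measure} ~ group * sex * dpi{' + dpi^2' if quadratic_time else ''} + (1 | subject_id)",
    )


def motor_onset_glm(cohort: pd.DataFrame) -> GLMResult:
    """OLS of motor-onset dpi on group * sex among symptomatic mice.

    Onset is typically observed only in PFF mice; factors with a single level
    in the symptomatic subset are dropped (noted).  Cells with one mouse make
    standard errors unreliable, which is flagged in the notes.
    """
    import statsmodels.api as sm

    sub = cohort.dropna(subset=["motor_onset_dpi"]).copy()
    if sub.empty:
        raise ValueError("no symptomatic mice: motor onset model cannot be fit")
    y = sub["motor_onset_dpi"].to_numpy(float)
    g = (sub["group"] == "PFF").to_numpy(float)
    s = (sub["sex"] == "M").to_numpy(float)
    notes = []
    cols = {"Intercept": np.ones_like(y)}
    if len(np.unique(g)) > 1:
        cols["group[PFF]"] = g
    else:
        notes.append("all symptomatic mice share one injection group; group term dropped")
    if len(np.unique(s)) > 1:
        cols["sex[M]"] = s
    else:
        notes.append("all symptomatic mice share one sex; sex term dropped")
    if "group[PFF]" in cols and "sex[M]" in cols:
        cols["group[PFF]:sex[M]"] = g * s
    cell_sizes = sub.groupby(["group", "sex"]).size()
    if (cell_sizes < 2).any():
        notes.append("cells with a single symptomatic mouse: standard errors unreliable")
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    return GLMResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        n_obs=int(fit.nobs),
        formula="motor_onset_dpi ~ group * sex",
        notes=notes,
    )


def bonferroni(p: np.ndarray, m: int = 8, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni correction: significant iff p < alpha/m (strict inequality).

    Default m = 8 covers the motor-task battery (2 latency tasks x 4
    timepoints).  Adjusted p is min(1, m*p).
    """
    if m <= 0:
        raise ValueError("number of comparisons m must be positive")
    p = np.atleast_1d(np.asarray(p, dtype=float))
    return pd.DataFrame(
        {
            "p": p,
            "p_adjusted": np.minimum(1.0, m * p),
            "significant": p < alpha / m,
        }
    )
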