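"""Patient-level signature scoring and survival association.

The signature score of a patient is the mean, over a fixed gene list, of
gene-wise z-scored bulk expression (population SD across patients); scores
therefore average to zero across the cohort. Patients are stratified into
quartiles for Kaplan–Meier display and the Q4-vs-Q1 contrast is tested with
a two-group log-rank test; the continuous association is estimated with Cox
proportional-hazards regression (Efron ties, via lifelines), univariately and
adjusted for pathological stage (as a factor) and age. The signature is
z-scaled before fitting so hazard ratios refer to a one-SD increase.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("regfate")


def signature_score(expression: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Mean gene-wise z-score over the signature genes, per patient.

    ``expression`` is patients × genes. Missing genes are dropped with a
    logged list; zero-variance genes are excluded with a warning; no usable
    gene is an error.
    """
    if expression.shape[0] < 2:
        raise ValidationError("need at least 2 patients")
    requested = list(dict.fromkeys(genes))
    present = [g for g in requested if g in expression.columns]
    missing = [g for g in requested if g not in expression.columns]
    if missing:
        logger.info("signature genes absent from the cohort: %s", missing)
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")

    sub = expression[present].to_numpy(dtype=float)
    sd = sub.std(axis=0)
    usable = sd > 0
    if not usable.all():
        dropped = [g for g, u in zip(present, usable) if not u]
        warnings.warn(f"excluding zero-variance signature genes: {dropped}")
    if not usable.any():
        raise ValidationError("all signature genes have zero variance")
    sub = sub[:, usable]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    return pd.Series(z.mean(axis=1), index=expression.index, name="signature_score")


def stratify_quartiles(scores: pd.Series) -> pd.Series:
    """Quartile labels Q1..Q4 by the empirical 25/50/75 percentiles.

    Percentiles use the linear-interpolation convention; ties are assigned to
    the lower quartile. All-equal scores are a degenerate-quartile error.
    """
    if len(scores) < 4:
        raise ValidationError("need at least 4 patients for quartiles")
    values = scores.to_numpy(dtype=float)
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    if q25 == q75:
        raise ValidationError("degenerate quartiles: scores do not vary")
    labels = np.where(values <= q25, "Q1",
             np.where(values <= q50, "Q2",
             np.where(values <= q75, "Q3", "Q4")))
    return pd.Series(labels, index=scores.index, name="quartile")


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    At each distinct event time the observed-minus-expected contribution for
    group 1 is accumulated with its hypergeometric variance (times with only
    one subject at risk contribute zero variance); the statistic is
    (ΣO − ΣE)²/ΣV on one degree of freedom. No events at all yields (0, 1)
    with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if names.size != 2:
        raise ValidationError(f"log-rank test needs exactly 2 groups, got {names.size}")
    in1 = groups == names[0]
    if in1.all() or (~in1).all():
        raise ValidationError("both groups must be non-empty")
    if events.sum() == 0:
        warnings.warn("no events in either group; log-rank statistic is 0")
        return 0.0, 1.0

    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        warnings.warn("zero log-rank variance; statistic undefined, reporting (0, 1)")
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_ph_fit(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties); one row per covariate.

    Returns a table with columns coef, HR, HR_lower95, HR_upper95, p. Stage
    should already be dummy-encoded by the caller (see ``survival_analysis``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise ValidationError("need at least 2 events to fit a Cox model")
    cov = covariates.astype(float)
    for c in cov.columns:
        if cov[c].std() == 0:
            raise ValidationError(f"zero-variance covariate: {c}")
        if not np.isfinite(cov[c]).all():
            raise ValidationError(f"non-finite covariate: {c}")

    frame = cov.copy()
    frame["time"] = times
    frame["event"] = events
    fitter = CoxPHFitter()
    fitter.fit(frame, duration_col="time", event_col="event")
    summary = fitter.summary
    out = pd.DataFrame(
        {
            "coef": summary["coef"],
            "HR": summary["exp(coef)"],
            "HR_lower95": summary["exp(coef) lower 95%"],
            "HR_upper95": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    out.index.name = "variable"
    return out


def stage_association(scores: pd.Series, stages) -> tuple[float, float]:
    """Kruskal–Wallis rank test of signature scores across stage groups."""
    stages = pd.Series(np.asarray(stages), index=scores.index)
    groups = [scores[stages == s].to_numpy(dtype=float) for s in sorted(stages.unique())]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValidationError("need at least 2 stage groups")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def survival_analysis(expression: pd.DataFrame, survival: pd.DataFrame,
                      signature_genes: list[str]) -> dict:
    """End-to-end clinical association of a signature gene list.

    Computes the signature score, quartile labels, the Q4-vs-Q1 log-rank
    test, univariable and stage/age-adjusted Cox models (signature z-scaled:
    hazard ratios per 1-SD increase), and the stage Kruskal–Wallis test.
    """
    common = expression.index.intersection(survival.index)
    if common.empty:
        raise ValidationError("no patients shared between expression and survival tables")
    expr = expression.loc[common]
    surv = survival.loc[common]

    scores = signature_score(expr, signature_genes)
    quartiles = stratify_quartiles(scores)

    extreme = quartiles.isin(["Q1", "Q4"])
    chi2, logrank_p = logrank_test(surv.loc[extreme, "time"],
                                   surv.loc[extreme, "event"],
                                   quartiles[extreme])

    sig_z = (scores - scores.mean()) / scores.std(ddof=0)
    uni = cox_ph_fit(surv["time"], surv["event"],
                     pd.DataFrame({"signature": sig_z}))

    covs = pd.DataFrame({"signature": sig_z})
    if "stage" in surv.columns and surv["stage"].nunique() > 1:
        dummies = pd.get_dummies(surv["stage"], prefix="stage", drop_first=True)
        covs = pd.concat([covs, dummies.astype(float)], axis=1)
    if "age" in surv.columns:
        covs["age"] = surv["age"].astype(float)
    multi = cox_ph_fit(surv["time"], surv["event"], covs)

    stage_stat, stage_p = (np.nan, np.nan)
    if "stage" in surv.columns and surv["stage"].nunique() > 1:
        stage_stat, stage_p = stage_association(scores, surv["stage"])

    return {
        "scores": scores,
        "quartiles": quartiles,
        "logrank_chi2": chi2,
        "logrank_p": logrank_p,
        "cox_univariable": uni,
        "cox_multivariable": multi,
        "stage_statistic": stage_stat,
        "stage_p": stage_p,
    }
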