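"""Cox prognostic-index survival stratification.

The host-gene methylation of the predicted sponge circRNAs enters a joint
(multivariate) Cox proportional-hazards fit; each patient then receives a
prognostic index

    PI = sum_i beta_i * x_i

over the fitted coefficients, and the cohort is split at the median PI into
high- and low-risk groups (ties go to low risk).  The two groups are
compared with a log-rank test and Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .types import ClinicalTable, MethylationProfile, ValidationError

log = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


@dataclass
class CoxModel:
    covariates: list[str]
    beta: pd.Series  # one coefficient per covariate
    log_likelihood: float
    converged: bool
    fitter: CoxPHFitter | None = None


@dataclass
class RiskAssignment:
    sample_id: str
    pi: float
    group: str  # high | low


def _design_frame(meth: MethylationProfile, clin: ClinicalTable,
                  covariates: list[str] | None) -> tuple[pd.DataFrame, list[str]]:
    covariates = covariates or list(meth.values.index)
    missing = [c for c in covariates if c not in meth.values.index]
    if missing:
        raise ValidationError(f"covariates absent from methylation: {missing}")
    samples = meth.values.columns.intersection(clin.table.index)
    if len(samples) == 0:
        raise ValidationError("no shared samples between methylation and clinical")
    x = meth.values.loc[covariates, samples].T
    frame = pd.concat([x, clin.table.loc[samples, ["time", "event"]]], axis=1)
    n_dropped = int(frame.isna().any(axis=1).sum())
    if n_dropped:
        log.warning("fit_cox: dropping %d samples with missing values", n_dropped)
        frame = frame.dropna()
    return frame, covariates


def fit_cox(
    meth: MethylationProfile,
    clin: ClinicalTable,
    covariates: list[str] | None = None,
) -> CoxModel:
    """Joint Cox proportional-hazards fit (Efron tie handling).

    Covariates default to every methylation feature.  Collinear or
    separated designs raise; non-convergence is flagged on the returned
    model and raises on downstream use.
    """
    frame, covariates = _design_frame(meth, clin, covariates)
    n_events = int(frame["event"].sum())
    if n_events <= len(covariates):
        raise ValidationError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    x = frame[covariates].to_numpy(float)
    rank = np.linalg.matrix_rank(np.column_stack([x - x.mean(axis=0)]))
    if rank < len(covariates):
        raise ValidationError("collinear covariates: design matrix is rank-deficient")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValidationError(f"Cox fit failed: {exc}") from exc
    beta = cph.params_.reindex(covariates)
    converged = bool(np.isfinite(beta).all())
    return CoxModel(
        covariates=covariates,
        beta=beta,
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        fitter=cph,
    )


def prognostic_index(
    model: CoxModel,
    meth: MethylationProfile,
    ties_to: str = LOW,
) -> list[RiskAssignment]:
    """Per-sample PI = sum_i beta_i x_i and median-split risk groups.

    Samples with a missing covariate value are excluded with a warning.
    A sample is high risk iff its PI strictly exceeds the median; median
    ties are assigned to ``ties_to`` (low risk by default).
    """
    if not model.converged:
        raise ValidationError("refusing to score with a non-converged Cox model")
    missing = [c for c in model.covariates if c not in meth.values.index]
    if missing:
        raise ValidationError(f"model covariates absent from methylation: {missing}")
    x = meth.values.loc[model.covariates]
    ok = ~x.isna().any(axis=0)
    if (~ok).any():
        log.warning(
            "prognostic_index: excluding %d samples with missing covariates",
            int((~ok).sum()),
        )
    x = x.loc[:, ok]
    pi = x.T.to_numpy(float) @ model.beta.to_numpy(float)
    pi = pd.Series(pi, index=x.columns, name="PI")
    median = float(pi.median())
    out = []
    for sample, value in pi.items():
        if value > median:
            group = HIGH
        elif value < median:
            group = LOW
        else:
            group = ties_to
        out.append(RiskAssignment(sample, float(value), group))
    return out


def stratify_and_test(
    assign: list[RiskAssignment], clin: ClinicalTable
) -> dict:
    """Two-group log-rank test plus Kaplan-Meier step tables.

    Returns the log-rank statistic, its p-value, per-group sizes and the KM
    survival estimates (one step table per group, starting at S(0)=1).
    """
    groups = pd.Series({a.sample_id: a.group for a in assign})
    groups = groups.loc[groups.index.intersection(clin.table.index)]
    high = groups.index[groups == HIGH]
    low = groups.index[groups == LOW]
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("both risk groups must be non-empty")
    t_h = clin.table.loc[high, "time"]
    e_h = clin.table.loc[high, "event"]
    t_l = clin.table.loc[low, "time"]
    e_l = clin.table.loc[low, "event"]
    res = logrank_test(t_h, t_l, event_observed_A=e_h, event_observed_B=e_l)
    km = {}
    for name, t, e in [(HIGH, t_h, e_h), (LOW, t_l, e_l)]:
        fitter = KaplanMeierFitter()
        fitter.fit(t, e, label=name)
        sf = fitter.survival_function_
        km[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf[name].to_numpy(float)}
        )
    return {
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "km": km,
    }


def write_risk_table(assign: list[RiskAssignment], path) -> None:
    pd.DataFrame(
        [{"sample": a.sample_id, "PI": a.pi, "group": a.group} for a in assign]
    ).sort_values("sample").to_csv(path, sep="\t", index=False)
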