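"""Projection of a spatially derived marker onto a bulk cohort.

Patients are dichotomized at the cohort median of the marker's bulk
expression (ties go to the low group, so "high" is strictly above the
cutoff). The two groups are compared with Kaplan-Meier curves and the
two-group log-rank test; a multivariable Cox proportional hazards model
(Efron tie handling) adjusts the marker's hazard ratio for pathological
stage, age, smoking status and sex. Mutation flags are compared between
groups with two-sided Fisher exact tests under Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .containers import BulkCohort
from .stats import bh_adjust

DEFAULT_TERMS = ("marker_high", "stage_34", "age", "smoking", "sex")


@dataclass
class SurvivalResult:
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    logrank_statistic: float
    logrank_p: float
    cox_table: pd.DataFrame | None = None
    metadata: dict | None = None


def median_split(values: np.ndarray) -> np.ndarray:
    """High/low labels at the median: high iff value > median (ties -> low).

    Invariant to monotone transforms of the values."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values to split")
    if np.all(v == v[0]):
        raise ValueError("all values identical; median split is degenerate")
    return v > np.median(v)


def km_estimate(times: np.ndarray, events: np.ndarray,
                risk_times: np.ndarray | None = None) -> pd.DataFrame:
    """Product-limit survival curve with the number at risk.

    Returns one row per distinct observed time with columns ``time``,
    ``survival`` and ``n_at_risk``; censored subjects leave the risk set
    after their censoring time. ``risk_times`` requests the risk table at
    specific time points (appended as extra rows flagged ``is_risk_point``).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty input")
    if np.any(~(t > 0)):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    out = pd.DataFrame({
        "time": sf.index.to_numpy(float),
        "survival": sf.iloc[:, 0].to_numpy(float),
    })
    out["n_at_risk"] = [int((t >= ti).sum()) for ti in out["time"]]
    out["is_risk_point"] = False
    if risk_times is not None:
        extra = pd.DataFrame({
            "time": np.asarray(risk_times, float),
            "survival": [float(kmf.predict(ti)) for ti in risk_times],
            "n_at_risk": [int((t >= ti).sum()) for ti in risk_times],
            "is_risk_point": True,
        })
        out = pd.concat([out, extra], ignore_index=True)
    return out


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p.

    Invariant to swapping the group labels. If neither group has any event,
    p = 1 is returned with a warning."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(cohort: BulkCohort, marker_gene: str,
                   marker_high: np.ndarray | None = None,
                   stage_binary: bool = True) -> pd.DataFrame:
    clin = cohort.clinical
    if marker_high is None:
        marker_high = median_split(cohort.marker(marker_gene).to_numpy())
    df = pd.DataFrame(index=clin.index)
    df["marker_high"] = marker_high.astype(int)
    if stage_binary:
        df["stage_34"] = (clin["stage"].to_numpy(int) >= 3).astype(int)
    else:
        df["stage"] = clin["stage"].to_numpy(int)
    df["age"] = clin["age"].to_numpy(float)
    df["smoking"] = clin["smoking"].to_numpy(int)
    df["sex"] = clin["sex"].to_numpy(int)
    df["time"] = clin["time"].to_numpy(float)
    df["event"] = clin["event"].to_numpy(int)
    return df


def cox_ph(cohort: BulkCohort, marker_gene: str,
           terms: tuple[str, ...] = DEFAULT_TERMS,
           stage_binary: bool = True) -> pd.DataFrame:
    """Multivariable Cox proportional hazards fit (Efron tie handling).

    Returns one row per term: HR, Wald 95% CI bounds and p. Non-convergence
    or complete separation raises rather than silently clipping."""
    df = _design_matrix(cohort, marker_gene, stage_binary=stage_binary)
    covariates = [c for c in df.columns if c not in ("time", "event") and c in terms]
    n_events = int(df["event"].sum())
    if n_events < len(covariates):
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} model terms"
        )
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        # lifelines signals complete separation / non-convergence via warnings
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            cph.fit(df[covariates + ["time", "event"]],
                    duration_col="time", event_col="event")
        except (ConvergenceError, ConvergenceWarning) as err:
            raise RuntimeError(f"Cox model did not converge: {err}") from None
    summ = cph.summary
    out = pd.DataFrame({
        "term": summ.index,
        "coef": summ["coef"].to_numpy(float),
        "HR": summ["exp(coef)"].to_numpy(float),
        "ci_low": summ["exp(coef) lower 95%"].to_numpy(float),
        "ci_high": summ["exp(coef) upper 95%"].to_numpy(float),
        "p": summ["p"].to_numpy(float),
    }).reset_index(drop=True)
    return out


def fisher_enrichment(flags_high: pd.DataFrame, flags_low: pd.DataFrame
                      ) -> pd.DataFrame:
    """Per-gene mutation enrichment between marker-high and marker-low groups.

    Inputs are 0/1 patient x gene flag frames. Per gene a 2x2 table
    (mutated/wild-type x high/low) is tested with the two-sided Fisher exact
    test; the reported OR is the conditional MLE; q-values are BH-adjusted
    over the tested genes."""
    if not flags_high.columns.equals(flags_low.columns):
        raise ValueError("gene columns differ between groups")
    rows = []
    for gene in flags_high.columns:
        a = int(flags_high[gene].sum())
        b = int(len(flags_high) - a)
        c = int(flags_low[gene].sum())
        d = int(len(flags_low) - c)
        if min(a, b, c, d) < 0:
            raise ValueError("negative counts")
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        orat = _odds_ratio([[a, b], [c, d]], kind="conditional").statistic
        rows.append({"gene": gene, "n_mut_high": a, "n_mut_low": c,
                     "odds_ratio": float(orat), "p": float(p)})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def survival_analysis(
    cohort: BulkCohort,
    marker_gene: str,
    subgroup: pd.Series | None = None,
    with_cox: bool = True,
    split_before_filter: bool = True,
) -> SurvivalResult:
    """Median split -> KM curves -> log-rank -> (optionally) multivariable Cox.

    ``subgroup`` is a boolean row filter (e.g. stage I/II only) applied after
    the median split by default, so the cutoff refers to the full cohort;
    the choice is recorded in the result metadata.
    """
    expr = cohort.marker(marker_gene).to_numpy()
    if split_before_filter or subgroup is None:
        high = median_split(expr)
    if subgroup is not None:
        keep = np.asarray(subgroup, bool)
        if keep.sum() == 0:
            raise ValueError("empty subgroup after filtering")
        clin = cohort.clinical.loc[keep]
        if not split_before_filter:
            high = median_split(expr[keep])
        else:
            high = high[keep]
    else:
        clin = cohort.clinical
    t = clin["time"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    stat, p = logrank(t[high], e[high], t[~high], e[~high])
    result = SurvivalResult(
        km_high=km_estimate(t[high], e[high]),
        km_low=km_estimate(t[~high], e[~high]),
        logrank_statistic=stat,
        logrank_p=p,
        metadata={
            "marker_gene": marker_gene,
            "n_high": int(high.sum()), "n_low": int((~high).sum()),
            "median_split": "computed on full cohort before subgroup filter"
            if split_before_filter else "computed within subgroup",
        },
    )
    if with_cox and subgroup is None:
        result.cox_table = cox_ph(cohort, marker_gene)
    return result
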