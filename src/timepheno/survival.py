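"""Kaplan-Meier estimation and log-rank tests across phenotypes and subtypes.

Survival is summarized per phenotype group with the product-limit estimator
and compared with the k-group log-rank test (observed minus expected event
counts with hypergeometric variance at each distinct event time; df = k - 1).
The panel mirrors the study design: endpoints (OS, PFS, BCSS, distant/local
RFS) crossed with receptor strata (whole cohort, HR+HER2-, HER2+, TN), with
the three immunofunctional phenotypes as the compared groups.  Estimation
and testing are delegated to lifelines; ties between events and censorings
at the same time follow the standard convention (censorings occur after
events).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ClinicalTable
from .phenotyping import LABELS, PhenotypeAssignment

logger = logging.getLogger(__name__)

SUBTYPES = ("HR+HER2-", "HER2+", "TN", "unknown")
WHOLE_COHORT = "whole"


class SurvivalError(ValueError):
    pass


@dataclass
class KmCurve:
    """Product-limit estimate over the distinct observed times of one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(time_months, event) -> KmCurve:
    """Kaplan-Meier curve for one group of (time, event) records."""
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise SurvivalError("no records")
    if (t < 0).any() or not np.isfinite(t).all():
        raise SurvivalError("times must be finite and non-negative")
    if not set(np.unique(e)) <= {0, 1}:
        raise SurvivalError("event flags must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table["observed"] / (table["at_risk"] * (table["at_risk"] - table["observed"]))
    gw = (surv.to_numpy() ** 2) * np.cumsum(np.nan_to_num(terms.to_numpy(), posinf=0.0))
    return KmCurve(
        times=surv.index.to_numpy(float),
        survival=surv.to_numpy(float),
        at_risk=table["at_risk"].to_numpy(int),
        greenwood_var=gw,
    )


def logrank_test(time_months, event, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square statistic, df, p)."""
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    if (t < 0).any():
        raise SurvivalError("times must be non-negative")
    uniq, counts = np.unique(g, return_counts=True)
    if uniq.size < 2:
        raise SurvivalError("log-rank needs >= 2 groups")
    if (counts == 0).any():
        raise SurvivalError("empty group")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), int(uniq.size - 1), float(res.p_value)


def subtype_strata(clinical: ClinicalTable) -> pd.Series:
    """Receptor-defined subtype per sample: HER2+ takes precedence, then
    HR+HER2- (ER and/or PgR positive), then TN; anything else is unknown."""
    df = clinical.data
    for col in ("er_status", "pgr_status", "her2_status"):
        if col not in df.columns:
            raise SurvivalError(f"clinical table lacks {col!r}")
    er, pgr, her2 = df["er_status"], df["pgr_status"], df["her2_status"]
    hr_pos = (er == "positive") | (pgr == "positive")
    hr_neg = (er == "negative") & (pgr == "negative")
    labels = np.select(
        [
            her2 == "positive",
            (her2 == "negative") & hr_pos,
            (her2 == "negative") & hr_neg,
        ],
        ["HER2+", "HR+HER2-", "TN"],
        default="unknown",
    )
    return pd.Series(labels, index=df.index, name="subtype")


def survival_panel(
    clinical: ClinicalTable,
    assignment: PhenotypeAssignment,
    endpoints: list[str] | None = None,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Log-rank comparisons of the three phenotypes per (endpoint, stratum).

    Strata default to the receptor subtypes plus the whole cohort.  A
    stratum/endpoint cell with fewer than two phenotype groups represented
    (or no events at all) is skipped with a log entry.  Returns a tidy table
    with group sizes, the chi-square statistic, df and p.
    """
    endpoints = endpoints or clinical.endpoints
    if strata is None:
        strata = subtype_strata(clinical)
    common = clinical.data.index.intersection(assignment.labels.index)
    if len(common) == 0:
        raise SurvivalError("no samples shared between clinical table and assignment")
    strata = strata.loc[common]
    labels = assignment.labels.loc[common]
    rows = []
    stratum_names = [WHOLE_COHORT, *[s for s in SUBTYPES if s != "unknown"]]
    for endpoint in endpoints:
        records = clinical.endpoint_records(endpoint)
        records = records.loc[records.index.intersection(common)]
        for stratum in stratum_names:
            ids = records.index if stratum == WHOLE_COHORT else records.index[
                strata.loc[records.index] == stratum
            ]
            sub = records.loc[ids]
            glab = labels.loc[ids]
            present = [lab for lab in LABELS if (glab == lab).any()]
            if len(present) < 2 or sub["event"].sum() == 0:
                logger.info(
                    "survival_panel: skipping endpoint=%s stratum=%s "
                    "(<2 phenotype groups or no events)", endpoint, stratum,
                )
                continue
            keep = glab.isin(present)
            stat, df, p = logrank_test(
                sub.loc[keep, "time_months"], sub.loc[keep, "event"], glab[keep]
            )
            row = {
                "endpoint": endpoint,
                "stratum": stratum,
                "n": int(keep.sum()),
                "n_events": int(sub.loc[keep, "event"].sum()),
                "logrank_statistic": stat,
                "df": df,
                "p_value": p,
            }
            for lab in LABELS:
                row[f"n_{lab}"] = int((glab == lab).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def km_by_group(time_months, event, groups) -> dict[str, KmCurve]:
    """Kaplan-Meier curve per group label (convenience for panel dumps)."""
    df = pd.DataFrame({"t": time_months, "e": event, "g": groups})
    return {g: kaplan_meier(sub["t"], sub["e"]) for g, sub in df.groupby("g")}
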