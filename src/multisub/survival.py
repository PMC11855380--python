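"""Kaplan-Meier estimation and the multi-group log-rank test.

These two statistics are the subtyping quality metric: a good partition of
patients separates the product-limit survival curves, and the log-rank
chi-square p-value quantifies that separation.

Conventions: a sample censored exactly at an event time counts as at risk
for that event time and leaves the risk set afterwards ("event first").
The multi-group statistic uses the full hypergeometric variance-covariance
of the observed-minus-expected vector over the first g-1 groups, not the
sum-of-marginals shortcut, so it is exact for any number of groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Assignment, ClinicalTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times of one group."""

    event_times: np.ndarray   # strictly increasing
    at_risk: np.ndarray       # n_j at each event time
    events: np.ndarray        # d_j at each event time
    survival: np.ndarray      # S(t_j), right-continuous step values


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def km_estimate(clinical: ClinicalTable,
                group_mask: np.ndarray | None = None) -> KMCurve:
    """Kaplan-Meier curve for the (sub)cohort selected by `group_mask`.

    With no events the curve is the empty step set, i.e. S(t) = 1 throughout.
    """
    time, event = clinical.time, clinical.event
    if group_mask is not None:
        group_mask = np.asarray(group_mask, dtype=bool)
        time, event = time[group_mask], event[group_mask]
    if len(time) == 0:
        raise ValidationError("empty group in km_estimate")
    ts = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in ts], dtype=int)
    d = np.array([((time == t) & (event == 1)).sum() for t in ts], dtype=int)
    with np.errstate(divide="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(ts, at_risk, d, surv)


def _logrank_arrays(time: np.ndarray, event: np.ndarray,
                    groups: np.ndarray) -> LogRankResult:
    """Log-rank over integer-coded groups (the computational core)."""
    codes, counts = np.unique(groups, return_counts=True)
    g = len(codes)
    if g < 2:
        raise ValidationError("log-rank needs at least two non-empty groups")
    ts = np.unique(time[event == 1])
    if len(ts) == 0:
        warnings.warn("all samples censored: log-rank p-value set to 1",
                      stacklevel=2)
        return LogRankResult(0.0, g - 1, 1.0)

    # at-risk counts per group at each event time via sorted searchsorted
    n_at = np.empty((len(ts), g))
    d_at = np.zeros((len(ts), g))
    for j, c in enumerate(codes):
        sel = groups == c
        tj = np.sort(time[sel])
        n_at[:, j] = len(tj) - np.searchsorted(tj, ts, side="left")
        te = time[sel & (event == 1)]
        idx = np.searchsorted(ts, te)
        np.add.at(d_at[:, j], idx, 1.0)

    n_tot = n_at.sum(axis=1)
    d_tot = d_at.sum(axis=1)
    O = d_at.sum(axis=0)
    E = ((d_tot / n_tot)[:, None] * n_at).sum(axis=0)

    # hypergeometric covariance, accumulated over event times with n_tot > 1
    V = np.zeros((g, g))
    ok = n_tot > 1
    p = n_at[ok] / n_tot[ok, None]                     # group at-risk shares
    scale = d_tot[ok] * (n_tot[ok] - d_tot[ok]) / (n_tot[ok] - 1.0)
    V = (scale[:, None, None]
         * (np.einsum("ti,ij->tij", p, np.eye(g)) -
            np.einsum("ti,tj->tij", p, p))).sum(axis=0)

    u = (O - E)[: g - 1]
    Vr = V[: g - 1, : g - 1]
    try:
        stat = float(u @ np.linalg.solve(Vr, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(Vr) @ u)
    stat = max(stat, 0.0)
    df = g - 1
    return LogRankResult(stat, df, float(stats.chi2.sf(stat, df)))


def logrank_test(clinical: ClinicalTable,
                 assignment: Assignment) -> LogRankResult:
    """Compare survival across the assigned subtypes.

    Groups that never contribute to any risk set are excluded with a
    warning; the chi-square degrees of freedom shrink accordingly.
    """
    if clinical.sample_ids != assignment.sample_ids:
        assignment = assignment.subset(clinical.sample_ids)
    groups = assignment.labels
    present = np.unique(groups)
    usable = []
    for c in present:
        if (groups == c).sum() > 0:
            usable.append(c)
    if len(usable) < len(present):
        log.warning("excluding %d empty groups from log-rank",
                    len(present) - len(usable))
    return _logrank_arrays(clinical.time, clinical.event, groups)


def km_table(clinical: ClinicalTable, assignment: Assignment) -> pd.DataFrame:
    """Per-group KM curves as a long table ready for external plotting."""
    rows = []
    for c in np.unique(assignment.labels):
        curve = km_estimate(clinical, assignment.labels == c)
        for t, n, d, s in zip(curve.event_times, curve.at_risk,
                              curve.events, curve.survival):
            rows.append({"group": int(c), "time": t, "at_risk": int(n),
                         "events": int(d), "survival": s})
    return pd.DataFrame(rows, columns=["group", "time", "at_risk",
                                       "events", "survival"])


def write_km(clinical: ClinicalTable, assignment: Assignment, path) -> None:
    km_table(clinical, assignment).to_csv(path, sep="\t", index=False)
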