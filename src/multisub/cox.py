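"""Survival-guided feature selection via univariate Cox proportional hazards.

Each feature is standardized and fit one at a time against right-censored
survival by maximizing the Cox partial likelihood with Breslow handling of
tied event times (Newton-Raphson, observed-information standard errors).
Features whose fit converges with a two-sided p below the threshold are
retained for clustering; everything else is discarded as survival-irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ClinicalTable, OmicsMatrix, ValidationError

log = logging.getLogger(__name__)

_TOL = 1e-9
_MAX_ITER = 50
_BETA_DIVERGED = 50.0  # |beta| beyond this on a unit-SD covariate = separation


@dataclass
class CoxFit:
    """Univariate fit summary: log hazard ratio per SD of the feature."""

    beta: float
    se: float
    z: float
    p_value: float
    converged: bool
    n_iter: int = 0


@dataclass
class FeatureScore:
    feature_id: str
    omics_name: str
    fit: CoxFit
    selected: bool = False


def _breslow_derivatives(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                         beta: float) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and Hessian at `beta`.

    Arrays must be pre-sorted by ascending time; the risk set at an event
    time is everyone with time >= t, so suffix sums give the Breslow terms.
    """
    eta = beta * x
    shift = eta.max()
    w = np.exp(eta - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x)[::-1])[::-1]
    s2 = np.cumsum((w * x * x)[::-1])[::-1]

    uniq, first_idx = np.unique(time, return_index=True)
    gi = np.searchsorted(uniq, time)
    d = np.bincount(gi, weights=event.astype(float), minlength=len(uniq))
    has = d > 0
    f = first_idx[has]
    dt = d[has]
    r0, r1, r2 = s0[f], s1[f], s2[f]
    mu = r1 / r0
    ll = float((eta * event).sum() - (dt * (np.log(r0) + shift)).sum())
    grad = float((x * event).sum() - (dt * mu).sum())
    hess = float(-(dt * (r2 / r0 - mu * mu)).sum())
    return ll, grad, hess


def cox_fit_univariate(x: np.ndarray, clinical: ClinicalTable) -> CoxFit:
    """Fit one standardized feature against survival.

    Degenerate inputs (constant feature, no observed events, monotone
    likelihood) are flagged as non-converged with p=1 rather than raised:
    real omics matrices contain such columns routinely.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (clinical.n_samples,):
        raise ValidationError("feature vector length must match clinical table")
    sd = x.std()
    if sd == 0.0 or not np.isfinite(sd):
        return CoxFit(0.0, np.inf, 0.0, 1.0, converged=False)
    if clinical.event.sum() == 0:
        return CoxFit(0.0, np.inf, 0.0, 1.0, converged=False)
    xs = (x - x.mean()) / sd

    order = np.argsort(clinical.time, kind="stable")
    xs, time, event = xs[order], clinical.time[order], clinical.event[order]

    beta = 0.0
    ll, grad, hess = _breslow_derivatives(xs, time, event, beta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        if hess >= -1e-12:  # no curvature left: flat or monotone likelihood
            break
        step = -grad / hess
        # halve the step until the partial likelihood does not decrease
        new_beta = beta + step
        new = _breslow_derivatives(xs, time, event, new_beta)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new = _breslow_derivatives(xs, time, event, new_beta)
            halvings += 1
        beta = new_beta
        ll, grad, hess = new
        if abs(beta) > _BETA_DIVERGED:
            break
        if abs(step) < _TOL:
            converged = True
            break

    if hess < -1e-12 and np.isfinite(beta):
        se = 1.0 / np.sqrt(-hess)
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        se, z, p = np.inf, 0.0, 1.0
        converged = False
    if abs(beta) > _BETA_DIVERGED:
        converged = False
    return CoxFit(float(beta), float(se), float(z), p, converged, it)


def apply_selection(scores: list[FeatureScore], p_threshold: float,
                    max_features: int | None = None) -> list[str]:
    """Set `selected` flags and return the kept feature IDs.

    Keeps converged fits with p strictly below the threshold; with
    `max_features`, the smallest-p ones among those.
    """
    for s in scores:
        s.selected = bool(s.fit.converged and s.fit.p_value < p_threshold)
    kept = [s for s in scores if s.selected]
    if max_features is not None and len(kept) > max_features:
        kept_sorted = sorted(kept, key=lambda s: (s.fit.p_value, s.feature_id))
        keep_ids = {s.feature_id for s in kept_sorted[:max_features]}
        for s in scores:
            s.selected = s.selected and s.feature_id in keep_ids
        kept = [s for s in scores if s.selected]
    return [s.feature_id for s in kept]


def select_features(omics: OmicsMatrix, clinical: ClinicalTable,
                    p_threshold: float = 0.05,
                    max_features: int | None = None
                    ) -> tuple[OmicsMatrix, list[FeatureScore]]:
    """Retain survival-associated features of one omics block.

    Returns the reduced matrix (original, unstandardized values; original
    column order) plus the full score list.  Raises if nothing survives.
    """
    if omics.sample_ids != clinical.sample_ids:
        raise ValidationError("omics and clinical sample IDs must be aligned")
    scores = [FeatureScore(fid, omics.omics_name,
                           cox_fit_univariate(omics.values[:, j], clinical))
              for j, fid in enumerate(omics.feature_ids)]
    kept = apply_selection(scores, p_threshold, max_features)
    if not kept:
        raise ValidationError(
            f"{omics.omics_name}: no feature passed Cox selection at "
            f"p<{p_threshold}; relax the threshold")
    log.info("%s: kept %d/%d features at p<%g", omics.omics_name,
             len(kept), omics.n_features, p_threshold)
    return omics.subset_features(kept), scores


def write_scores(scores: list[FeatureScore], path) -> None:
    import pandas as pd

    pd.DataFrame([{"omics": s.omics_name, "feature_id": s.feature_id,
                   "beta": s.fit.beta, "se": s.fit.se, "p": s.fit.p_value,
                   "selected": s.selected} for s in scores]
                 ).to_csv(path, sep="\t", index=False)
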