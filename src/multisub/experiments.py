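"""Scriptable experiment drivers: dropout robustness, k-sweep, cost scaling.

Each driver re-runs the full pipeline under a perturbed design and tabulates
the subtype-separation p-values (or, for the cost study, the instrumented
density-evaluation counts, which are the hardware-independent measure of
solver expense).  All drivers are deterministic given the master seed:
trial seeds are derived by fixed offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import em, io
from .datatypes import ClinicalTable, OmicsMatrix
from .stacking import stack, zscore_block
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .survival import LogRankResult
from .synthetic import SynthDataset

log = logging.getLogger(__name__)

_TRIAL_OFFSET = 7919  # fixed prime stride between trial seeds


def _as_inputs(data) -> tuple[list[OmicsMatrix], ClinicalTable]:
    if isinstance(data, SynthDataset):
        return data.omics, data.clinical
    omics, clinical = data
    return list(omics), clinical


@dataclass
class DropoutResult:
    n_patients_kept: int
    trial_pvalues: list[float]

    @property
    def mean_pvalue(self) -> float:
        return float(np.mean(self.trial_pvalues))


def dropout_robustness(data, keep_counts: list[int], n_trials: int = 5,
                       config: PipelineConfig | None = None,
                       seed: int = 0) -> list[DropoutResult]:
    """Withhold random patients and re-run the pipeline, several trials each.

    Patients to keep are drawn uniformly without replacement per trial; the
    pipeline seed is fixed across trials so that, at full retention, every
    trial reproduces the base run exactly.  keep counts too small to support
    2k cluster members are skipped with a warning.
    """
    config = config or PipelineConfig()
    omics, clinical = _as_inputs(data)
    n = clinical.n_samples
    results = []
    for keep in keep_counts:
        if keep > n or keep < 2 * config.k:
            log.warning("skipping keep_count=%d (n=%d, k=%d)", keep, n, config.k)
            continue
        pvals = []
        for t in range(n_trials):
            rng = np.random.default_rng(seed + _TRIAL_OFFSET * (t + 1))
            kept_idx = np.sort(rng.choice(n, size=keep, replace=False))
            kept_ids = [clinical.sample_ids[i] for i in kept_idx]
            sub_omics = [m.subset_samples(kept_ids) for m in omics]
            sub_clin = clinical.subset(kept_ids)
            res = run_pipeline(sub_omics, sub_clin, config, seed=seed)
            pvals.append(res.logrank.p_value)
        results.append(DropoutResult(keep, pvals))
    return results


def dropout_table(results: list[DropoutResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"n_patients_kept": r.n_patients_kept}
        row.update({f"trial_{i + 1}": p for i, p in enumerate(r.trial_pvalues)})
        row["mean_pvalue"] = r.mean_pvalue
        rows.append(row)
    return pd.DataFrame(rows)


def k_sweep(data, k_values: list[int],
            config: PipelineConfig | None = None,
            seed: int = 0) -> list[tuple[int, LogRankResult]]:
    """Re-run the pipeline for each candidate number of subtypes."""
    config = config or PipelineConfig()
    omics, clinical = _as_inputs(data)
    out = []
    for k in k_values:
        res = run_pipeline(omics, clinical, replace(config, k=k), seed=seed)
        out.append((k, res.logrank))
    return out


def k_sweep_table(results: list[tuple[int, LogRankResult]]) -> pd.DataFrame:
    return pd.DataFrame([{"k": k, "statistic": lr.statistic, "df": lr.df,
                          "p_value": lr.p_value} for k, lr in results])


def cost_scaling(data, feature_counts: list[int],
                 solvers: tuple[str, ...] = ("em", "em-star"),
                 config: PipelineConfig | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Density-evaluation counts per solver as the feature space grows.

    The stacked (z-scored, unselected) matrix is truncated to each width in
    `feature_counts`; both solvers start from the identical initialization
    (same seed and init method), so the counts differ only through the
    active-set mechanics.
    """
    config = config or PipelineConfig()
    omics, clinical = _as_inputs(data)
    omics, clinical = io.align_samples(omics, clinical)
    joint = stack([zscore_block(m)[0] for m in omics])
    rows = []
    for d in feature_counts:
        if d > joint.n_features:
            log.warning("skipping d=%d (> %d stacked features)",
                        d, joint.n_features)
            continue
        x = joint.truncate(d)
        for solver in solvers:
            if solver == "em":
                model, _, _ = em.fit_em(x, config.k, init=config.init,
                                        seed=seed, tol=config.tol,
                                        max_iter=config.max_iter)
            else:
                model, _, _, _ = em.fit_em_star(
                    x, config.k, init=config.init, seed=seed, tol=config.tol,
                    max_iter=config.max_iter,
                    settle_quantile=config.settle_quantile,
                    recheck_every=config.recheck_every)
            rows.append({"solver": solver, "n_features": d,
                         "n_density_evals": model.n_density_evals,
                         "n_iterations": len(model.loglik_trace),
                         "final_loglik": model.final_loglik})
    return pd.DataFrame(rows)
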