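"""Differential-expression screen: one subtype's tumors vs a reference set.

Effect size is the log2 fold change of group means with pseudocount 1;
the test is Welch's two-sample t on log2(x+1) values.  A feature is called
differentially expressed when |log2FC| >= 3.5 (inclusive) AND raw p < 0.05
(strict) — the fold-change magnitude gate plus nominal significance.
Benjamini-Hochberg adjusted p-values are reported alongside for
transparency but do not gate the call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix, ValidationError

DEFAULT_LFC = 3.5
DEFAULT_P = 0.05


@dataclass
class DEResult:
    feature_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    significant: bool


def is_significant(log2_fold_change: float, p_value: float,
                   lfc_threshold: float = DEFAULT_LFC,
                   p_threshold: float = DEFAULT_P) -> bool:
    """The call rule: |log2FC| >= threshold (inclusive) and p < threshold."""
    return bool(abs(log2_fold_change) >= lfc_threshold
                and p_value < p_threshold)


def differential_expression(tumor: OmicsMatrix, normal: OmicsMatrix,
                            lfc_threshold: float = DEFAULT_LFC,
                            p_threshold: float = DEFAULT_P) -> list[DEResult]:
    """Per-feature DE results for one subtype against the reference matrix."""
    if tumor.feature_ids != normal.feature_ids:
        raise ValidationError("tumor and normal matrices must share feature IDs")
    if tumor.n_samples < 2 or normal.n_samples < 2:
        raise ValidationError("each group needs >= 2 samples (variance undefined)")
    if (tumor.values < 0).any() or (normal.values < 0).any():
        raise ValidationError("expression values must be nonnegative")

    mean_t = tumor.values.mean(axis=0)
    mean_n = normal.values.mean(axis=0)
    # difference of logs, so swapping the groups negates the value exactly
    lfc = np.log2(mean_t + 1.0) - np.log2(mean_n + 1.0)

    lt = np.log2(tumor.values + 1.0)
    ln = np.log2(normal.values + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant features
        res = stats.ttest_ind(lt, ln, axis=0, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    adj = stats.false_discovery_control(p, method="bh")

    return [DEResult(fid, float(l), float(pv), float(ap),
                     is_significant(l, pv, lfc_threshold, p_threshold))
            for fid, l, pv, ap in zip(tumor.feature_ids, lfc, p, adj)]


def top_n(results: list[DEResult], n: int = 50) -> list[DEResult]:
    """The n significant hits with largest |log2FC| (ties: smaller p first)."""
    if n < 1:
        raise ValidationError("top_n needs n >= 1")
    sig = [r for r in results if r.significant]
    sig.sort(key=lambda r: (-abs(r.log2_fold_change), r.p_value, r.feature_id))
    if len(sig) < n:
        warnings.warn(f"only {len(sig)} significant features available "
                      f"(requested {n})", stacklevel=2)
    return sig[:n]


def write_de(results: list[DEResult], path) -> None:
    """Volcano-plot-ready TSV: log2fc, p, adjusted p, -log10 adj p, flag."""
    df = pd.DataFrame([{"feature_id": r.feature_id,
                        "log2fc": r.log2_fold_change,
                        "p": r.p_value, "adj_p": r.adjusted_p,
                        "neg_log10_adj_p": -np.log10(max(r.adjusted_p, 1e-300)),
                        "significant": r.significant} for r in results])
    df.to_csv(path, sep="\t", index=False)
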