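"""Concordance between discovered subtypes and reference labels.

The primary output is the raw contingency table (clusters x reference
subtypes, e.g. PAM50 LumA/LumB/Her2/Basal); the adjusted Rand index is the
scalar chance-corrected summary of the same cross-classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .datatypes import Assignment, LabelTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    row_labels: list[int]       # cluster indices
    col_labels: list[str]       # reference subtype names
    counts: np.ndarray          # nonnegative integers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


def _matched(assignment: Assignment,
             labels: LabelTable) -> tuple[list[str], np.ndarray, list[str]]:
    common = [s for s in assignment.sample_ids if s in set(labels.sample_ids)]
    if not common:
        raise ValidationError("no samples shared between assignment and labels")
    unmatched = (set(assignment.sample_ids) | set(labels.sample_ids)) - set(common)
    if unmatched:
        log.info("concordance: %d samples lack one of the two labelings",
                 len(unmatched))
    a = assignment.subset(common)
    l = labels.subset(common)
    return common, a.labels, l.label


def crosstab(assignment: Assignment, labels: LabelTable) -> ContingencyTable:
    """Cluster-by-reference counts over the sample-ID intersection."""
    _, clust, ref = _matched(assignment, labels)
    tab = pd.crosstab(pd.Series(clust, name="cluster"),
                      pd.Series(ref, name="reference"))
    return ContingencyTable(list(tab.index), list(tab.columns),
                            tab.to_numpy())


def adjusted_rand(assignment: Assignment, labels: LabelTable) -> float:
    """Permutation-model adjusted Rand index in [-1, 1]."""
    _, clust, ref = _matched(assignment, labels)
    return float(adjusted_rand_score(ref, clust))


def write_crosstab(tab: ContingencyTable, path) -> None:
    tab.to_frame().to_csv(path, sep="\t", index_label="cluster")
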