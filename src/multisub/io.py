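"""Reading, writing and sample alignment for omics and clinical tables.

Matrices are delimited text (tab or comma, auto-detected): first row holds
feature IDs, first column holds sample IDs.  Clinical tables are TSV with
columns ``sample_id``, ``time``, ``event``; label tables have ``sample_id``
and ``label``.

Missing-value policy on load: cells that are empty or ``NA`` are imputed
per-feature with the median over observed entries; features missing in more
than 20% of samples are dropped.  Both actions are logged for audit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (Assignment, ClinicalTable, LabelTable, OmicsMatrix,
                        ParseError, ValidationError)

log = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA")
MAX_MISSING_FRACTION = 0.20


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path: str | Path, omics_name: str) -> OmicsMatrix:
    """Load a samples x features matrix, applying the missing-value policy."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicated sample ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicated feature ID {dup!r}")

    df = df.mask(df.isin(list(MISSING_TOKENS)))
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(f"{path.name}: non-numeric cell at sample {row!r}, "
                             f"feature {col!r}") from None

    frac_missing = numeric.isna().mean(axis=0)
    dropped = list(frac_missing.index[frac_missing > MAX_MISSING_FRACTION])
    if dropped:
        log.warning("%s: dropping %d features with >%.0f%% missing values: %s",
                    path.name, len(dropped), 100 * MAX_MISSING_FRACTION, dropped)
        numeric = numeric.drop(columns=dropped)
    if numeric.isna().any().any():
        imputed = list(numeric.columns[numeric.isna().any()])
        log.info("%s: median-imputing missing entries in %d features",
                 path.name, len(imputed))
        numeric = numeric.fillna(numeric.median(axis=0))

    return OmicsMatrix(omics_name, list(numeric.index.astype(str)),
                       list(numeric.columns.astype(str)), numeric.to_numpy())


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    return ClinicalTable(list(df["sample_id"].astype(str)),
                         df["time"].to_numpy(float), df["event"].to_numpy())


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.to_frame().to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> LabelTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    return LabelTable(list(df["sample_id"]), list(df["label"]))


def write_labels(t: LabelTable, path: str | Path) -> None:
    pd.DataFrame({"sample_id": t.sample_ids, "label": t.label}
                 ).to_csv(path, sep="\t", index=False)


def write_assignments(a: Assignment, path: str | Path) -> None:
    pd.DataFrame({"sample_id": a.sample_ids, "subtype": a.labels}
                 ).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> Assignment:
    df = pd.read_csv(path, sep="\t")
    return Assignment(list(df["sample_id"].astype(str)), df["subtype"].to_numpy())


def write_report(report: dict, path: str | Path) -> None:
    """JSON run report (parameters, log-likelihood trace, p-values)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def align_samples(omics: list[OmicsMatrix],
                  clinical: ClinicalTable) -> tuple[list[OmicsMatrix], ClinicalTable]:
    """Restrict all inputs to the common sample set, lexicographically ordered.

    Dropped sample IDs are reported per input via logging.  Raises
    ValidationError if the intersection is empty.
    """
    if not omics:
        raise ValidationError("align_samples needs at least one omics matrix")
    common = set(clinical.sample_ids)
    for m in omics:
        common &= set(m.sample_ids)
    if not common:
        raise ValidationError("no samples shared across all inputs")
    order = sorted(common)
    for m in omics:
        dropped = sorted(set(m.sample_ids) - common)
        if dropped:
            log.info("align: dropping %d samples from %s: %s",
                     len(dropped), m.omics_name, dropped)
    dropped_clin = sorted(set(clinical.sample_ids) - common)
    if dropped_clin:
        log.info("align: dropping %d samples from clinical: %s",
                 len(dropped_clin), dropped_clin)
    return [m.subset_samples(order) for m in omics], clinical.subset(order)
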