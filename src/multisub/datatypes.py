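"""Core data containers shared across the subtyping pipeline.

Samples are rows everywhere: an omics matrix is patients x features, the
clinical table holds one survival record per patient, and subtype
assignments map each patient to a cluster label in ``1..k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MultisubError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(MultisubError, ValueError):
    """Invalid configuration (bad probability vector, nonpositive scale, ...)."""


class ValidationError(MultisubError, ValueError):
    """Structurally invalid data (duplicate IDs, shape mismatch, ...)."""


class ParseError(MultisubError, ValueError):
    """A delimited file could not be parsed into a numeric table."""


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} ID: {dup!r}")


@dataclass
class OmicsMatrix:
    """One -omics data type as a real samples x features matrix with IDs."""

    omics_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"{self.omics_name}: shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, f"{self.omics_name} sample")
        _check_unique(self.feature_ids, f"{self.omics_name} feature")
        if not np.isfinite(self.values).all():
            raise ValidationError(f"{self.omics_name}: non-finite values present")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Restrict to `sample_ids`, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(self.omics_name, list(sample_ids),
                           list(self.feature_ids), self.values[idx])

    def subset_features(self, feature_ids: list[str]) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return OmicsMatrix(self.omics_name, list(self.sample_ids),
                           list(feature_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)


@dataclass
class ClinicalTable:
    """Per-sample right-censored survival data: time in days, event 0/1."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("clinical table columns must match sample count")
        _check_unique(self.sample_ids, "clinical sample")
        if (self.time < 0).any():
            raise ValidationError("survival times must be nonnegative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(list(sample_ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "time": self.time, "event": self.event})


@dataclass
class LabelTable:
    """Reference categorical labels per sample (e.g. PAM50 subtypes)."""

    sample_ids: list[str]
    label: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.label = [str(l) for l in self.label]
        if len(self.label) != len(self.sample_ids):
            raise ValidationError("label column must match sample count")
        _check_unique(self.sample_ids, "label sample")
        if any(l == "" for l in self.label):
            raise ValidationError("empty labels are not allowed")

    def subset(self, sample_ids: list[str]) -> "LabelTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return LabelTable(list(sample_ids), [self.label[pos[s]] for s in sample_ids])


@dataclass
class Assignment:
    """Hard subtype assignment: sample -> cluster label in 1..k."""

    sample_ids: list[str]
    labels: np.ndarray  # int, 1-based cluster indices

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValidationError("assignment labels must match sample count")
        if len(self.labels) and self.labels.min() < 1:
            raise ValidationError("cluster labels are 1-based")
        _check_unique(self.sample_ids, "assignment sample")

    @property
    def k(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def subset(self, sample_ids: list[str]) -> "Assignment":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return Assignment(list(sample_ids), self.labels[idx])

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="subtype")
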