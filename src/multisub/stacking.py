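"""Standardize selected omics blocks and stack them into one joint matrix.

Methylation beta values, expression counts and miRNA abundances live on
incommensurable scales; per-feature z-scoring inside each block puts every
column on mean 0 / SD 1 before horizontal concatenation, so the joint
Gaussian mixture weighs each feature equally regardless of origin.
Block provenance (which columns came from which omics) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix, ValidationError


def zscore_block(m: OmicsMatrix) -> tuple[OmicsMatrix, list[str]]:
    """Center/scale each feature (sample SD, denominator n-1).

    Constant features become all-zero columns; their IDs are returned as the
    second element so callers can drop or report them.
    """
    if m.n_samples < 2:
        raise ValidationError("z-scoring needs at least 2 samples")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    constant = sd == 0.0
    sd_safe = np.where(constant, 1.0, sd)
    z = (m.values - mean) / sd_safe
    z[:, constant] = 0.0
    flags = [f for f, c in zip(m.feature_ids, constant) if c]
    return OmicsMatrix(m.omics_name, list(m.sample_ids),
                       list(m.feature_ids), z), flags


@dataclass
class StackedMatrix:
    """Joint feature matrix with per-omics column provenance."""

    sample_ids: list[str]
    blocks: list[tuple[str, list[str]]]  # (omics_name, feature_ids) in order
    values: np.ndarray

    @property
    def block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, fids in self.blocks:
            out[name] = slice(start, start + len(fids))
            start += len(fids)
        return out

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def get_block(self, omics_name: str) -> np.ndarray:
        return self.values[:, self.block_slices[omics_name]]

    def truncate(self, n_features: int) -> "StackedMatrix":
        """First `n_features` columns, preserving block provenance."""
        blocks, remaining = [], n_features
        for name, fids in self.blocks:
            take = min(len(fids), remaining)
            if take:
                blocks.append((name, fids[:take]))
            remaining -= take
            if remaining <= 0:
                break
        return StackedMatrix(list(self.sample_ids), blocks,
                             self.values[:, :n_features].copy())


def stack(omics: list[OmicsMatrix]) -> StackedMatrix:
    """Concatenate blocks horizontally in the given order."""
    if not omics:
        raise ValidationError("stack needs at least one omics matrix")
    ref = omics[0].sample_ids
    for m in omics[1:]:
        if m.sample_ids != ref:
            raise ValidationError(
                f"sample IDs of {m.omics_name} differ from {omics[0].omics_name}; "
                "run align_samples first")
    blocks = [(m.omics_name, list(m.feature_ids)) for m in omics]
    values = np.hstack([m.values for m in omics])
    return StackedMatrix(list(ref), blocks, values)


def write_stacked(s: StackedMatrix, path) -> None:
    """TSV with a two-row header (omics, feature_id) for audit."""
    cols = pd.MultiIndex.from_tuples(
        [(name, fid) for name, fids in s.blocks for fid in fids],
        names=["omics", "feature_id"])
    pd.DataFrame(s.values, index=s.sample_ids, columns=cols
                 ).to_csv(path, sep="\t", index_label="sample_id")
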