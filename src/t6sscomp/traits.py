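"""Metabolic resource-overlap scores from binary trait matrices.

The trait matrix is a strains x traits pandas DataFrame of 0/1 indicators
(presence of a resource-acquisition trait, e.g. a microTrait granularity-3
call). The overlap of a community member with the focal strain is the
fraction of the focal strain's traits that the member shares:

    O = |traits(focal) ∩ traits(strain)| / |traits(focal)|

O is directional (normalized by the focal strain's repertoire) and lies in
[0, 1]; it is not a symmetric similarity index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedScoreError

__all__ = ["validate_trait_matrix", "resource_overlap", "overlap_table"]


def validate_trait_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a strains x traits matrix is strictly binary with unique labels."""
    if matrix.index.has_duplicates:
        raise FormatError("duplicate strain identifiers in trait matrix")
    if matrix.columns.has_duplicates:
        raise FormatError("duplicate trait identifiers in trait matrix")
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = sorted({v for v in np.unique(values) if v not in (0, 1)})
        raise FormatError(f"trait matrix must be binary; found values {bad}")
    return matrix.astype(int)


def resource_overlap(focal: pd.Series, strain: pd.Series) -> float:
    """Fraction of the focal strain's traits shared by ``strain``."""
    if not focal.index.equals(strain.index):
        if set(focal.index) != set(strain.index):
            raise FormatError("focal and strain rows use different trait universes")
        strain = strain.reindex(focal.index)
    f = focal.to_numpy().astype(bool)
    s = strain.to_numpy().astype(bool)
    n_focal = int(f.sum())
    if n_focal == 0:
        raise UndefinedScoreError("focal strain has no traits; overlap undefined")
    return float((f & s).sum() / n_focal)


def overlap_table(matrix: pd.DataFrame, focal_id: str) -> pd.Series:
    """Overlap with the focal strain for every strain in the matrix.

    Returns a Series indexed by strain (focal included, with O = 1 by
    construction when the focal has >= 1 trait).
    """
    matrix = validate_trait_matrix(matrix)
    if focal_id not in matrix.index:
        raise ValueError(f"unknown focal strain: {focal_id!r}")
    focal = matrix.loc[focal_id]
    out = pd.Series(
        {sid: resource_overlap(focal, matrix.loc[sid]) for sid in matrix.index},
        name="resource_overlap",
    )
    out.index.name = "strain"
    return out
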