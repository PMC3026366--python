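"""Imputation and binary quantization of time-series expression data.

The downstream metrics operate on the Boolean formalism: each gene is ON (1)
or OFF (0) at each time point.  Continuous data are quantized per gene by a
rank rule: sort the gene's values, drop the smallest and largest as outliers,
threshold at the median of what remains; values strictly above the threshold
become 1.  Missing time points are filled first — interior gaps by the mean of
their temporal neighbours, leading/trailing gaps by the nearest observed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["BinaryExpressionMatrix", "impute_missing", "binarize", "as_binary"]


@dataclass
class BinaryExpressionMatrix:
    """Quantized ON/OFF expression: genes × time points over {0, 1}."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("binary values must be a 2-D grid")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("binary matrix may contain only 0 and 1")
        self.values = self.values.astype(np.int8)
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError("gene id count does not match row count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.values[i]

    def prefix(self, m: int) -> "BinaryExpressionMatrix":
        """First ``m`` time points (used by data-size sweeps)."""
        if not 1 <= m <= self.n_timepoints:
            raise ValidationError(f"prefix length {m} outside [1, {self.n_timepoints}]")
        return BinaryExpressionMatrix(list(self.gene_ids), self.values[:, :m].copy())


def impute_missing(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing cells from temporal neighbours.

    Interior gaps take the mean of the two adjacent time points; a missing
    first or last point copies the nearest observed value.  Runs of
    consecutive interior gaps are filled iteratively left-to-right, so each
    gap uses the already-imputed value to its left.  Observed cells are never
    altered.
    """
    values = expr.values.copy()
    mask = expr.mask.copy()
    m = expr.n_timepoints
    for i, gid in enumerate(expr.gene_ids):
        if mask[i].all():
            raise ValidationError(f"gene {gid!r} has no observed values")
        if not mask[i].any():
            continue
        observed = np.flatnonzero(~mask[i])
        first, last = observed[0], observed[-1]
        # leading/trailing gaps: nearest observed time point
        values[i, :first] = values[i, first]
        values[i, last + 1 :] = values[i, last]
        mask[i, :first] = False
        mask[i, last + 1 :] = False
        # interior gaps, left to right; right neighbour is the next observed
        for t in range(first + 1, last):
            if mask[i, t]:
                nxt = t + 1
                while mask[i, nxt]:
                    nxt += 1
                values[i, t] = (values[i, t - 1] + values[i, nxt]) / 2.0
                mask[i, t] = False
    assert not mask.any()
    return ExpressionMatrix(list(expr.gene_ids), values, np.zeros_like(mask))


def binarize(expr: ExpressionMatrix) -> BinaryExpressionMatrix:
    """Quantize each gene's trajectory to {0, 1} by the trimmed-median rule.

    Per gene: sort values ascending, discard exactly one minimum and one
    maximum as outliers, set the threshold to the median of the remaining
    values, and map every original value (including the trimmed extremes) to
    1 iff strictly above the threshold.  Ties at the threshold go to 0, so a
    constant gene becomes all-0 (OFF) with a logged warning.
    """
    if expr.mask.any():
        raise ValidationError("binarize requires imputed data (no missing values)")
    m = expr.n_timepoints
    if m < 4:
        raise ValidationError(
            f"binarization needs at least 4 time points (got {m}): "
            "outlier trimming must leave at least 2 values"
        )
    out = np.empty_like(expr.values, dtype=np.int8)
    for i, gid in enumerate(expr.gene_ids):
        row = expr.values[i]
        trimmed = np.sort(row)[1:-1]
        threshold = float(np.median(trimmed))
        out[i] = (row > threshold).astype(np.int8)
        if (row == row[0]).all():
            logger.warning("gene %s is constant; quantized to all-OFF", gid)
    return BinaryExpressionMatrix(list(expr.gene_ids), out)


def as_binary(expr: ExpressionMatrix) -> BinaryExpressionMatrix:
    """Adopt an already-binary matrix without re-quantizing (``--assume-binary``)."""
    if expr.mask.any():
        raise ValidationError("binary input may not contain missing values")
    if not np.isin(expr.values, (0.0, 1.0)).all():
        raise ValidationError("matrix is not strictly {0,1}-valued")
    return BinaryExpressionMatrix(list(expr.gene_ids), expr.values.astype(np.int8))
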