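"""Background subtraction, quantile normalization, and detectability calls.

These re-implement the generic array preprocessing the screening design
relies on: a per-sample background level is subtracted from raw intensities
(negative results are kept, not clipped — they are the detectability signal),
every sample is then forced onto the common rank-mean reference distribution,
and a probe is called *detected* in a sample iff its background-subtracted
value is strictly positive.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["subtract_background", "quantile_normalize", "detect_mask"]

#: Boolean probes × samples frame; True where the probe is detected.
DetectabilityMask = pd.DataFrame


def subtract_background(
    matrix: ExpressionMatrix,
    background: float | Sequence[float] | pd.Series,
) -> ExpressionMatrix:
    """Subtract a per-sample background level from a raw matrix.

    ``background`` is a scalar (applied to every sample) or one non-negative
    value per sample, in column order or keyed by sample id. Negative results
    are retained.
    """
    if matrix.stage != "raw":
        raise ValueError(f"expected stage 'raw', got {matrix.stage!r}")
    if np.isscalar(background):
        bg = pd.Series(float(background), index=matrix.data.columns)
    elif isinstance(background, pd.Series):
        missing = set(matrix.data.columns) - set(background.index)
        if missing:
            raise ValueError(f"background missing samples: {sorted(missing)}")
        bg = background.reindex(matrix.data.columns).astype(float)
    else:
        values = np.asarray(list(background), dtype=float)
        if values.shape != (matrix.n_samples,):
            raise ValueError(
                f"background length {values.size} != number of samples {matrix.n_samples}"
            )
        bg = pd.Series(values, index=matrix.data.columns)
    if (bg < 0).any():
        raise ValueError("background levels must be non-negative")
    return matrix.with_stage(matrix.data.sub(bg, axis=1), "bg_subtracted")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common rank-mean distribution.

    The reference distribution is the row-wise mean of the column-sorted
    input; each column's values are replaced by the reference value at their
    rank. Tied values within a column receive the mean of the reference
    values at the ranks the tie block occupies, so the transform is
    rank-preserving and idempotent.

    A single-sample matrix is returned unchanged (with the new stage tag) and
    a warning, since there is nothing to normalize against.
    """
    if matrix.n_probes < 1:
        raise ValueError("quantile normalization requires at least one probe")
    if matrix.n_samples < 2:
        warnings.warn(
            "quantile normalization of a single-sample matrix is a no-op",
            UserWarning,
            stacklevel=2,
        )
        return matrix.with_stage(matrix.data.copy(), "normalized")

    values = matrix.data.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average the mapped reference values over tie blocks
        sorted_col = col[order]
        block_start = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        block_id = np.zeros(len(col), dtype=int)
        block_id[block_start] = 1
        block_id = np.cumsum(block_id) - 1
        sums = np.bincount(block_id, weights=reference)
        counts = np.bincount(block_id)
        mapped[order] = (sums / counts)[block_id]
        out[:, j] = mapped

    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.with_stage(data, "normalized")


def detect_mask(matrix: ExpressionMatrix) -> DetectabilityMask:
    """Detection calls on a background-subtracted matrix.

    A probe is detected in a sample iff its background-subtracted value is
    strictly greater than zero; exactly zero counts as undetected.
    """
    if matrix.stage != "bg_subtracted":
        raise ValueError(f"expected stage 'bg_subtracted', got {matrix.stage!r}")
    return matrix.data > 0
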