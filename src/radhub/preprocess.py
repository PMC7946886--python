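"""Expression preprocessing: quantile normalization and CV gene filtering.

Datasets are quantile normalized before network construction so every sample
shares one reference distribution, then genes are ranked by coefficient of
variation (CV = sd / mean) and low-variability genes are dropped to avoid
spurious correlations. Expression is assumed to arrive on log2 scale; the CV
is computed on the unlogged (2^x) scale by default, where it is invariant to
multiplicative rescaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    """CV filter settings.

    ``cv_mode`` selects between keeping the top fraction of genes by CV
    (``top_fraction``) and an absolute CV cutoff (``absolute_cutoff``).
    ``unlog_base = 2`` computes the CV on the 2^x scale; ``None`` uses the
    values as-is.
    """

    cv_mode: str = "top_fraction"
    cv_top_fraction: float = 0.5
    cv_cutoff: float = 0.0
    unlog_base: int | None = 2

    def __post_init__(self) -> None:
        if self.cv_mode not in ("top_fraction", "absolute_cutoff"):
            raise ConfigurationError(f"unknown cv_mode {self.cv_mode!r}")
        if self.cv_mode == "top_fraction" and not 0 < self.cv_top_fraction <= 1:
            raise ConfigurationError("cv_top_fraction must be in (0, 1]")
        if self.cv_mode == "absolute_cutoff" and self.cv_cutoff < 0:
            raise ConfigurationError("cv_cutoff must be >= 0")
        if self.unlog_base not in (2, None):
            raise ConfigurationError("unlog_base must be 2 or None")


def _as_array(values) -> tuple[np.ndarray, bool]:
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float), True
    return np.asarray(values, dtype=float), False


def quantile_normalize(values):
    """Force every column (sample) onto the common rank-mean distribution.

    Each column's values are replaced by the across-column mean of the order
    statistics at each rank. Tied values within a column receive the mean of
    the reference values over their tied ranks, which makes the operation
    deterministic and idempotent. Accepts and returns either a numpy array
    or a DataFrame (index/columns preserved).
    """
    arr, is_frame = _as_array(values)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValidationError("expected a 2-D matrix with at least one row")
    if np.isnan(arr).any():
        cells = [tuple(int(v) for v in rc) for rc in np.argwhere(np.isnan(arr))[:10]]
        raise ValidationError(f"missing values at (row, col): {cells}")
    if arr.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is the identity")
        out = arr.copy()
    else:
        reference = np.sort(arr, axis=0).mean(axis=1)
        out = np.empty_like(arr)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            order = np.argsort(col, kind="stable")
            ranked = np.empty_like(col)
            ranked[order] = reference
            # ties: average the reference values across each tied run
            uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
            if len(uniq) < len(col):
                sums = np.zeros(len(uniq))
                np.add.at(sums, inverse, ranked)
                ranked = (sums / counts)[inverse]
            out[:, j] = ranked
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def cv_filter(values, gene_ids, config: PreprocessConfig | None = None):
    """Keep high-CV genes; returns (filtered matrix, kept gene ids).

    The CV is sd/mean per gene, computed on the unlogged scale when
    ``unlog_base`` is 2. In ``top_fraction`` mode the ceil(fraction * n)
    highest-CV genes are kept; in ``absolute_cutoff`` mode genes with
    CV >= cutoff. Original gene order is preserved among kept genes.
    """
    if config is None:
        config = PreprocessConfig()
    arr, is_frame = _as_array(values)
    gene_ids = [str(g) for g in gene_ids]
    if arr.shape[0] != len(gene_ids):
        raise ValidationError(
            f"matrix has {arr.shape[0]} rows but {len(gene_ids)} gene ids were given"
        )
    scale = np.power(2.0, arr) if config.unlog_base == 2 else arr
    means = scale.mean(axis=1)
    if np.any(means <= 0):
        bad = [gene_ids[i] for i in np.where(means <= 0)[0][:10]]
        raise ValidationError(f"CV undefined for genes with non-positive mean: {bad}")
    sds = scale.std(axis=1, ddof=1)
    cv = sds / means

    if config.cv_mode == "top_fraction":
        n_keep = math.ceil(config.cv_top_fraction * len(gene_ids))
        # rank by CV descending, stable in original gene order
        order = np.lexsort((np.arange(len(cv)), -cv))
        keep_mask = np.zeros(len(cv), dtype=bool)
        keep_mask[order[:n_keep]] = True
    else:
        keep_mask = cv >= config.cv_cutoff

    kept_idx = np.where(keep_mask)[0]
    kept_ids = [gene_ids[i] for i in kept_idx]
    if is_frame:
        return values.iloc[kept_idx], kept_ids
    return arr[kept_idx], kept_ids
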