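"""Core expression-dataset container.

An :class:`ExpressionDataset` bundles a log2-scale genes x samples matrix
with per-sample metadata (condition, arm, dose in Gy, hours post-irradiation).
It is the unit on which one coexpression network is built and from which
irradiated-vs-control contrasts are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: metadata columns every dataset must carry, keyed by sample id (the index)
METADATA_COLUMNS = ("condition_id", "arm", "dose_gray", "time_hours")

ARMS = ("control", "irradiated")


@dataclass
class ExpressionDataset:
    """Genes x samples log2 expression with aligned sample metadata.

    Parameters
    ----------
    dataset_id:
        Identifier of the dataset (one network is built per dataset).
    values:
        DataFrame indexed by gene id with one column per sample id.
    metadata:
        DataFrame indexed by sample id with columns ``condition_id``,
        ``arm`` (control/irradiated), ``dose_gray`` and ``time_hours``.
    """

    dataset_id: str
    values: pd.DataFrame
    metadata: pd.DataFrame

    gene_ids: list[str] = field(init=False, repr=False)
    sample_ids: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in {self.dataset_id}: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise ValidationError(f"duplicate sample ids in {self.dataset_id}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [
                (str(self.values.index[i]), str(self.values.columns[j]))
                for i, j in zip(*np.where(~np.vectorize(_is_number)(arr)))
            ]
            raise ValidationError(f"non-numeric expression cells: {bad[:5]}")
        if np.isnan(arr.astype(float)).any():
            i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {missing_cols}")
        unmatched = [s for s in self.values.columns if s not in self.metadata.index]
        if unmatched:
            raise ValidationError(
                f"samples absent from metadata in {self.dataset_id}: {unmatched[:5]}"
            )
        bad_arms = set(self.metadata["arm"]) - set(ARMS)
        if bad_arms:
            raise ValidationError(f"unknown arm labels: {sorted(bad_arms)}")
        # keep metadata aligned to the matrix column order; normalize axis
        # names so in-memory and file-loaded datasets compare equal
        self.metadata = self.metadata.loc[list(self.values.columns)]
        self.values = self.values.rename_axis(index=None, columns=None)
        self.gene_ids = [str(g) for g in self.values.index]
        self.sample_ids = [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def condition_ids(self) -> list[str]:
        """Condition identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.metadata["condition_id"]:
            seen.setdefault(str(c), None)
        return list(seen)

    def condition_samples(self, condition_id: str, arm: str) -> list[str]:
        """Sample ids of one arm of one condition."""
        if arm not in ARMS:
            raise ValidationError(f"unknown arm {arm!r}")
        mask = (self.metadata["condition_id"].astype(str) == str(condition_id)) & (
            self.metadata["arm"] == arm
        )
        return [str(s) for s in self.metadata.index[mask]]

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Return a copy of the dataset carrying a new expression matrix."""
        return ExpressionDataset(self.dataset_id, values, self.metadata.copy())


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
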