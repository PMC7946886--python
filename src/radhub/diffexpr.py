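"""Fold-change differential expression and cross-condition consistency.

For every irradiated-vs-control condition the per-gene log2 fold change is
the difference of arm means (data are already log2). A gene is called up or
down in a condition when |log2FC| >= 1 (the two-fold rule, boundary
inclusive). Across all conditions of the study, a gene is directionally
consistent when it is called in at least ``ceil(min_sig_fraction * n)``
conditions and a strict majority of its calls share one direction. Welch
t-test p-values are carried as a purely descriptive annotation; the decision
rule is fold change alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .dataset import ExpressionDataset
from .errors import ConfigurationError, ValidationError


@dataclass
class DEContrast:
    """One irradiated-vs-control comparison.

    ``frame`` is indexed by gene id with columns ``log2fc``, ``call``
    (up/down/ns) and ``p_value`` (annotation only).
    """

    condition_id: str
    frame: pd.DataFrame
    fc_threshold_log2: float = 1.0


@dataclass
class DEConsistency:
    """Cross-condition directional summary.

    ``frame`` is indexed by gene id with columns ``n_up``, ``n_down`` and
    ``status`` in {consistent_up, consistent_down, inconsistent, not_DE}.
    """

    frame: pd.DataFrame
    n_conditions: int
    min_sig: int

    def status_of(self, gene: str) -> str:
        return str(self.frame.loc[gene, "status"])

    def genes_with_status(self, status: str) -> frozenset[str]:
        return frozenset(str(g) for g in self.frame.index[self.frame["status"] == status])


def contrast_log2fc(
    dataset: ExpressionDataset,
    condition_id: str,
    fc_threshold_log2: float = 1.0,
) -> DEContrast:
    """Mean-difference log2 fold change and two-fold calls for one condition."""
    if fc_threshold_log2 <= 0:
        raise ConfigurationError("fc_threshold_log2 must be positive")
    ctrl = dataset.condition_samples(condition_id, "control")
    irr = dataset.condition_samples(condition_id, "irradiated")
    if not ctrl or not irr:
        missing = "control" if not ctrl else "irradiated"
        raise ValidationError(f"condition {condition_id!r} has no {missing} samples")
    if len(ctrl) < 2 or len(irr) < 2:
        raise ValidationError(
            f"condition {condition_id!r} needs >= 2 samples per arm "
            f"(control={len(ctrl)}, irradiated={len(irr)})"
        )
    c = dataset.values[ctrl].to_numpy(float)
    t = dataset.values[irr].to_numpy(float)
    log2fc = t.mean(axis=1) - c.mean(axis=1)
    call = np.where(
        log2fc >= fc_threshold_log2,
        "up",
        np.where(log2fc <= -fc_threshold_log2, "down", "ns"),
    )
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant arms make the Welch annotation NaN; calls use fold change only
        warnings.simplefilter("ignore", RuntimeWarning)
        p = ttest_ind(t, c, axis=1, equal_var=False).pvalue
    frame = pd.DataFrame(
        {"log2fc": log2fc, "call": call, "p_value": p},
        index=pd.Index(dataset.gene_ids, name="gene_id"),
    )
    return DEContrast(str(condition_id), frame, fc_threshold_log2)


def dataset_contrasts(
    dataset: ExpressionDataset, fc_threshold_log2: float = 1.0
) -> list[DEContrast]:
    """All per-condition contrasts of one dataset."""
    return [
        contrast_log2fc(dataset, cid, fc_threshold_log2) for cid in dataset.condition_ids
    ]


def summarize_consistency(
    contrasts: list[DEContrast], min_sig_fraction: float = 0.25
) -> DEConsistency:
    """Majority-rule directional consistency across conditions.

    min_sig = ceil(min_sig_fraction * n_conditions). Status per gene:
    ``not_DE`` when n_up + n_down < min_sig; otherwise ``consistent_up`` /
    ``consistent_down`` by strict majority, or ``inconsistent`` on a tie.
    """
    if not contrasts:
        raise ValidationError("need at least one contrast")
    if not 0 < min_sig_fraction <= 1:
        raise ConfigurationError("min_sig_fraction must be in (0, 1]")
    index = contrasts[0].frame.index
    for c in contrasts[1:]:
        if not c.frame.index.equals(index):
            raise ValidationError(
                f"contrast {c.condition_id!r} is over a different gene universe"
            )
    calls = np.stack([c.frame["call"].to_numpy() for c in contrasts])
    n_up = (calls == "up").sum(axis=0)
    n_down = (calls == "down").sum(axis=0)
    n_conditions = len(contrasts)
    min_sig = math.ceil(min_sig_fraction * n_conditions)
    total = n_up + n_down
    status = np.where(
        total < min_sig,
        "not_DE",
        np.where(
            n_up > n_down,
            "consistent_up",
            np.where(n_down > n_up, "consistent_down", "inconsistent"),
        ),
    )
    frame = pd.DataFrame(
        {"n_up": n_up, "n_down": n_down, "status": status},
        index=index.rename("gene_id"),
    )
    return DEConsistency(frame, n_conditions, min_sig)
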