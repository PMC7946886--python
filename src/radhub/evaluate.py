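"""Scoring pipeline output against planted synthetic truth."""

from __future__ import annotations

import numpy as np
from scipy.special import comb

from .hubs import HubSet
from .network import UNASSIGNED, NetworkModel
from .simulate import SyntheticTruth
from .targets import CandidateTable


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two flat partitions.

    Computed from the contingency table: ARI = (sum_ij C(n_ij,2) - E) /
    (max - E) with the usual expected-index correction; 1 for identical
    partitions (up to relabeling), ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    if n < 2:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def module_recovery_ari(truth: SyntheticTruth, network: NetworkModel) -> float:
    """ARI between detected and planted module labels.

    Restricted to genes that are both planted into a module and assigned to
    a detected module, so the score reflects partition agreement rather than
    background handling.
    """
    detected = network.partition.to_series()
    genes = [
        g
        for g in detected.index
        if truth.module_of_gene.get(str(g), 0) != 0 and detected[g] != UNASSIGNED
    ]
    if not genes:
        return float("nan")
    planted = [truth.module_of_gene[str(g)] for g in genes]
    found = [int(detected[g]) for g in genes]
    return adjusted_rand_index(planted, found)


def hub_recall(truth: SyntheticTruth, hubset: HubSet, network_genes) -> float:
    """Fraction of planted hubs (present in the network) selected as hubs."""
    present = truth.hub_genes & {str(g) for g in network_genes}
    if not present:
        return float("nan")
    return len(present & hubset.genes) / len(present)


def planted_candidate_set(truth: SyntheticTruth) -> frozenset[str]:
    """Planted hub AND druggable AND directionally-consistent genes."""
    return frozenset(
        g
        for g in truth.hub_genes & truth.druggable_genes
        if truth.consistent_direction.get(g, "none") in ("up", "down")
    )


def candidate_metrics(truth: SyntheticTruth, candidates: CandidateTable) -> dict[str, float]:
    """Precision/recall of the candidate table against the planted truth set."""
    planted = planted_candidate_set(truth)
    found = candidates.genes
    tp = len(planted & found)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {
        "n_planted": len(planted),
        "n_candidates": len(found),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
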