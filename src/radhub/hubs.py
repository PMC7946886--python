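"""Hub-gene selection per network and cross-network consensus.

Within one network, hub genes are the top fraction (20% by default) of
module-assigned genes ranked by intramodular connectivity. Across networks,
a consensus hub is a gene selected in at least ``min_networks`` of the
independently built networks; the overlap-degree histogram (how many genes
are hubs in exactly j networks) is the basis for choosing the hub fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .network import UNASSIGNED, ConnectivityTable, NetworkModel


@dataclass
class HubSet:
    """Top-connectivity genes of one network."""

    dataset_id: str
    top_fraction: float
    genes: frozenset[str]
    threshold_k: float


@dataclass
class ConsensusTable:
    """Per-gene hub membership counts across networks.

    ``frame`` has one row per gene appearing in any hub set, with columns
    ``hub_count`` and ``member_networks``; ``histogram`` maps overlap degree
    j to the number of genes that are hubs in exactly j networks.
    """

    frame: pd.DataFrame
    n_networks: int
    min_networks: int
    histogram: dict[int, int]

    @property
    def consensus_genes(self) -> frozenset[str]:
        mask = self.frame["hub_count"] >= self.min_networks
        return frozenset(str(g) for g in self.frame.index[mask])


def select_hubs(
    connectivity: ConnectivityTable,
    top_fraction: float = 0.20,
    dataset_id: str = "network",
) -> HubSet:
    """Top-``top_fraction`` genes by intramodular connectivity.

    Only module-assigned genes are ranked (unassigned genes have k_within 0
    by convention). Genes exactly tied with the boundary connectivity are all
    included, so selection never depends on input order.
    """
    if not 0 < top_fraction < 1:
        raise ConfigurationError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if len(connectivity) == 0:
        raise ValidationError("empty connectivity table")
    frame = connectivity.frame
    assigned = frame[frame["module"] != UNASSIGNED]
    if assigned.empty:
        warnings.warn(f"{dataset_id}: all genes unassigned; hub set is empty")
        return HubSet(dataset_id, top_fraction, frozenset(), float("nan"))
    kw = assigned["k_within"].to_numpy(float)
    n_select = math.ceil(top_fraction * len(assigned))
    threshold = float(np.sort(kw)[::-1][n_select - 1])
    genes = frozenset(str(g) for g in assigned.index[kw >= threshold])
    return HubSet(dataset_id, top_fraction, genes, threshold)


def consensus_hubs(hubsets: list[HubSet], min_networks: int = 2) -> ConsensusTable:
    """Count hub membership of every gene across networks."""
    if len(hubsets) < 2:
        raise ValidationError("need at least 2 hub sets")
    ids = [h.dataset_id for h in hubsets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate dataset ids among hub sets: {ids}")
    if min_networks < 1:
        raise ConfigurationError("min_networks must be >= 1")
    membership: dict[str, list[str]] = {}
    for h in hubsets:
        for g in h.genes:
            membership.setdefault(g, []).append(h.dataset_id)
    rows = [
        {
            "gene_id": g,
            "hub_count": len(nets),
            "member_networks": ",".join(sorted(nets)),
        }
        for g, nets in membership.items()
    ]
    frame = pd.DataFrame(rows, columns=["gene_id", "hub_count", "member_networks"])
    frame = frame.sort_values(
        ["hub_count", "gene_id"], ascending=[False, True]
    ).set_index("gene_id")
    histogram = {
        j: int((frame["hub_count"] == j).sum()) for j in range(1, len(hubsets) + 1)
    }
    return ConsensusTable(frame, len(hubsets), min_networks, histogram)


def overlap_profile(
    networks: list[NetworkModel],
    fractions=(0.05, 0.10, 0.20),
) -> pd.DataFrame:
    """Overlap-degree histograms across candidate hub fractions.

    For each fraction, hub sets are recomputed in every network and the
    number of genes shared by exactly j networks is tabulated. The returned
    frame is indexed by fraction with one column per overlap degree; it is
    the quantitative basis for preferring the fraction whose hub sets overlap
    in the most networks.
    """
    if len(networks) < 2:
        raise ValidationError("need at least 2 networks")
    for f in fractions:
        if not 0 < f <= 1:
            raise ConfigurationError(f"invalid hub fraction {f}")
    rows = {}
    for f in fractions:
        if f == 1.0:
            hubsets = [
                HubSet(
                    net.dataset_id,
                    f,
                    frozenset(
                        g
                        for g, l in zip(net.partition.gene_ids, net.partition.labels)
                        if l != UNASSIGNED
                    ),
                    0.0,
                )
                for net in networks
            ]
        else:
            hubsets = [
                select_hubs(net.connectivity, top_fraction=f, dataset_id=net.dataset_id)
                for net in networks
            ]
        table = consensus_hubs(hubsets, min_networks=1)
        rows[f] = table.histogram
    frame = pd.DataFrame(rows).T.sort_index()
    frame.index.name = "top_fraction"
    frame.columns = [f"shared_by_{j}" for j in frame.columns]
    return frame
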