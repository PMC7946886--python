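"""Drug-target catalog handling and candidate-table construction.

The candidate table is the three-way intersection at the heart of the
target-prioritization chain: genes that are consensus hubs in at least
``min_networks`` coexpression networks, are targets of at least one drug in
the catalog, and are directionally consistent in the differential-expression
summary. Direction is copied from the DE status; the proposed modulation
(inhibit/activate) is left unassigned for downstream curation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .diffexpr import DEConsistency
from .errors import ValidationError
from .hubs import ConsensusTable

CATALOG_COLUMNS = ("gene_id", "drug_name", "status")

VALID_STATUSES = frozenset(
    {
        "approved",
        "launched",
        "clinical_phase",
        "preclinical",
        "investigational",
        "discovery",
    }
)


@dataclass
class DrugTargetCatalog:
    """Validated (gene, drug, development status) records."""

    frame: pd.DataFrame

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene_id"].astype(str))

    def drugs_for(self, gene: str) -> list[tuple[str, str]]:
        sub = self.frame[self.frame["gene_id"].astype(str) == str(gene)]
        return sorted(zip(sub["drug_name"].astype(str), sub["status"].astype(str)))

    def __len__(self) -> int:
        return len(self.frame)


def load_catalog(path: str | Path) -> DrugTargetCatalog:
    """Read and validate a drug-target TSV (gene_id, drug_name, status)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"catalog {path} missing columns: {missing}")
    if frame.empty:
        warnings.warn(f"catalog {path} is empty")
        return DrugTargetCatalog(frame)
    bad_status = frame[~frame["status"].isin(VALID_STATUSES)]
    if not bad_status.empty:
        lines = [int(i) + 2 for i in bad_status.index[:10]]  # +2: header + 1-based
        raise ValidationError(
            f"unknown drug status values {sorted(set(bad_status['status']))} "
            f"on lines {lines} of {path}"
        )
    dup = frame.duplicated(subset=["gene_id", "drug_name"])
    if dup.any():
        lines = [int(i) + 2 for i in frame.index[dup][:10]]
        raise ValidationError(f"duplicate (gene, drug) pairs on lines {lines} of {path}")
    return DrugTargetCatalog(frame.reset_index(drop=True))


def catalog_from_frame(frame: pd.DataFrame) -> DrugTargetCatalog:
    """Validate an in-memory catalog DataFrame (same rules as load_catalog)."""
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"catalog frame missing columns: {missing}")
    bad = set(frame["status"]) - VALID_STATUSES
    if bad:
        raise ValidationError(f"unknown drug status values: {sorted(bad)}")
    if frame.duplicated(subset=["gene_id", "drug_name"]).any():
        raise ValidationError("duplicate (gene, drug) pairs in catalog frame")
    return DrugTargetCatalog(frame.reset_index(drop=True))


@dataclass
class CandidateTable:
    """Prioritized drug-target candidates.

    One row per gene passing all three filters, ordered by
    (-hub_count, -(n_up + n_down), gene_id). Columns: hub_count,
    member_networks, direction, n_up, n_down, drugs (semicolon-joined
    ``drug(status)`` entries), proposed_modulation.
    """

    frame: pd.DataFrame
    min_networks: int

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(str(g) for g in self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def build_candidates(
    consensus: ConsensusTable,
    de: DEConsistency,
    catalog: DrugTargetCatalog,
    min_networks: int = 2,
) -> CandidateTable:
    """Consensus hubs that are druggable and directionally consistent."""
    if consensus.frame.empty or len(catalog) == 0:
        warnings.warn("empty consensus table or catalog: no candidates")
        return CandidateTable(_empty_frame(), min_networks)
    druggable = catalog.genes
    rows = []
    for gene, row in consensus.frame.iterrows():
        gene = str(gene)
        if int(row["hub_count"]) < min_networks or gene not in druggable:
            continue
        if gene not in de.frame.index:
            continue
        status = str(de.frame.loc[gene, "status"])
        if status not in ("consistent_up", "consistent_down"):
            continue
        drugs = ";".join(f"{d}({s})" for d, s in catalog.drugs_for(gene))
        rows.append(
            {
                "gene_id": gene,
                "hub_count": int(row["hub_count"]),
                "member_networks": str(row["member_networks"]),
                "direction": "up" if status == "consistent_up" else "down",
                "n_up": int(de.frame.loc[gene, "n_up"]),
                "n_down": int(de.frame.loc[gene, "n_down"]),
                "drugs": drugs,
                "proposed_modulation": "unassigned",
            }
        )
    if not rows:
        warnings.warn("no genes pass the hub/druggable/consistency intersection")
        return CandidateTable(_empty_frame(), min_networks)
    frame = pd.DataFrame(rows)
    frame["n_calls"] = frame["n_up"] + frame["n_down"]
    frame = frame.sort_values(
        ["hub_count", "n_calls", "gene_id"], ascending=[False, False, True]
    ).drop(columns="n_calls")
    return CandidateTable(frame.set_index("gene_id"), min_networks)


def annotate_candidates(candidates: CandidateTable, annotations: pd.DataFrame) -> CandidateTable:
    """Left-join optional per-gene annotations (disease links, curated notes).

    Annotations are descriptive pass-through columns keyed by ``gene_id``;
    they never filter the table. Genes without annotation rows keep empty
    strings.
    """
    if "gene_id" not in annotations.columns:
        raise ValidationError("annotations need a gene_id column")
    if annotations["gene_id"].duplicated().any():
        raise ValidationError("annotations must have one row per gene")
    extra = annotations.set_index("gene_id")
    joined = candidates.frame.join(extra, how="left").fillna("")
    return CandidateTable(joined, candidates.min_networks)


def _empty_frame() -> pd.DataFrame:
    cols = [
        "hub_count",
        "member_networks",
        "direction",
        "n_up",
        "n_down",
        "drugs",
        "proposed_modulation",
    ]
    return pd.DataFrame(columns=cols, index=pd.Index([], name="gene_id"))
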