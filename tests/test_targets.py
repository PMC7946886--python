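"""Drug-target catalog handling and the candidate intersection."""

import pandas as pd
import pytest

from radhub.diffexpr import DEConsistency
from radhub.errors import ValidationError
from radhub.hubs import ConsensusTable
from radhub.targets import annotate_candidates, build_candidates, catalog_from_frame, load_catalog


def write_catalog(tmp_path, rows, name="catalog.tsv"):
    path = tmp_path / name
    frame = pd.DataFrame(rows, columns=["gene_id", "drug_name", "status"])
    frame.to_csv(path, sep="\t", index=False)
    return path


def make_consensus(counts):
    frame = pd.DataFrame(
        {
            "gene_id": list(counts),
            "hub_count": list(counts.values()),
            "member_networks": ["DS1,DS2"] * len(counts),
        }
    ).set_index("gene_id")
    return ConsensusTable(frame, n_networks=5, min_networks=2, histogram={})


def make_de(status_by_gene, n_up=9, n_down=2):
    rows = []
    for gene, status in status_by_gene.items():
        if status == "consistent_up":
            rows.append((gene, n_up, n_down, status))
        elif status == "consistent_down":
            rows.append((gene, n_down, n_up, status))
        else:
            rows.append((gene, 1, 1, status))
    frame = pd.DataFrame(
        rows, columns=["gene_id", "n_up", "n_down", "status"]
    ).set_index("gene_id")
    return DEConsistency(frame, n_conditions=32, min_sig=8)


class TestLoadCatalog:
    def test_well_formed_file(self, tmp_path):
        path = write_catalog(
            tmp_path,
            [("g1", "drugA", "approved"), ("g1", "drugB", "preclinical"), ("g2", "drugA", "launched")],
        )
        catalog = load_catalog(path)
        assert len(catalog) == 3
        assert catalog.drugs_for("g1") == [("drugA", "approved"), ("drugB", "preclinical")]

    def test_duplicate_pair_names_line(self, tmp_path):
        path = write_catalog(
            tmp_path, [("g1", "drugA", "approved"), ("g1", "drugA", "approved")]
        )
        with pytest.raises(ValidationError, match="lines \\[3\\]"):
            load_catalog(path)

    def test_unknown_status_rejected_with_line(self, tmp_path):
        path = write_catalog(tmp_path, [("g1", "drugA", "fda_super_approved")])
        with pytest.raises(ValidationError, match="line"):
            load_catalog(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"gene_id": ["g1"], "drug_name": ["d"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="status"):
            load_catalog(path)

    def test_empty_catalog_warns(self, tmp_path):
        path = write_catalog(tmp_path, [])
        with pytest.warns(UserWarning, match="empty"):
            catalog = load_catalog(path)
        assert len(catalog) == 0


class TestBuildCandidates:
    def test_rule_conjunction(self):
        consensus = make_consensus({"g1": 3})
        de = make_de({"g1": "consistent_up"})
        catalog = catalog_from_frame(
            pd.DataFrame({"gene_id": ["g1"], "drug_name": ["drugA"], "status": ["approved"]})
        )
        table = build_candidates(consensus, de, catalog, min_networks=2)
        assert table.genes == {"g1"}
        row = table.frame.loc["g1"]
        assert row["direction"] == "up" and row["drugs"] == "drugA(approved)"
        assert row["proposed_modulation"] == "unassigned"

    def test_single_network_hub_excluded(self):
        consensus = make_consensus({"g1": 1})
        de = make_de({"g1": "consistent_up"})
        catalog = catalog_from_frame(
            pd.DataFrame({"gene_id": ["g1"], "drug_name": ["d"], "status": ["approved"]})
        )
        with pytest.warns(UserWarning):
            table = build_candidates(consensus, de, catalog, min_networks=2)
        assert len(table) == 0

    def test_equals_bruteforce_intersection(self, rng):
        genes = [f"g{i:02d}" for i in range(30)]
        hub_counts = {g: int(rng.integers(1, 6)) for g in rng.choice(genes, 18, replace=False)}
        statuses = {
            g: rng.choice(["consistent_up", "consistent_down", "inconsistent", "not_DE"])
            for g in genes
        }
        druggable = set(rng.choice(genes, 12, replace=False))
        catalog = catalog_from_frame(
            pd.DataFrame(
                {"gene_id": sorted(druggable), "drug_name": "drugX", "status": "approved"}
            )
        )
        table = build_candidates(
            make_consensus(hub_counts), make_de(statuses), catalog, min_networks=2
        )
        expected = {
            g
            for g in genes
            if hub_counts.get(g, 0) >= 2
            and g in druggable
            and statuses[g] in ("consistent_up", "consistent_down")
        }
        assert table.genes == expected

    def test_removing_catalog_records_never_adds_candidates(self, rng):
        genes = [f"g{i}" for i in range(12)]
        consensus = make_consensus({g: 3 for g in genes[:8]})
        de = make_de({g: "consistent_up" for g in genes})
        full = pd.DataFrame(
            {"gene_id": genes[:6], "drug_name": "drugX", "status": "approved"}
        )
        before = build_candidates(consensus, de, catalog_from_frame(full), 2).genes
        for drop in range(len(full)):
            reduced = catalog_from_frame(full.drop(index=drop))
            after = build_candidates(consensus, de, reduced, 2).genes
            assert after <= before

    def test_deterministic_ordering(self):
        consensus = make_consensus({"b": 3, "a": 3, "c": 5})
        de = make_de({"a": "consistent_up", "b": "consistent_up", "c": "consistent_down"})
        catalog = catalog_from_frame(
            pd.DataFrame(
                {"gene_id": ["a", "b", "c"], "drug_name": "d", "status": "approved"}
            )
        )
        table = build_candidates(consensus, de, catalog, 2)
        assert list(table.frame.index) == ["c", "a", "b"]

    def test_annotations_pass_through_without_filtering(self):
        consensus = make_consensus({"g1": 3, "g2": 2})
        de = make_de({"g1": "consistent_up", "g2": "consistent_down"})
        catalog = catalog_from_frame(
            pd.DataFrame(
                {"gene_id": ["g1", "g2"], "drug_name": "d", "status": "approved"}
            )
        )
        table = build_candidates(consensus, de, catalog, 2)
        notes = pd.DataFrame({"gene_id": ["g1"], "disease": ["immunodeficiency"]})
        annotated = annotate_candidates(table, notes)
        assert len(annotated) == len(table)
        assert annotated.frame.loc["g1", "disease"] == "immunodeficiency"
        assert annotated.frame.loc["g2", "disease"] == ""
        with pytest.raises(ValidationError):
            annotate_candidates(table, pd.DataFrame({"gene": ["g1"]}))

    def test_candidate_recovery_on_synthetic_collection(self, small_collection):
        from radhub.diffexpr import dataset_contrasts, summarize_consistency
        from radhub.evaluate import candidate_metrics
        from radhub.hubs import consensus_hubs, select_hubs
        from radhub.network import build_network
        from radhub.preprocess import PreprocessConfig, cv_filter, quantile_normalize

        config, datasets, truth, catalog_frame = small_collection
        hubsets, contrasts = [], []
        for ds in datasets:
            normalized = ds.with_values(quantile_normalize(ds.values))
            contrasts.extend(dataset_contrasts(normalized))
            filtered, _ = cv_filter(normalized.values, normalized.gene_ids, PreprocessConfig())
            net = build_network(filtered, dataset_id=ds.dataset_id)
            hubsets.append(select_hubs(net.connectivity, 0.2, ds.dataset_id))
        consensus = consensus_hubs(hubsets, 2)
        de = summarize_consistency(contrasts, 0.25)
        table = build_candidates(consensus, de, catalog_from_frame(catalog_frame), 2)
        metrics = candidate_metrics(truth, table)
        assert metrics["n_planted"] >= 1
        assert metrics["precision"] >= 0.8
        assert metrics["recall"] >= 0.9
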