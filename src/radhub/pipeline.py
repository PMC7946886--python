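"""End-to-end orchestration of the target-discovery pipeline.

Stages: load or simulate datasets -> quantile normalization -> per-condition
differential expression -> CV filtering -> per-dataset network construction
-> hub selection -> cross-network consensus -> directional-consistency
summary -> drug-target intersection -> enrichment. All intermediates are
persisted as TSV/JSON under the output directory, and identical config +
seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import dataset_contrasts, summarize_consistency
from .enrichment import (
    build_collection,
    hypergeometric_enrichment,
    read_gmt,
    shared_enrichment_summary,
)
from .errors import ConfigurationError, RadhubError
from .evaluate import candidate_metrics, hub_recall, module_recovery_ari
from .hubs import consensus_hubs, overlap_profile, select_hubs
from .io import read_collection, write_json, write_tsv
from .network import build_network
from .preprocess import PreprocessConfig, cv_filter, quantile_normalize
from .simulate import (
    SyntheticConfig,
    SyntheticTruth,
    generate_collection,
    synthetic_annotations,
    write_collection,
)
from .targets import build_candidates

log = logging.getLogger("radhub")


def _block(cls):
    """Decorator adding strict dict round-tripping to a config block."""

    def from_dict(inner, d):
        known = {f.name for f in dataclasses.fields(inner)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown keys in {inner.__name__} block: {sorted(unknown)}"
            )
        return inner(**d)

    cls.from_dict = classmethod(from_dict)
    return cls


@_block
@dataclass(frozen=True)
class NetworkParams:
    beta_max: int = 20
    r2_cutoff: float = 0.80
    n_bins: int = 10
    min_module_size: int = 30
    cut_height: float | None = None  # None = widest-gap dendrogram cut


@_block
@dataclass(frozen=True)
class HubParams:
    top_fraction: float = 0.20
    min_networks: int = 2
    profile_fractions: tuple[float, ...] = (0.05, 0.10, 0.20)


@_block
@dataclass(frozen=True)
class DEParams:
    fold_change: float = 2.0  # linear-scale threshold; log2 applied internally
    min_sig_fraction: float = 0.25

    @property
    def fc_threshold_log2(self) -> float:
        if self.fold_change <= 1:
            raise ConfigurationError("fold_change must exceed 1")
        return math.log2(self.fold_change)


@_block
@dataclass(frozen=True)
class IntegrationParams:
    min_networks: int = 2


@_block
@dataclass(frozen=True)
class EnrichmentParams:
    fdr: float = 0.05
    min_term_size: int = 3
    annotations: str | None = None  # GMT path; synthetic annotations if absent


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved pipeline configuration.

    Exactly one of ``synthetic`` (generate the study in-process) or
    ``input_manifest`` (read a written collection) must be provided. The
    global ``seed`` drives every random choice; in synthetic mode it
    replaces the generator's own seed so one integer reproduces the run.
    """

    seed: int = 0
    synthetic: SyntheticConfig | None = None
    input_manifest: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    hubs: HubParams = field(default_factory=HubParams)
    de: DEParams = field(default_factory=DEParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_manifest is None):
            raise ConfigurationError(
                "provide exactly one of a synthetic block or an input manifest"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("network", NetworkParams),
            ("hubs", HubParams),
            ("de", DEParams),
            ("integration", IntegrationParams),
            ("enrichment", EnrichmentParams),
        ):
            if key in d and d[key] is not None:
                if sub is PreprocessConfig:
                    known_pp = {f.name for f in dataclasses.fields(PreprocessConfig)}
                    unknown_pp = set(d[key]) - known_pp
                    if unknown_pp:
                        raise ConfigurationError(
                            f"unknown keys in preprocess block: {sorted(unknown_pp)}"
                        )
                    d[key] = PreprocessConfig(**d[key])
                else:
                    d[key] = sub.from_dict(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Auditable per-stage counts of one pipeline run."""

    seed: int
    versions: dict[str, str]
    datasets: dict[str, dict]
    consensus_histogram: dict[int, int]
    n_consensus_hubs: int
    n_druggable_consensus_hubs: int
    de_summary: dict[str, int]
    n_conditions: int
    min_sig: int
    n_candidates: int
    truth_metrics: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derive_seed(root_seed: int, salt: int) -> int:
    # keep derived seeds in int32 range for portability
    return int(np.random.SeedSequence([root_seed, salt]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute all stages and persist every intermediate under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(config.to_dict(), outdir / "resolved_config.json")

    truth: SyntheticTruth | None
    stage = "load"
    try:
        if config.synthetic is not None:
            stage = "simulate"
            syn = dataclasses.replace(config.synthetic, seed=_derive_seed(config.seed, 1))
            datasets, truth, catalog_frame = generate_collection(syn)
            manifest = write_collection(
                datasets, truth, catalog_frame, outdir / "collection",
                config=syn, overwrite=True,
            )
            log.info("simulated %d datasets (manifest %s)", len(datasets), manifest)
            from .targets import catalog_from_frame

            catalog = catalog_from_frame(catalog_frame)
        else:
            datasets, truth, catalog = read_collection(config.input_manifest)
            log.info("loaded %d datasets from %s", len(datasets), config.input_manifest)

        if len(datasets) < config.hubs.min_networks:
            raise ConfigurationError(
                f"{len(datasets)} dataset(s) cannot support consensus across "
                f"min_networks={config.hubs.min_networks}"
            )

        networks = []
        hubsets = []
        contrasts_all = []
        ds_report: dict[str, dict] = {}
        enrichment_per_network: list[pd.DataFrame] = []

        annotations = None
        if config.enrichment.annotations is not None:
            annotations = read_gmt(config.enrichment.annotations)
        elif truth is not None and truth.module_of_gene:
            annotations = synthetic_annotations(truth, seed=_derive_seed(config.seed, 2))

        for ds in datasets:
            stage = f"preprocess[{ds.dataset_id}]"
            normalized = ds.with_values(quantile_normalize(ds.values))

            stage = f"differential_expression[{ds.dataset_id}]"
            contrasts = dataset_contrasts(normalized, config.de.fc_threshold_log2)
            contrasts_all.extend(contrasts)

            stage = f"cv_filter[{ds.dataset_id}]"
            filtered, kept = cv_filter(
                normalized.values, normalized.gene_ids, config.preprocess
            )

            stage = f"network[{ds.dataset_id}]"
            net = build_network(
                filtered,
                dataset_id=ds.dataset_id,
                beta_grid=range(1, config.network.beta_max + 1),
                r2_cutoff=config.network.r2_cutoff,
                n_bins=config.network.n_bins,
                min_module_size=config.network.min_module_size,
                cut_height=config.network.cut_height,
            )
            networks.append(net)
            write_tsv(
                net.soft_threshold.to_frame(),
                outdir / "network" / f"{ds.dataset_id}_soft_threshold.tsv",
                index=False,
            )
            write_tsv(
                net.connectivity.frame,
                outdir / "network" / f"{ds.dataset_id}_membership.tsv",
            )
            write_tsv(
                net.eigengene_frame().rename_axis("sample_id"),
                outdir / "network" / f"{ds.dataset_id}_eigengenes.tsv",
            )

            stage = f"hubs[{ds.dataset_id}]"
            hub = select_hubs(
                net.connectivity,
                top_fraction=config.hubs.top_fraction,
                dataset_id=ds.dataset_id,
            )
            hubsets.append(hub)
            hub_frame = (
                net.connectivity.frame.loc[sorted(hub.genes)]
                .sort_values("k_within", ascending=False)
            )
            hub_frame["rank"] = range(1, len(hub_frame) + 1)
            write_tsv(hub_frame, outdir / "hubs" / f"{ds.dataset_id}_hubs.tsv")

            if annotations is not None:
                stage = f"enrichment[{ds.dataset_id}]"
                collection = build_collection(
                    annotations, kept, min_term_size=config.enrichment.min_term_size
                )
                res = hypergeometric_enrichment(
                    hub.genes, collection, fdr_threshold=config.enrichment.fdr
                )
                enrichment_per_network.append(res)
                write_tsv(res, outdir / "enrichment" / f"{ds.dataset_id}_hub_enrichment.tsv")

            entry = {
                "n_samples": ds.n_samples,
                "n_conditions": len(ds.condition_ids),
                "n_genes_input": ds.n_genes,
                "n_genes_after_cv": len(kept),
                "chosen_beta": net.soft_threshold.chosen_beta,
                "fallback_beta": net.soft_threshold.fallback_beta,
                "signed_r2_at_beta": float(
                    net.soft_threshold.signed_r2[
                        net.soft_threshold.grid.index(net.beta)
                    ]
                ),
                "n_modules": net.n_modules,
                "n_unassigned": int((net.partition.labels == 0).sum()),
                "n_hubs": len(hub.genes),
            }
            if truth is not None:
                entry["module_recovery_ari"] = module_recovery_ari(truth, net)
                entry["hub_recall"] = hub_recall(truth, hub, net.partition.gene_ids)
            ds_report[ds.dataset_id] = entry
            log.info("%s: beta=%s modules=%d hubs=%d", ds.dataset_id, net.beta,
                     net.n_modules, len(hub.genes))

        stage = "consensus"
        consensus = consensus_hubs(hubsets, min_networks=config.hubs.min_networks)
        write_tsv(consensus.frame, outdir / "hubs" / "consensus.tsv")
        profile = overlap_profile(networks, fractions=config.hubs.profile_fractions)
        write_tsv(profile, outdir / "hubs" / "overlap_profile.tsv")

        stage = "de_consistency"
        de = summarize_consistency(contrasts_all, config.de.min_sig_fraction)
        fc_table = pd.DataFrame(
            {c.condition_id: c.frame["log2fc"] for c in contrasts_all}
        )
        calls_table = pd.DataFrame(
            {c.condition_id: c.frame["call"] for c in contrasts_all}
        )
        write_tsv(fc_table.rename_axis("gene_id"), outdir / "de" / "log2fc.tsv")
        write_tsv(calls_table.rename_axis("gene_id"), outdir / "de" / "calls.tsv")
        write_tsv(de.frame, outdir / "de" / "consistency.tsv")

        stage = "target_integration"
        candidates = build_candidates(
            consensus, de, catalog, min_networks=config.integration.min_networks
        )
        write_tsv(candidates.frame, outdir / "targets" / "candidates.tsv")

        if enrichment_per_network:
            stage = "enrichment_summary"
            shared = shared_enrichment_summary(enrichment_per_network)
            write_tsv(shared, outdir / "enrichment" / "shared_terms.tsv", index=False)

        stage = "report"
        druggable_consensus = consensus.consensus_genes & catalog.genes
        status_counts = de.frame["status"].value_counts().to_dict()
        report = RunReport(
            seed=config.seed,
            versions=_versions(),
            datasets=ds_report,
            consensus_histogram=consensus.histogram,
            n_consensus_hubs=len(consensus.consensus_genes),
            n_druggable_consensus_hubs=len(druggable_consensus),
            de_summary={k: int(v) for k, v in sorted(status_counts.items())},
            n_conditions=de.n_conditions,
            min_sig=de.min_sig,
            n_candidates=len(candidates),
            truth_metrics=candidate_metrics(truth, candidates) if truth is not None else None,
        )
        write_json(report.to_dict(), outdir / "report.json")
        return report
    except RadhubError as exc:
        raise RadhubError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _versions() -> dict[str, str]:
    import scipy

    return {
        "radhub": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
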