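"""Synthetic multi-dataset expression collections with planted ground truth.

The generator emulates the structure of a multi-cohort radiation-response
transcriptomics study: several datasets over a shared gene universe, each
with irradiated-vs-control conditions at varying dose (Gy) and time
post-exposure, module-correlated expression, planted hub genes shared across
datasets, planted differential-expression directions, and a druggable-gene
subset with a drug catalog. Every downstream stage of the pipeline can then
be scored against known truth without any external download.

Model
-----
Each module m in dataset d has an eigengene over samples,

    e_m = standardize( f_m(dose, time) + z ),   z ~ N(0, 1) per sample,

where ``f_m`` is a saturating monotone function of dose damped by an
exponential time decay (control samples have dose 0). A gene g in module m
is a noisy reflection of its module eigengene,

    x_g = mu_g + c_g * ( s_g * u_g * e_m + noise_sd * sqrt(1 - u_g^2) * eps ),

with |u_g| drawn from the hub loading interval for planted hubs and the
non-hub interval otherwise, random sign s_g, and eps ~ N(0, 1). The
``sqrt(1 - u^2)`` noise scaling is the standard factor-analysis
parameterization: at ``noise_sd = 1`` the loading u_g equals the gene's
correlation with its eigengene, which is exactly the module-membership
quantity the coexpression machinery estimates. The per-gene amplitude c_g
models biological variability on the log2 scale and is invisible to the
correlation structure; module genes draw larger amplitudes than background
genes on average, so coefficient-of-variation filtering preferentially
retains coherent biology, as it does on real data. Background genes are
pure noise around their baseline. Planted differential expression adds
``+/- de_effect_log2`` to the irradiated samples of selected conditions.

Module memberships, hub status, druggability and DE directions are shared
across datasets; loadings and signs are re-drawn per dataset. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigurationError, ValidationError

DOSE_GRID = (0.5, 1.0, 2.0, 5.0, 10.0)
TIME_GRID = (6.0, 24.0, 48.0, 168.0)

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic collection.

    Defaults mirror a five-cohort radiation study at desk scale: per-dataset
    sample counts (48, 28, 169, 70, 60) and 32 irradiated-vs-control
    conditions overall, with five planted modules of 100 genes over a
    1000-gene universe.
    """

    n_genes: int = 1000
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    n_datasets: int = 5
    samples_per_dataset: tuple[int, ...] = (48, 28, 169, 70, 60)
    conditions_per_dataset: tuple[int, ...] = (4, 2, 14, 6, 6)
    hub_fraction_per_module: float = 0.12
    loading_range_hub: tuple[float, float] = (0.80, 0.95)
    loading_range_nonhub: tuple[float, float] = (0.40, 0.60)
    noise_sd: float = 1.0
    de_effect_log2: float = 1.5
    frac_de: float = 0.08
    de_hub_enrichment: float = 6.0
    frac_druggable: float = 0.30
    min_sig_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(int(s) for s in self.module_sizes))
        object.__setattr__(
            self, "samples_per_dataset", tuple(int(s) for s in self.samples_per_dataset)
        )
        object.__setattr__(
            self, "conditions_per_dataset", tuple(int(c) for c in self.conditions_per_dataset)
        )
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_modules": self.n_modules,
            "n_datasets": self.n_datasets,
        }
        for name, v in counts.items():
            if int(v) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError(
                f"module_sizes has {len(self.module_sizes)} entries for "
                f"n_modules={self.n_modules}"
            )
        if len(self.samples_per_dataset) != self.n_datasets:
            raise ConfigurationError(
                f"samples_per_dataset has {len(self.samples_per_dataset)} entries "
                f"for n_datasets={self.n_datasets}"
            )
        if len(self.conditions_per_dataset) != self.n_datasets:
            raise ConfigurationError("conditions_per_dataset must have one entry per dataset")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if any(n < 4 for n in self.samples_per_dataset):
            raise ConfigurationError("every dataset needs at least 4 samples")
        for n, c in zip(self.samples_per_dataset, self.conditions_per_dataset):
            if c <= 0:
                raise ConfigurationError("conditions per dataset must be positive")
            if n < 4 * c:
                raise ConfigurationError(
                    f"{n} samples cannot host {c} conditions with >= 2 samples per arm"
                )
        if not 0 < self.hub_fraction_per_module < 1:
            raise ConfigurationError("hub_fraction_per_module must be in (0, 1)")
        for name, (lo, hi) in (
            ("loading_range_hub", self.loading_range_hub),
            ("loading_range_nonhub", self.loading_range_nonhub),
        ):
            if not (0 < lo <= hi < 1):
                raise ConfigurationError(f"{name} must be an interval inside (0, 1)")
        if self.loading_range_nonhub[1] >= self.loading_range_hub[0]:
            raise ConfigurationError("hub loading range must lie strictly above non-hub range")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.de_effect_log2 <= 0:
            raise ConfigurationError("de_effect_log2 must be positive")
        for name, frac in (("frac_de", self.frac_de), ("frac_druggable", self.frac_druggable)):
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.de_hub_enrichment < 1:
            raise ConfigurationError("de_hub_enrichment must be >= 1")
        if not 0 < self.min_sig_fraction <= 1:
            raise ConfigurationError("min_sig_fraction must be in (0, 1]")

    @property
    def n_conditions_total(self) -> int:
        return int(sum(self.conditions_per_dataset))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown synthetic config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_collection`.

    ``module_of_gene`` maps each gene to its module label (0 = background),
    ``de_direction`` maps planted (gene, condition) pairs to a direction,
    and ``consistent_direction`` is the per-gene majority-rule summary of
    the planted calls (``none`` for genes without a qualifying majority).
    ``planted_eigengenes`` stores the realized eigengene of each
    (dataset, module) pair for factor-recovery checks.
    """

    module_of_gene: dict[str, int]
    hub_genes: frozenset[str]
    de_direction: dict[tuple[str, str], str]
    consistent_direction: dict[str, str]
    druggable_genes: frozenset[str]
    condition_ids: tuple[str, ...]
    min_sig_fraction: float = 0.25
    planted_eigengenes: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def derive_consistency(self) -> dict[str, str]:
        """Recompute per-gene direction from ``de_direction`` by the majority rule.

        A gene is directionally consistent when it carries at least
        ``ceil(min_sig_fraction * n_conditions)`` planted calls and a strict
        majority of them share one direction; otherwise ``none``.
        """
        n_cond = len(self.condition_ids)
        min_sig = math.ceil(self.min_sig_fraction * n_cond)
        up: dict[str, int] = {}
        down: dict[str, int] = {}
        for (gene, _cond), direction in self.de_direction.items():
            if direction == "up":
                up[gene] = up.get(gene, 0) + 1
            else:
                down[gene] = down.get(gene, 0) + 1
        out: dict[str, str] = {g: "none" for g in self.module_of_gene}
        for gene in set(up) | set(down):
            n_up, n_down = up.get(gene, 0), down.get(gene, 0)
            if n_up + n_down < min_sig or n_up == n_down:
                out[gene] = "none"
            else:
                out[gene] = "up" if n_up > n_down else "down"
        return out


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _allocate_conditions(n_samples: int, n_conditions: int) -> list[tuple[int, int]]:
    """Split samples of one dataset into (n_control, n_irradiated) per condition."""
    base, extra = divmod(n_samples, n_conditions)
    sizes = [base + (1 if i < extra else 0) for i in range(n_conditions)]
    return [(s // 2, s - s // 2) for s in sizes]


def _plant_de(
    rng: np.random.Generator,
    genes: list[str],
    condition_ids: list[str],
    frac_de: float,
    min_sig_fraction: float,
    weights: np.ndarray | None = None,
) -> dict[tuple[str, str], str]:
    """Choose planted DE genes and their per-condition directions.

    Each planted gene receives calls in enough conditions to clear the
    minimum-significance gate with margin, with a small minority of calls in
    the opposite direction so the strict-majority rule is exercised. Optional
    per-gene weights bias which genes respond (radiation-responsive biology
    concentrates in the coherent modules and their hubs).
    """
    n_cond = len(condition_ids)
    min_sig = math.ceil(min_sig_fraction * n_cond)
    lo = min(n_cond, min_sig + 4)
    hi = min(n_cond, min_sig + 10)
    hi = max(hi, lo)
    n_de = int(round(frac_de * len(genes)))
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    de_genes = rng.choice(np.array(genes), size=n_de, replace=False, p=p)
    planted: dict[tuple[str, str], str] = {}
    cond_arr = np.array(condition_ids)
    for gene in de_genes:
        total = int(rng.integers(lo, hi + 1))
        major = "up" if rng.random() < 0.5 else "down"
        minor = "down" if major == "up" else "up"
        n_minor = min(int(rng.binomial(total, 0.12)), max(0, (total - 1) // 2))
        chosen = rng.choice(cond_arr, size=total, replace=False)
        for j, cond in enumerate(chosen):
            planted[(str(gene), str(cond))] = minor if j < n_minor else major
    return planted


def _dose_response(
    dose: np.ndarray, time: np.ndarray, amp: float, half_dose: float, tau: float
) -> np.ndarray:
    """Saturating monotone dose effect damped by time post-exposure."""
    return amp * (dose / (dose + half_dose)) * np.exp(-time / tau)


def generate_collection(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], SyntheticTruth, pd.DataFrame]:
    """Generate the full synthetic study: datasets, planted truth, drug catalog.

    Returns
    -------
    datasets:
        One :class:`ExpressionDataset` per configured dataset.
    truth:
        Planted module/hub/DE/druggability ground truth.
    catalog:
        Drug-target catalog DataFrame with columns
        ``gene_id, drug_name, status``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_datasets + 1)
    rng = np.random.default_rng(children[0])

    genes = _gene_ids(config.n_genes)
    module_of_gene: dict[str, int] = {g: 0 for g in genes}
    pos = 0
    module_members: list[list[str]] = []
    for m, size in enumerate(config.module_sizes, start=1):
        members = genes[pos : pos + size]
        for g in members:
            module_of_gene[g] = m
        module_members.append(members)
        pos += size

    hub_genes: set[str] = set()
    for members in module_members:
        n_hub = max(1, int(round(config.hub_fraction_per_module * len(members))))
        hub_genes.update(rng.choice(np.array(members), size=n_hub, replace=False).tolist())

    n_druggable = int(round(config.frac_druggable * config.n_genes))
    druggable = set(rng.choice(np.array(genes), size=n_druggable, replace=False).tolist())

    baseline = rng.uniform(6.0, 10.0, size=config.n_genes)
    # per-gene biological amplitude on the log2 scale, a gene property shared
    # across datasets; module genes are more variable than background on
    # average, so CV filtering enriches for coherent biology as on real data
    is_module_gene = np.array([module_of_gene[g] != 0 for g in genes])
    amplitude = np.where(
        is_module_gene,
        np.exp(rng.uniform(np.log(0.75), np.log(1.15), size=config.n_genes)),
        np.exp(rng.uniform(np.log(0.40), np.log(1.30), size=config.n_genes)),
    )

    dataset_ids = [f"DS{d + 1}" for d in range(config.n_datasets)]
    condition_ids: list[str] = []
    cond_design: dict[str, list[tuple[str, int, int, float, float]]] = {}
    for d, ds in enumerate(dataset_ids):
        design = []
        arms = _allocate_conditions(
            config.samples_per_dataset[d], config.conditions_per_dataset[d]
        )
        for j, (n_ctrl, n_irr) in enumerate(arms, start=1):
            cid = f"{ds}:c{j}"
            dose = float(rng.choice(DOSE_GRID))
            time = float(rng.choice(TIME_GRID))
            design.append((cid, n_ctrl, n_irr, dose, time))
            condition_ids.append(cid)
        cond_design[ds] = design

    # DE propensity: hubs respond most often, module genes next, background
    # least — radiation response concentrates in the coherent modules — and
    # high-amplitude genes respond more than quiet ones
    de_weights = np.array(
        [
            config.de_hub_enrichment
            if g in hub_genes
            else (1.0 if module_of_gene[g] != 0 else 0.4)
            for g in genes
        ]
    )
    de_weights = de_weights * amplitude**2
    de_direction = _plant_de(
        rng, genes, condition_ids, config.frac_de, config.min_sig_fraction, de_weights
    )

    # per-module dose-response shape, shared across datasets so the planted
    # biology is coherent; amplitude kept well below the unit eigengene noise
    mod_amp = rng.uniform(0.2, 0.4, size=config.n_modules) * rng.choice(
        [-1.0, 1.0], size=config.n_modules
    )
    mod_half = rng.uniform(1.0, 5.0, size=config.n_modules)
    mod_tau = rng.uniform(48.0, 168.0, size=config.n_modules)

    datasets: list[ExpressionDataset] = []
    planted_eigengenes: dict[tuple[str, int], np.ndarray] = {}
    for d, ds in enumerate(dataset_ids):
        rng_d = np.random.default_rng(children[d + 1])
        design = cond_design[ds]
        sample_ids: list[str] = []
        meta_rows = []
        for cid, n_ctrl, n_irr, dose, time in design:
            for arm, n_arm in (("control", n_ctrl), ("irradiated", n_irr)):
                for _ in range(n_arm):
                    sid = f"{ds}_s{len(sample_ids) + 1:03d}"
                    sample_ids.append(sid)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "condition_id": cid,
                            "arm": arm,
                            "dose_gray": dose if arm == "irradiated" else 0.0,
                            "time_hours": time,
                        }
                    )
        metadata = pd.DataFrame(meta_rows).set_index("sample_id")
        n_samp = len(sample_ids)

        dose_v = metadata["dose_gray"].to_numpy(float)
        time_v = metadata["time_hours"].to_numpy(float)
        eig = np.empty((config.n_modules, n_samp))
        for m in range(config.n_modules):
            raw = _dose_response(dose_v, time_v, mod_amp[m], mod_half[m], mod_tau[m])
            raw = raw + rng_d.standard_normal(n_samp)
            sd = raw.std()
            eig[m] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
            planted_eigengenes[(ds, m + 1)] = eig[m].copy()

        values = np.empty((config.n_genes, n_samp))
        for i, g in enumerate(genes):
            m = module_of_gene[g]
            if m == 0:
                values[i] = baseline[i] + amplitude[i] * config.noise_sd * rng_d.standard_normal(
                    n_samp
                )
            else:
                lo, hi = (
                    config.loading_range_hub
                    if g in hub_genes
                    else config.loading_range_nonhub
                )
                u = rng_d.uniform(lo, hi)
                s = -1.0 if rng_d.random() < 0.5 else 1.0
                noise = config.noise_sd * math.sqrt(1.0 - u * u)
                values[i] = baseline[i] + amplitude[i] * (
                    s * u * eig[m - 1] + noise * rng_d.standard_normal(n_samp)
                )

        gene_index = {g: i for i, g in enumerate(genes)}
        sample_index = {s: j for j, s in enumerate(sample_ids)}
        for cid, *_ in design:
            irr = metadata.index[
                (metadata["condition_id"] == cid) & (metadata["arm"] == "irradiated")
            ]
            cols = [sample_index[s] for s in irr]
            for g in genes:
                direction = de_direction.get((g, cid))
                if direction is not None:
                    shift = config.de_effect_log2 if direction == "up" else -config.de_effect_log2
                    values[gene_index[g], cols] += shift

        frame = pd.DataFrame(values, index=genes, columns=sample_ids)
        datasets.append(ExpressionDataset(ds, frame, metadata))

    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        hub_genes=frozenset(hub_genes),
        de_direction=de_direction,
        consistent_direction={},
        druggable_genes=frozenset(druggable),
        condition_ids=tuple(condition_ids),
        min_sig_fraction=config.min_sig_fraction,
        planted_eigengenes=planted_eigengenes,
    )
    truth.consistent_direction = truth.derive_consistency()

    catalog = _make_catalog(rng, sorted(druggable))
    return datasets, truth, catalog


CATALOG_STATUSES = (
    "approved",
    "launched",
    "clinical_phase",
    "preclinical",
    "investigational",
    "discovery",
)


def _make_catalog(rng: np.random.Generator, druggable: list[str]) -> pd.DataFrame:
    """One to three drugs per druggable gene, drawn from a shared compound pool."""
    pool = [f"CMPD{i:04d}" for i in range(1, max(2, len(druggable)) + 1)]
    rows = []
    for gene in druggable:
        n_drugs = 1 + int(rng.binomial(2, 0.25))
        drugs = rng.choice(np.array(pool), size=n_drugs, replace=False)
        for drug in drugs:
            rows.append(
                {
                    "gene_id": gene,
                    "drug_name": str(drug),
                    "status": str(rng.choice(np.array(CATALOG_STATUSES))),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "drug_name", "status"])


def synthetic_annotations(
    truth: SyntheticTruth,
    n_random_terms: int = 20,
    term_size_range: tuple[int, int] = (20, 80),
    seed: int = 0,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Build a GMT-style annotation collection from the planted truth.

    One term per planted module plus random gene sets, so enrichment of
    hub/candidate sets against the module terms has known signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    genes = np.array(sorted(truth.module_of_gene))
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    modules = sorted({m for m in truth.module_of_gene.values() if m > 0})
    for m in modules:
        members = frozenset(g for g, mm in truth.module_of_gene.items() if mm == m)
        terms[f"MOD{m:02d}"] = (f"planted module {m}", members)
    lo, hi = term_size_range
    for t in range(1, n_random_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=min(size, len(genes)), replace=False))
        terms[f"RAND{t:03d}"] = (f"random set {t}", members)
    return terms


def write_collection(
    datasets: list[ExpressionDataset],
    truth: SyntheticTruth,
    catalog: pd.DataFrame,
    directory: str | Path,
    config: SyntheticConfig | None = None,
    overwrite: bool = False,
) -> Path:
    """Persist a synthetic collection as TSV files plus a JSON manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set. Returns the manifest path.
    """
    if not datasets:
        raise ValidationError("empty dataset list")
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise ValidationError(
            f"directory {directory} is not empty; pass overwrite=True to replace"
        )
    directory.mkdir(parents=True, exist_ok=True)

    files: dict[str, dict[str, str]] = {"datasets": {}, "metadata": {}, "truth": {}}
    for ds in datasets:
        expr = directory / f"{ds.dataset_id}_expression.tsv"
        meta = directory / f"{ds.dataset_id}_metadata.tsv"
        ds.values.rename_axis("gene_id").to_csv(expr, sep="\t")
        ds.metadata.rename_axis("sample_id").to_csv(meta, sep="\t")
        files["datasets"][ds.dataset_id] = expr.name
        files["metadata"][ds.dataset_id] = meta.name

    gene_rows = []
    for g in sorted(truth.module_of_gene):
        gene_rows.append(
            {
                "gene_id": g,
                "module": truth.module_of_gene[g],
                "is_hub": int(g in truth.hub_genes),
                "is_druggable": int(g in truth.druggable_genes),
                "consistent_direction": truth.consistent_direction.get(g, "none"),
            }
        )
    truth_genes = directory / "truth_genes.tsv"
    pd.DataFrame(gene_rows).to_csv(truth_genes, sep="\t", index=False)
    files["truth"]["genes"] = truth_genes.name

    de_rows = [
        {"gene_id": g, "condition_id": c, "direction": direction}
        for (g, c), direction in sorted(truth.de_direction.items())
    ]
    truth_de = directory / "truth_de.tsv"
    pd.DataFrame(de_rows, columns=["gene_id", "condition_id", "direction"]).to_csv(
        truth_de, sep="\t", index=False
    )
    files["truth"]["de"] = truth_de.name

    catalog_path = directory / "drug_catalog.tsv"
    catalog.to_csv(catalog_path, sep="\t", index=False)
    files["catalog"] = catalog_path.name

    manifest = {
        "files": files,
        "condition_ids": list(truth.condition_ids),
        "min_sig_fraction": truth.min_sig_fraction,
        "config": config.to_dict() if config is not None else None,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
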