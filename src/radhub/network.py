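"""Weighted gene-coexpression network construction.

The network for one dataset is built from pairwise Pearson correlations
raised to a soft-threshold power beta (unsigned convention, a_ij = |r_ij|^beta),
where beta is the smallest integer on the grid for which the network's degree
distribution fits scale-free topology with signed R^2 at or above a cutoff
(0.80 by default). Genes are then clustered by average-linkage hierarchical
clustering on 1 - TOM, where TOM is the topological overlap measure, and each
surviving cluster is a module summarized by its eigengene (first principal
component). Hubness is quantified by intramodular connectivity: the sum of a
gene's adjacency to the other genes of its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .errors import ConfigurationError, DegenerateTopologyError, ValidationError

#: module label of genes not assigned to any module
UNASSIGNED = 0

DEFAULT_BETA_GRID = tuple(range(1, 21))


def _matrix(values) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float)
    return np.asarray(values, dtype=float)


def correlation_matrix(values) -> np.ndarray:
    """Pearson correlation between gene rows; symmetric, unit diagonal.

    Requires at least 3 samples and non-zero variance for every gene
    (CV-filter first if needed).
    """
    arr = _matrix(values)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValidationError("need a genes x samples matrix with >= 3 samples")
    sds = arr.std(axis=1)
    if np.any(sds == 0):
        ids = (
            list(values.index)
            if isinstance(values, pd.DataFrame)
            else list(range(arr.shape[0]))
        )
        bad = [ids[i] for i in np.where(sds == 0)[0][:10]]
        raise ValidationError(f"zero-variance genes (CV-filter first): {bad}")
    cor = np.corrcoef(arr)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency(correlations, beta: int) -> np.ndarray:
    """Soft-threshold adjacency a_ij = |r_ij|^beta with zero diagonal."""
    if beta < 1:
        raise ConfigurationError(f"beta must be >= 1, got {beta}")
    cor = np.asarray(correlations, dtype=float)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


@dataclass
class ScaleFreeFit:
    """One scale-free topology fit: signed R^2, slope of the log-log
    regression, mean connectivity, and the binned degree table it was fit on."""

    signed_r2: float
    slope: float
    mean_k: float
    bin_mean_k: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    bin_freq: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def scale_free_fit(adj, n_bins: int = 10) -> ScaleFreeFit:
    """Assess scale-free topology of the weighted degree distribution.

    Connectivities k_i = sum_j a_ij are split into ``n_bins`` equal-width
    bins; log10 of the empirical bin frequency is regressed on log10 of the
    bin mean connectivity over non-empty bins. The signed R^2 is
    ``-sign(slope) * R^2`` so that only decreasing degree distributions can
    score high. Degenerate distributions (all k equal, or fewer than three
    usable bins) raise :class:`DegenerateTopologyError`, which is distinct
    from a merely poor fit.
    """
    A = np.asarray(adj, dtype=float)
    if A.shape[0] < 3:
        raise ValidationError("need at least 3 genes")
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    k = A.sum(axis=1)
    if np.ptp(k) == 0:
        raise DegenerateTopologyError("all genes have identical connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    nonempty = counts > 0
    mean_k_bin = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / k.size
    usable = mean_k_bin > 0
    mean_k_bin, freq = mean_k_bin[usable], freq[usable]
    if mean_k_bin.size < 3:
        raise DegenerateTopologyError(
            f"only {mean_k_bin.size} usable connectivity bins; fit undefined"
        )
    fit = linregress(np.log10(mean_k_bin), np.log10(freq))
    signed_r2 = -np.sign(fit.slope) * fit.rvalue**2 if fit.slope != 0 else 0.0
    return ScaleFreeFit(
        signed_r2=float(signed_r2),
        slope=float(fit.slope),
        mean_k=float(k.mean()),
        bin_mean_k=mean_k_bin,
        bin_freq=freq,
    )


@dataclass
class SoftThresholdResult:
    """Scale-free fits across the beta grid and the selected power.

    ``chosen_beta`` is the smallest grid beta whose signed R^2 reaches
    ``r2_cutoff``; when none qualifies it is None and ``fallback_beta``
    records the argmax-signed-R^2 power instead.
    """

    grid: tuple[int, ...]
    signed_r2: np.ndarray
    mean_connectivity: np.ndarray
    slope: np.ndarray
    r2_cutoff: float
    chosen_beta: int | None
    fallback_beta: int

    @property
    def effective_beta(self) -> int:
        return self.chosen_beta if self.chosen_beta is not None else self.fallback_beta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": list(self.grid),
                "signed_r2": self.signed_r2,
                "mean_connectivity": self.mean_connectivity,
                "slope": self.slope,
            }
        )


def pick_soft_threshold(
    values,
    beta_grid=DEFAULT_BETA_GRID,
    r2_cutoff: float = 0.80,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Select the soft-threshold power by the scale-free fit criterion."""
    grid = tuple(int(b) for b in beta_grid)
    if not grid:
        raise ConfigurationError("beta grid is empty")
    cor = correlation_matrix(values)
    r2 = np.full(len(grid), np.nan)
    mean_k = np.full(len(grid), np.nan)
    slope = np.full(len(grid), np.nan)
    for i, beta in enumerate(grid):
        adj = adjacency(cor, beta)
        try:
            fit = scale_free_fit(adj, n_bins=n_bins)
        except DegenerateTopologyError:
            mean_k[i] = adj.sum(axis=1).mean()
            continue
        r2[i], mean_k[i], slope[i] = fit.signed_r2, fit.mean_k, fit.slope
    qualifying = [b for b, v in zip(grid, r2) if np.isfinite(v) and v >= r2_cutoff]
    chosen = min(qualifying) if qualifying else None
    finite = np.where(np.isfinite(r2))[0]
    fallback = grid[int(finite[np.argmax(r2[finite])])] if finite.size else grid[0]
    return SoftThresholdResult(
        grid=grid,
        signed_r2=r2,
        mean_connectivity=mean_k,
        slope=slope,
        r2_cutoff=r2_cutoff,
        chosen_beta=chosen,
        fallback_beta=fallback,
    )


def tom_similarity(adj) -> np.ndarray:
    """Topological overlap measure.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    L_ij = sum_u a_iu a_uj and k_i the weighted degree; TOM_ii = 1. Shared
    neighbours make TOM a more robust similarity than raw adjacency.
    """
    A = np.asarray(adj, dtype=float)
    if A.min() < 0 or A.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    L = A @ A
    k = A.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / (min_k + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


@dataclass
class ModulePartition:
    """Gene -> module assignment (labels 1..M by decreasing size; 0 = unassigned).

    ``cut_height`` records the dissimilarity at which the dendrogram was
    actually cut (whether fixed or gap-derived).
    """

    gene_ids: list[str]
    labels: np.ndarray
    min_module_size: int
    cut_height: float

    @property
    def module_labels(self) -> list[int]:
        return sorted({int(l) for l in self.labels if l != UNASSIGNED})

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="module")


def detect_modules(
    tom,
    min_module_size: int = 30,
    cut_height: float | None = None,
    gene_ids=None,
) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a static dendrogram cut.

    By default the cut height is chosen data-driven: the midpoints between
    consecutive distinct merge heights are candidate cuts, and the cut
    retained is the one whose flat clustering maximizes weighted modularity
    on the TOM graph. Modularity is zero for the degenerate one-cluster
    partition and penalizes both fragmented modules and merged unrelated
    modules, so the choice adapts to the dissimilarity scale — which varies
    strongly with the soft-threshold power, leaving no fixed height that
    works across the beta grid. Pass an explicit ``cut_height`` in (0, 1] to
    cut at an absolute dissimilarity instead.

    Clusters below ``min_module_size`` are marked unassigned; survivors are
    relabeled 1..M by decreasing size, ties broken by the smallest member
    gene id.
    """
    if min_module_size < 2:
        raise ConfigurationError("min_module_size must be >= 2")
    if cut_height is not None and not 0 < cut_height <= 1:
        raise ConfigurationError("cut_height must be in (0, 1]")
    T = np.asarray(tom, dtype=float)
    n = T.shape[0]
    if gene_ids is None:
        width = max(4, len(str(n)))
        gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    gene_ids = [str(g) for g in gene_ids]
    dissim = 1.0 - T
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method="average")
    if cut_height is not None:
        t = cut_height
        raw = fcluster(Z, t=t, criterion="distance")
    else:
        t, raw = _auto_partition(Z, T, dissim, min_module_size)

    labels = np.full(n, UNASSIGNED, dtype=int)
    clusters: list[tuple[int, str, np.ndarray]] = []
    for c in np.unique(raw):
        idx = np.where(raw == c)[0]
        if idx.size >= min_module_size:
            clusters.append((idx.size, min(gene_ids[i] for i in idx), idx))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, _, idx) in enumerate(clusters, start=1):
        labels[idx] = new_label
    return ModulePartition(gene_ids, labels, min_module_size, float(t))


def _cluster_q(sim: np.ndarray, idx: np.ndarray, strength: np.ndarray, total: float) -> float:
    """One cluster's contribution to Newman weighted modularity."""
    within = sim[np.ix_(idx, idx)].sum()
    deg = strength[idx].sum()
    return within / total - (deg / total) ** 2


def _modularity_cut(
    Z: np.ndarray,
    sim: np.ndarray,
    strength: np.ndarray,
    total: float,
    idx: np.ndarray,
):
    """Modularity-optimal flat cut of a (sub-)dendrogram over genes ``idx``.

    Candidate cuts are midpoints between consecutive distinct merge heights
    (the upper 100 suffice: module roots and between-module joins live
    there); modularity terms are scored against the global graph totals.
    Returns (height, labels); deterministic, ties toward lower cuts.
    """
    heights = np.unique(Z[:, 2])
    if heights.size < 2:
        t = float(heights[-1]) if heights.size else 1.0
        return t, fcluster(Z, t=t, criterion="distance")
    candidates = (heights[:-1] + heights[1:]) / 2.0
    if candidates.size > 100:
        candidates = candidates[-100:]
    best_q = -np.inf
    best_t = float(candidates[-1])
    best_labels = None
    for t in candidates:
        labels = fcluster(Z, t=t, criterion="distance")
        q = sum(
            _cluster_q(sim, idx[labels == c], strength, total)
            for c in np.unique(labels)
        )
        if q > best_q + 1e-12:
            best_q, best_t, best_labels = q, float(t), labels
    if best_labels is None:
        best_labels = fcluster(Z, t=best_t, criterion="distance")
    return best_t, best_labels


def _auto_partition(Z: np.ndarray, tom: np.ndarray, dissim: np.ndarray, min_module_size: int):
    """Modularity-guided flat clustering with recursive cluster splitting.

    A single global cut height maximizing weighted modularity is found
    first. Each resulting cluster is then re-clustered on its own
    sub-dendrogram and split whenever that increases global modularity —
    the case a single height cannot handle is a fused pair of modules whose
    internal join sits below other modules' roots.
    """
    sim = tom - np.diag(np.diag(tom))
    strength = sim.sum(axis=1)
    total = strength.sum()
    n = sim.shape[0]
    if total <= 0:
        # empty network: every gene its own cluster
        return 1.0, np.arange(1, n + 1)
    all_idx = np.arange(n)
    t, labels = _modularity_cut(Z, sim, strength, total, all_idx)

    out = np.zeros(n, dtype=int)
    next_label = 1
    stack = [all_idx[labels == c] for c in np.unique(labels)]
    while stack:
        idx = stack.pop()
        if idx.size < 2 * min_module_size:
            out[idx] = next_label
            next_label += 1
            continue
        sub_z = linkage(
            squareform(dissim[np.ix_(idx, idx)], checks=False), method="average"
        )
        _, sub_labels = _modularity_cut(sub_z, sim, strength, total, idx)
        parts = [idx[sub_labels == c] for c in np.unique(sub_labels)]
        if len(parts) < 2:
            out[idx] = next_label
            next_label += 1
            continue
        q_whole = _cluster_q(sim, idx, strength, total)
        q_split = sum(_cluster_q(sim, p, strength, total) for p in parts)
        if q_split > q_whole + 1e-12:
            stack.extend(parts)
        else:
            out[idx] = next_label
            next_label += 1
    return t, out


def module_eigengene(values, partition: ModulePartition, module_label: int) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Scaled to unit variance, with the sign chosen so the eigengene correlates
    positively with the module's mean standardized profile.
    """
    arr = _matrix(values)
    idx = np.where(partition.labels == module_label)[0]
    if idx.size < 2:
        raise ValidationError(
            f"module {module_label} has {idx.size} genes; eigengene needs >= 2"
        )
    sub = arr[idx]
    sds = sub.std(axis=1, ddof=1)
    if np.any(sds == 0):
        sds = np.where(sds == 0, 1.0, sds)
    std = (sub - sub.mean(axis=1, keepdims=True)) / sds[:, None]
    _, _, vt = np.linalg.svd(std, full_matrices=False)
    eig = vt[0]
    mean_profile = std.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    sd = eig.std(ddof=1)
    return eig / sd if sd > 0 else eig


@dataclass
class ConnectivityTable:
    """Per-gene total and intramodular connectivity plus module label."""

    frame: pd.DataFrame  # columns: module, k_total, k_within

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    def __len__(self) -> int:
        return len(self.frame)


def intramodular_connectivity(adj, partition: ModulePartition) -> ConnectivityTable:
    """Connectivity sums: k_total over all genes, k_within over same-module genes.

    Unassigned genes have k_within = 0 by convention.
    """
    A = np.asarray(adj, dtype=float)
    if A.shape[0] != len(partition.gene_ids):
        raise ValidationError(
            f"adjacency is over {A.shape[0]} genes, partition over {len(partition.gene_ids)}"
        )
    k_total = A.sum(axis=1)
    k_within = np.zeros_like(k_total)
    for label in partition.module_labels:
        mask = partition.labels == label
        k_within[mask] = A[np.ix_(mask, mask)].sum(axis=1)
    frame = pd.DataFrame(
        {"module": partition.labels, "k_total": k_total, "k_within": k_within},
        index=pd.Index(partition.gene_ids, name="gene_id"),
    )
    return ConnectivityTable(frame)


@dataclass
class NetworkModel:
    """Everything the downstream stages need about one dataset's network."""

    dataset_id: str
    soft_threshold: SoftThresholdResult
    partition: ModulePartition
    connectivity: ConnectivityTable
    eigengenes: dict[int, np.ndarray]
    sample_ids: list[str]

    @property
    def beta(self) -> int:
        return self.soft_threshold.effective_beta

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules

    def eigengene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"ME{label}": vec for label, vec in sorted(self.eigengenes.items())},
            index=self.sample_ids,
        )


def build_network(
    values: pd.DataFrame,
    dataset_id: str = "network",
    beta_grid=DEFAULT_BETA_GRID,
    r2_cutoff: float = 0.80,
    n_bins: int = 10,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> NetworkModel:
    """Full single-dataset network construction.

    Correlation -> soft-threshold selection -> adjacency -> TOM ->
    average-linkage module detection -> eigengenes -> connectivity.
    """
    soft = pick_soft_threshold(values, beta_grid=beta_grid, r2_cutoff=r2_cutoff, n_bins=n_bins)
    cor = correlation_matrix(values)
    adj = adjacency(cor, soft.effective_beta)
    tom = tom_similarity(adj)
    partition = detect_modules(
        tom,
        min_module_size=min_module_size,
        cut_height=cut_height,
        gene_ids=list(values.index),
    )
    connectivity = intramodular_connectivity(adj, partition)
    eigengenes = {
        label: module_eigengene(values, partition, label)
        for label in partition.module_labels
    }
    return NetworkModel(
        dataset_id=dataset_id,
        soft_threshold=soft,
        partition=partition,
        connectivity=connectivity,
        eigengenes=eigengenes,
        sample_ids=[str(s) for s in values.columns],
    )
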