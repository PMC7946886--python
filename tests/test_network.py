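"""Coexpression network construction: correlation, soft threshold, TOM, modules."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from radhub.errors import ConfigurationError, DegenerateTopologyError, ValidationError
from radhub.evaluate import adjusted_rand_index
from radhub.network import (
    UNASSIGNED,
    adjacency,
    correlation_matrix,
    detect_modules,
    intramodular_connectivity,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)


def tom_bruteforce(adj):
    """O(n^3) reference implementation of the topological overlap measure."""
    n = adj.shape[0]
    k = adj.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n) if u != i and u != j)
            # the u == i and u == j terms vanish because the diagonal is zero
            out[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return out


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestCorrelation:
    def test_duplicated_and_negated_genes(self, rng):
        base = rng.normal(size=10)
        x = np.vstack([base, base, -base])
        cor = correlation_matrix(x)
        assert cor[0, 1] == pytest.approx(1.0)
        assert cor[0, 2] == pytest.approx(-1.0)

    def test_hand_checked_pair(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]])
        cor = correlation_matrix(x)
        assert cor[0, 1] == pytest.approx(0.9827, abs=5e-5)
        # agreement with scipy's pearsonr as an independent check
        assert cor[0, 1] == pytest.approx(pearsonr(x[0], x[1]).statistic, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, rng):
        cor = correlation_matrix(rng.normal(size=(15, 20)))
        np.testing.assert_allclose(cor, cor.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cor), 1.0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            correlation_matrix(rng.normal(size=(5, 2)))

    def test_zero_variance_gene_named(self, rng):
        import pandas as pd

        frame = pd.DataFrame(rng.normal(size=(3, 6)), index=["a", "flat", "c"])
        frame.loc["flat"] = 2.0
        with pytest.raises(ValidationError, match="flat"):
            correlation_matrix(frame)


class TestAdjacency:
    def test_analytic_values(self):
        cor = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert adjacency(cor, 2)[0, 1] == pytest.approx(0.25)
        cor = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert adjacency(cor, 6)[0, 1] == pytest.approx(0.531441)

    def test_beta_one_is_absolute_correlation(self, rng):
        cor = correlation_matrix(rng.normal(size=(8, 30)))
        a = adjacency(cor, 1)
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(a[off], np.abs(cor)[off])
        assert np.all(np.diag(a) == 0)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            adjacency(np.eye(3), 0)


class TestScaleFreeFit:
    def test_planted_power_law_scores_high(self):
        # rank-one adjacency with connectivity counts following an exact
        # discretized power law: frequency(k) ~ k^-2 across ten k levels
        levels = np.arange(1, 11) * 0.1
        counts = np.round(120 * np.arange(1, 11) ** -2.0).astype(int)
        k_target = np.repeat(levels, counts)
        s = k_target.sum()
        a = np.outer(k_target, k_target) / s
        np.fill_diagonal(a, 0.0)
        fit = scale_free_fit(a)
        assert fit.signed_r2 >= 0.95
        # reconstruct the regression from the binned table with an independent fit
        slope, intercept = np.polyfit(np.log10(fit.bin_mean_k), np.log10(fit.bin_freq), 1)
        r = np.corrcoef(np.log10(fit.bin_mean_k), np.log10(fit.bin_freq))[0, 1]
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.signed_r2 == pytest.approx(-np.sign(slope) * r**2, abs=1e-10)

    def test_degenerate_degrees_signalled(self):
        a = np.full((10, 10), 0.5)
        np.fill_diagonal(a, 0.0)
        with pytest.raises(DegenerateTopologyError):
            scale_free_fit(a)

    def test_increasing_frequency_gives_nonpositive_score(self):
        # many high-connectivity genes, few low ones -> positive log-log slope
        levels = np.arange(1, 11) * 0.1
        counts = np.round(1.2 * np.arange(1, 11) ** 2.0).astype(int)
        k_target = np.repeat(levels, counts)
        a = np.outer(k_target, k_target) / k_target.sum()
        np.fill_diagonal(a, 0.0)
        fit = scale_free_fit(a)
        assert fit.signed_r2 <= 0


class TestSoftThreshold:
    def test_selection_rule_and_fallback(self, small_collection):
        _, datasets, _, _ = small_collection
        values = datasets[0].values
        res = pick_soft_threshold(values)
        qualifying = [
            b for b, r in zip(res.grid, res.signed_r2) if np.isfinite(r) and r >= 0.80
        ]
        assert res.chosen_beta == min(qualifying)
        # unreachable cutoff: no beta qualifies, fallback records the argmax
        res_hi = pick_soft_threshold(values, r2_cutoff=0.999)
        assert res_hi.chosen_beta is None
        finite = np.isfinite(res_hi.signed_r2)
        best = np.array(res_hi.grid)[finite][np.argmax(res_hi.signed_r2[finite])]
        assert res_hi.fallback_beta == best

    def test_mean_connectivity_strictly_decreases(self, rng):
        res = pick_soft_threshold(rng.normal(size=(40, 25)))
        assert np.all(np.diff(res.mean_connectivity) < 0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            pick_soft_threshold(rng.normal(size=(10, 10)), beta_grid=[])


class TestTom:
    def test_three_gene_worked_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        # k = 1 each, shared neighbour weight 0.25 -> (0.25 + 0.5) / (1 + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_empty_network(self):
        tom = tom_similarity(np.zeros((4, 4)))
        off = ~np.eye(4, dtype=bool)
        assert np.all(tom[off] == 0)

    def test_matches_bruteforce_oracle(self, rng):
        a = random_adjacency(rng, 25)
        np.testing.assert_allclose(tom_similarity(a), tom_bruteforce(a), atol=1e-10)

    def test_range_and_symmetry(self, rng):
        tom = tom_similarity(random_adjacency(rng, 30))
        assert tom.min() >= 0 and tom.max() <= 1
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_entries_outside_unit_interval_rejected(self):
        a = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValidationError):
            tom_similarity(a)


def block_tom(sizes, within=0.6, between=0.0):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    return tom


class TestDetectModules:
    def test_separable_blocks_recovered(self):
        tom = block_tom([40, 35])
        part = detect_modules(tom, min_module_size=10)
        planted = [1] * 40 + [2] * 35
        assert adjusted_rand_index(planted, part.labels) == pytest.approx(1.0)
        # labels ordered by decreasing size
        assert list(part.labels[:40]) == [1] * 40

    def test_no_structure_leaves_everything_unassigned(self):
        tom = np.zeros((50, 50))
        np.fill_diagonal(tom, 1.0)
        part = detect_modules(tom, min_module_size=30)
        assert np.all(part.labels == UNASSIGNED)

    def test_small_clusters_dropped(self):
        tom = block_tom([40, 5])
        part = detect_modules(tom, min_module_size=10)
        assert part.n_modules == 1
        assert np.all(part.labels[-5:] == UNASSIGNED)

    def test_absolute_cut_height_still_supported(self):
        tom = block_tom([40, 35], within=0.6)
        part = detect_modules(tom, min_module_size=10, cut_height=0.8)
        assert part.n_modules == 2
        assert part.cut_height == pytest.approx(0.8)

    def test_gene_order_invariance(self, rng):
        tom = block_tom([30, 25, 20], within=0.5)
        noise = rng.uniform(0, 0.05, size=tom.shape)
        tom = np.clip(tom + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(tom, 1.0)
        ids = [f"g{i:03d}" for i in range(tom.shape[0])]
        part = detect_modules(tom, min_module_size=10, gene_ids=ids)
        perm = rng.permutation(tom.shape[0])
        part_perm = detect_modules(
            tom[np.ix_(perm, perm)], min_module_size=10, gene_ids=[ids[i] for i in perm]
        )
        a = part.to_series().sort_index()
        b = part_perm.to_series().sort_index()
        assert adjusted_rand_index(a.to_numpy(), b.to_numpy()) == pytest.approx(1.0)

    def test_min_module_size_guard(self):
        with pytest.raises(ConfigurationError):
            detect_modules(np.eye(5), min_module_size=1)


class TestModuleEigengene:
    def _partition(self, n, label=1):
        from radhub.network import ModulePartition

        return ModulePartition(
            [f"g{i}" for i in range(n)], np.full(n, label), 2, 0.99
        )

    def test_identical_genes_recover_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = np.tile(profile, (6, 1))
        eig = module_eigengene(x, self._partition(6), 1)
        std = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.corrcoef(eig, std)[0, 1] == pytest.approx(1.0)
        assert eig.std(ddof=1) == pytest.approx(1.0)

    def test_noise_free_factor_recovered(self, rng):
        factor = rng.normal(size=40)
        loadings = rng.uniform(0.5, 1.0, size=10) * rng.choice([-1, 1], size=10)
        x = np.outer(loadings, factor)
        eig = module_eigengene(x, self._partition(10), 1)
        assert abs(np.corrcoef(eig, factor)[0, 1]) == pytest.approx(1.0)

    def test_noisy_planted_module_tracks_stored_factor(self):
        from radhub.simulate import SyntheticConfig, generate_collection

        config = SyntheticConfig(
            n_genes=100, n_modules=1, module_sizes=(100,), n_datasets=1,
            samples_per_dataset=(60,), conditions_per_dataset=(6,),
            loading_range_nonhub=(0.4, 0.6), noise_sd=1.0, frac_de=0.0, seed=1,
        )
        datasets, truth, _ = generate_collection(config)
        x = datasets[0].values.to_numpy()
        eig = module_eigengene(x, self._partition(100), 1)
        planted = truth.planted_eigengenes[("DS1", 1)]
        assert abs(np.corrcoef(eig, planted)[0, 1]) >= 0.9

    def test_repeated_calls_identical(self, rng):
        x = rng.normal(size=(12, 30))
        part = self._partition(12)
        np.testing.assert_array_equal(
            module_eigengene(x, part, 1), module_eigengene(x, part, 1)
        )

    def test_tiny_module_rejected(self, rng):
        from radhub.network import ModulePartition

        part = ModulePartition(["a", "b"], np.array([1, 2]), 2, 0.99)
        with pytest.raises(ValidationError):
            module_eigengene(rng.normal(size=(2, 10)), part, 1)


class TestIntramodularConnectivity:
    def test_uniform_triangle(self):
        from radhub.network import ModulePartition

        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        part = ModulePartition(["a", "b", "c"], np.array([1, 1, 1]), 2, 0.99)
        table = intramodular_connectivity(a, part)
        np.testing.assert_allclose(table.frame["k_within"], 1.0)

    def test_single_module_makes_k_within_equal_k_total(self, rng):
        from radhub.network import ModulePartition

        a = random_adjacency(rng, 20)
        part = ModulePartition([f"g{i}" for i in range(20)], np.ones(20, int), 2, 0.99)
        table = intramodular_connectivity(a, part)
        np.testing.assert_allclose(table.frame["k_within"], table.frame["k_total"])

    def test_matches_bruteforce_double_loop(self, rng):
        from radhub.network import ModulePartition

        n = 30
        a = random_adjacency(rng, n)
        labels = rng.integers(0, 3, size=n)
        part = ModulePartition([f"g{i}" for i in range(n)], labels, 2, 0.99)
        table = intramodular_connectivity(a, part)
        for i in range(n):
            k_tot = sum(a[i, j] for j in range(n) if j != i)
            k_in = (
                sum(a[i, j] for j in range(n) if j != i and labels[j] == labels[i])
                if labels[i] != UNASSIGNED
                else 0.0
            )
            assert table.frame["k_total"].iloc[i] == pytest.approx(k_tot, abs=1e-12)
            assert table.frame["k_within"].iloc[i] == pytest.approx(k_in, abs=1e-12)

    def test_unassigned_has_zero_k_within(self, rng):
        from radhub.network import ModulePartition

        a = random_adjacency(rng, 10)
        labels = np.array([0] * 5 + [1] * 5)
        part = ModulePartition([f"g{i}" for i in range(10)], labels, 2, 0.99)
        table = intramodular_connectivity(a, part)
        assert np.all(table.frame["k_within"].iloc[:5] == 0)

    def test_gene_set_mismatch_rejected(self, rng):
        from radhub.network import ModulePartition

        part = ModulePartition(["a", "b"], np.array([1, 1]), 2, 0.99)
        with pytest.raises(ValidationError):
            intramodular_connectivity(random_adjacency(rng, 3), part)
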