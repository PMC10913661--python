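"""Module extraction: hybrid tree cut recovery, invariance, consensus."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from methagene.clustering import cluster_modules, module_profiles

from conftest import matrix_from_density


def _archetype_rows(archetypes, n_per, sd, seed, n_bins=50):
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for k, base in enumerate(archetypes):
        rows.append(base + rng.normal(0, sd, (n_per, n_bins)))
        truth.extend([k] * n_per)
    return np.clip(np.vstack(rows), 0, 1), np.array(truth)


def _three_archetypes(n_bins=50):
    x = np.linspace(0, 1, n_bins)
    flat = np.full(n_bins, 0.8)
    dip = 0.8 - 0.6 * np.exp(-((x - 0.05) ** 2) / 0.02)
    peak = 0.1 + 0.6 * np.exp(-((x - 0.5) ** 2) / 0.02)
    return [flat, dip, peak]


class TestClusterModules:
    def test_two_planted_archetypes(self):
        flat, dip, _ = _three_archetypes()
        rows, truth = _archetype_rows([flat, dip], 100, sd=0.02, seed=0)
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=20)
        assert a.n_modules == 2
        assert adjusted_rand_score(truth, a.labels) >= 0.9

    def test_identical_rows_single_module(self):
        rows = np.tile(np.linspace(0, 1, 30), (60, 1))
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=10)
        assert a.n_modules == 1
        assert (a.labels == 1).all()

    def test_three_archetypes_match_nearest_archetype_oracle(self):
        archetypes = _three_archetypes()
        rows, truth = _archetype_rows(archetypes, 60, sd=0.03, seed=1)
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=20)
        assert a.n_modules == 3
        # independent oracle: nearest archetype by euclidean distance
        dists = np.stack([np.linalg.norm(rows - arch, axis=1) for arch in archetypes])
        oracle = np.argmin(dists, axis=0)
        assert adjusted_rand_score(oracle, a.labels) >= 0.99

    def test_permutation_invariance_of_partition(self):
        flat, dip, _ = _three_archetypes()
        rows, truth = _archetype_rows([flat, dip], 50, sd=0.02, seed=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(rows))
        a1 = cluster_modules(matrix_from_density(rows), min_module_size=15)
        a2 = cluster_modules(matrix_from_density(rows[perm]), min_module_size=15)
        assert adjusted_rand_score(a1.labels[perm], a2.labels) == 1.0

    def test_partition_completeness(self):
        flat, dip, peak = _three_archetypes()
        rows, _ = _archetype_rows([flat, dip, peak], 40, sd=0.05, seed=4)
        rows[::7, ::3] = np.nan  # some missing bins
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=15)
        assert len(a.labels) == len(rows)
        assert (a.labels >= 0).all()
        sizes = a.module_sizes
        assert (sizes >= 15).all()
        assert sizes.sum() + (a.labels == 0).sum() == len(rows)

    def test_mostly_missing_rows_go_to_module_zero(self):
        flat, dip, _ = _three_archetypes()
        rows, _ = _archetype_rows([flat, dip], 40, sd=0.02, seed=5)
        rows[0, : rows.shape[1] * 3 // 4] = np.nan  # 75% missing
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=15)
        assert a.labels[0] == 0

    def test_too_few_rows_is_error(self):
        rows = np.tile(np.linspace(0, 1, 20), (10, 1))
        with pytest.raises(ValueError, match="min_module_size"):
            cluster_modules(matrix_from_density(rows), min_module_size=20)

    def test_modules_numbered_by_decreasing_size(self):
        flat, dip, _ = _three_archetypes()
        rows, truth = _archetype_rows([flat, dip], 30, sd=0.02, seed=6)
        rows = np.vstack([rows, dip + np.random.default_rng(7).normal(0, 0.02, (60, 50))])
        a = cluster_modules(matrix_from_density(np.clip(rows, 0, 1)), min_module_size=20)
        sizes = a.module_sizes
        assert list(sizes.values) == sorted(sizes.values, reverse=True)


class TestModuleProfiles:
    def test_identical_member_rows_consensus(self):
        row = np.linspace(0.1, 0.9, 25)
        rows = np.tile(row, (50, 1))
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=10)
        prof = module_profiles(mat, a)
        assert np.allclose(prof.filter(like="bin_").iloc[0], row)

    def test_two_member_mean(self):
        from methagene.clustering import ModuleAssignment
        rows = np.array([[0.2, 0.4], [0.6, 0.8]])
        mat = matrix_from_density(rows)
        a = ModuleAssignment(region_ids=mat.region_ids, labels=np.array([1, 1]),
                             distance="euclidean", linkage="average",
                             min_module_size=1, deep_split=2)
        prof = module_profiles(mat, a)
        assert np.allclose(prof.filter(like="bin_").iloc[0], [0.4, 0.6])

    def test_consensus_matches_column_mean_oracle(self):
        flat, dip, _ = _three_archetypes()
        rows, truth = _archetype_rows([flat, dip], 50, sd=0.02, seed=8)
        mat = matrix_from_density(rows)
        a = cluster_modules(mat, min_module_size=20)
        prof = module_profiles(mat, a).set_index("module_id")
        for module_id in range(1, a.n_modules + 1):
            members = rows[a.labels == module_id]
            assert np.allclose(
                prof.loc[module_id].filter(like="bin_").to_numpy(float),
                members.mean(axis=0),
            )
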