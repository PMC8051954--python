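import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from adtopt.data_model import CountMatrix
from adtopt.equalize import (
    equalize_celltypes,
    match_in_embedding,
    sequencing_saturation,
    thin_counts,
    thin_counts_read_level,
)


def labels(spec: dict) -> pd.Series:
    values = [t for t, n in spec.items() for _ in range(n)]
    return pd.Series(values, index=[f"{t}{i}" for i, t in enumerate(values)])


class TestEqualizeCelltypes:
    def test_min_rule_across_conditions(self):
        result = equalize_celltypes(
            {"c1": labels({"T": 100, "B": 50}), "c2": labels({"T": 80, "B": 60})}, seed=0
        )
        assert result.per_type["c1"].to_dict() == {"T": 80, "B": 50}
        assert len(result.kept["c1"]) == len(result.kept["c2"]) == 130

    def test_identical_conditions_keep_everything(self):
        same = labels({"T": 10, "B": 5})
        result = equalize_celltypes({"c1": same, "c2": same.copy()}, seed=1)
        assert sorted(result.kept["c1"]) == sorted(same.index)
        assert sorted(result.kept["c2"]) == sorted(same.index)

    def test_type_absent_from_one_condition_is_dropped(self, caplog):
        result = equalize_celltypes(
            {"c1": labels({"T": 10, "NK": 4}), "c2": labels({"T": 8})}, seed=0
        )
        assert "NK" not in result.per_type.index
        assert any("NK" in r.message for r in caplog.records)

    def test_no_shared_types_errors(self):
        with pytest.raises(ValueError, match="share no cell types"):
            equalize_celltypes({"c1": labels({"T": 5}), "c2": labels({"B": 5})})

    def test_composition_identical_across_conditions(self):
        result = equalize_celltypes(
            {"c1": labels({"T": 30, "B": 20, "NK": 7}), "c2": labels({"T": 21, "B": 29, "NK": 9})},
            seed=3,
        )
        assert (result.per_type["c1"] == result.per_type["c2"]).all()

    def test_deterministic_given_seed(self):
        spec = {"c1": labels({"T": 50, "B": 30}), "c2": labels({"T": 40, "B": 35})}
        first = equalize_celltypes(spec, seed=9)
        second = equalize_celltypes(spec, seed=9)
        assert first.kept == second.kept


class TestMatchInEmbedding:
    def _inputs(self, n_a=3, n_b=10, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        coords_a = rng.normal(0, 1, size=(n_a, 2))
        coords_b = coords_a.copy() if identical else rng.normal(0, 1, size=(n_b, 2))
        index = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(len(coords_b))]
        coords = pd.DataFrame(np.vstack([coords_a, coords_b]), index=index, columns=["x", "y"])
        clusters = pd.Series("c0", index=index)
        samples = pd.Series(["A"] * n_a + ["B"] * len(coords_b), index=index)
        return coords, clusters, samples

    def test_identical_coordinates_match_zero_distance(self):
        coords, clusters, samples = self._inputs(n_a=4, n_b=4, identical=True)
        result = match_in_embedding(coords, clusters, samples, seed=0)
        for a, b in zip(sorted(result.kept["A"]), sorted(result.kept["B"])):
            assert np.allclose(coords.loc[a], coords.loc[b])

    def test_smaller_sample_size_sets_pair_count(self):
        coords, clusters, samples = self._inputs(n_a=3, n_b=10)
        result = match_in_embedding(coords, clusters, samples, seed=0)
        assert len(result.kept["A"]) == len(result.kept["B"]) == 3

    def test_greedy_total_distance_close_to_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        n_a, n_b = 20, 50
        coords_a = rng.normal(0, 1, size=(n_a, 2))
        coords_b = rng.normal(0, 1, size=(n_b, 2))
        index = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        coords = pd.DataFrame(np.vstack([coords_a, coords_b]), index=index, columns=["x", "y"])
        clusters = pd.Series("c0", index=index)
        samples = pd.Series(["A"] * n_a + ["B"] * n_b, index=index)
        result = match_in_embedding(coords, clusters, samples, seed=7)

        # brute-force greedy oracle over the same seed-shuffled order
        order = [f"a{i}" for i in range(n_a)]
        np.random.default_rng(7).shuffle(order)
        used: set[str] = set()
        oracle_total = 0.0
        for a in order:
            best, best_d = None, np.inf
            for j in range(n_b):
                b = f"b{j}"
                if b in used:
                    continue
                d = float(np.linalg.norm(coords.loc[a] - coords.loc[b]))
                if d < best_d:
                    best, best_d = b, d
            used.add(best)
            oracle_total += best_d

        pairs_b = {b for b in result.kept["B"]}
        matched_total = 0.0
        # recompute the implementation's total matched distance pair by pair
        impl_used: set[str] = set()
        for a in order:
            dists = {
                b: float(np.linalg.norm(coords.loc[a] - coords.loc[b]))
                for b in pairs_b - impl_used
            }
            b = min(dists, key=dists.get)
            impl_used.add(b)
            matched_total += dists[b]
        assert matched_total <= oracle_total * 1.10

    def test_three_samples_rejected(self):
        coords, clusters, samples = self._inputs()
        samples.iloc[0] = "C"
        with pytest.raises(ValueError, match="exactly two samples"):
            match_in_embedding(coords, clusters, samples)

    def test_dimension_mismatch_rejected(self):
        coords, clusters, samples = self._inputs()
        coords.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            match_in_embedding(coords, clusters, samples)


class TestThinCounts:
    def _matrix(self, values):
        values = np.atleast_2d(values)
        return CountMatrix(
            [f"f{i}" for i in range(values.shape[0])],
            [f"b{j}" for j in range(values.shape[1])],
            sp.csr_matrix(values),
        )

    def test_identity_and_zero_targets(self):
        matrix = self._matrix([[3, 5], [2, 0]])
        same = thin_counts(matrix, 10, seed=0)
        assert np.array_equal(same.to_dense(), matrix.to_dense())
        zero = thin_counts(matrix, 0, seed=0)
        assert zero.to_dense().sum() == 0

    def test_target_above_total_errors(self):
        with pytest.raises(ValueError, match="outside"):
            thin_counts(self._matrix([[1, 1]]), 5)

    def test_exact_total_and_entrywise_bound(self):
        matrix = self._matrix([[10, 20, 0], [5, 0, 30]])
        thinned = thin_counts(matrix, 17, seed=4)
        assert thinned.to_dense().sum() == 17
        assert np.all(thinned.to_dense() <= matrix.to_dense())

    def test_mean_kept_matches_hypergeometric_expectation(self):
        """Thinning [100, 300] to 200 keeps on average [50, 150]."""
        matrix = self._matrix([[100, 300]])
        n_rep = 10_000
        kept = np.zeros(2)
        for seed in range(n_rep):
            kept += thin_counts(matrix, 200, seed=seed).to_dense().ravel()
        mean = kept / n_rep
        # hypergeometric marginal: var = n*(K/N)*(1-K/N)*(N-n)/(N-1)
        var = 200 * 0.25 * 0.75 * (400 - 200) / (400 - 1)
        se = np.sqrt(var / n_rep)
        assert abs(mean[0] - 50) <= 3 * se
        assert abs(mean[1] - 150) <= 3 * se

    def test_two_stage_thinning_matches_direct_in_distribution(self):
        """Thinning to t then t' is distributed like thinning directly to t'."""
        rng = np.random.default_rng(0)
        base = self._matrix(rng.integers(5, 30, size=(3, 3)))
        total = int(base.to_dense().sum())
        t, t_final = int(total * 0.7), int(total * 0.3)
        staged, direct = [], []
        for seed in range(1000):
            step = thin_counts(base, t, seed=seed)
            staged.append(thin_counts(step, t_final, seed=10_000 + seed).to_dense()[0, 0])
            direct.append(thin_counts(base, t_final, seed=20_000 + seed).to_dense()[0, 0])
        assert mannwhitneyu(staged, direct).pvalue > 0.01

    def test_read_level_thinning_bounds(self):
        matrix = self._matrix([[50, 100]])
        thinned = thin_counts_read_level(matrix, keep_read_fraction=0.3, reads_per_umi=2.0, seed=1)
        assert np.all(thinned.to_dense() <= matrix.to_dense())
        full = thin_counts_read_level(matrix, keep_read_fraction=1.0, reads_per_umi=2.0, seed=1)
        assert np.array_equal(full.to_dense(), matrix.to_dense())


class TestSequencingSaturation:
    @pytest.mark.parametrize(
        "reads,umis,expected",
        [(1000, 230, 0.77), (500, 500, 0.0), (100, 0, 1.0)],
    )
    def test_values(self, reads, umis, expected):
        assert sequencing_saturation(reads, umis) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sequencing_saturation(0, 0)
        with pytest.raises(ValueError):
            sequencing_saturation(10, 11)
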