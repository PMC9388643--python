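import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_tom
from strictlnc.annotation_io import ValidationError
from strictlnc.coexpression import (
    NetworkConfig,
    bicor,
    bicor_matrix,
    compute_eigengenes,
    detect_modules,
    normalize_counts,
    scale_free_fit,
    signed_adjacency,
    tom_similarity,
)


def block_data(rng, n_blocks=2, n_per=60, n_samples=60, r=0.8):
    rows, truth = [], []
    for b in range(n_blocks):
        f = rng.normal(0, 1, n_samples)
        for _ in range(n_per):
            rows.append(np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(0, 1, n_samples))
            truth.append(b + 1)
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return df, truth


class TestNormalization:
    def test_identical_samples_get_unit_size_factors(self):
        counts = pd.DataFrame({"s1": [10, 40, 100], "s2": [10, 40, 100]},
                              index=list("abc"))
        norm = normalize_counts(counts)
        assert (norm["s1"] == norm["s2"]).all()

    def test_doubled_sample_is_rescaled_back(self):
        rng = np.random.default_rng(1)
        base = rng.integers(500, 5000, size=50)
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base},
                              index=[f"g{i}" for i in range(50)])
        norm = normalize_counts(counts)
        # up to the +1 pseudocount effect at large counts
        assert np.allclose(norm["s3"], norm["s1"], atol=1e-2)

    def test_constant_gene_stays_constant(self):
        counts = pd.DataFrame({"s1": [7, 100], "s2": [7, 100]}, index=["g", "h"])
        norm = normalize_counts(counts)
        assert norm.loc["g"].nunique() == 1

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [5, 1], "s2": [0, 0]}, index=["g", "h"])
        with pytest.raises(ValidationError, match="all-zero"):
            normalize_counts(counts)


class TestBicor:
    def test_affine_relation_is_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        assert bicor(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)
        assert bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pearson_on_clean_affine_data(self):
        x = np.linspace(-3, 3, 41)
        y = 0.5 * x + 2
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(bicor(x, y) - pearson) < 1e-6

    def test_robust_to_a_gross_outlier(self):
        rng = np.random.default_rng(5)
        closer = 0
        for _ in range(100):
            x = rng.normal(0, 1, 30)
            y = 0.8 * x + rng.normal(0, 0.5, 30)
            ref = np.corrcoef(x, y)[0, 1]
            xo = np.append(x, 10.0)
            yo = np.append(y, -10.0)
            pearson_out = np.corrcoef(xo, yo)[0, 1]
            if abs(bicor(xo, yo) - ref) < abs(pearson_out - ref):
                closer += 1
        assert closer >= 90

    def test_zero_mad_falls_back_to_pearson_weighting(self):
        # x has MAD 0 (majority identical); bicor must still be defined
        x = np.array([1.0, 1, 1, 1, 1, 1, 5.0])
        y = 2 * x + 3  # same zero-MAD pattern; Pearson fallback gives 1
        assert bicor(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_both_vectors_is_nan(self):
        assert np.isnan(bicor([1.0, 1, 1, 1], [2.0, 2, 2, 2]))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            bicor([1, 2, 3], [1, 2])

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (6, 30))
        M = bicor_matrix(X)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert M[i, j] == pytest.approx(bicor(X[i], X[j]), abs=1e-12)


class TestAdjacencyAndTom:
    def test_extremes_and_hand_value(self):
        corr = np.array([[1.0, 1.0, -1.0, 0.0]] * 4)
        adj = signed_adjacency(corr, 12)
        assert adj[0, 1] == pytest.approx(1.0)
        assert adj[0, 2] == pytest.approx(0.0)
        assert adj[0, 3] == pytest.approx(2.44140625e-4)  # 0.5 ** 12

    def test_monotone_in_correlation(self):
        corrs = np.linspace(-1, 1, 21)
        adj = ((1 + corrs) / 2) ** 12
        assert (np.diff(adj) >= 0).all()

    def test_tom_matches_bruteforce_to_1e12(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(5, 16))
            corr = np.clip(rng.uniform(-1, 1, (n, n)), -1, 1)
            corr = (corr + corr.T) / 2
            np.fill_diagonal(corr, 1.0)
            adj = signed_adjacency(corr, 6)
            tom = tom_similarity(adj)
            assert np.allclose(tom, brute_force_tom(adj), atol=1e-12)
            assert np.allclose(tom, tom.T, atol=1e-12)
            assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestScaleFreeFit:
    def test_degenerate_equal_connectivity_reports_missing(self):
        corr = np.full((60, 60), 0.5)
        np.fill_diagonal(corr, 1.0)
        table = scale_free_fit(corr, beta_grid=[6])
        assert np.isnan(table["r_squared"].iloc[0])

    def test_r_squared_bounded_and_connectivity_decreasing(self):
        rng = np.random.default_rng(4)
        X, _ = block_data(rng, n_blocks=3, n_per=30, n_samples=40)
        corr = bicor_matrix(X.values)
        table = scale_free_fit(corr, beta_grid=[2, 6, 12])
        valid = table["r_squared"].dropna()
        assert ((valid >= -1) & (valid <= 1)).all()
        assert table["mean_connectivity"].is_monotonic_decreasing


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        df, truth = block_data(rng)
        modules = detect_modules(df, NetworkConfig())
        detected = [int(modules.labels[g]) for g in df.index]
        assert modules.n_modules == 2
        assert adjusted_rand_score(truth, detected) >= 0.8

    def test_small_cluster_goes_to_module_zero(self):
        rng = np.random.default_rng(1)
        df, _ = block_data(rng, n_blocks=1, n_per=40)
        modules = detect_modules(df, NetworkConfig(min_module_size=50))
        assert set(modules.labels.unique()) == {0}

    def test_fewer_genes_than_min_size_warns(self):
        rng = np.random.default_rng(2)
        df, _ = block_data(rng, n_blocks=1, n_per=10)
        with pytest.warns(UserWarning, match="module 0"):
            modules = detect_modules(df, NetworkConfig(min_module_size=50))
        assert modules.sizes == {0: 10}

    def test_module_indices_ordered_by_decreasing_size(self):
        rng = np.random.default_rng(3)
        a, truth_a = block_data(rng, n_blocks=1, n_per=80)
        b, _ = block_data(rng, n_blocks=1, n_per=55)
        b.index = [f"h{i}" for i in range(len(b))]
        df = pd.concat([a, b])
        modules = detect_modules(df, NetworkConfig())
        assert modules.sizes[1] >= modules.sizes[2]


class TestEigengenes:
    def test_identical_profiles_give_unit_norm_common_profile(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 30)
        df = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        modules = detect_modules(df, NetworkConfig(min_module_size=3))
        egs, kme = compute_eigengenes(df, modules)
        (eg,) = egs.values()
        assert np.linalg.norm(eg.vector) == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eg.vector, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eg.vector, z)[0, 1] > 0
        assert kme.dropna().values == pytest.approx(np.ones(5))

    def test_recovers_planted_latent_factor(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            r2 = np.random.default_rng(seed)
            factor = r2.normal(0, 1, 40)
            df = pd.DataFrame(
                [factor + r2.normal(0, 0.3, 40) for _ in range(30)],
                index=[f"g{i}" for i in range(30)],
            )
            modules = detect_modules(df, NetworkConfig(min_module_size=10))
            egs, _ = compute_eigengenes(df, modules)
            assert egs, "no module detected"
            eg = egs[1].vector
            assert abs(np.corrcoef(eg, factor)[0, 1]) >= 0.9

    def test_first_singular_vector_beats_random_directions(self):
        rng = np.random.default_rng(2)
        factor = rng.normal(0, 1, 25)
        df = pd.DataFrame(
            [factor + rng.normal(0, 0.5, 25) for _ in range(15)],
            index=[f"g{i}" for i in range(15)],
        )
        modules = detect_modules(df, NetworkConfig(min_module_size=5))
        egs, _ = compute_eigengenes(df, modules)
        eg = egs[1].vector.values
        Z = ((df.T - df.mean(axis=1)) / df.std(axis=1, ddof=0)).T.values
        best = ((Z @ eg) ** 2).sum()
        for _ in range(100):
            v = rng.normal(0, 1, 25)
            v /= np.linalg.norm(v)
            assert ((Z @ v) ** 2).sum() <= best + 1e-9
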