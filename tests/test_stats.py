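"""Normalization, variance F-tests, correlation-distance clustering, t-SNE."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from spikequant.stats import (
    ploidy_variance_screen,
    species_distance_matrix,
    tsne_embed,
    upgma_tree,
    variance_f_test,
    zscore_normalize,
)
from spikequant.synthetic import TraitTableSpec, generate_trait_table, sample_species_means
from spikequant.traits import TRAIT_COLUMNS, species_mean_vectors


def naive_upgma(D):
    """Brute-force UPGMA: explicit average-linkage over index sets."""
    D = np.asarray(D, dtype=float)
    clusters = {i: [i] for i in range(D.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ka, kb = keys[a], keys[b]
                d = np.mean([D[i, j] for i in clusters[ka] for j in clusters[kb]])
                if best is None or d < best[0]:
                    best = (d, ka, kb)
        d, ka, kb = best
        heights.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(ka) + clusters.pop(kb)
    return np.array(heights)


def random_distance_matrix(n, rng):
    M = rng.uniform(0.1, 2.0, size=(n, n))
    D = (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


class TestZscore:
    def test_two_point_column(self):
        df = pd.DataFrame({c: [0.0, 2.0] for c in TRAIT_COLUMNS})
        out = zscore_normalize(df)
        assert np.allclose(out[TRAIT_COLUMNS].iloc[0], -np.sqrt(0.5))
        assert np.allclose(out[TRAIT_COLUMNS].iloc[1], np.sqrt(0.5))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 9)), columns=TRAIT_COLUMNS)
        once = zscore_normalize(df)
        twice = zscore_normalize(once)
        assert np.allclose(once[TRAIT_COLUMNS], twice[TRAIT_COLUMNS], atol=1e-9)
        assert np.allclose(once[TRAIT_COLUMNS].mean(), 0.0, atol=1e-9)
        assert np.allclose(once[TRAIT_COLUMNS].std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({c: np.arange(5.0) for c in TRAIT_COLUMNS})
        df["circularity"] = 0.5
        with pytest.raises(ValueError, match="circularity"):
            zscore_normalize(df)


class TestVarianceFTest:
    def test_ratio_of_sample_variances(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        r = variance_f_test(2.0 * base, base)
        assert r.F == pytest.approx(4.0)
        assert (r.df1, r.df2) == (9, 9)

    def test_identical_samples(self):
        x = np.arange(12.0)
        r = variance_f_test(x, x)
        assert r.F == 1.0
        assert r.p == pytest.approx(1.0, abs=1e-9)
        assert not r.significant

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(scale=1.7, size=25)
        fwd, rev = variance_f_test(x, y), variance_f_test(y, x)
        assert fwd.F * rev.F == pytest.approx(1.0, rel=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-9)

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            variance_f_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_type_i_error_calibrated(self):
        """Monte-Carlo rejection rate under the null stays near alpha."""
        rng = np.random.default_rng(123)
        reps, rejections = 2000, 0
        for _ in range(reps):
            r = variance_f_test(rng.normal(size=30), rng.normal(size=30), alpha=0.05)
            rejections += r.significant
        assert 0.038 <= rejections / reps <= 0.062


class TestPloidyScreen:
    def test_returns_nine_results_under_null(self):
        df = generate_trait_table(TraitTableSpec(seed=0))
        results = ploidy_variance_screen(df)
        assert [r.trait for r in results] == TRAIT_COLUMNS
        assert all(r.F > 0 and 0 <= r.p <= 1 for r in results)

    def test_inflated_traits_flagged(self):
        infl = np.array([3.0] * 6 + [1.0] * 3)
        hits = np.zeros(9)
        n_seeds = 10
        for seed in range(n_seeds):
            spec = TraitTableSpec(n_species_per_ploidy=2, n_plants_per_species=50,
                                  variance_inflation=infl, seed=seed)
            results = ploidy_variance_screen(generate_trait_table(spec))
            hits += [r.significant for r in results]
        assert (hits[:6] >= 0.9 * n_seeds).all()
        assert (hits[6:] <= 0.3 * n_seeds).all()

    def test_duplicate_projections_ignored(self):
        df = generate_trait_table(TraitTableSpec(seed=3))
        dup = df.copy()
        dup["projection"] = 1
        jittered = pd.concat([df, dup], ignore_index=True)
        base = ploidy_variance_screen(df)
        deduped = ploidy_variance_screen(jittered)
        for a, b in zip(base, deduped):
            assert a.F == pytest.approx(b.F, rel=1e-12)

    def test_tiny_group_rejected(self):
        df = generate_trait_table(TraitTableSpec(n_species_per_ploidy=1,
                                                 n_plants_per_species=1, seed=0))
        with pytest.raises(ValueError, match="at least 2"):
            ploidy_variance_screen(df)


class TestSpeciesDistance:
    def test_identical_vectors_at_zero(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=9)
        M = pd.DataFrame([v, v, rng.normal(size=9)], columns=TRAIT_COLUMNS,
                         index=["a", "b", "c"])
        D = species_distance_matrix(M, normalize_columns=False)
        assert D.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_at_two(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=9)
        M = pd.DataFrame([v, 2 * v.mean() - v], columns=TRAIT_COLUMNS, index=["a", "b"])
        D = species_distance_matrix(M, normalize_columns=False)
        assert D.loc["a", "b"] == pytest.approx(2.0, abs=1e-9)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(rng.normal(size=(5, 9)), columns=TRAIT_COLUMNS)
        D = species_distance_matrix(M, normalize_columns=True).to_numpy()
        Z = ((M - M.mean()) / M.std(ddof=1)).to_numpy()
        for i in range(5):
            for j in range(5):
                a, b = Z[i] - Z[i].mean(), Z[j] - Z[j].mean()
                expected = 0.0 if i == j else 1 - (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert abs(D[i, j] - expected) < 1e-12

    def test_values_in_range(self):
        rng = np.random.default_rng(6)
        M = pd.DataFrame(rng.normal(size=(8, 9)), columns=TRAIT_COLUMNS)
        D = species_distance_matrix(M).to_numpy()
        assert (D >= 0.0).all() and (D <= 2.0 + 1e-12).all()
        assert np.allclose(np.diag(D), 0.0)

    def test_constant_vector_rejected(self):
        M = pd.DataFrame([[1.0] * 9, np.arange(9.0)], columns=TRAIT_COLUMNS)
        with pytest.raises(ValueError, match="zero variance|constant"):
            species_distance_matrix(M, normalize_columns=False)


class TestUpgma:
    def test_three_leaf_worked_example(self):
        D = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        tree = upgma_tree(D, ["A", "B", "C"])
        assert np.allclose(tree.merge_heights, [2.0, 8.0])
        first = tree.merges[0]
        assert {first[0], first[1]} == {0, 1}

    def test_identical_leaves_merge_first_at_zero(self):
        rng = np.random.default_rng(7)
        D = random_distance_matrix(5, rng)
        D[1, 3] = D[3, 1] = 0.0
        tree = upgma_tree(D)
        assert tree.merge_heights[0] == 0.0
        assert {tree.merges[0][0], tree.merges[0][1]} == {1, 3}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_implementation(self, seed):
        rng = np.random.default_rng(seed)
        D = random_distance_matrix(6, rng)
        tree = upgma_tree(D)
        assert np.allclose(tree.merge_heights, naive_upgma(D), atol=1e-12)

    def test_heights_monotone(self):
        rng = np.random.default_rng(8)
        D = random_distance_matrix(10, rng)
        heights = upgma_tree(D).merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            upgma_tree(D)

    def test_newick_roundtrip(self):
        from Bio import Phylo

        rng = np.random.default_rng(9)
        labels = [f"sp{i}" for i in range(6)]
        tree = upgma_tree(random_distance_matrix(6, rng), labels)
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(labels)

    def test_flat_cut_two_groups(self):
        D = np.array([
            [0.0, 0.1, 1.5, 1.5],
            [0.1, 0.0, 1.5, 1.5],
            [1.5, 1.5, 0.0, 0.1],
            [1.5, 1.5, 0.1, 0.0],
        ])
        groups = upgma_tree(D, ["a1", "a2", "b1", "b2"]).cut(2)
        assert groups["a1"] == groups["a2"]
        assert groups["b1"] == groups["b2"]
        assert groups["a1"] != groups["b1"]


class TestTsne:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 9))
        a = tsne_embed(X, perplexity=10, seed=4)
        b = tsne_embed(X, perplexity=10, seed=4)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.coordinates.shape == (60, 2)

    def test_duplicated_rows_are_mutual_neighbors(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(size=(48, 9)), np.tile(rng.normal(size=9), (2, 1))])
        coords = tsne_embed(X, perplexity=10, seed=0).coordinates
        d = np.linalg.norm(coords - coords[48], axis=1)
        d[48] = np.inf
        assert np.argmin(d) == 49

    def test_separated_clusters_stay_separated(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 0.1, size=(50, 9))
        b = rng.normal(1.0, 0.1, size=(50, 9))
        coords = tsne_embed(np.vstack([a, b]), perplexity=15, seed=1).coordinates
        labels = np.repeat([0, 1], 50)
        assert silhouette_score(coords, labels) >= 0.8

    def test_perplexity_too_large_rejected(self):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(np.random.default_rng(0).normal(size=(20, 9)), perplexity=30)


class TestTemplateRecovery:
    def test_two_morphology_groups_recovered_by_tree_cut(self):
        """Species simulated from the long-thin and short-compact templates
        separate cleanly at the k = 2 cut of the UPGMA tree."""
        successes = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            means = np.vstack([
                sample_species_means("long_thin", 4, rng),
                sample_species_means("short_compact", 4, rng),
            ])
            spec = TraitTableSpec(n_species_per_ploidy=4, n_plants_per_species=15,
                                  trait_means=means[:4], seed=seed)
            # build one table per template so species carry distinct means
            df_a = generate_trait_table(spec)
            spec_b = TraitTableSpec(n_species_per_ploidy=4, n_plants_per_species=15,
                                    trait_means=means[4:], seed=seed + 1000)
            df_b = generate_trait_table(spec_b)
            df_b = df_b.assign(species="sc_" + df_b["species"])
            table = pd.concat([df_a, df_b], ignore_index=True)
            vectors = species_mean_vectors(table)
            tree = upgma_tree(species_distance_matrix(vectors))
            groups = tree.cut(2)
            short_labels = {g for name, g in groups.items() if name.startswith("sc_")}
            long_labels = {g for name, g in groups.items() if not name.startswith("sc_")}
            successes += short_labels.isdisjoint(long_labels)
        assert successes >= 0.9 * n_seeds
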