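"""Enrichment-statistic tests, anchored on an exhaustive walk oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from m6ametab.gsva import (
    GsvaParams,
    density_transform,
    gsva_scores,
    rank_statistic,
    sample_ranks,
    walk_statistic,
)
from m6ametab.io import ExpressionMatrix, GeneSetCollection


def brute_force_walk(order, in_set, tau=1.0, mode="diff_of_maxima"):
    """Step-by-step reference walk, written independently of the library.

    ``order`` is the list of (gene, rank) pairs in walk order (rank 1
    first); ``in_set`` the membership set.
    """
    n = len(order)
    m = sum(1 for g, _ in order if g in in_set)
    weights = {
        g: abs(n / 2.0 - r + 0.5) ** tau for g, r in order if g in in_set
    }
    total_w = sum(weights.values())
    dev, best_pos, best_neg = 0.0, 0.0, 0.0
    for g, r in order:
        if g in in_set:
            dev += (weights[g] / total_w) if total_w > 0 else 1.0 / m
        else:
            dev -= 1.0 / (n - m)
        best_pos = max(best_pos, dev)
        best_neg = min(best_neg, dev)
    if mode == "diff_of_maxima":
        return best_pos + best_neg
    # largest-magnitude deviation; a magnitude tie resolves positive
    return best_pos if best_pos >= -best_neg else best_neg


def _rank_series(values, genes):
    order = np.argsort([(-v, g) for v, g in zip(values, genes)], axis=0)
    s = pd.Series(index=genes, dtype=int)
    ranked = sorted(zip(values, genes), key=lambda t: (-t[0], t[1]))
    for pos, (_, g) in enumerate(ranked, start=1):
        s[g] = pos
    return s


class TestDensityTransform:
    def test_ecdf_matches_rank_fraction(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"], columns=list("abc"))
        )
        out = density_transform(m, kernel="ecdf")
        assert np.allclose(out.loc["G1"], [1 / 3, 2 / 3, 1.0])

    def test_constant_gene_gaussian_gives_half(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["G1"],
                         columns=list("abcd"))
        )
        out = density_transform(m, kernel="gaussian")
        assert np.allclose(out.loc["G1"], 0.5)

    @pytest.mark.parametrize("kernel", ["gaussian", "ecdf"])
    def test_monotone_within_gene(self, kernel):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 20))
        m = ExpressionMatrix(
            pd.DataFrame(values, index=[f"G{i}" for i in range(5)],
                         columns=[f"S{i}" for i in range(20)])
        )
        out = density_transform(m, kernel=kernel).to_numpy()
        for row_x, row_t in zip(values, out):
            order = np.argsort(row_x)
            assert np.all(np.diff(row_t[order]) > 0)
        assert ((out > 0) & (out < 1)).all() or kernel == "ecdf"

    def test_too_few_samples_errors(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=list("ab"))
        )
        with pytest.raises(ValueError, match="3 samples"):
            density_transform(m)


class TestSampleRanks:
    def test_distinct_values_rank_descending(self):
        df = pd.DataFrame({"s": [0.1, 0.9, 0.5, 0.3]},
                          index=["G1", "G2", "G3", "G4"])
        ranks = sample_ranks(df)
        assert list(ranks["s"]) == [4, 1, 2, 3]

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({"s": [0.5, 0.5, 0.9]}, index=["GB", "GA", "GC"])
        ranks = sample_ranks(df)
        assert ranks.loc["GC", "s"] == 1
        assert ranks.loc["GA", "s"] == 2  # tie: GA before GB
        assert ranks.loc["GB", "s"] == 3

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_symmetric_statistic_sums_to_zero(self, n):
        ranks = pd.DataFrame({"s": np.arange(1, n + 1)},
                             index=[f"G{i}" for i in range(n)])
        assert rank_statistic(ranks)["s"].sum() == pytest.approx(0.0)


class TestWalkStatistic:
    def test_top_set_positive_bottom_set_negative(self):
        genes = [f"G{i}" for i in range(10)]
        ranks = pd.Series(np.arange(1, 11), index=genes)
        assert walk_statistic(ranks, genes[:3]) > 0
        assert walk_statistic(ranks, genes[-3:]) < 0

    def test_matches_enumerated_five_gene_walk(self):
        # 5 genes, set of 2: exhaustive hand enumeration via the oracle
        genes = ["A", "B", "C", "D", "E"]
        for perm in itertools.permutations(range(1, 6)):
            ranks = pd.Series(perm, index=genes, dtype=float)
            order = sorted(zip(genes, perm), key=lambda t: t[1])
            for gene_set in itertools.combinations(genes, 2):
                expected = brute_force_walk(order, set(gene_set))
                got = walk_statistic(ranks, list(gene_set))
                assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mode", ["diff_of_maxima", "max_deviation"])
    def test_exhaustive_oracle_small_instances(self, mode):
        """Every instance with <= 8 genes and <= 3-gene sets, both modes."""
        rng = np.random.default_rng(7)
        for n_genes in (4, 6, 8):
            genes = [f"G{i}" for i in range(n_genes)]
            for _ in range(30):
                perm = rng.permutation(np.arange(1, n_genes + 1))
                ranks = pd.Series(perm, index=genes, dtype=float)
                order = sorted(zip(genes, perm), key=lambda t: t[1])
                for size in (1, 2, 3):
                    for gene_set in itertools.combinations(genes, size):
                        expected = brute_force_walk(order, set(gene_set),
                                                    mode=mode)
                        got = walk_statistic(ranks, list(gene_set), mode=mode)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_bounded_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            genes = [f"G{i}" for i in range(n)]
            ranks = pd.Series(rng.permutation(np.arange(1, n + 1)),
                              index=genes, dtype=float)
            size = int(rng.integers(1, n - 1))
            gene_set = list(rng.choice(genes, size=size, replace=False))
            score = walk_statistic(ranks, gene_set)
            assert -1.0 <= score <= 1.0

    def test_empty_intersection_errors(self):
        ranks = pd.Series([1, 2, 3], index=["A", "B", "C"], dtype=float)
        with pytest.raises(ValueError, match="no member"):
            walk_statistic(ranks, ["X"])


class TestGsvaScores:
    def _matrix(self, seed=0, n_genes=30, n_samples=12):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            pd.DataFrame(
                rng.normal(5, 1, size=(n_genes, n_samples)),
                index=[f"G{i:02d}" for i in range(n_genes)],
                columns=[f"S{i:02d}" for i in range(n_samples)],
            )
        )

    def _sets(self, expr, sizes=(5, 6)):
        rng = np.random.default_rng(42)
        return GeneSetCollection(
            sets={
                f"SET{j}": list(rng.choice(expr.genes, size=s, replace=False))
                for j, s in enumerate(sizes)
            }
        )

    def test_matches_per_sample_walk(self):
        expr = self._matrix()
        sets = self._sets(expr)
        params = GsvaParams()
        scores = gsva_scores(expr, sets, params)
        transformed = density_transform(expr, params.kernel)
        ranks = sample_ranks(transformed)
        for name, members in sets.sets.items():
            for s in expr.samples:
                expected = walk_statistic(ranks[s], members, params.tau,
                                          params.mode)
                assert scores.values.loc[name, s] == pytest.approx(expected)

    def test_duplicate_samples_get_identical_columns(self):
        expr = self._matrix()
        dup = ExpressionMatrix(
            pd.concat(
                [expr.data, expr.data.add_suffix("_copy", axis=1)], axis=1
            )
        )
        scores = gsva_scores(dup, self._sets(expr))
        for s in expr.samples:
            assert np.allclose(
                scores.values[s], scores.values[f"{s}_copy"]
            )

    def test_ecdf_scores_invariant_under_monotone_transform(self):
        expr = self._matrix()
        sets = self._sets(expr)
        params = GsvaParams(kernel="ecdf")
        base = gsva_scores(expr, sets, params)
        warped = ExpressionMatrix(np.exp(expr.data / 2.0) + 3.0)
        again = gsva_scores(warped, sets, params)
        pd.testing.assert_frame_equal(base.values, again.values)

    def test_permuting_samples_permutes_columns(self):
        expr = self._matrix()
        sets = self._sets(expr)
        params = GsvaParams(kernel="ecdf")
        base = gsva_scores(expr, sets, params)
        perm = list(reversed(expr.samples))
        permuted = gsva_scores(expr.subset_samples(perm), sets, params)
        pd.testing.assert_frame_equal(permuted.values, base.values[perm])

    def test_small_sets_skipped_with_report(self):
        expr = self._matrix()
        sets = GeneSetCollection(
            sets={"TINY": expr.genes[:2], "OK": expr.genes[:6]}
        )
        with pytest.warns(UserWarning, match="TINY"):
            scores = gsva_scores(expr, sets)
        assert scores.set_names == ["OK"]
        assert "TINY" in scores.skipped

    def test_all_sets_skipped_errors(self):
        expr = self._matrix()
        sets = GeneSetCollection(sets={"TINY": expr.genes[:2]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all gene sets"):
                gsva_scores(expr, sets)

    def test_methylation_score_tracks_pattern_index(self, default_cohort):
        """The regulator set's enrichment rises across latent patterns."""
        from scipy.stats import spearmanr

        cohort = default_cohort
        scores = gsva_scores(
            cohort.expression,
            GeneSetCollection(
                sets={"mRNA_methylation":
                      cohort.gene_sets.sets["mRNA_methylation"]}
            ),
        )
        rho, _ = spearmanr(
            cohort.truth_samples["cluster"],
            scores.values.loc["mRNA_methylation"],
        )
        assert rho > 0.5
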