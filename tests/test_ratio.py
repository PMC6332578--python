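"""Fraction-matched X:AA ratio estimation: selection rules, bootstrap, rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from xdosage import (
    CellGroup,
    DegenerateInputError,
    bootstrap_ratio_ci,
    compute_expressed_fraction,
    mwu_vs_unity,
    select_matched_gene_sets,
    xaa_ratio_common_threshold,
    xaa_ratio_per_autosome,
    xaa_ratio_per_cell,
    xaa_ratio_population,
)

from conftest import make_annotation, make_matrix


def _one_cell_setup(x_means, a_means):
    """A single-cell group whose gene means equal the given values."""
    genes = {}
    values = {}
    for i, v in enumerate(x_means):
        genes[f"x{i}"] = {"chromosome": "X"}
        values[f"x{i}"] = [v]
    for i, v in enumerate(a_means):
        genes[f"a{i:02d}"] = {"chromosome": "1"}
        values[f"a{i:02d}"] = [v]
    ann = make_annotation(genes)
    matrix = make_matrix(values, ["c1"])
    group = CellGroup("E5", "TE", "male", ("c1",))
    return matrix, group, ann


class TestExpressedFraction:
    @pytest.mark.parametrize("means,expected", [
        ([20.0] * 10, 1.0),
        ([1.0] * 10, 0.0),
        ([20, 15, 12, 2, 3, 4, 5, 6, 7, 8], 0.3),
    ])
    def test_direct_count(self, means, expected):
        assert compute_expressed_fraction(pd.Series(means), 10.0) == expected

    def test_empty_is_error(self):
        with pytest.raises(DegenerateInputError):
            compute_expressed_fraction(pd.Series(dtype=float), 10.0)


class TestMatchedSelection:
    def test_x_fraction_and_selected_sets(self):
        matrix, group, ann = _one_cell_setup(
            [20, 12, 8, 2], [100, 50, 40, 30, 22, 9, 8, 7, 6, 5])
        means = matrix["c1"]
        sets = select_matched_gene_sets(means, ann, 10.0)
        assert sets.x_fraction == 0.5
        assert set(sets.selected_x) == {"x0", "x1"}
        # round(0.5 * 10) = 5 top autosomal genes
        assert list(sets.selected_a) == ["a00", "a01", "a02", "a03", "a04"]

    def test_all_x_above_threshold_selects_every_autosome(self):
        matrix, group, ann = _one_cell_setup([20, 30], [15, 25, 35])
        sets = select_matched_gene_sets(matrix["c1"], ann, 10.0)
        assert sets.x_fraction == 1.0
        assert len(sets.selected_a) == 3

    def test_zero_expressed_fraction_is_error(self):
        matrix, group, ann = _one_cell_setup([1, 2], [15, 25, 35])
        with pytest.raises(DegenerateInputError, match="no expressed X-linked"):
            select_matched_gene_sets(matrix["c1"], ann, 10.0)

    def test_ties_broken_lexicographically(self):
        matrix, group, ann = _one_cell_setup([20, 1, 1, 1], [5.0, 5.0, 5.0, 5.0])
        sets = select_matched_gene_sets(matrix["c1"], ann, 10.0)
        # x_fraction 0.25 -> 1 autosomal gene; tie on mean -> lowest gene id
        assert list(sets.selected_a) == ["a00"]

    def test_non_ortholog_genes_excluded(self):
        ann = make_annotation({
            "x0": {"chromosome": "X"},
            "x1": {"chromosome": "X", "one2one_chicken": False},
            "a0": {"chromosome": "2"},
        })
        means = pd.Series({"x0": 20.0, "x1": 1.0, "a0": 30.0})
        sets = select_matched_gene_sets(means, ann, 10.0)
        # x1 is outside the ortholog universe, so the fraction is 1/1
        assert sets.x_fraction == 1.0


class TestPopulationRatio:
    def test_hand_computed_ratio(self):
        matrix, group, ann = _one_cell_setup(
            [20, 12, 8, 2], [100, 50, 40, 30, 22, 9, 8, 7, 6, 5])
        est = xaa_ratio_population(matrix, group, ann, 10.0, n_boot=10, seed=0)
        # median(20,12)=16, median(100,50,40,30,22)=40
        assert est.point == pytest.approx(0.4)
        assert est.n_x == 2 and est.n_a == 5

    def test_identical_distributions_give_unity(self):
        matrix, group, ann = _one_cell_setup([20, 30, 40], [20, 30, 40])
        est = xaa_ratio_population(matrix, group, ann, 10.0, n_boot=10, seed=0)
        assert est.point == pytest.approx(1.0)

    def test_scale_invariance(self):
        matrix, group, ann = _one_cell_setup(
            [20, 12, 8, 2], [100, 50, 40, 30, 22, 9, 8, 7, 6, 5])
        lam = 3.7
        est1 = xaa_ratio_population(matrix, group, ann, 10.0, n_boot=5, seed=1)
        est2 = xaa_ratio_population(matrix * lam, group, ann, 10.0 * lam,
                                    n_boot=5, seed=1)
        assert est2.point == pytest.approx(est1.point)


class TestBootstrap:
    def test_degenerate_lists_collapse_ci(self):
        lo, hi = bootstrap_ratio_ci([4.0] * 6, [8.0] * 9, n_boot=100, seed=0)
        assert lo == hi == pytest.approx(0.5)

    def test_deterministic_given_seed(self, rng):
        x = rng.lognormal(2, 1, 40)
        a = rng.lognormal(2, 1, 80)
        assert bootstrap_ratio_ci(x, a, seed=42) == bootstrap_ratio_ci(x, a, seed=42)

    def test_ci_brackets_point_for_well_behaved_input(self, rng):
        x = rng.lognormal(2.0, 0.5, 200)
        a = rng.lognormal(2.5, 0.5, 400)
        point = np.median(x) / np.median(a)
        lo, hi = bootstrap_ratio_ci(x, a, n_boot=1000, seed=3)
        assert lo <= point <= hi


def _mwu_exhaustive_two_sided(x, y):
    """Oracle: exact two-sided p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n1n2 = n1 * len(y)

    def u_stat(xs, ys):
        return sum(1 for a, b in itertools.product(xs, ys) if a > b)

    observed = abs(u_stat(x, y) - n1n2 / 2)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(xs, ys) - n1n2 / 2) >= observed:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_exact_small_sample_matches_permutation_oracle(self):
        assert _mwu_exhaustive_two_sided([1, 2], [3, 4]) == pytest.approx(1 / 3)
        assert mwu_vs_unity([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert mwu_vs_unity(vals, vals) == pytest.approx(1.0)

    def test_large_sample_matches_closed_form_normal_approximation(self, rng):
        # independent oracle: tie-corrected z from ranks, no continuity term
        for _ in range(100):
            n1 = int(rng.integers(25, 60))
            n2 = int(rng.integers(25, 60))
            x = np.round(rng.normal(0, 1, n1), 1)
            y = np.round(rng.normal(0.3, 1, n2), 1)
            ranks = rankdata(np.concatenate([x, y]))
            u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            n = n1 + n2
            _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
            tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
            sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term))
            from scipy.stats import norm
            expected = 2 * norm.sf(abs(u - n1 * n2 / 2) / sigma)
            assert mwu_vs_unity(x, y) == pytest.approx(min(expected, 1.0), abs=1e-6)


class TestPerCellAndPerAutosome:
    def test_per_cell_summary_enumerates_ratios(self):
        # three cells engineered to give ratios 0.4, 0.5, 0.6
        genes = {f"x{i}": {"chromosome": "X"} for i in range(2)}
        genes.update({f"a{i}": {"chromosome": "1"} for i in range(4)})
        ann = make_annotation(genes)
        cells = ["c1", "c2", "c3"]
        matrix = make_matrix({
            "x0": [16.0, 20.0, 24.0],
            "x1": [1.0, 1.0, 1.0],
            "a0": [40.0, 40.0, 40.0],
            "a1": [40.0, 40.0, 40.0],
            "a2": [1.0, 1.0, 1.0],
            "a3": [1.0, 1.0, 1.0],
        }, cells)
        group = CellGroup("E5", "TE", "male", tuple(cells))
        summary = xaa_ratio_per_cell(matrix, group, ann, 10.0)
        assert summary.median == pytest.approx(0.5)
        assert summary.minimum == pytest.approx(0.4)
        assert summary.maximum == pytest.approx(0.6)
        assert summary.n_skipped == 0

    def test_all_cells_skipped_is_error(self):
        matrix, group, ann = _one_cell_setup([1, 2], [15, 25])
        with pytest.raises(DegenerateInputError):
            xaa_ratio_per_cell(matrix, group, ann, 10.0)

    def test_per_autosome_sparsity(self):
        genes = {"x0": {"chromosome": "X"},
                 "a0": {"chromosome": "1"}, "a1": {"chromosome": "1"},
                 "b0": {"chromosome": "7"}, "b1": {"chromosome": "7"}}
        ann = make_annotation(genes)
        matrix = make_matrix({g: [20.0] for g in genes}, ["c1"])
        group = CellGroup("E5", "TE", "male", ("c1",))
        out = xaa_ratio_per_autosome(matrix, group, ann, 10.0, n_boot=5, seed=0)
        assert set(out) == {"1", "7"}
        assert out["1"].point == pytest.approx(1.0)
        assert out["7"].point == pytest.approx(1.0)


class TestSensitivityVariants:
    def test_wilcoxon_per_cell_variant(self):
        from xdosage import wilcoxon_vs_unity

        assert wilcoxon_vs_unity([1.0, 1.0, 1.0]) == 1.0
        # ratios consistently below 1 -> small p
        assert wilcoxon_vs_unity([0.4, 0.5, 0.45, 0.55, 0.5, 0.48]) < 0.05

    def test_reselection_bootstrap_deterministic_and_brackets_estimate(self, rng):
        from xdosage import reselection_bootstrap_ci

        matrix, group, ann = _one_cell_setup(
            list(rng.lognormal(2.5, 1.0, 100)),
            list(rng.lognormal(2.5, 1.0, 400)))
        means = matrix["c1"]
        est = xaa_ratio_population(matrix, group, ann, 10.0, n_boot=5, seed=0)
        ci1 = reselection_bootstrap_ci(means, ann, 10.0, n_boot=300, seed=9)
        ci2 = reselection_bootstrap_ci(means, ann, 10.0, n_boot=300, seed=9)
        assert ci1 == ci2
        assert ci1[0] <= est.point <= ci1[1]


class TestGeneratorRecovery:
    @pytest.mark.parametrize("true_ratio", [0.5, 1.0])
    def test_matched_estimator_unbiased_on_planted_truth(self, true_ratio):
        from xdosage.experiments import matched_estimate

        # averaging over seeds isolates bias from per-run sampling spread;
        # 100 cells keeps the selection step's noise-induced bias negligible
        points = [matched_estimate(true_ratio, seed=s) for s in range(1, 5)]
        assert np.mean(points) == pytest.approx(true_ratio, abs=0.05)


class TestCommonThreshold:
    def test_identical_distributions_agree_with_matched(self):
        matrix, group, ann = _one_cell_setup([20, 30, 40], [20, 30, 40])
        matched = xaa_ratio_population(matrix, group, ann, 10.0, n_boot=5, seed=0)
        common = xaa_ratio_common_threshold(matrix, group, ann, 10.0, n_boot=5, seed=0)
        assert matched.point == pytest.approx(1.0)
        assert common.point == pytest.approx(1.0)

    def test_overestimates_when_truth_below_one(self):
        # X distribution = autosomal shifted down two-fold: the common cut
        # keeps only the top of X, inflating the ratio above the truth 0.5
        a_vals = list(np.linspace(5, 100, 40))
        x_vals = [v / 2 for v in a_vals]
        matrix, group, ann = _one_cell_setup(x_vals, a_vals)
        matched = xaa_ratio_population(matrix, group, ann, 10.0, n_boot=5, seed=0)
        common = xaa_ratio_common_threshold(matrix, group, ann, 10.0, n_boot=5, seed=0)
        assert matched.point == pytest.approx(0.5, abs=0.05)
        assert common.point > matched.point
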