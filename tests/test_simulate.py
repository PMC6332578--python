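"""Generator ground truth: determinism, planted flags, noise model shape."""

import numpy as np
import pandas as pd
import pytest

from xdosage.simulate import (
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    recovery_config,
    sample_stratum,
)


def _small_config(**overrides):
    defaults = dict(
        n_genes_per_chromosome={"1": 60, "2": 60, "X": 40, "Y": 10},
        strata=[("E5", "TE", "male"), ("E5", "TE", "female")],
        n_cells_per_stratum=15,
        seed=1,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


class TestAnnotationGeneration:
    def test_same_seed_identical_tables(self):
        a1, _ = generate_annotation(_small_config())
        a2, _ = generate_annotation(_small_config())
        pd.testing.assert_frame_equal(a1, a2)

    def test_different_seed_differs(self):
        a1, _ = generate_annotation(_small_config(seed=1))
        a2, _ = generate_annotation(_small_config(seed=2))
        assert not a1.equals(a2)

    def test_zero_hk_probability_plants_no_housekeeping(self):
        cfg = _small_config(hk_probability={"1": 0.0, "2": 0.0, "X": 0.0, "Y": 0.0})
        ann, _ = generate_annotation(cfg)
        assert not ann["housekeeping"].any()

    def test_hk_fraction_concentrates_at_probability(self):
        counts = {str(i): 500 for i in range(1, 21)}  # ~10,000 genes
        counts["X"] = 500
        probs = {str(i): 0.2 for i in range(1, 21)}
        probs["X"] = 0.2
        cfg = SyntheticConfig(n_genes_per_chromosome=counts,
                              hk_probability=probs,
                              strata=[("E5", "TE", "male")], seed=4)
        ann, _ = generate_annotation(cfg)
        assert ann["housekeeping"].mean() == pytest.approx(0.2, abs=0.02)

    def test_coordinates_non_overlapping_and_ordered(self):
        ann, _ = generate_annotation(_small_config())
        for _, sub in ann.groupby("chromosome"):
            sub = sub.sort_values("start")
            assert (sub["start"] <= sub["end"]).all()
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()

    def test_chicken_fields_iff_ortholog(self):
        ann, _ = generate_annotation(_small_config())
        has_chicken = ann["chicken_chromosome"].notna()
        assert (has_chicken == ann["one2one_chicken"]).all()
        x_ortho = ann[(ann["chromosome"] == "X") & ann["one2one_chicken"]]
        assert x_ortho["x_syntenic"].all()
        assert set(x_ortho["chicken_chromosome"]) <= {"1", "4"}


class TestExpressionGeneration:
    def test_same_seed_identical_matrices(self):
        cfg = _small_config()
        ann, _ = generate_annotation(cfg)
        m1, meta1, _ = generate_expression(cfg, ann)
        m2, meta2, _ = generate_expression(cfg, ann)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(meta1, meta2)

    def test_zero_noise_reproduces_stratum_means_exactly(self):
        cfg = _small_config(noise_a=0.0, noise_b=0.0)
        ann, _ = generate_annotation(cfg)
        matrix, meta, truth = generate_expression(cfg, ann)
        male_cells = truth.cell_sex.index[truth.cell_sex == "male"]
        r = cfg.true_ratio[("E5", "male")]
        x_genes = ann.index[ann["chromosome"] == "X"]
        a_genes = ann.index[ann["chromosome"].isin(("1", "2"))]
        male = matrix.loc[:, male_cells]
        # every cell equals its stratum mean: one distinct value per gene
        assert (male.nunique(axis=1) == 1).all()
        np.testing.assert_allclose(
            male.loc[x_genes].iloc[:, 0],
            truth.base_means.loc[x_genes] * r)
        np.testing.assert_allclose(
            male.loc[a_genes].iloc[:, 0], truth.base_means.loc[a_genes])

    def test_y_genes_zero_in_females_expressed_in_males(self):
        cfg = _small_config()
        ann, _ = generate_annotation(cfg)
        matrix, _, truth = generate_expression(cfg, ann)
        y_genes = ann.index[ann["chromosome"] == "Y"]
        females = truth.cell_sex.index[truth.cell_sex == "female"]
        males = truth.cell_sex.index[truth.cell_sex == "male"]
        assert (matrix.loc[y_genes, females] == 0).all().all()
        assert (matrix.loc[y_genes, males].sum(axis=0) > 1.0).all()

    def test_x_ratio_planted_by_construction(self):
        cfg = recovery_config(0.5, n_x=200, n_a=1000, n_cells=5,
                              seed=9)
        ann, _ = generate_annotation(cfg)
        _, _, truth = generate_expression(cfg, ann)
        assert truth.true_ratio[("E5", "male")] == 0.5

    def test_noise_curve_recovered_by_regression(self):
        # diploid genes: cv^2 vs 1/mean regression recovers (a, b) within 20%
        rng = np.random.default_rng(12)
        means = rng.lognormal(3.0, 1.0, 2000)
        a_true, b_true = 10.0, 0.25
        block = sample_stratum(means, np.full(2000, 2), a_true,
                               np.full(2000, b_true), 200,
                               np.random.default_rng(13))
        est_mean = block.mean(axis=1)
        est_cv2 = (block.std(axis=1, ddof=1) / est_mean) ** 2
        slope, intercept = np.polyfit(1.0 / est_mean, est_cv2, 1)
        assert slope == pytest.approx(a_true, rel=0.2)
        assert intercept == pytest.approx(b_true, rel=0.2)


class TestPloidyNoise:
    def test_haploid_noisier_than_diploid_identical_allele_parameters(self):
        rng_means = np.random.default_rng(21)
        means = rng_means.lognormal(2.5, 1.0, 1000)
        cv_medians = {}
        for ploidy in (1, 2):
            block = sample_stratum(means, np.full(1000, ploidy), 10.0,
                                   np.full(1000, 0.25), 150,
                                   np.random.default_rng(22))
            cv = block.std(axis=1, ddof=1) / block.mean(axis=1)
            cv_medians[ploidy] = np.median(cv)
        assert cv_medians[1] > cv_medians[2]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"hk_probability": {"1": 1.5}},
        {"ortholog_probability": -0.1},
        {"noise_a": -1.0},
        {"true_ratio": {("E5", "male"): 0.0}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)

    def test_missing_ratio_for_stratum_is_error(self):
        cfg = _small_config(true_ratio={("E4", "male"): 0.5})
        ann, _ = generate_annotation(cfg)
        with pytest.raises(ValueError, match="true_ratio"):
            generate_expression(cfg, ann)
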