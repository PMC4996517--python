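"""Simulation generators: genotypes, penetrance, mixture traits, categorization."""

import numpy as np
import pytest
from scipy import stats

from gidscan import (
    CategoricalPenetrance,
    QuantPenetranceModel,
    categorize_trait,
    classify_blood_pressure,
    compose_phenotypes,
    model_from_heritability,
    penetrance_from_odds,
    simulate_categorical_phenotype,
    simulate_genotypes,
    simulate_null_dataset,
    simulate_quantitative_phenotype,
)
from gidscan.simulate import (
    genotype_cell_probs,
    strong_three_class_model,
    xor_pattern,
)


class TestGenotypes:
    def test_hwe_frequencies_at_maf_half(self):
        G = simulate_genotypes(60_000, 1, 0.5, seed=1)
        freqs = np.bincount(G[:, 0], minlength=3) / 60_000
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_low_maf_limit_is_nearly_all_reference(self):
        G = simulate_genotypes(5_000, 2, 1e-6, seed=2)
        assert G.sum() == 0

    def test_seed_reproducibility(self):
        a = simulate_genotypes(100, 5, 0.3, seed=3)
        b = simulate_genotypes(100, 5, 0.3, seed=3)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 2, maf)


class TestPenetranceFromOdds:
    def test_unit_odds_recover_the_prevalence(self):
        v = (0.3, 0.4, 0.3)
        pen = penetrance_from_odds(v, np.ones((9, 3)))
        np.testing.assert_allclose(pen.table, np.tile(v, (9, 1)), atol=1e-12)

    def test_rows_always_sum_to_one(self, rng):
        OR = rng.uniform(0.2, 8.0, size=(9, 3))
        pen = penetrance_from_odds((0.3, 0.4, 0.3), OR)
        np.testing.assert_allclose(pen.table.sum(axis=1), 1.0)

    def test_huge_odds_ratio_approaches_an_indicator(self):
        OR = np.ones((9, 3))
        OR[4, 2] = 1e9
        pen = penetrance_from_odds((0.3, 0.4, 0.3), OR)
        assert pen.table[4, 2] == pytest.approx(1.0, abs=1e-6)

    def test_ipf_matches_target_marginals(self):
        OR = np.ones((9, 3))
        OR[::2, 0] = 4.0
        mafs = (0.3, 0.3)
        pen = penetrance_from_odds((0.3, 0.4, 0.3), OR, mafs=mafs, ipf=True)
        np.testing.assert_allclose(
            pen.achieved_prevalence(mafs), (0.3, 0.4, 0.3), atol=1e-5
        )

    def test_nonpositive_odds_rejected(self):
        with pytest.raises(ValueError):
            penetrance_from_odds((0.5, 0.5), np.array([[1.0, -2.0]] * 9))


class TestCategoricalPhenotype:
    def test_degenerate_row_is_deterministic(self):
        table = np.tile([0.25, 0.5, 0.25], (9, 1))
        table[0] = [1.0, 0.0, 0.0]
        pen = CategoricalPenetrance(table=table, prevalence=(0.3, 0.4, 0.3))
        G = np.zeros((50, 2), dtype=int)  # everyone in cell 0
        y = simulate_categorical_phenotype(G, (0, 1), pen, seed=4)
        assert np.all(y == 1)

    def test_class_frequencies_converge_to_the_weighted_penetrance(self):
        """Goodness-of-fit of simulated class frequencies at n=1e5."""
        pen = strong_three_class_model()
        G = simulate_genotypes(100_000, 2, 0.5, seed=5)
        y = simulate_categorical_phenotype(G, (0, 1), pen, seed=6)
        expected = genotype_cell_probs((0.5, 0.5)) @ pen.table
        observed = np.bincount(y, minlength=4)[1:]
        gof = stats.chisquare(observed, expected * 100_000)
        assert gof.pvalue > 0.01

    def test_constant_penetrance_gives_near_zero_causal_gids(self):
        from gidscan import compute_gids, build_contingency_table

        pen = CategoricalPenetrance(
            table=np.tile([0.3, 0.4, 0.3], (9, 1)), prevalence=(0.3, 0.4, 0.3)
        )
        G = simulate_genotypes(20_000, 2, 0.5, seed=7)
        y = simulate_categorical_phenotype(G, (0, 1), pen, seed=8)
        assert compute_gids(build_contingency_table(G, (0, 1), y)) < 0.05


class TestQuantitativeTrait:
    def test_flat_table_with_zero_alpha_is_pure_noise(self):
        model = QuantPenetranceModel(
            f=np.full((3, 3), 2.0), sigma_L=1.0, sigma_H=1.0, alpha=0.0,
            mafs=(0.3, 0.3),
        )
        G = simulate_genotypes(50_000, 2, 0.3, seed=9)
        y = simulate_quantitative_phenotype(G, (0, 1), model, seed=10)
        assert y.mean() == pytest.approx(2.0, abs=0.02)
        assert y.std() == pytest.approx(1.0, abs=0.02)

    def test_high_cell_moments_match_the_mixture_closed_form(self):
        """Mixture cells: mean f_ij, variance sigma_H^2 + alpha^2 = 1.16."""
        f = np.zeros((3, 3))
        f[2, 2] = 1.5  # the only high-mean cell
        model = QuantPenetranceModel(
            f=f, sigma_L=0.8, sigma_H=1.0, alpha=0.4, mafs=(0.5, 0.5)
        )
        G = np.full((200_000, 2), 2, dtype=int)  # every sample in cell (2,2)
        y = simulate_quantitative_phenotype(G, (0, 1), model, seed=11)
        assert y.mean() == pytest.approx(1.5, abs=0.02)
        assert y.var() == pytest.approx(1.0**2 + 0.4**2, rel=0.02)

    def test_low_cell_uses_the_narrow_normal(self):
        f = np.zeros((3, 3))
        f[0, 0] = -1.0
        model = QuantPenetranceModel(
            f=f, sigma_L=0.8, sigma_H=1.2, alpha=0.4, mafs=(0.5, 0.5)
        )
        G = np.zeros((200_000, 2), dtype=int)
        y = simulate_quantitative_phenotype(G, (0, 1), model, seed=12)
        assert y.mean() == pytest.approx(-1.0, abs=0.02)
        assert y.var() == pytest.approx(0.8**2, rel=0.02)

    def test_heritability_scaling_hits_its_target(self):
        for h2 in (0.01, 0.05, 0.1, 0.2, 0.4):
            model = model_from_heritability(xor_pattern(), h2, mafs=(0.2, 0.4))
            assert model.heritability() == pytest.approx(h2, rel=1e-9)

    def test_weighted_fbar_differs_from_unweighted_for_skewed_mafs(self):
        model_w = QuantPenetranceModel(
            f=xor_pattern(), sigma_L=1, sigma_H=1, alpha=0.4, mafs=(0.2, 0.2)
        )
        model_u = QuantPenetranceModel(
            f=xor_pattern(), sigma_L=1, sigma_H=1, alpha=0.4, mafs=(0.2, 0.2),
            fbar_mode="unweighted",
        )
        assert model_w.fbar != pytest.approx(model_u.fbar)


class TestCategorizeTrait:
    def test_three_class_thresholds(self):
        y = np.array([-1.0, 0.0, 1.0, -0.2, 0.2])
        y = (y - y.mean()) / y.std(ddof=1)  # standardized trait
        classes = categorize_trait(np.array([-1.0, 0.0, 1.0]) * 10, 3)
        np.testing.assert_array_equal(classes, [1, 2, 3])

    def test_two_class_split_at_the_mean(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        np.testing.assert_array_equal(categorize_trait(y, 2), [1, 1, 2, 2])

    def test_boundary_value_joins_the_upper_class(self):
        # symmetric trait: the J=4 middle threshold is exactly the mean
        y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        classes = categorize_trait(y, 4)
        assert classes[2] == 3

    @pytest.mark.parametrize(
        "J, expected",
        [
            (2, [0.5, 0.5]),
            (3, [stats.norm.cdf(-0.43), stats.norm.cdf(0.43) - stats.norm.cdf(-0.43),
                 stats.norm.sf(0.43)]),
            (4, [stats.norm.cdf(-0.67), 0.5 - stats.norm.cdf(-0.67),
                 stats.norm.cdf(0.67) - 0.5, stats.norm.sf(0.67)]),
        ],
    )
    def test_class_proportions_on_a_large_normal_sample(self, J, expected):
        y = np.random.default_rng(13).normal(5.0, 2.0, size=100_000)
        classes = categorize_trait(y, J)
        props = np.bincount(classes, minlength=J + 1)[1:] / y.size
        np.testing.assert_allclose(props, expected, atol=0.01)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            categorize_trait(np.ones(10), 2)


class TestNullDataset:
    def test_reproducible_and_independent_of_genotype(self):
        G1, y1 = simulate_null_dataset(400, 20, 0.2, seed=14)
        G2, y2 = simulate_null_dataset(400, 20, 0.2, seed=14)
        np.testing.assert_array_equal(G1, G2)
        np.testing.assert_array_equal(y1, y2)

    def test_categorical_null_matches_prevalence(self):
        _, y = simulate_null_dataset(
            50_000, 2, 0.3, trait_kind="categorical",
            prevalence=(0.3, 0.4, 0.3), seed=15,
        )
        freqs = np.bincount(y, minlength=4)[1:] / 50_000
        np.testing.assert_allclose(freqs, (0.3, 0.4, 0.3), atol=0.01)

    def test_every_pair_has_small_gids_at_large_n(self):
        from gidscan import scan_order, categorize_trait

        G, trait = simulate_null_dataset(8_000, 6, 0.3, seed=16)
        res = scan_order(G, categorize_trait(trait, 3), order=2)
        assert res.gids.max() < 0.1


class TestBloodPressure:
    # the full 9-band grid: (sbp, dbp) representative -> (class, label)
    GRID = [
        (115, 75, 1, "normal"),
        (115, 85, 2, "prehypertension"),
        (115, 95, 3, "hypertension"),
        (130, 75, 4, "prehypertension"),
        (130, 85, 5, "prehypertension"),
        (130, 95, 6, "hypertension"),
        (145, 75, 7, "hypertension"),
        (145, 85, 8, "hypertension"),
        (145, 95, 9, "hypertension"),
    ]

    @pytest.mark.parametrize("sbp, dbp, cls, label", GRID)
    def test_all_nine_bands(self, sbp, dbp, cls, label):
        got_cls, got_label = classify_blood_pressure(sbp, dbp)
        assert (got_cls, got_label) == (cls, label)

    def test_band_edges_are_left_closed(self):
        assert classify_blood_pressure(120, 79)[0] == 4
        assert classify_blood_pressure(140, 90)[0] == 9

    def test_vectorized_matches_scalars(self):
        sbp = np.array([g[0] for g in self.GRID])
        dbp = np.array([g[1] for g in self.GRID])
        classes, labels = classify_blood_pressure(sbp, dbp)
        np.testing.assert_array_equal(classes, [g[2] for g in self.GRID])
        np.testing.assert_array_equal(labels, [g[3] for g in self.GRID])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_blood_pressure(np.nan, 80)


class TestComposePhenotypes:
    def test_two_three_class_components_make_nine_states(self):
        a = np.array([1, 2, 3, 3])
        b = np.array([1, 1, 2, 3])
        composite = compose_phenotypes([a, b], n_classes=[3, 3])
        np.testing.assert_array_equal(composite, [1, 4, 8, 9])
        assert composite.max() <= 9

    def test_worked_index(self):
        assert compose_phenotypes([[2], [1]], n_classes=[3, 3])[0] == 4

    def test_single_component_is_identity(self):
        v = np.array([2, 1, 3])
        np.testing.assert_array_equal(compose_phenotypes([v]), v)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compose_phenotypes([])

    def test_composite_agrees_with_bp_classifier(self):
        """SBP/DBP band composition reproduces the 9-class JNC7 grid."""
        sbp = np.array([115, 115, 130, 145, 145], dtype=float)
        dbp = np.array([75, 95, 85, 75, 95], dtype=float)
        sband = 1 + np.digitize(sbp, [120, 140])
        dband = 1 + np.digitize(dbp, [80, 90])
        composite = compose_phenotypes([sband, dband], n_classes=[3, 3])
        classes, _ = classify_blood_pressure(sbp, dbp)
        np.testing.assert_array_equal(composite, classes)
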