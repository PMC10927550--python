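import dendropy
import numpy as np
import pandas as pd
import pytest

from alpshift.diversity import (
    cell_metrics,
    distinctiveness_restrictedness,
    endemism,
    hill_q1_taxonomic,
    hill_q1_tree,
    rarity,
    relative_metric,
    uniqueness_weights,
)
from alpshift.trees import FeatureTree, gower_distance


@pytest.fixture
def balanced_tree():
    # ((A:1,B:1):1,(C:1,D:1):1);
    return FeatureTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


class TestHillTaxonomic:
    @pytest.mark.parametrize(
        "shares, expected",
        [
            ([0.5, 0.5], 2.0),
            ([1.0], 1.0),
            ([0.7, 0.2, 0.1], 2.2295918739204166),  # exp(Shannon) computed directly
        ],
    )
    def test_examples(self, shares, expected):
        assert hill_q1_taxonomic(np.array(shares)) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.random(6) + 1e-6
            td = hill_q1_taxonomic(x)
            assert td == pytest.approx(hill_q1_taxonomic(10.0 * x))
            assert 1.0 <= td <= 6.0 + 1e-12

    def test_empty_cell_is_nan(self):
        assert np.isnan(hill_q1_taxonomic(np.zeros(3)))


class TestHillTree:
    def test_star_tree_collapses_to_taxonomic(self):
        star = FeatureTree.star(["a", "b", "c"], 1.0)
        x = np.array([0.5, 0.3, 0.2])
        assert hill_q1_tree(x, star) == pytest.approx(hill_q1_taxonomic(x), abs=1e-10)

    def test_single_species_gives_root_to_tip_length(self, balanced_tree):
        x = np.zeros(4)
        x[balanced_tree.species.index("A")] = 5.0
        # A's path to the root is 1 + 1 = 2
        assert hill_q1_tree(x, balanced_tree) == pytest.approx(2.0)

    def test_branch_length_doubling_doubles_pd(self, balanced_tree):
        x = np.array([0.4, 0.1, 0.3, 0.2])
        doubled = FeatureTree(
            balanced_tree.species,
            2.0 * balanced_tree.lengths,
            balanced_tree.membership,
        )
        assert hill_q1_tree(x, doubled) == pytest.approx(
            2.0 * hill_q1_tree(x, balanced_tree), rel=1e-12
        )

    def test_against_dendropy_patristic_distances(self):
        """Tree flattening agrees with dendropy's independent path lengths."""
        newick = "((A:0.5,B:1.5):0.7,(C:0.2,(D:0.9,E:0.4):0.3):1.1);"
        ft = FeatureTree.from_newick(newick)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        ours = ft.pairwise_distances()
        for i, a in enumerate(ft.species):
            for j, b in enumerate(ft.species):
                assert ours[i, j] == pytest.approx(
                    pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-12
                )


class TestRelativeMetric:
    def test_exact_quadratic_gives_zero_residuals(self):
        x = np.linspace(0, 3, 50)
        y = 1.0 + 2.0 * x - 0.5 * x**2
        res = relative_metric(y, x)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        y = rng.random(100)
        assert relative_metric(y, x).sum() == pytest.approx(0.0, abs=1e-9)

    def test_planted_noise_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.random(500) * 4
        sigma = 0.3
        noise = rng.normal(0, sigma, 500)
        y = 2.0 + x + noise
        res = relative_metric(y, x)
        rms = np.sqrt(np.mean(res**2))
        assert abs(rms - sigma) / sigma < 0.10

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_metric(np.ones(3), np.arange(3.0))
        with pytest.raises(ValueError):
            relative_metric(np.arange(5.0), np.ones(5))


class TestEndemism:
    def test_single_cell_species_contributes_one(self):
        A = np.array([[1.0, 0.5], [0.0, 0.5]])  # species 0 confined to cell 0
        we = endemism(A)
        assert we[0] == pytest.approx(1.0 + 0.5)
        assert we[1] == pytest.approx(0.5)

    def test_uniform_species_give_constant_s_over_n(self):
        A = np.full((4, 3), 0.2)
        np.testing.assert_allclose(endemism(A), 3 / 4)

    def test_two_tip_star_worked_example(self):
        star = FeatureTree.star(["A", "B"], 1.0)
        A = np.array([[1.0, 0.5], [0.0, 0.5]])
        pe = endemism(A, star)
        np.testing.assert_allclose(pe, [1.5, 0.5])
        assert pe.sum() == pytest.approx(star.total_length)

    def test_conservation_identities_on_random_cubes(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            n_cells, n_sp = int(rng.integers(4, 30)), int(rng.integers(2, 8))
            A = rng.random((n_cells, n_sp)) * (rng.random((n_cells, n_sp)) < 0.6)
            A[0] += 1e-3  # ensure every species occupies at least one cell
            tree = FeatureTree.from_traits(
                pd.DataFrame(
                    rng.normal(size=(n_sp, 4)), index=[f"s{i}" for i in range(n_sp)]
                )
            )
            we = endemism(A)
            pe = endemism(A, tree)
            assert we.sum() == pytest.approx(n_sp, rel=1e-9)
            assert pe.sum() == pytest.approx(tree.total_length, rel=1e-9)

    def test_star_tree_pe_equals_we(self):
        rng = np.random.default_rng(4)
        A = rng.random((6, 4)) + 0.01
        star = FeatureTree.star(["a", "b", "c", "d"], 1.0)
        np.testing.assert_allclose(endemism(A, star), endemism(A), atol=1e-10)

    def test_label_permutation_invariance(self, balanced_tree):
        rng = np.random.default_rng(5)
        A = rng.random((5, 4)) + 0.01
        perm = [2, 0, 3, 1]
        species_perm = [balanced_tree.species[i] for i in perm]
        tree_perm = balanced_tree.reindex(species_perm)
        np.testing.assert_allclose(
            endemism(A, balanced_tree), endemism(A[:, perm], tree_perm), atol=1e-12
        )


class TestRarity:
    def test_identical_species_zero_rarity(self):
        star = FeatureTree.star(["a", "b", "c"], 0.0)  # zero distances
        A = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        np.testing.assert_allclose(rarity(A, star), 0.0)

    def test_ubiquitous_species_contributes_nothing(self):
        star = FeatureTree.star(["a", "b"], 1.0)
        A = np.array([[1.0, 1.0], [1.0, 0.0]])  # species a occupies every cell
        dist, R = distinctiveness_restrictedness(A, star)
        assert R[0] == 0.0
        scores = rarity(A, star)
        # cell 1 holds only the ubiquitous species -> zero rarity there
        assert scores[1] == pytest.approx(0.0)

    def test_three_species_hand_computed(self):
        # chain tree A-B close, C distant
        ft = FeatureTree.from_newick("((A:1,B:1):2,C:3);")
        A = np.array(
            [
                [2.0, 0.0, 1.0],
                [0.0, 1.0, 1.0],
                [0.0, 0.0, 0.0],
            ]
        )
        d = ft.pairwise_distances()
        dmax = d.max()
        dist = d.sum(axis=1) / 2 / dmax
        occ = (A > 0).sum(axis=0)
        R = 1 - occ / 3
        score = dist * R
        expected0 = (2 * score[0] + 1 * score[2]) / 3.0
        expected1 = (1 * score[1] + 1 * score[2]) / 2.0
        out = rarity(A, ft)
        assert out[0] == pytest.approx(expected0)
        assert out[1] == pytest.approx(expected1)
        assert np.isnan(out[2])

    def test_single_species_rejected(self):
        one = FeatureTree.star(["a"], 1.0)
        with pytest.raises(ValueError):
            rarity(np.array([[1.0]]), one)


class TestUniquenessWeights:
    def test_uniform_facets_give_two(self):
        star = FeatureTree.star(["a", "b", "c"], 1.0)
        A = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        w = uniqueness_weights(star, star, A)
        np.testing.assert_allclose(w, 2.0)

    def test_facet_scale_invariance(self, balanced_tree):
        rng = np.random.default_rng(6)
        A = (rng.random((6, 4)) < 0.5) * rng.random((6, 4))
        A[0] += 0.01
        func = FeatureTree(
            balanced_tree.species, balanced_tree.lengths.copy(), balanced_tree.membership, "functional"
        )
        w1 = uniqueness_weights(balanced_tree, func, A)
        doubled = FeatureTree(
            balanced_tree.species, 2.0 * balanced_tree.lengths, balanced_tree.membership, "functional"
        )
        w2 = uniqueness_weights(balanced_tree, doubled, A)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_degenerate_tree_warns_uniform(self):
        flat = FeatureTree.star(["a", "b"], 0.0)
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            w = uniqueness_weights(flat, flat, A)
        np.testing.assert_allclose(w, 2.0)


class TestFunctionalTree:
    def test_gower_is_range_normalized_manhattan(self):
        df = pd.DataFrame({"t1": [0.0, 1.0, 2.0], "t2": [0.0, 0.0, 4.0]}, index=list("abc"))
        d = gower_distance(df)
        assert d[0, 1] == pytest.approx((0.5 + 0.0) / 2)
        assert d[0, 2] == pytest.approx((1.0 + 1.0) / 2)

    def test_upgma_tree_is_ultrametric(self):
        rng = np.random.default_rng(7)
        traits = pd.DataFrame(rng.normal(size=(8, 4)), index=[f"s{i}" for i in range(8)])
        ft = FeatureTree.from_traits(traits)
        depths = ft.root_to_tip()
        np.testing.assert_allclose(depths, depths[0], atol=1e-10)
        assert ft.kind == "functional"


def test_cell_metrics_frame_is_complete(balanced_tree):
    rng = np.random.default_rng(8)
    A = rng.random((30, 4)) * (rng.random((30, 4)) < 0.7)
    A[:4] += 0.05
    func = FeatureTree.from_traits(
        pd.DataFrame(rng.normal(size=(4, 4)), index=balanced_tree.species)
    )
    df = cell_metrics(A, balanced_tree, func)
    assert list(df.columns) == [
        "TD", "PD", "FD", "rPD", "rFD", "WE", "PE", "FE", "rPE", "rFE", "PR", "FR",
    ]
    occupied = A.sum(axis=1) > 0
    assert np.isfinite(df.loc[occupied, "TD"]).all()
    assert (df.loc[occupied, "TD"] >= 1.0 - 1e-12).all()
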