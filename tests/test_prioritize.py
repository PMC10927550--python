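import numpy as np
import pytest

from alpshift.prioritize import (
    FeatureMatrix,
    expansion_overlap,
    performance_curves,
    rank_abf,
    rank_caz,
)


def reference_removal_order(values, weights, algorithm, z=0.25, pa=None):
    """From-scratch greedy ranker: plain Python loops, no incremental state.

    Recomputes every cell's marginal loss from the full remaining matrix
    at every step; used as the independent oracle for both rules.
    """
    values = np.asarray(values, dtype=float)
    n_cells, n_feat = values.shape
    totals = values.sum(axis=0)
    removed = []
    remaining = set(range(n_cells))
    if pa is None:
        strata = [set(remaining)]
    else:
        strata = [
            {i for i in remaining if not pa[i]},
            {i for i in remaining if pa[i]},
        ]
    for stratum in strata:
        while stratum:
            rem_tot = [sum(values[i, j] for i in remaining) for j in range(n_feat)]
            best_cell, best_delta = None, None
            for i in sorted(stratum):
                if algorithm == "caz":
                    delta = max(
                        weights[j] * (values[i, j] / rem_tot[j] if rem_tot[j] > 0 else 0.0)
                        for j in range(n_feat)
                    )
                else:
                    delta = 0.0
                    for j in range(n_feat):
                        R = rem_tot[j] / totals[j]
                        q = values[i, j] / totals[j]
                        delta += weights[j] * (R**z - max(R - q, 0.0) ** z)
                if best_delta is None or delta < best_delta - 1e-12:
                    best_cell, best_delta = i, delta
            removed.append(best_cell)
            stratum.discard(best_cell)
            remaining.discard(best_cell)
    return removed


class TestCAZ:
    def test_three_cell_worked_example(self):
        F = FeatureMatrix(np.array([[0.8, 0.1], [0.2, 0.1], [0.0, 0.8]]))
        r = rank_caz(F)
        assert list(r.removal_order) == [1, 2, 0]  # cell2, cell3, cell1
        np.testing.assert_allclose(r.rank, [1.0, 1 / 3, 2 / 3])

    def test_single_feature_orders_by_value(self):
        rng = np.random.default_rng(0)
        vals = rng.random((8, 1)) + 0.01
        r = rank_caz(FeatureMatrix(vals))
        assert list(np.argsort(r.rank)) == list(np.argsort(vals[:, 0]))

    def test_duplicated_features_leave_ranks_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.random((6, 3))
        vals[0] += 0.01
        r1 = rank_caz(FeatureMatrix(vals))
        r2 = rank_caz(FeatureMatrix(np.hstack([vals, vals])))
        np.testing.assert_array_equal(r1.removal_order, r2.removal_order)


class TestABF:
    def test_z_one_reduces_to_static_weighted_sum(self):
        rng = np.random.default_rng(2)
        for rep in range(50):
            n, m = int(rng.integers(3, 15)), int(rng.integers(1, 5))
            vals = rng.random((n, m))
            vals[0] += 0.01
            w = rng.random(m) + 0.1
            F = FeatureMatrix(vals.copy(), w.copy())
            r = rank_abf(F, z=1.0)
            static = (vals / vals.sum(axis=0) * w).sum(axis=1)
            # state-independent benefit: removal order = ascending static score
            expected = sorted(range(n), key=lambda i: (static[i], i))
            assert list(r.removal_order) == expected

    def test_single_feature_matches_caz_order(self):
        rng = np.random.default_rng(3)
        vals = rng.random((7, 1)) + 0.01
        a = rank_abf(FeatureMatrix(vals.copy()))
        c = rank_caz(FeatureMatrix(vals.copy()))
        np.testing.assert_array_equal(a.removal_order, c.removal_order)

    def test_invalid_z(self):
        with pytest.raises(ValueError):
            rank_abf(FeatureMatrix(np.ones((2, 1))), z=0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("algorithm", ["caz", "abf"])
    def test_random_instances_match_reference(self, algorithm):
        rng = np.random.default_rng(4)
        ranker = rank_caz if algorithm == "caz" else rank_abf
        for rep in range(100):
            n_cells = int(rng.integers(3, 37))  # up to a 6x6 grid
            n_feat = int(rng.integers(1, 6))
            vals = np.round(rng.random((n_cells, n_feat)), 2)
            vals[rng.random(vals.shape) < 0.3] = 0.0
            vals[0] += 0.01  # keep every feature represented
            w = np.round(rng.random(n_feat), 2) + 0.1
            F = FeatureMatrix(vals.copy(), w.copy())
            got = list(ranker(F).removal_order)
            want = reference_removal_order(vals, w, algorithm)
            assert got == want, f"{algorithm} mismatch on instance {rep}"

    def test_weight_scaling_leaves_ranks_unchanged(self):
        rng = np.random.default_rng(5)
        vals = rng.random((10, 3)) + 0.01
        w = rng.random(3) + 0.1
        r1 = rank_caz(FeatureMatrix(vals.copy(), w.copy()))
        r2 = rank_caz(FeatureMatrix(vals.copy(), 7.5 * w))
        np.testing.assert_array_equal(r1.removal_order, r2.removal_order)
        a1 = rank_abf(FeatureMatrix(vals.copy(), w.copy()))
        a2 = rank_abf(FeatureMatrix(vals.copy(), 7.5 * w))
        np.testing.assert_array_equal(a1.removal_order, a2.removal_order)


class TestExpansionMode:
    def test_empty_mask_equals_selection(self):
        rng = np.random.default_rng(6)
        vals = rng.random((9, 2)) + 0.01
        sel = rank_caz(FeatureMatrix(vals.copy()))
        exp = rank_caz(FeatureMatrix(vals.copy()), np.zeros(9, bool), mode="expansion")
        np.testing.assert_array_equal(sel.removal_order, exp.removal_order)

    def test_pa_cells_outrank_all_free_cells(self):
        rng = np.random.default_rng(7)
        vals = rng.random((12, 3)) + 0.01
        pa = rng.random(12) < 0.4
        if not pa.any() or pa.all():
            pa[0], pa[1] = True, False
        r = rank_caz(FeatureMatrix(vals), pa, mode="expansion")
        assert r.rank[pa].min() > r.rank[~pa].max()

    def test_expansion_preserves_free_cell_relative_order_single_feature(self):
        rng = np.random.default_rng(8)
        vals = rng.random((9, 1)) + 0.01
        pa = np.zeros(9, bool)
        pa[[2, 5]] = True
        r = rank_caz(FeatureMatrix(vals.copy()), pa, mode="expansion")
        want = reference_removal_order(vals, np.ones(1), "caz", pa=pa)
        assert list(r.removal_order) == want
        free = np.nonzero(~pa)[0]
        # relative order among free cells follows their feature value
        order = sorted(free, key=lambda i: r.rank[i])
        assert order == sorted(free, key=lambda i: vals[i, 0])

    def test_single_free_cell_gets_lowest_rank(self):
        vals = np.ones((5, 1))
        pa = np.array([True, True, False, True, True])
        r = rank_caz(FeatureMatrix(vals), pa, mode="expansion")
        assert r.rank[2] == pytest.approx(1 / 5)

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError, match="nothing to expand"):
            rank_caz(FeatureMatrix(np.ones((3, 1))), np.ones(3, bool), mode="expansion")


class TestPerformanceCurves:
    def test_endpoints(self):
        rng = np.random.default_rng(9)
        vals = rng.random((10, 2)) + 0.01
        F = FeatureMatrix(vals)
        r = rank_caz(F)
        curves = performance_curves(r, F, fractions=np.array([0.0, 1.0]))
        at0 = curves[curves.fraction == 0.0]
        at1 = curves[curves.fraction == 1.0]
        assert (at0.representation == 0.0).all()
        np.testing.assert_allclose(at1.representation, 1.0)

    def test_point_feature_step_curve(self):
        vals = np.ones((5, 1)) * 0.1
        point = np.zeros(5)
        point[3] = 1.0
        F = FeatureMatrix(np.column_stack([vals[:, 0]]))
        r = rank_caz(F)
        curves = performance_curves(
            r, F, fractions=np.linspace(0, 1, 6), extra_layers={"point": point}
        )
        pc = curves[curves.feature == "point"].sort_values("fraction")
        jump_at = 1.0 - r.rank[3]
        reps = pc.representation.to_numpy()
        fracs = pc.fraction.to_numpy()
        # inclusion rule is rank > 1 - f: the jump happens strictly above jump_at
        assert ((reps == 1.0) == (fracs > jump_at + 1e-9)).all()

    def test_mean_species_curve_monotone(self):
        rng = np.random.default_rng(10)
        vals = rng.random((20, 4)) * (rng.random((20, 4)) < 0.7)
        vals[0] += 0.01
        F = FeatureMatrix(vals)
        r = rank_abf(F)
        curves = performance_curves(r, F)
        mean = curves[curves.feature == "mean_species"].sort_values("fraction")
        assert (np.diff(mean.representation) >= -1e-12).all()
        assert mean.representation.iloc[-1] == pytest.approx(1.0)


class TestExpansionOverlap:
    def make_ranks(self, orders, pa):
        n = len(pa)
        ranks = {}
        for name, order in orders.items():
            rank = np.empty(n)
            rank[np.asarray(order)] = (np.arange(n) + 1) / n
            ranks[name] = type(
                "R", (), {"rank": rank, "mode": "expansion", "pa_mask": pa}
            )()
        return ranks

    def test_identical_ranks_perfect_overlap(self):
        rng = np.random.default_rng(11)
        vals = rng.random((20, 2)) + 0.01
        pa = np.zeros(20, bool)
        pa[:5] = True
        r = rank_caz(FeatureMatrix(vals), pa, mode="expansion")
        counts, summary = expansion_overlap({"a": r, "b": r, "c": r}, pa, top=0.2)
        n_top = round(0.2 * 15)
        assert (counts == 3).sum() == n_top
        assert summary["protected_fraction_after"] == pytest.approx(
            (5 + n_top) / 20
        )

    def test_disjoint_top_sets_expand_nothing(self):
        from alpshift.prioritize import PriorityRank

        pa = np.zeros(15, bool)
        n = 15
        ranks = {}
        # three rankings whose top-3 free sets are pairwise disjoint
        for k, top_cells in enumerate([[0, 1, 2], [3, 4, 5], [6, 7, 8]]):
            rank = np.linspace(1 / n, 0.6, n)
            rank[top_cells] = [0.9, 0.95, 1.0]
            ranks[f"s{k}"] = PriorityRank(rank, "CAZ", "expansion", pa)
        counts, summary = expansion_overlap(ranks, pa, top=0.2)
        assert (counts >= 2).sum() == 0
        assert summary["protected_fraction_after"] == summary["protected_fraction_before"]

    def test_pairwise_shared_cells_count_two(self):
        from alpshift.prioritize import PriorityRank

        pa = np.zeros(10, bool)
        n = 10
        base = np.linspace(1 / n, 0.5, n)

        def with_top(cells):
            r = base.copy()
            r[cells] = [0.9, 1.0]
            return PriorityRank(r, "CAZ", "expansion", pa)

        ranks = {"a": with_top([0, 1]), "b": with_top([1, 2]), "c": with_top([3, 4])}
        counts, _ = expansion_overlap(ranks, pa, top=0.2)
        assert counts[1] == 2
        assert (counts >= 2).sum() == 1

    def test_selection_mode_rejected(self):
        r = rank_caz(FeatureMatrix(np.ones((4, 1))))
        with pytest.raises(ValueError):
            expansion_overlap({"a": r}, np.zeros(4, bool))
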