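import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from trophograd import gradient_partitioning as gp
from trophograd.core_data import DistanceMatrix


def euclidean_dm(y):
    y = np.asarray(y, dtype=float)
    return DistanceMatrix([f"s{i}" for i in range(len(y))],
                          squareform(pdist(y)), "euclidean")


def direct_rda_r2(y, x):
    """Independent oracle: redundancy-analysis R^2 by least squares on the
    raw centered response."""
    y = np.asarray(y, dtype=float)
    y = y - y.mean(axis=0, keepdims=True)
    design = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    return (fitted**2).sum() / (y**2).sum()


class TestVifPrune:
    def test_duplicate_column_removed(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(30)})
        pruned, removed = gp.vif_prune(X)
        assert len(removed) == 1
        assert removed[0] in ("a", "b")
        assert pruned.shape[1] == 2

    def test_orthogonal_columns_kept(self):
        n = 16
        X = pd.DataFrame({
            "a": np.tile([1.0, -1.0], n // 2),
            "b": np.repeat([1.0, -1.0], n // 2),
        })
        pruned, removed = gp.vif_prune(X)
        assert removed == []

    def test_near_collinear_triad(self, rng):
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40)
        x3 = x1 + x2 + 1e-4 * rng.standard_normal(40)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        pruned, removed = gp.vif_prune(X)
        assert len(removed) == 1
        # oracle: after removing any one of the triad, remaining VIFs < 10
        x = pruned.to_numpy()
        for j in range(2):
            assert gp._vif(x, j) < 10


class TestDbrda:
    def test_perfect_fit(self, rng):
        x = rng.standard_normal((20, 1))
        y = 2.0 * x
        res = gp.dbrda(euclidean_dm(y), pd.DataFrame(x), n_perm=0)
        assert res.R2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_rda_oracle(self, rng):
        # multivariate response, Euclidean distances
        for trial in range(5):
            r = np.random.default_rng(trial)
            y = r.standard_normal((25, 4))
            x = r.standard_normal((25, 3))
            res = gp.dbrda(euclidean_dm(y), pd.DataFrame(x), n_perm=0)
            assert res.R2 == pytest.approx(direct_rda_r2(y, x), abs=1e-10)

    def test_adjusted_r2_ezekiel(self, rng):
        y = rng.standard_normal((25, 3))
        x = rng.standard_normal((25, 2))
        res = gp.dbrda(euclidean_dm(y), pd.DataFrame(x), n_perm=0)
        expected = 1.0 - (1.0 - res.R2) * 24 / (25 - 2 - 1)
        assert res.adj_R2 == pytest.approx(expected, abs=1e-12)

    def test_permutation_p_reproducible(self, rng):
        y = rng.standard_normal((18, 3))
        x = rng.standard_normal((18, 2))
        d = euclidean_dm(y)
        a = gp.dbrda(d, pd.DataFrame(x), n_perm=99, seed=4)
        b = gp.dbrda(d, pd.DataFrame(x), n_perm=99, seed=4)
        assert a.p == b.p
        assert 0.0 < a.p <= 1.0

    def test_saturated_error(self, rng):
        y = rng.standard_normal((6, 2))
        x = rng.standard_normal((6, 5))
        with pytest.raises(ValueError, match="saturated"):
            gp.dbrda(euclidean_dm(y), pd.DataFrame(x), n_perm=0)


class TestHierarchicalPartition:
    def test_single_group_equals_full_model(self, rng):
        y = rng.standard_normal((25, 3))
        X = pd.DataFrame(rng.standard_normal((25, 2)), columns=["a", "b"])
        d = euclidean_dm(y)
        effects, total = gp.hierarchical_partition(d, X, {"g": ["a", "b"]})
        full = gp.dbrda(d, X, n_perm=0).adj_R2
        assert effects["g"] == pytest.approx(full, abs=1e-12)
        assert total == pytest.approx(full, abs=1e-12)

    def test_effects_sum_to_total(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            y = r.standard_normal((30, 3))
            X = pd.DataFrame(r.standard_normal((30, 6)),
                             columns=list("abcdef"))
            groups = {"g1": ["a", "b"], "g2": ["c"], "g3": ["d", "e"],
                      "g4": ["f"]}
            effects, total = gp.hierarchical_partition(euclidean_dm(y), X,
                                                       groups)
            assert sum(effects.values()) == pytest.approx(total, abs=1e-9)

    def test_orthogonal_groups_marginal_effects(self):
        """Orthogonal design columns: each group's independent effect equals
        its marginal contribution.

        The identity is exact on raw R^2; on Ezekiel-adjusted R^2 the
        parameter-count penalties differ between nested models, leaving an
        O(1/n) gap, so the adjusted comparison uses a 10/n tolerance.
        """
        n = 240
        h = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1],
                      [1, -1, -1, 1]], dtype=float)
        cols = np.kron(np.ones((n // 4, 1)), h[:, 1:])  # 3 orthogonal columns
        rng = np.random.default_rng(0)
        y = (cols @ np.array([[1.0, 0.5, 0.2]]).T
             + 0.1 * rng.standard_normal((n, 1)))
        X = pd.DataFrame(cols, columns=["a", "b", "c"])
        d = euclidean_dm(y)
        groups = {"g1": ["a"], "g2": ["b"], "g3": ["c"]}
        effects, total = gp.hierarchical_partition(d, X, groups)
        # exact identity on raw R^2 (independent least-squares oracle)
        r2_full = direct_rda_r2(y, cols)
        r2_marginals = [direct_rda_r2(y, cols[:, [j]]) for j in range(3)]
        assert sum(r2_marginals) == pytest.approx(r2_full, abs=1e-9)
        for g, marginal_col in zip(groups, ["a", "b", "c"]):
            marginal = gp.dbrda(d, X[[marginal_col]], n_perm=0).adj_R2
            assert effects[g] == pytest.approx(marginal, abs=10.0 / n)

    def test_label_permutation_invariance(self, rng):
        y = rng.standard_normal((25, 2))
        X = pd.DataFrame(rng.standard_normal((25, 4)), columns=list("abcd"))
        d = euclidean_dm(y)
        g1 = {"p": ["a", "b"], "q": ["c"], "r": ["d"]}
        g2 = {"r": ["d"], "q": ["c"], "p": ["a", "b"]}
        e1, _ = gp.hierarchical_partition(d, X, g1)
        e2, _ = gp.hierarchical_partition(d, X, g2)
        for k in e1:
            assert e1[k] == pytest.approx(e2[k], abs=1e-12)

    def test_overlapping_groups_rejected(self, rng):
        y = rng.standard_normal((20, 2))
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            gp.hierarchical_partition(euclidean_dm(y), X,
                                      {"g1": ["a"], "g2": ["a", "b"]})


class TestVariationPartition:
    def test_orthogonal_groups_no_shared(self):
        n = 240
        h = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1],
                      [1, -1, -1, 1]], dtype=float)
        cols = np.kron(np.ones((n // 4, 1)), h[:, 1:])
        rng = np.random.default_rng(1)
        y = cols @ np.diag([1.0, 0.8, 0.6]) @ np.ones((3, 1)) \
            + 0.05 * rng.standard_normal((n, 1))
        X = pd.DataFrame(cols, columns=["a", "b", "c"])
        out = gp.variation_partition(euclidean_dm(y), X,
                                     {"g1": ["a"], "g2": ["b"], "g3": ["c"]})
        for key in ("shared_g1_g2", "shared_g1_g3", "shared_g2_g3",
                    "shared_all"):
            assert abs(out[key]) < 0.02

    def test_duplicated_signal_is_shared(self, rng):
        n = 40
        z = rng.standard_normal(n)
        y = z[:, None] + 0.05 * rng.standard_normal((n, 1))
        X = pd.DataFrame({
            "a": z + 0.01 * rng.standard_normal(n),
            "b": z + 0.01 * rng.standard_normal(n),
            "c": rng.standard_normal(n),
        })
        out = gp.variation_partition(euclidean_dm(y), X,
                                     {"g1": ["a"], "g2": ["b"], "g3": ["c"]})
        assert out["shared_g1_g2"] > 0.8
        assert out["unique_g1"] < 0.1
        assert out["unique_g2"] < 0.1

    def test_wrong_group_count(self, rng):
        y = rng.standard_normal((10, 2))
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="exactly 3"):
            gp.variation_partition(euclidean_dm(y), X,
                                   {"g1": ["a"], "g2": ["b"]})


class TestMovingWindow:
    def make_inputs(self, rng, n=24):
        gradient = np.sort(rng.uniform(19, 47, n))
        y = rng.standard_normal((n, 3))
        X = pd.DataFrame(rng.standard_normal((n, 3)),
                         columns=["MAT", "pH", "PB_edges"])
        groups = {"climatic": ["MAT"], "edaphic": ["pH"], "PB": ["PB_edges"]}
        return euclidean_dm(y), X, groups, gradient

    def test_window_count(self, rng):
        d, X, groups, gradient = self.make_inputs(rng)
        windows = gp.moving_window(d, X, groups, gradient, window_size=10)
        assert len(windows) == 24 - 10 + 1

    def test_full_window_equals_whole_dataset(self, rng):
        d, X, groups, gradient = self.make_inputs(rng)
        windows = gp.moving_window(d, X, groups, gradient, window_size=24)
        assert len(windows) == 1
        effects, total = gp.hierarchical_partition(d, X, groups)
        assert windows[0].total_adj_R2 == pytest.approx(total, abs=1e-12)

    def test_window_membership(self, rng):
        d, X, groups, gradient = self.make_inputs(rng)
        windows = gp.moving_window(d, X, groups, gradient, window_size=10)
        order = np.argsort(gradient)
        expected = [d.ids[i] for i in order[1:11]]
        assert windows[1].member_sites == expected

    def test_centers_ordered(self, rng):
        d, X, groups, gradient = self.make_inputs(rng)
        windows = gp.moving_window(d, X, groups, gradient, window_size=12)
        centers = [w.center for w in windows]
        assert centers == sorted(centers)

    def test_oversized_window_error(self, rng):
        d, X, groups, gradient = self.make_inputs(rng)
        with pytest.raises(ValueError, match="exceeds"):
            gp.moving_window(d, X, groups, gradient, window_size=25)

    def test_effects_sum_within_each_window(self, rng):
        d, X, groups, gradient = self.make_inputs(rng)
        for w in gp.moving_window(d, X, groups, gradient, window_size=12):
            assert sum(w.independent_effects.values()) == pytest.approx(
                w.total_adj_R2, abs=1e-9)


class TestPlantedDriverRecovery:
    def test_climatic_driver_dominates(self):
        """When composition is driven by MAT only, the climatic group's
        independent effect is the largest of the four groups."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 40
            mat = np.sort(r.uniform(0, 15, n))
            y = np.column_stack([mat, mat**0.5]) \
                + 0.5 * r.standard_normal((n, 2))
            X = pd.DataFrame({
                "MAT": mat + 0.1 * r.standard_normal(n),
                "MAP": r.standard_normal(n),
                "pH": r.standard_normal(n),
                "C_N": r.standard_normal(n),
                "PB_edges": r.standard_normal(n),
                "VB_edges": r.standard_normal(n),
            })
            groups = {"climatic": ["MAT", "MAP"], "edaphic": ["pH", "C_N"],
                      "PB": ["PB_edges"], "VB": ["VB_edges"]}
            effects, _ = gp.hierarchical_partition(euclidean_dm(y), X, groups)
            if max(effects, key=effects.get) == "climatic":
                hits += 1
        assert hits >= round(0.9 * n_seeds)
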