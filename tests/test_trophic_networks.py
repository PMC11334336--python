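import numpy as np
import pytest
from scipy import stats

from trophograd import trophic_networks as tn
from trophograd.core_data import AsvTable


def table(counts, kingdom="bacteria", prefix="a"):
    counts = np.asarray(counts)
    return AsvTable([f"s{i}" for i in range(counts.shape[0])],
                    [f"{prefix}{j}" for j in range(counts.shape[1])],
                    counts, kingdom)


class TestSpearmanBlock:
    @staticmethod
    def _with_filler(col, total=100):
        # second ASV absorbs the remainder so relative abundance of the
        # first column stays proportional to the raw counts
        col = np.asarray(col)
        return np.column_stack([col, total - col])

    def test_monotone_rho_one(self):
        prey = table(self._with_filler([1, 2, 3, 4, 5]))
        pred = table(self._with_filler([2, 4, 8, 16, 32]), "protist", "p")
        blk = tn.spearman_block(prey, pred)
        assert blk.rho[0, 0] == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        prey = table(self._with_filler([1, 2, 3, 4, 5]))
        pred = table(self._with_filler([50, 40, 30, 20, 10]), "protist", "p")
        blk = tn.spearman_block(prey, pred)
        assert blk.rho[0, 0] == pytest.approx(-1.0)

    def test_average_rank_ties(self):
        # x=(1,2,2,4), y=(1,3,3,5): identical tie structure -> rho = 1
        prey = table(self._with_filler([1, 2, 2, 4]))
        pred = table(self._with_filler([1, 3, 3, 5]), "protist", "p")
        blk = tn.spearman_block(prey, pred)
        assert blk.rho[0, 0] == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        prey = table(rng.integers(0, 50, size=(20, 6)))
        pred = table(rng.integers(0, 50, size=(20, 4)), "protist", "p")
        blk = tn.spearman_block(prey, pred)
        ra_prey = prey.counts / prey.counts.sum(1, keepdims=True)
        ra_pred = pred.counts / pred.counts.sum(1, keepdims=True)
        for i in range(4):
            for j in range(6):
                expected = stats.spearmanr(ra_pred[:, i], ra_prey[:, j]).statistic
                assert blk.rho[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_warns_zero(self):
        prey = table([[1, 5], [2, 5], [3, 5], [4, 5]])
        pred = table([[1], [2], [1], [3]], "protist", "p")
        with pytest.warns(UserWarning, match="constant"):
            blk = tn.spearman_block(prey, pred)
        assert blk.rho[0, 1] == 0.0


class TestWignerReference:
    def test_surmise_closed_form_at_one(self):
        # (pi/2) * exp(-pi/4) evaluates to 0.71619 (independent arithmetic)
        assert tn.wigner_surmise(1.0) == pytest.approx(
            (np.pi / 2.0) * np.exp(-np.pi / 4.0))
        assert tn.wigner_surmise(1.0) == pytest.approx(0.71619, abs=1e-4)

    def test_poisson_at_zero(self):
        assert tn.poisson_spacing(0.0) == pytest.approx(1.0)

    def test_densities_integrate_to_one(self):
        u = np.linspace(0, 20, 200001)
        for dens in (tn.wigner_surmise, tn.poisson_spacing):
            assert np.trapezoid(dens(u), u) == pytest.approx(1.0, abs=1e-4)


class TestSymmetricEmbedding:
    def test_eigenvalues_are_plus_minus_singular_values(self, rng):
        b = rng.normal(size=(5, 8))
        embedded = np.block([[np.zeros((5, 5)), b],
                             [b.T, np.zeros((8, 8))]])
        eig = np.sort(np.linalg.eigvalsh(embedded))
        sv = np.sort(np.linalg.svd(b, compute_uv=False))
        np.testing.assert_allclose(eig[-5:], sv, atol=1e-10)       # +sigma
        np.testing.assert_allclose(eig[:5], -sv[::-1], atol=1e-10)  # -sigma
        np.testing.assert_allclose(eig[5:-5], 0.0, atol=1e-10)      # zeros


class TestRmtThreshold:
    def _noise_block(self, seed, n_pred=80, n_prey=150, n_sites=73):
        rng = np.random.default_rng(seed)
        pred = np.apply_along_axis(stats.rankdata, 0,
                                   rng.normal(size=(n_sites, n_pred)))
        prey = np.apply_along_axis(stats.rankdata, 0,
                                   rng.normal(size=(n_sites, n_prey)))
        pred -= pred.mean(0)
        prey -= prey.mean(0)
        rho = (pred.T @ prey) / np.outer(
            np.sqrt((pred**2).sum(0)), np.sqrt((prey**2).sum(0)))
        return tn.CorrelationBlock([f"p{i}" for i in range(n_pred)],
                                   [f"b{j}" for j in range(n_prey)], rho)

    def test_noise_block_excludes_most_entries(self):
        excluded = []
        for seed in range(5):
            blk = self._noise_block(seed)
            scan = tn.rmt_threshold(blk, min_eigenvalues=20)
            frac = (np.abs(blk.rho) < scan.chosen_threshold).mean()
            excluded.append(frac)
        assert np.mean(excluded) >= 0.99

    def test_chosen_threshold_in_grid(self):
        blk = self._noise_block(0)
        scan = tn.rmt_threshold(blk, min_eigenvalues=20)
        assert np.any(np.isclose(scan.thresholds, scan.chosen_threshold))

    def test_scan_table_shape(self):
        blk = self._noise_block(1)
        scan = tn.rmt_threshold(blk, min_eigenvalues=20)
        t = scan.table()
        assert set(t.columns) == {"threshold", "n_eigenvalues", "poisson_p",
                                  "wigner_p"}
        assert (t["n_eigenvalues"].to_numpy()[1:]
                <= t["n_eigenvalues"].to_numpy()[:-1] + 1e-9).all()

    def test_planted_pairs_recalled(self):
        # strong planted pairs survive the chosen threshold
        recalls = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            blk = self._noise_block(seed)
            rho = blk.rho.copy()
            planted = [(i, i) for i in range(20)]
            for i, j in planted:
                rho[i, j] = 0.9 * np.sign(rng.normal() + 1e-12)
            blk = tn.CorrelationBlock(blk.predator_ids, blk.prey_ids, rho)
            scan = tn.rmt_threshold(blk, min_eigenvalues=20)
            got = sum(abs(rho[i, j]) >= scan.chosen_threshold
                      for i, j in planted)
            recalls.append(got / len(planted))
        assert np.mean(recalls) >= 0.8


class TestBuildMetaNetwork:
    def block(self, rho):
        rho = np.asarray(rho, dtype=float)
        return tn.CorrelationBlock([f"p{i}" for i in range(rho.shape[0])],
                                   [f"b{j}" for j in range(rho.shape[1])],
                                   rho)

    def test_full_block(self):
        net = tn.build_meta_network(self.block([[0.9, -0.8], [0.7, 0.95]]), 0.6)
        assert net.edge_count == 4
        assert net.node_count == 4
        assert net.connectance == pytest.approx(0.25)

    def test_empty_network_valid(self):
        net = tn.build_meta_network(self.block([[0.1, 0.2], [0.0, 0.3]]), 0.6)
        assert net.edge_count == 0
        assert net.connectance == 0.0

    def test_single_edge(self):
        net = tn.build_meta_network(self.block([[0.9, 0.1], [0.2, 0.3]]), 0.6)
        assert (net.edge_count, net.node_count) == (1, 2)
        assert net.connectance == pytest.approx(0.25)

    def test_monotone_in_threshold(self, rng):
        blk = self.block(rng.uniform(-1, 1, size=(10, 15)))
        edges = [tn.build_meta_network(blk, t).edge_count
                 for t in np.linspace(0.1, 0.95, 18)]
        assert all(a >= b for a, b in zip(edges, edges[1:]))

    def test_positive_only_mode(self):
        blk = self.block([[0.9, -0.9]])
        both = tn.build_meta_network(blk, 0.6)
        pos = tn.build_meta_network(blk, 0.6, positive_only=True)
        assert both.edge_count == 2
        assert pos.edge_count == 1

    def test_isolated_nodes_excluded(self):
        net = tn.build_meta_network(
            self.block([[0.9, 0.0, 0.0], [0.0, 0.0, 0.0]]), 0.5)
        assert net.node_count == 2  # p0 and b0 only


class TestSiteSubnetworks:
    def setup_method(self):
        # path network: p0-b0, p0-b1 (A-B, B-C with B = p0)
        self.block = tn.CorrelationBlock(
            ["p0"], ["b0", "b1"], np.array([[0.9, 0.8]]))
        self.meta = tn.build_meta_network(self.block, 0.5)

    def test_full_induction_equals_meta(self):
        prey = table([[3, 4]], prefix="b")
        pred = table([[5]], "protist", "p")
        df = tn.site_subnetworks(self.meta, prey, pred)
        assert df.loc[0, "E"] == self.meta.edge_count
        assert df.loc[0, "N"] == self.meta.node_count
        assert df.loc[0, "C"] == pytest.approx(self.meta.connectance)

    def test_no_asvs_present(self):
        prey = table([[0, 0]], prefix="b")
        pred = table([[0]], "protist", "p")
        prey.counts[:] = 0  # bypass all-zero check: counts only, no distance
        df = tn.site_subnetworks(self.meta, prey, pred)
        assert df.loc[0, "E"] == 0
        assert df.loc[0, "C"] == 0.0

    def test_missing_hub_empties_network(self):
        # site has both prey but lacks the hub predator
        prey = table([[2, 2]], prefix="b")
        pred = table([[0]], "protist", "p")
        df = tn.site_subnetworks(self.meta, prey, pred)
        assert (df.loc[0, "E"], df.loc[0, "N"]) == (0, 0)

    def test_site_metrics_bounded_by_meta(self, rng):
        n_sites = 15
        prey = table(rng.integers(0, 4, size=(n_sites, 12)), prefix="b")
        pred = table(rng.integers(0, 4, size=(n_sites, 6)), "protist", "p")
        blk = tn.CorrelationBlock(list(pred.asv_ids), list(prey.asv_ids),
                                  rng.uniform(-1, 1, size=(6, 12)))
        meta = tn.build_meta_network(blk, 0.5)
        df = tn.site_subnetworks(meta, prey, pred)
        assert (df["E"] <= meta.edge_count).all()
        assert (df["N"] <= meta.node_count).all()
        assert ((0 <= df["C"]) & (df["C"] <= 1)).all()

    def test_sample_mismatch_error(self):
        prey = table([[1, 1]], prefix="b")
        pred = AsvTable(["other"], ["p0"], np.array([[1]]), "protist")
        with pytest.raises(ValueError, match="sample"):
            tn.site_subnetworks(self.meta, prey, pred)


class TestThresholdSensitivity:
    def test_identical_levels_correlation_one(self, rng):
        prey = table(rng.integers(0, 20, size=(30, 20)), prefix="b")
        pred = table(rng.integers(0, 20, size=(30, 8)), "protist", "p")
        df = tn.threshold_sensitivity(prey, pred, (0.2, 0.2), threshold=0.3)
        e_rows = df[df.metric == "E"]["spearman_r"].dropna().to_numpy()
        np.testing.assert_allclose(e_rows, 1.0)

    def test_single_level_error(self, rng):
        prey = table(rng.integers(0, 20, size=(10, 5)), prefix="b")
        pred = table(rng.integers(0, 20, size=(10, 3)), "protist", "p")
        with pytest.raises(ValueError, match="at least 2"):
            tn.threshold_sensitivity(prey, pred, (0.3,), threshold=0.5)

    def test_cross_level_positive_on_planted_data(self):
        from trophograd import synthetic_data as sd
        from trophograd.core_data import rarefy
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = sd.SimulationConfig(seed=seed)
            meta, tables, regs = sd.simulate_survey(cfg)
            prey = rarefy(tables["bacteria"], seed=seed)
            pred = rarefy(tables["protist"], seed=seed + 1).select_samples(
                prey.sample_ids)
            df = tn.threshold_sensitivity(prey, pred, (0.2, 0.3, 0.4),
                                          threshold=0.55)
            e_rows = df[df.metric == "E"]["spearman_r"].dropna()
            if len(e_rows) and (e_rows > 0.5).all():
                hits += 1
        assert hits >= round(0.8 * n_seeds)
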