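import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epidrugscreen.benchmarks import tom_bruteforce
from epidrugscreen.coexpr import (
    adjacency_matrix,
    build_network,
    detect_modules,
    hub_neighborhood,
    module_drug_effect,
    pick_soft_threshold,
    tom_matrix,
)
from epidrugscreen.errors import (
    DegenerateInputError,
    ParameterError,
    UnknownEntityError,
)


class TestTomMatrix:
    def test_empty_adjacency_gives_identity(self):
        assert np.allclose(tom_matrix(np.zeros((5, 5))), np.eye(5))

    def test_complete_graph_n4_is_all_ones(self):
        """Hand evaluation: a_ij = 1, n = 4 -> tom_ij = (2 + 1)/(3 + 1 - 1) = 1."""
        adj = np.ones((4, 4)) - np.eye(4)
        tom = tom_matrix(adj)
        assert np.allclose(tom, np.ones((4, 4)))

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            raw = rng.uniform(0, 1, size=(20, 20))
            adj = (raw + raw.T) / 2
            np.fill_diagonal(adj, 0.0)
            assert np.abs(tom_matrix(adj) - tom_bruteforce(adj)).max() < 1e-10

    def test_bounds_and_symmetry_on_random_inputs(self, rng):
        raw = rng.uniform(0, 1, size=(30, 30))
        adj = (raw + raw.T) / 2
        np.fill_diagonal(adj, 0.0)
        tom = tom_matrix(adj)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self, rng):
        adj = rng.uniform(0, 1, size=(5, 5))
        with pytest.raises(ParameterError, match="symmetric"):
            tom_matrix(adj)


def block_tom(sizes, within=0.8, between=0.05, n_background=0):
    n = sum(sizes) + n_background
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    return tom


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        tom = block_tom([50, 50])
        labels = detect_modules(tom, min_module_size=30)
        assert set(labels[:50]) == {1} or set(labels[:50]) == {2}
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_identity_tom_leaves_all_unassigned(self):
        assert (detect_modules(np.eye(40), min_module_size=30) == 0).all()

    def test_minimum_size_boundary(self):
        # 29 perfectly correlated genes with min size 30 -> unassigned
        tom = block_tom([29])
        assert (detect_modules(tom, min_module_size=30) == 0).all()
        tom = block_tom([30])
        assert (detect_modules(tom, min_module_size=30) == 1).all()

    def test_modules_labeled_by_decreasing_size(self):
        tom = block_tom([35, 80])
        labels = detect_modules(tom, min_module_size=30)
        assert set(labels[:35]) == {2}
        assert set(labels[35:]) == {1}

    def test_invariant_to_gene_permutation(self, rng):
        tom = block_tom([40, 60], n_background=20)
        perm = rng.permutation(tom.shape[0])
        base = detect_modules(tom, min_module_size=30)
        permuted = detect_modules(tom[np.ix_(perm, perm)], min_module_size=30)
        assert adjusted_rand_score(base[perm], permuted) == 1.0


class TestSoftThreshold:
    @staticmethod
    def _scale_free_expression(n_genes=300, n_samples=120, seed=0):
        """One latent factor with power-law-ish loadings: the connectivity
        k_i ~ w_i**beta follows an approximate power law."""
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.05, 1.0, size=n_genes)
        w = u ** 0.6
        z = rng.standard_normal(n_samples)
        data = w[:, None] * z[None, :] + np.sqrt(1 - w**2)[:, None] * rng.standard_normal(
            (n_genes, n_samples)
        )
        return pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])

    def test_scale_free_data_reaches_fit_cut(self):
        norm = self._scale_free_expression()
        beta, table = pick_soft_threshold(norm)
        assert table.attrs["converged"]
        assert table.loc[table["power"] == beta, "fit_r2"].iloc[0] >= 0.8

    def test_beta_is_smallest_power_meeting_cut(self):
        norm = self._scale_free_expression(seed=1)
        beta, table = pick_soft_threshold(norm)
        below = table[table["power"] < beta]
        assert (below["fit_r2"] < 0.8).all()

    def test_two_genes_rejected(self):
        norm = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 30)))
        with pytest.raises(DegenerateInputError):
            pick_soft_threshold(norm)

    def test_no_power_reaching_cut_falls_back_with_flag(self):
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(rng.normal(size=(80, 40)))
        beta, table = pick_soft_threshold(norm, fit_cut=0.999)  # unreachable cut
        assert not table.attrs["converged"]
        assert (table["fit_r2"] < 0.999).all()
        # the fallback never picks a power with a disconnected network when
        # a connected alternative exists
        viable = table[table["mean_k"] >= 1.0]
        if len(viable):
            assert beta in set(viable["power"])

    def test_constant_genes_dropped_with_count(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(50, 30))
        data[:5] = 1.0  # constant rows
        norm = pd.DataFrame(data)
        _, table = pick_soft_threshold(norm)
        assert table.attrs["n_constant_dropped"] == 5


class TestHubNeighborhood:
    def _norm(self, rng, n_genes=60, n_samples=50):
        data = rng.normal(size=(n_genes, n_samples))
        return pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])

    def test_duplicated_hub_ranks_first_with_zero_spoke(self, rng):
        norm = self._norm(rng)
        norm.loc["twin"] = norm.loc["g0"]
        hood = hub_neighborhood(norm, "g0", k=20)
        assert hood["gene"].iloc[0] == "twin"
        assert hood["r"].iloc[0] == pytest.approx(1.0)
        assert hood["spoke_length"].iloc[0] == pytest.approx(0.0)

    def test_returns_exactly_k_neighbors(self, rng):
        hood = hub_neighborhood(self._norm(rng), "g0", k=20)
        assert len(hood) == 20
        assert (hood["spoke_length"].diff().dropna() >= -1e-12).all()

    def test_planted_partners_beat_noise_genes(self, rng):
        norm = self._norm(rng)
        z = rng.standard_normal(norm.shape[1])
        for g in ["g0", "g1", "g2", "g3"]:
            norm.loc[g] = z + 0.05 * rng.standard_normal(norm.shape[1])
        hood = hub_neighborhood(norm, "g0", k=3)
        assert set(hood["gene"]) == {"g1", "g2", "g3"}

    def test_constant_hub_rejected(self, rng):
        norm = self._norm(rng)
        norm.loc["g0"] = 1.0
        with pytest.raises(DegenerateInputError):
            hub_neighborhood(norm, "g0", k=5)

    def test_unknown_hub_rejected(self, rng):
        with pytest.raises(UnknownEntityError):
            hub_neighborhood(self._norm(rng), "nope", k=5)


class TestModuleDrugEffect:
    def _fc(self, entries):
        return pd.DataFrame(entries, columns=["gene", "cell_line", "compound", "log2fc"])

    def test_zero_fold_changes_give_zero_effect(self):
        fc = self._fc([("g1", "L", "D1", 0.0), ("g2", "L", "D1", 0.0)])
        out = module_drug_effect({"g1", "g2"}, fc)
        assert out.loc["D1", "mean_log2fc"] == 0.0

    def test_linearity(self, rng):
        entries = [
            (f"g{i}", f"L{j}", d, float(rng.normal()))
            for i in range(5)
            for j in range(3)
            for d in ("D1", "D2")
        ]
        fc = self._fc(entries)
        doubled = fc.assign(log2fc=2 * fc["log2fc"])
        a = module_drug_effect({f"g{i}" for i in range(5)}, fc)
        b = module_drug_effect({f"g{i}" for i in range(5)}, doubled)
        assert np.allclose(2 * a["mean_log2fc"], b["mean_log2fc"])

    def test_empty_module_rejected(self):
        with pytest.raises(ParameterError):
            module_drug_effect(set(), self._fc([("g", "L", "D", 0.0)]))

    def test_absent_genes_rejected(self):
        with pytest.raises(UnknownEntityError):
            module_drug_effect({"zz"}, self._fc([("g", "L", "D", 0.0)]))


class TestBuildNetwork:
    def test_planted_blocks_end_to_end(self, rng):
        """Two latent-factor gene blocks recovered through the full chain
        (adjacency -> TOM -> modules) at a fixed power."""
        n_samples = 100
        z1, z2 = rng.standard_normal(n_samples), rng.standard_normal(n_samples)
        rows = []
        for i in range(40):
            rows.append(0.9 * z1 + 0.45 * rng.standard_normal(n_samples))
        for i in range(40):
            rows.append(0.9 * z2 + 0.45 * rng.standard_normal(n_samples))
        for i in range(20):
            rows.append(rng.standard_normal(n_samples))
        norm = pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(100)])
        net = build_network(norm, beta=6, min_module_size=30)
        labels = np.array([net.module_of[g] for g in net.genes])
        truth = np.array([1] * 40 + [2] * 40 + [0] * 20)
        assert adjusted_rand_score(truth, labels) > 0.95
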