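import numpy as np
import pandas as pd
import pytest

from epidrugscreen import expression as ex
from epidrugscreen import synthetic as syn
from epidrugscreen.errors import MissingDataError, ParameterError
from epidrugscreen.synthetic import ExpressionBundle

from conftest import make_grid


def bundle_from_counts(counts: dict, meta: list) -> ExpressionBundle:
    """counts: sample -> list; meta: (sample, line, compound) triples."""
    genes = [f"G{i}" for i in range(len(next(iter(counts.values()))))]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(
        [(l, c, 0) for _s, l, c in meta],
        index=pd.Index([s for s, _l, _c in meta], name="sample"),
        columns=["cell_line", "compound", "dose_nM"],
    )
    return ExpressionBundle(counts=frame, samples=samples)


class TestNormalize:
    @pytest.mark.parametrize("method", ["cpm_log2", "median_of_ratios_log2"])
    def test_library_size_invariance(self, method):
        c1 = np.array([10, 50, 200, 1000, 40])
        counts = pd.DataFrame({"s1": c1, "s2": 2 * c1})
        norm = ex.normalize(counts, method=method)
        assert np.allclose(norm["s1"], norm["s2"])

    def test_cpm_arithmetic(self):
        counts = pd.DataFrame({"s": [999]})
        norm = ex.normalize(counts, method="cpm_log2")
        assert norm["s"].iloc[0] == pytest.approx(np.log2(1e6 + 1))

    def test_median_of_ratios_matches_hand_oracle(self):
        """Size factors recomputed gene by gene with explicit loops."""
        counts = pd.DataFrame(
            {
                "s1": [100, 20, 7, 250, 1],
                "s2": [180, 35, 14, 600, 3],
                "s3": [90, 18, 5, 230, 2],
            }
        )
        arr = counts.to_numpy(dtype=float)
        ratios = {s: [] for s in range(3)}
        for g in range(5):
            row = arr[g]
            if (row > 0).all():
                geo = np.exp(sum(np.log(x) for x in row) / 3)
                for s in range(3):
                    ratios[s].append(row[s] / geo)
        sf = [np.median(ratios[s]) for s in range(3)]
        oracle = np.log2(arr / np.array(sf)[None, :] + 1)
        norm = ex.normalize(counts, method="median_of_ratios_log2")
        assert np.allclose(norm.to_numpy(), oracle)

    def test_all_zero_gene_retained(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [0, 20]})
        norm = ex.normalize(counts, method="cpm_log2")
        assert norm.shape == counts.shape
        assert (norm.iloc[0] == 0).all()

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ParameterError, match="s2"):
            ex.normalize(counts)

    def test_idempotent_on_equal_libsize_cpm(self):
        c = pd.DataFrame({"s1": [10, 90], "s2": [60, 40]})  # equal libsizes
        n1 = ex.normalize(c, method="cpm_log2")
        assert np.allclose(
            n1["s1"], np.log2(c["s1"] / 100 * 1e6 + 1)
        )


class TestFoldChanges:
    def test_duplicated_control_gives_zero(self):
        b = bundle_from_counts(
            {"ctrl": [10, 50, 90], "trt": [10, 50, 90]},
            [("ctrl", "L", "control"), ("trt", "L", "D")],
        )
        fc = ex.fold_changes(b)
        assert np.allclose(fc["log2fc"], 0.0)

    def test_fourfold_count_change_at_equal_libsize(self):
        # equal library sizes, pseudocount -> 0: log2fc exactly 2
        b = bundle_from_counts(
            {"ctrl": [10, 990], "trt": [40, 960]},
            [("ctrl", "L", "control"), ("trt", "L", "D")],
        )
        b.norm = ex.normalize(b.counts, method="cpm_log2", pseudocount=1e-12)
        fc = ex.fold_changes(b)
        assert fc.loc[fc["gene"] == "G0", "log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_missing_control_names_the_line(self):
        b = bundle_from_counts(
            {"trt": [10, 20]},
            [("trt", "L7", "D")],
        )
        with pytest.raises(MissingDataError, match="L7"):
            ex.fold_changes(b)


class TestGeneSets:
    def _fc(self, values):
        return pd.DataFrame(
            [("G%d" % i, "L", "D", v) for i, v in enumerate(values)],
            columns=["gene", "cell_line", "compound", "log2fc"],
        )

    def test_small_changes_yield_empty_sets(self):
        grid = ex.derive_gene_sets(self._fc([0.99, -0.5, 0.0]), threshold=2.0)
        assert grid.up_sets[("L", "D")] == set()
        assert grid.down_sets[("L", "D")] == set()

    def test_boundary_is_inclusive(self):
        grid = ex.derive_gene_sets(self._fc([1.0, -1.0]), threshold=2.0)
        assert grid.up_sets[("L", "D")] == {"G0"}
        assert grid.down_sets[("L", "D")] == {"G1"}

    def test_up_down_disjoint(self, rng):
        fc = self._fc(rng.normal(0, 1.5, size=200))
        grid = ex.derive_gene_sets(fc)
        assert grid.up_sets[("L", "D")].isdisjoint(grid.down_sets[("L", "D")])

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ParameterError):
            ex.derive_gene_sets(self._fc([0.0]), threshold=1.0)

    def test_planted_down_sets_recovered_exactly_noiseless(self, small_bundle):
        truth, bundle = small_bundle
        fc = ex.fold_changes(bundle)
        grid = ex.derive_gene_sets(fc)
        planted = truth.consistent_down["D1"]
        for line in [f"L{i}" for i in range(1, 7)]:
            down = grid.down_sets[(line, "D1")]
            specific_down = truth.line_specific_sets[(line, "D1")][1]
            assert down == planted | specific_down


class TestTargetCountVsIc50:
    def test_exact_proportionality_gives_r_one(self):
        sizes = {"D1": 2, "D2": 4, "D3": 6, "D4": 8}
        grid = make_grid(
            up_cells={("L", d): {f"g{d}{i}" for i in range(n)} for d, n in sizes.items()}
        )
        ic50s = pd.DataFrame(
            {
                "compound": list(sizes),
                "cell_line": "L",
                "ic50_M": [10.0 ** (-6 - n / 2) for n in sizes.values()],
            }
        )
        r, p, n = ex.target_count_vs_ic50(grid, ic50s)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_constant_counts_undefined(self):
        grid = make_grid(
            up_cells={("L", d): {"g1", "g2"} for d in ("D1", "D2", "D3")}
        )
        ic50s = pd.DataFrame(
            {"compound": ["D1", "D2", "D3"], "cell_line": "L", "ic50_M": [1e-7, 1e-6, 1e-5]}
        )
        r, p, _ = ex.target_count_vs_ic50(grid, ic50s)
        assert np.isnan(r) and np.isnan(p)

    def test_planted_potency_coupling_detected(self):
        """When per-drug transcriptome effect sizes are planted to scale
        with potency, the correlation is positive and significant."""
        from epidrugscreen.benchmarks import potency_coupling

        out = potency_coupling(n_seeds=10, dispersion=0.1, base_seed=1)
        assert out["significant_rate"] >= 0.9
        assert out["r_mean"] > 0.5

    def test_too_few_drugs_rejected(self):
        grid = make_grid(up_cells={("L", "D1"): {"g"}, ("L", "D2"): set()})
        ic50s = pd.DataFrame(
            {"compound": ["D1", "D2"], "cell_line": "L", "ic50_M": [1e-7, 1e-6]}
        )
        with pytest.raises(ParameterError):
            ex.target_count_vs_ic50(grid, ic50s)


class TestClustering:
    def test_planted_clusters_recovered(self, small_bundle):
        truth, bundle = small_bundle
        result = ex.baseline_clusters(bundle, seed=0)
        assert result.cluster_of_line == truth.cluster_of_line

    def test_cluster_one_is_the_larger_cluster(self, small_bundle):
        _, bundle = small_bundle
        result = ex.baseline_clusters(bundle, seed=0)
        sizes = pd.Series(result.cluster_of_line).value_counts()
        assert sizes[1] >= sizes[2]

    def test_duplicate_profiles_co_cluster(self, small_bundle):
        truth, bundle = small_bundle
        counts = bundle.counts.copy()
        samples = bundle.samples.copy()
        # clone line L1's control as a new line L9
        counts["L9|control"] = counts["L1|control"]
        samples.loc["L9|control"] = ["L9", "control", 0]
        clone = ExpressionBundle(counts=counts, samples=samples)
        result = ex.baseline_clusters(clone, seed=0)
        assert result.cluster_of_line["L9"] == result.cluster_of_line["L1"]

    def test_partition_invariant_to_line_order(self, small_bundle):
        _, bundle = small_bundle
        perm = list(bundle.counts.columns)[::-1]
        shuffled = ExpressionBundle(
            counts=bundle.counts[perm], samples=bundle.samples.loc[perm]
        )
        a = ex.baseline_clusters(bundle, seed=0).cluster_of_line
        b = ex.baseline_clusters(shuffled, seed=0).cluster_of_line
        assert a == b


class TestClusterDe:
    def test_planted_markers_rank_on_top(self, small_bundle):
        truth, bundle = small_bundle
        clusters = ex.baseline_clusters(bundle, seed=0)
        de = ex.cluster_de(clusters, bundle)
        markers = truth.cluster_marker_genes
        top = set(de["gene"].head(len(markers)))
        assert len(top & markers) / len(markers) >= 0.9
        # markers are higher in cluster 1
        top_rows = de[de["gene"].isin(markers)]
        assert (top_rows["mean_diff"] > 0).all()

    def test_bh_q_monotone_in_p_order(self, small_bundle):
        _, bundle = small_bundle
        clusters = ex.baseline_clusters(bundle, seed=0)
        de = ex.cluster_de(clusters, bundle).sort_values("p")
        assert (de["q"].diff().dropna() >= -1e-12).all()

    def test_constant_gene_scores_zero(self, small_bundle):
        _, bundle = small_bundle
        clone = ExpressionBundle(counts=bundle.counts, samples=bundle.samples)
        clone.norm = ex.normalize(clone.counts)
        clone.norm.loc["G0000"] = 9.0  # identical normalized expression everywhere
        clusters = ex.baseline_clusters(clone, seed=0)
        de = ex.cluster_de(clusters, clone).set_index("gene")
        assert de.loc["G0000", "mean_diff"] == pytest.approx(0.0)
        assert de.loc["G0000", "rank_score"] == pytest.approx(0.0)
        assert de.loc["G0000", "variance_floored"]

    def test_label_permutation_null_calibration(self, small_bundle):
        """With cluster labels permuted at random the p-value distribution
        is approximately uniform: ~5% of genes below 0.05."""
        truth, bundle = small_bundle
        rng = np.random.default_rng(0)
        lines = [f"L{i}" for i in range(1, 7)]
        fracs = []
        for _ in range(30):
            labels = rng.permutation([1, 1, 1, 1, 2, 2])
            fake = ex.ClusterResult(
                cluster_of_line=dict(zip(lines, labels)),
                pc_scores=pd.DataFrame(index=lines),
            )
            de = ex.cluster_de(fake, bundle)
            null_genes = de[~de["gene"].isin(truth.cluster_marker_genes)]
            fracs.append((null_genes["p"] < 0.05).mean())
        assert 0.0 <= float(np.mean(fracs)) <= 0.15


class TestClusterDrugResistance:
    def _ic50s(self, shift_drugs, lines1, lines2, rng):
        rows = []
        for d in ["D%d" % i for i in range(1, 5)]:
            for line in lines1 + lines2:
                base = 1e-7 * 10 ** rng.normal(0, 0.05)
                if d in shift_drugs and line in lines2:
                    base *= 10
                rows.append((d, line, base))
        return pd.DataFrame(rows, columns=["compound", "cell_line", "ic50_M"])

    def test_planted_shift_detected_with_direction(self, rng):
        lines1, lines2 = ["A", "B", "C", "D"], ["E", "F", "G"]
        clusters = ex.ClusterResult(
            cluster_of_line={l: 1 for l in lines1} | {l: 2 for l in lines2},
            pc_scores=pd.DataFrame(),
        )
        out = ex.cluster_drug_resistance(
            clusters, self._ic50s({"D1", "D2"}, lines1, lines2, rng)
        ).set_index("compound")
        assert out.loc["D1", "significant"] and out.loc["D1", "cluster2_higher"]
        assert out.loc["D2", "significant"] and out.loc["D2", "cluster2_higher"]

    def test_singleton_cluster_reports_means_without_p(self, rng):
        clusters = ex.ClusterResult(
            cluster_of_line={"A": 1, "B": 1, "C": 2}, pc_scores=pd.DataFrame()
        )
        out = ex.cluster_drug_resistance(
            clusters, self._ic50s(set(), ["A", "B"], ["C"], rng)
        )
        assert out["p"].isna().all()
        assert out["mean_ic50_c2"].notna().all()
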