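"""Planted-truth recovery scenarios.

Each function builds a synthetic study with known ground truth, runs the
relevant pipeline stages, and measures how well the planted structure is
recovered. The scenarios define the study conditions (panel sizes, noise
levels, effect sizes) once; they are used both by the test suite and by the
reproduction script.

Brute-force oracles for the TOM and the interval operations live here too:
they are deliberately naive (triple loops, all-pairs scans) and independent
of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import atac as atac_mod
from . import coexpr as coexpr_mod
from . import expression as expr_mod
from . import overlap as overlap_mod
from . import ranking as rank_mod
from . import synthetic as syn
from .dose_response import delta_auc_table, fit_ic50, fit_ic50_table, fourpl


# ---------------------------------------------------------------------------
# Screen: delayed-action class recovery
# ---------------------------------------------------------------------------


def screen_class_recovery(n_seeds: int = 50, noise_sd: float = 0.05, base_seed: int = 1) -> dict:
    """Fraction of seeds in which the planted delayed-action class ranks 1.

    106 compounds / 36 classes on 5 lines, two timepoints (ragged doses),
    duplicate wells. Also reports how often the planted inert class is
    auto-selected as the reference.
    """
    top_hits = 0
    ref_hits = 0
    for s in range(n_seeds):
        seed = base_seed + s
        truth = syn.screen_truth_106(seed=seed, noise_sd=noise_sd)
        table = syn.generate_screen(
            truth,
            doses={3.0: syn.EARLY_DOSES_M, 28.0: syn.LATE_DOSES_M},
            timepoints=[3.0, 28.0],
            replicates=2,
            seed=seed + 100_000,
        )
        deltas = delta_auc_table(table, 3.0, 28.0)
        ranks = rank_mod.rank_compounds(deltas)
        classes = rank_mod.class_average_ranks(ranks, truth.class_of, "auto")
        top_class = classes.loc[classes["class_rank"] == 1, "drug_class"].iloc[0]
        top_hits += int(top_class == "BET")
        ref_hits += int(classes.attrs["reference_class"] == "BRPF")
    return {
        "top_rank_rate": top_hits / n_seeds,
        "reference_auto_rate": ref_hits / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# IC-50 recovery
# ---------------------------------------------------------------------------


def ic50_recovery(n_curves: int = 200, noise_sd: float = 0.05, seed: int = 0) -> dict:
    """Median |log10(ic50_hat / ic50_true)| over simulated 4-dose curves.

    Curves are 4PL (top 1, bottom 0, Hill 1) at the standard panel doses
    (10 nM .. 10 uM) with the true IC-50 log-uniform inside that range and
    Gaussian viability noise truncated at 0.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(syn.PANEL_DOSES_M)
    errors = []
    for _ in range(n_curves):
        true_ic50 = 10.0 ** rng.uniform(-8.0, -5.0)
        v = fourpl(doses, 1.0, 0.0, true_ic50, 1.0)
        v = np.maximum(0.0, v + rng.normal(0.0, noise_sd, size=v.size))
        fit = fit_ic50(doses, v)
        errors.append(abs(np.log10(fit.ic50 / true_ic50)))
    return {
        "median_abs_log10_error": float(np.median(errors)),
        "n_curves": n_curves,
    }


# ---------------------------------------------------------------------------
# Expression scenarios
# ---------------------------------------------------------------------------


def _panel_fc(truth, dispersion, seed, **gen_kwargs):
    bundle = syn.generate_expression(
        truth, syn.PANEL_LINES, syn.PANEL_COMPOUNDS,
        dispersion=dispersion, seed=seed, **gen_kwargs,
    )
    bundle.norm = expr_mod.normalize(bundle.counts)
    return bundle, expr_mod.fold_changes(bundle)


def consistent_set_recovery(
    n_seeds: int = 50,
    dispersion: float = 0.1,
    effect_log2fc: float = 1.5,
    base_seed: int = 1,
) -> dict:
    """Recovery of a planted 100-gene consistent down-set on a 12x12 grid.

    One BET-like compound down-regulates the same 100 genes in every line;
    every (line, compound) cell additionally carries line-specific sets.
    Precision/recall of the consistent-down call (3/4-of-lines rule) and
    the rate at which the planted compound is classified a down-regulator.
    """
    precisions, recalls, downreg = [], [], 0
    for s in range(n_seeds):
        seed = base_seed + s
        truth = syn.expression_truth(
            n_genes=2000,
            seed=seed,
            effect_log2fc=effect_log2fc,
            consistent_down_size=100,
            module_sizes=(),
        )
        _, fc = _panel_fc(truth, dispersion, seed + 50_000)
        grid = expr_mod.derive_gene_sets(fc)
        cons, _ = overlap_mod.consistent_sets(grid, "down")
        planted = truth.consistent_down["CPI203"]
        found = cons["CPI203"]
        inter = len(found & planted)
        precisions.append(inter / len(found) if found else 0.0)
        recalls.append(inter / len(planted))
        classes = overlap_mod.classify_regulators(grid)
        label = classes.loc[classes["compound"] == "CPI203", "classification"].iloc[0]
        downreg += int(label == "down-regulator")
    return {
        "precision_mean": float(np.mean(precisions)),
        "recall_mean": float(np.mean(recalls)),
        "down_regulator_rate": downreg / n_seeds,
        "n_seeds": n_seeds,
    }


def stress_set_recovery(
    n_seeds: int = 10, dispersion: float = 0.1, base_seed: int = 1
) -> dict:
    """Recovery of the per-line universal ("stress") up-sets.

    Mean recall of the all-compounds rule at the given dispersion, plus an
    exact-recovery check in the near-noiseless limit.
    """
    recalls = []
    for s in range(n_seeds):
        seed = base_seed + s
        truth = syn.expression_truth(n_genes=2000, seed=seed, module_sizes=())
        _, fc = _panel_fc(truth, dispersion, seed + 60_000)
        grid = expr_mod.derive_gene_sets(fc)
        univ = overlap_mod.universal_sets(grid, "up", min_fraction=1.0)
        per_line = [
            len(univ[line] & truth.line_stress_up[line]) / len(truth.line_stress_up[line])
            for line in syn.PANEL_LINES
        ]
        recalls.append(float(np.mean(per_line)))
    # noiseless limit: planted sets must come back exactly
    truth0 = syn.expression_truth(n_genes=2000, seed=base_seed, module_sizes=())
    _, fc0 = _panel_fc(
        truth0, 1e-6, base_seed + 70_000, extra_log2_sd=0.0, equal_libsize=True
    )
    univ0 = overlap_mod.universal_sets(
        expr_mod.derive_gene_sets(fc0), "up", min_fraction=1.0
    )
    exact = all(univ0[line] == truth0.line_stress_up[line] for line in syn.PANEL_LINES)
    return {
        "recall_mean": float(np.mean(recalls)),
        "noiseless_exact": bool(exact),
        "n_seeds": n_seeds,
    }


def cluster_association(n_seeds: int = 25, dispersion: float = 0.1, base_seed: int = 1) -> dict:
    """Planted two-cluster design: clustering, IC-50 association, marker DE.

    Four of twelve lines form a resistant cluster: their IC-50s are 10x
    higher for six of the twelve drugs, and 40 marker genes are elevated by
    2 log2 units in the sensitive cluster at baseline. Per seed: baseline
    PCA clustering (ARI vs truth), per-drug Welch test on fitted log10
    IC-50s (are all six planted drugs flagged with cluster 2 higher?), and
    recall of the planted markers in the top of the DE ranking.
    """
    resistant_lines = syn.PANEL_LINES[-4:]
    resistant_drugs = set(syn.PANEL_COMPOUNDS[:6])
    aris, all6_hits, exact_hits, marker_recalls, false_flags = [], 0, 0, [], []
    for s in range(n_seeds):
        seed = base_seed + s
        struth = syn.screen_truth_panel(
            seed=seed,
            noise_sd=0.05,
            resistant_lines=resistant_lines,
            resistant_compounds=resistant_drugs,
            resistance_factor=10.0,
        )
        panel = syn.generate_screen(
            struth, doses=syn.PANEL_DOSES_M, timepoints=[7.0], replicates=3,
            seed=seed + 10_000,
        )
        ic50s = fit_ic50_table(panel, day=7.0)

        etruth = syn.expression_truth(
            n_genes=2000, seed=seed, module_sizes=(), cluster2_lines=resistant_lines
        )
        bundle, _ = _panel_fc(etruth, dispersion, seed + 20_000)
        clusters = expr_mod.baseline_clusters(bundle, seed=seed)
        truth_labels = [etruth.cluster_of_line[l] for l in sorted(etruth.cluster_of_line)]
        found_labels = [clusters.cluster_of_line[l] for l in sorted(clusters.cluster_of_line)]
        aris.append(adjusted_rand_score(truth_labels, found_labels))

        res = expr_mod.cluster_drug_resistance(clusters, ic50s)
        flagged = set(
            res.loc[res["significant"] & res["cluster2_higher"], "compound"]
        )
        all6_hits += int(resistant_drugs <= flagged)
        exact_hits += int(flagged == resistant_drugs)
        false_flags.append(len(flagged - resistant_drugs))

        de = expr_mod.cluster_de(clusters, bundle)
        markers = etruth.cluster_marker_genes
        top = set(de["gene"].head(len(markers)))
        marker_recalls.append(len(top & markers) / len(markers))
    return {
        "ari_mean": float(np.mean(aris)),
        "all_planted_flagged_rate": all6_hits / n_seeds,
        "exact_set_rate": exact_hits / n_seeds,
        "mean_false_flags": float(np.mean(false_flags)),
        "marker_recall_mean": float(np.mean(marker_recalls)),
        "n_seeds": n_seeds,
    }


def potency_coupling(n_seeds: int = 20, dispersion: float = 0.1, base_seed: int = 1) -> dict:
    """Planted coupling between transcriptome effect size and potency.

    Line-specific set sizes scale with -log10 IC-50; rate of seeds with a
    positive, significant Pearson correlation between per-drug mean target
    count and per-drug mean potency.
    """
    hits = 0
    rs = []
    for s in range(n_seeds):
        seed = base_seed + s
        struth = syn.screen_truth_panel(seed=seed, noise_sd=0.05)
        base_ic50 = {
            comp: float(
                np.mean([struth.fourpl[(l, comp)][2] for l in syn.PANEL_LINES])
            )
            for comp in syn.PANEL_COMPOUNDS
        }
        potency = {c: -np.log10(v) for c, v in base_ic50.items()}
        etruth = syn.expression_truth(
            n_genes=2000, seed=seed, module_sizes=(), couple_sizes_to=potency
        )
        panel = syn.generate_screen(
            struth, doses=syn.PANEL_DOSES_M, timepoints=[7.0], replicates=3,
            seed=seed + 30_000,
        )
        ic50s = fit_ic50_table(panel, day=7.0)
        _, fc = _panel_fc(etruth, dispersion, seed + 40_000)
        grid = expr_mod.derive_gene_sets(fc)
        r, p, _n = expr_mod.target_count_vs_ic50(grid, ic50s)
        rs.append(r)
        hits += int(r > 0 and p < 0.05)
    return {"significant_rate": hits / n_seeds, "r_mean": float(np.mean(rs)), "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Co-expression scenarios and TOM oracle
# ---------------------------------------------------------------------------


def tom_bruteforce(adjacency: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, the oracle for ``tom_matrix``."""
    a = np.asarray(adjacency, dtype=float).copy()
    n = a.shape[0]
    for i in range(n):
        a[i, i] = 0.0
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = 0.0
            for u in range(n):
                if u != i and u != j:
                    shared += a[i, u] * a[u, j]
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def tom_oracle_check(n_instances: int = 25, n: int = 20, seed: int = 0) -> dict:
    """Max |tom_matrix - brute force| over random symmetric adjacencies."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        raw = rng.uniform(0.0, 1.0, size=(n, n))
        adj = (raw + raw.T) / 2.0
        np.fill_diagonal(adj, 0.0)
        diff = np.abs(coexpr_mod.tom_matrix(adj) - tom_bruteforce(adj))
        worst = max(worst, float(diff.max()))
    return {"max_abs_diff": worst, "n_instances": n_instances}


def _module_scenario_truth(seed: int):
    return syn.expression_truth(
        n_genes=260,  # 30 + 60 + 120 planted module genes + 50 background
        seed=seed,
        module_sizes=(30, 60, 120),
        n_cluster_markers=0,
        consistent_down_size=0,
        consistent_down_compound="__none__",
        stress_set_size=0,
        specific_down_size=0,
        specific_up_size=0,
    )


def module_recovery(n_seeds: int = 20, dispersion: float = 0.1, base_seed: int = 1) -> dict:
    """Planted-module recovery: ARI of detected vs planted modules, and the
    number of same-module partners in the largest module's hub top-20
    neighborhood. Modules of 30/60/120 genes (latent-factor correlation
    ~0.7) plus 50 background genes across 156 samples."""
    aris, hub_overlaps = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        truth = _module_scenario_truth(seed)
        bundle = syn.generate_expression(
            truth, syn.PANEL_LINES, syn.PANEL_COMPOUNDS,
            dispersion=dispersion, seed=seed + 80_000,
        )
        bundle.norm = expr_mod.normalize(bundle.counts)
        # fixed canonical unsigned power: planted-module data is modular,
        # not scale-free, so the R^2 criterion is not informative here
        net = coexpr_mod.build_network(bundle.norm, min_module_size=30, beta=6)
        truth_label = {}
        for mid, genes, _hub in truth.modules:
            for g in genes:
                truth_label[g] = mid
        t = [truth_label.get(g, 0) for g in net.genes]
        d = [net.module_of[g] for g in net.genes]
        aris.append(adjusted_rand_score(t, d))

        big_mid, big_genes, big_hub = max(truth.modules, key=lambda m: len(m[1]))
        hood = coexpr_mod.hub_neighborhood(bundle.norm, big_hub, k=20)
        hub_overlaps.append(len(set(hood["gene"]) & big_genes))
    return {
        "ari_mean": float(np.mean(aris)),
        "hub_overlap_mean": float(np.mean(hub_overlaps)),
        "n_seeds": n_seeds,
    }


def module_effect_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Module-drug effect in the near-noiseless limit.

    One BET-like drug down-shifts the first planted module by 1 log2 unit;
    per seed the module's mean fold change under that drug should sit at
    -1.0 and be the minimum across drugs.
    """
    effects, min_hits = [], 0
    for s in range(n_seeds):
        seed = base_seed + s
        truth = syn.expression_truth(
            n_genes=600,
            seed=seed,
            effect_log2fc=1.0,
            module_sizes=(30, 60),
            consistent_down_size=0,
            stress_set_size=0,
            specific_down_size=0,
            specific_up_size=0,
        )
        bundle = syn.generate_expression(
            truth, syn.PANEL_LINES, syn.PANEL_COMPOUNDS,
            dispersion=1e-6, seed=seed + 90_000,
            extra_log2_sd=0.0, equal_libsize=True,
        )
        bundle.norm = expr_mod.normalize(bundle.counts)
        fc = expr_mod.fold_changes(bundle)
        module1 = truth.modules[0][1]
        eff = coexpr_mod.module_drug_effect(module1, fc)["mean_log2fc"]
        effects.append(float(eff["CPI203"]))
        min_hits += int(eff.idxmin() == "CPI203")
    return {
        "planted_effect_mean": float(np.mean(effects)),
        "max_abs_error": float(np.max(np.abs(np.asarray(effects) + 1.0))),
        "min_across_drugs_rate": min_hits / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# ATAC oracles and planted recovery
# ---------------------------------------------------------------------------


def match_peaks_bruteforce(control: pd.DataFrame, treated: pd.DataFrame, min_ro: float = 0.5):
    """All-pairs greedy matching, the O(n*m) oracle for ``match_peaks``."""
    ctrl = atac_mod.validate_peaks(control)
    trt = atac_mod.validate_peaks(treated)
    cands = []
    for i in range(len(ctrl)):
        for j in range(len(trt)):
            c, t = ctrl.iloc[i], trt.iloc[j]
            if atac_mod.normalize_chrom(c["chrom"]) != atac_mod.normalize_chrom(t["chrom"]):
                continue
            ov = min(c["end"], t["end"]) - max(c["start"], t["start"])
            if ov <= 0:
                continue
            fc = ov / (c["end"] - c["start"])
            ft = ov / (t["end"] - t["start"])
            if fc >= min_ro and ft >= min_ro:
                cands.append(
                    (
                        atac_mod.normalize_chrom(c["chrom"]),
                        -min(fc, ft),
                        -ov,
                        min(c["start"], t["start"]),
                        max(c["start"], t["start"]),
                        i,
                        j,
                    )
                )
    cands.sort()
    used_c, used_t, n_matched = set(), set(), 0
    for *_key, i, j in cands:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        n_matched += 1
    return n_matched, len(ctrl) - n_matched, len(trt) - n_matched


def link_bruteforce(peaks: pd.DataFrame, tss: dict, window: int) -> dict:
    """All-pairs TSS-window linking, the oracle for ``link_peaks_to_genes``."""
    peaks = atac_mod.validate_peaks(peaks)
    out = {}
    for gene, entry in tss.items():
        chrom, pos = atac_mod.normalize_chrom(entry[0]), int(entry[1])
        hits = []
        for i in range(len(peaks)):
            p = peaks.iloc[i]
            if atac_mod.normalize_chrom(p["chrom"]) != chrom:
                continue
            if p["start"] < pos + window and p["end"] > pos - window:
                hits.append(i)
        out[gene] = hits
    return out


def _random_peakset(rng, n: int, genome: int = 2_000_000) -> pd.DataFrame:
    starts = rng.choice(genome, size=n, replace=False)
    widths = rng.integers(100, 1000, size=n)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + widths,
            "score": rng.lognormal(3.0, 0.5, size=n),
        }
    )


def atac_oracle_check(n_peaks: int = 500, seed: int = 0) -> dict:
    """Agreement of match and link operations with their brute-force oracles."""
    rng = np.random.default_rng(seed)
    control = _random_peakset(rng, n_peaks)
    treated = _random_peakset(rng, n_peaks)
    delta = atac_mod.match_peaks(control, treated)
    oracle = match_peaks_bruteforce(control, treated)
    match_equal = (len(delta.matched), len(delta.lost), len(delta.gained)) == oracle

    tss = {
        f"G{i:03d}": ("chr1", int(p), "+")
        for i, p in enumerate(rng.choice(2_000_000, size=50, replace=False))
    }
    fast = atac_mod.link_peaks_to_genes(control, tss, window=20_000)
    slow = link_bruteforce(control, tss, window=20_000)
    link_equal = all(sorted(fast[g]) == sorted(slow[g]) for g in tss)
    return {
        "match_counts_equal": bool(match_equal),
        "link_maps_equal": bool(link_equal),
        "n_peaks": n_peaks,
    }


def atac_planted_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Planted TSS-proximal peak loss: module genes lose more than background.

    Per seed, peaks are lost at 60% near module-gene TSSs vs 10% globally;
    the per-gene pooled losses (lost + significant decreases) of module
    genes must exceed the background genes' average.
    """
    hits = 0
    for s in range(n_seeds):
        seed = base_seed + s
        genes = [f"G{i:04d}" for i in range(150)]
        module_genes = set(genes[:30])
        truth = syn.peak_truth(
            genes,
            module_genes,
            genome_length=60_000_000,
            n_background_peaks=500,
            lost_fraction_global=0.1,
            lost_near_module_tss=0.6,
            seed=seed,
        )
        control = syn.generate_peaks(truth, "control", seed=seed)
        treated = syn.generate_peaks(truth, "treated", seed=seed + 1)
        delta = atac_mod.match_peaks(control, treated)
        union = pd.concat([control, delta.gained], ignore_index=True).drop_duplicates(
            subset=["chrom", "start", "end"]
        )
        links = atac_mod.link_peaks_to_genes(union, truth.tss_table, window=truth.link_window)
        per_gene, _ = atac_mod.gene_set_peak_changes(delta, links, genes, union)
        pooled = per_gene["n_lost"] + per_gene["n_sig_down"]
        is_module = per_gene["gene"].isin(module_genes)
        hits += int(pooled[is_module].mean() > pooled[~is_module].mean())
    return {"module_exceeds_background_rate": hits / n_seeds, "n_seeds": n_seeds}
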