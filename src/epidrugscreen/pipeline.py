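"""End-to-end driver chaining every stage on synthetic or user data.

Stage order: simulate (when no user data is supplied) -> screen (delta AUC +
volcano) -> rank -> ic50 -> express (normalize, fold changes, gene sets,
clusters, cluster DE) -> overlap -> coexpr -> atac. Every artifact is a
plain-text file; ``manifest.json`` lists each artifact with its SHA-256
hash, so identical config + seed reproduces byte-identical manifests.

A stage failure aborts the run with the failing stage named; files written
by the failing stage are kept with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import coexpr as coexpr_mod
from . import expression as expr_mod
from . import io as io_mod
from . import overlap as overlap_mod
from . import ranking as rank_mod
from . import synthetic as syn
from .config import RunConfig
from .dose_response import delta_auc_table, fit_ic50_table, volcano_stats
from .errors import StageError

log = logging.getLogger("epidrugscreen")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


class _Run:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[Path] = []
        self.stage_files: list[Path] = []

    def emit(self, name: str) -> Path:
        path = self.outdir / name
        self.stage_files.append(path)
        return path

    def commit_stage(self):
        self.artifacts.extend(self.stage_files)
        self.stage_files = []

    def abandon_stage(self):
        for path in self.stage_files:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        self.stage_files = []


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict.

    The manifest maps artifact name -> SHA-256 and is also written to
    ``<outdir>/manifest.json``.
    """
    cfg = config
    run = _Run(cfg)
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate, True),
        ("screen", _stage_screen, cfg.run_screen),
        ("rank", _stage_rank, cfg.run_rank and cfg.run_screen),
        ("ic50", _stage_ic50, cfg.run_ic50),
        ("express", _stage_express, cfg.run_express),
        ("overlap", _stage_overlap, cfg.run_overlap and cfg.run_express),
        ("coexpr", _stage_coexpr, cfg.run_coexpr and cfg.run_express),
        ("atac", _stage_atac, cfg.run_atac),
    ]
    for name, fn, enabled in stages:
        if not enabled:
            continue
        t0 = time.perf_counter()
        try:
            fn(run, state)
        except Exception as exc:
            run.abandon_stage()
            raise StageError(name, str(exc)) from exc
        run.commit_stage()
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    manifest = {
        "artifacts": {p.name: _sha256(p) for p in sorted(run.artifacts)},
        "seed": cfg.seed,
    }
    _json_dump(manifest, run.outdir / "manifest.json")
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_simulate(run: _Run, state: dict):
    """Generate synthetic inputs for anything the config does not supply.

    User-supplied files are *not* read here; the stage that consumes them
    reads them, so a malformed file fails in the stage it belongs to.
    """
    cfg = run.cfg
    rng_seed = cfg.seed

    if not cfg.viability_screen_csv:
        truth106 = syn.screen_truth_106(seed=rng_seed, noise_sd=cfg.noise_sd)
        table = syn.generate_screen(
            truth106,
            doses={cfg.early_day: syn.EARLY_DOSES_M, cfg.late_day: syn.LATE_DOSES_M},
            timepoints=[cfg.early_day, cfg.late_day],
            replicates=2,
            seed=rng_seed + 1,
        )
        io_mod.write_viability_csv(table, run.emit("viability_screen.csv"))
        state["screen_table"] = table
        state["screen_truth"] = truth106

    resistant_lines = syn.PANEL_LINES[-4:]
    resistant_compounds = syn.PANEL_COMPOUNDS[:6]
    if not cfg.viability_panel_csv:
        panel_truth = syn.screen_truth_panel(
            seed=rng_seed + 2,
            noise_sd=cfg.noise_sd,
            resistant_lines=resistant_lines,
            resistant_compounds=resistant_compounds,
        )
        panel = syn.generate_screen(
            panel_truth,
            doses=syn.PANEL_DOSES_M,
            timepoints=[cfg.panel_day],
            replicates=3,
            seed=rng_seed + 3,
        )
        io_mod.write_viability_csv(panel, run.emit("viability_panel.csv"))
        state["panel_table"] = panel
        state["panel_truth"] = panel_truth

    if not (cfg.counts_tsv and cfg.samples_tsv):
        # transcriptome effect sizes scale with compound potency when the
        # panel truth is synthetic too (more potent drugs move more genes)
        potency = None
        if "panel_truth" in state:
            pt = state["panel_truth"]
            potency = {
                comp: float(
                    -np.log10(
                        np.mean([pt.fourpl[(l, comp)][2] for l in syn.PANEL_LINES])
                    )
                )
                for comp in syn.PANEL_COMPOUNDS
            }
        etruth = syn.expression_truth(
            lines=syn.PANEL_LINES,
            compounds=syn.PANEL_COMPOUNDS,
            n_genes=cfg.n_genes,
            seed=rng_seed + 4,
            cluster2_lines=resistant_lines,
            couple_sizes_to=potency,
        )
        bundle = syn.generate_expression(
            etruth,
            syn.PANEL_LINES,
            syn.PANEL_COMPOUNDS,
            dispersion=cfg.dispersion,
            seed=rng_seed + 5,
        )
        io_mod.write_counts_tsv(bundle.counts, run.emit("counts.tsv"))
        io_mod.write_samples_tsv(bundle.samples, run.emit("samples.tsv"))
        state["bundle"] = bundle
        state["expression_truth"] = etruth

    if not (cfg.control_bed and cfg.treated_bed and cfg.tss_bed):
        etruth = state.get("expression_truth")
        genes = etruth.gene_ids if etruth else [f"G{i:04d}" for i in range(cfg.n_genes)]
        module_genes = etruth.modules[0][1] if etruth else set(genes[:30])
        ptruth = syn.peak_truth(genes, module_genes, seed=rng_seed + 6)
        control = syn.generate_peaks(ptruth, "control", seed=rng_seed + 7)
        treated = syn.generate_peaks(ptruth, "treated", seed=rng_seed + 8)
        io_mod.write_bed_peaks(control, run.emit("control.bed"))
        io_mod.write_bed_peaks(treated, run.emit("treated_CPI203.bed"))
        io_mod.write_tss_bed(ptruth.tss_table, run.emit("tss.bed"))
        state["control_peaks"] = control
        state["treated_peaks"] = treated
        state["tss"] = ptruth.tss_table
        state["peak_truth"] = ptruth

    truth_summary = {}
    if "expression_truth" in state:
        et = state["expression_truth"]
        truth_summary["expression"] = {
            "cluster_of_line": et.cluster_of_line,
            "modules": [
                {"id": mid, "hub": hub, "genes": sorted(genes)}
                for mid, genes, hub in et.modules
            ],
            "consistent_down": {
                c: sorted(s) for c, s in et.consistent_down.items() if s
            },
            "effect_log2fc": et.effect_log2fc,
        }
    if truth_summary:
        _json_dump(truth_summary, run.emit("truth.json"))


def _stage_screen(run: _Run, state: dict):
    cfg = run.cfg
    if "screen_table" not in state:
        state["screen_table"] = io_mod.read_viability_csv(cfg.viability_screen_csv)
    deltas = delta_auc_table(state["screen_table"], cfg.early_day, cfg.late_day)
    deltas.to_csv(run.emit("delta_auc.csv"), index=False)
    volcano = volcano_stats(state["screen_table"], cfg.early_day, cfg.late_day)
    volcano.to_csv(run.emit("volcano.csv"), index=False)
    state["deltas"] = deltas


def _stage_rank(run: _Run, state: dict):
    cfg = run.cfg
    deltas = state["deltas"]
    class_of = dict(
        state["screen_table"][["compound", "drug_class"]].drop_duplicates().itertuples(
            index=False, name=None
        )
    )
    ranks = rank_mod.rank_compounds(deltas)
    classes = rank_mod.class_average_ranks(ranks, class_of, cfg.reference_class)
    classes.to_csv(run.emit("class_ranks.csv"), index=False)
    top = rank_mod.select_top(classes, ranks, class_of, min(cfg.top_k, len(classes)))
    top.to_csv(run.emit("top_classes.csv"), index=False)
    state["ranks"] = ranks


def _stage_ic50(run: _Run, state: dict):
    cfg = run.cfg
    if "panel_table" not in state:
        state["panel_table"] = io_mod.read_viability_csv(cfg.viability_panel_csv)
    fits = fit_ic50_table(state["panel_table"], day=cfg.panel_day)
    fits.to_csv(run.emit("ic50.csv"), index=False)
    state["ic50s"] = fits


def _stage_express(run: _Run, state: dict):
    cfg = run.cfg
    if "bundle" not in state:
        state["bundle"] = syn.ExpressionBundle(
            counts=io_mod.read_counts_tsv(cfg.counts_tsv),
            samples=io_mod.read_samples_tsv(cfg.samples_tsv),
        )
    bundle = state["bundle"]
    bundle.norm = expr_mod.normalize(
        bundle.counts, method=cfg.normalize_method, pseudocount=cfg.pseudocount
    )
    fc = expr_mod.fold_changes(bundle, pseudocount=cfg.pseudocount)
    fc.to_csv(run.emit("fc_long.csv"), index=False)
    grid = expr_mod.derive_gene_sets(fc, threshold=cfg.fc_threshold)
    grid.count_matrix("up").to_csv(run.emit("set_counts_up.csv"))
    grid.count_matrix("down").to_csv(run.emit("set_counts_down.csv"))
    gmt = {}
    for (line, comp), s in sorted(grid.up_sets.items()):
        gmt[f"{line}|{comp}|up"] = ("", sorted(s))
    for (line, comp), s in sorted(grid.down_sets.items()):
        gmt[f"{line}|{comp}|down"] = ("", sorted(s))
    io_mod.write_gmt(gmt, run.emit("gene_sets.gmt"))

    clusters = expr_mod.baseline_clusters(bundle, n_pcs=cfg.n_pcs, seed=cfg.seed)
    pd.Series(clusters.cluster_of_line, name="cluster").rename_axis("cell_line").to_csv(
        run.emit("clusters.csv")
    )
    de = expr_mod.cluster_de(clusters, bundle)
    de.to_csv(run.emit("cluster_de.csv"), index=False)

    summary = {}
    if "ic50s" in state:
        r, p, n = expr_mod.target_count_vs_ic50(grid, state["ic50s"])
        summary["target_count_vs_potency"] = {"pearson_r": r, "p": p, "n_drugs": n}
        resistance = expr_mod.cluster_drug_resistance(clusters, state["ic50s"])
        resistance.to_csv(run.emit("cluster_resistance.csv"), index=False)
        summary["n_drugs_cluster2_more_resistant"] = resistance.attrs[
            "n_significant_cluster2_higher"
        ]
    _json_dump(summary, run.emit("express_summary.json"))
    state["fc"] = fc
    state["grid"] = grid
    state["clusters"] = clusters


def _stage_overlap(run: _Run, state: dict):
    cfg = run.cfg
    report = overlap_mod.consistency_report(
        state["grid"],
        min_fraction_consistent=cfg.min_fraction_consistent,
        min_fraction_universal=cfg.min_fraction_universal,
    )
    _json_dump(report, run.emit("consistency_report.json"))
    # membership of the focal compound's per-line down-sets (<= 20 sets)
    grid = state["grid"]
    regulators = overlap_mod.classify_regulators(grid)
    downs = regulators[regulators["classification"] == "down-regulator"]
    focal = downs.sort_values("median_down", ascending=False)["compound"].iloc[0] if len(downs) else grid.compounds[0]
    named = {
        f"{line}|{focal}|down": grid.down_sets.get((line, focal), set())
        for line in grid.lines
    }
    membership, _regions = overlap_mod.intersection_matrix(named)
    membership.to_csv(run.emit("membership.csv"))
    state["report"] = report


def _stage_coexpr(run: _Run, state: dict):
    cfg = run.cfg
    bundle = state["bundle"]
    norm = bundle.norm
    net = coexpr_mod.build_network(
        norm, fit_cut=cfg.fit_cut, min_module_size=cfg.min_module_size
    )
    pd.Series(net.module_of, name="module").rename_axis("gene").to_csv(
        run.emit("modules.csv")
    )
    hub = cfg.hub_gene
    if hub is None:
        # highest-connectivity gene in the largest module
        genes = np.array(net.genes)
        labels = np.array([net.module_of[g] for g in genes])
        if (labels > 0).any():
            in_mod = labels == 1
            k = net.adjacency.sum(axis=1)
            hub = str(genes[in_mod][np.argmax(k[in_mod])])
        else:
            hub = str(genes[0])
    hood = coexpr_mod.hub_neighborhood(norm, hub, k=cfg.hub_k)
    hood.to_csv(run.emit("hub_neighborhood.csv"), index=False)
    module_genes = set(hood["gene"]) | {hub}
    effects = coexpr_mod.module_drug_effect(module_genes, state["fc"])
    effects.to_csv(run.emit("module_effects.csv"))
    state["network"] = net
    state["hub"] = hub
    state["hub_module_genes"] = module_genes


def _stage_atac(run: _Run, state: dict):
    cfg = run.cfg
    if "control_peaks" not in state:
        state["control_peaks"] = io_mod.read_bed_peaks(cfg.control_bed)
        state["treated_peaks"] = io_mod.read_bed_peaks(cfg.treated_bed)
        state["tss"] = io_mod.read_tss_bed(cfg.tss_bed)
    control, treated = state["control_peaks"], state["treated_peaks"]
    delta = atac_mod.match_peaks(
        control, treated, min_reciprocal_overlap=cfg.min_reciprocal_overlap
    )
    summary = delta.summary()
    summary["n_control"] = int(len(control))
    summary["n_treated"] = int(len(treated))
    union = pd.concat([control, delta.gained], ignore_index=True).drop_duplicates(
        subset=["chrom", "start", "end"]
    )
    links = atac_mod.link_peaks_to_genes(union, state["tss"], window=cfg.link_window)
    genes = sorted(state.get("hub_module_genes") or state["tss"])
    per_gene, pooled = atac_mod.gene_set_peak_changes(
        delta, links, genes, union, min_abs_log2=cfg.min_abs_log2
    )
    per_gene.drop(columns="significant_changes").to_csv(
        run.emit("gene_peak_changes.csv"), index=False
    )
    summary["gene_set"] = pooled
    _json_dump(summary, run.emit("peaks_delta_summary.json"))
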