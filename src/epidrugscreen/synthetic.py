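"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline is tested by recovery: the generators
here plant known structure (a delayed-action drug class, a consistent
down-regulated gene set, baseline expression clusters, co-expression modules
with hubs, treatment-induced chromatin-peak losses near module genes) and the
analysis stages must find it. No external data is ever required.

Three generators:

* :func:`generate_screen` -- replicate-level viability tables from 4PL
  dose-response curves with compound kinetics (acute / delayed / inert).
* :func:`generate_expression` -- negative-binomial RNA-seq count matrices
  with planted fold-change sets, cluster markers and latent-factor
  co-expression modules.
* :func:`generate_peaks` -- scored ATAC peak intervals with
  treatment-induced losses enriched near module-gene TSSs.

Counts are Gamma-Poisson (negative binomial) with the dispersion argument
given as the *biological coefficient of variation* of the Gamma mixing
distribution: ``dispersion=0.1`` means 10% extra-Poisson variability
(variance = mu + (dispersion*mu)**2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import VIABILITY_COLUMNS, fourpl
from .errors import ParameterError, UnknownEntityError

LN2 = math.log(2.0)

# ---------------------------------------------------------------------------
# Screen truth
# ---------------------------------------------------------------------------

KINETICS = ("acute", "delayed", "inert")


@dataclass
class ScreenTruth:
    """Generative description of a viability screen.

    ``fourpl`` maps (cell_line, compound) to (top, bottom, ic50, hill) with
    viabilities as fractions of control and ic50 in molar. ``kinetics`` maps
    each compound to one of ``acute | delayed | inert``: a delayed compound's
    effective IC-50 shrinks by ``kinetic_ic50_factor`` at the latest
    timepoint (efficacy builds up over exposure), an acute compound's grows
    by the same factor (the culture recovers), and inert compounds sit at
    viability 1 everywhere.
    """

    lines: list
    compounds: list  # list of (compound, drug_class)
    fourpl: dict  # (line, compound) -> (top, bottom, ic50, hill)
    kinetics: dict  # compound -> kinetics
    noise_sd: float = 0.05
    kinetic_ic50_factor: float = 20.0

    def __post_init__(self):
        comps = [c for c, _ in self.compounds]
        if len(set(comps)) != len(comps):
            raise ParameterError("duplicate compound ids")
        for comp in comps:
            if self.kinetics.get(comp) not in KINETICS:
                raise ParameterError(f"compound {comp!r} needs kinetics in {KINETICS}")
        for line in self.lines:
            for comp in comps:
                key = (line, comp)
                if key not in self.fourpl:
                    raise UnknownEntityError(
                        f"no 4PL parameters for line={line!r}, compound={comp!r}"
                    )
                top, bottom, ic50, hill = self.fourpl[key]
                if not (0.0 <= bottom <= top <= 1.2):
                    raise ParameterError(f"need 0 <= bottom <= top <= 1.2 at {key}")
                if ic50 <= 0 or hill <= 0:
                    raise ParameterError(f"ic50 and hill must be positive at {key}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def class_of(self) -> dict:
        return dict(self.compounds)


def generate_screen(
    truth: ScreenTruth,
    doses,
    timepoints,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Viability table for every compound x line x dose x timepoint x replicate.

    ``doses`` is either a single ascending list applied at every timepoint or
    a mapping timepoint -> dose list (ragged designs, e.g. two doses early
    and one late). Mean viability is the 4PL value at the kinetics-scaled
    IC-50; Gaussian noise with sd ``truth.noise_sd`` is added and truncated
    at 0 (fractions stay physical; means are unbiased at moderate noise).
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    timepoints = sorted(timepoints)
    if isinstance(doses, dict):
        dose_of = {t: sorted(doses[t]) for t in timepoints}
    else:
        dose_of = {t: sorted(doses) for t in timepoints}
    for t, ds in dose_of.items():
        if any(d <= 0 for d in ds):
            raise ParameterError(f"doses must be positive at day {t}")
    t0, t1 = timepoints[0], timepoints[-1]
    span = (t1 - t0) or 1.0

    rng = np.random.default_rng(seed)
    rows = []
    for comp, cls in truth.compounds:
        kin = truth.kinetics[comp]
        for line in truth.lines:
            top, bottom, ic50, hill = truth.fourpl[(line, comp)]
            for day in timepoints:
                frac = (day - t0) / span
                factor = truth.kinetic_ic50_factor ** frac
                if kin == "delayed":
                    ic50_eff = ic50 / factor
                elif kin == "acute":
                    ic50_eff = ic50 * factor
                else:
                    ic50_eff = ic50
                for dose in dose_of[day]:
                    mean = 1.0 if kin == "inert" else float(
                        fourpl(dose, top, bottom, ic50_eff, hill)
                    )
                    for rep in range(1, replicates + 1):
                        v = mean
                        if truth.noise_sd > 0:
                            v = max(0.0, v + rng.normal(0.0, truth.noise_sd))
                        rows.append((comp, cls, line, dose, day, rep, v))
    return pd.DataFrame(rows, columns=VIABILITY_COLUMNS)


# -- stock screen designs ---------------------------------------------------

PRIMARY_LINES = ["357", "372", "385", "408", "412"]
PANEL_LINES = [f"GS{i:02d}" for i in range(1, 13)]
PANEL_COMPOUNDS = [
    "A485",
    "Alexidine",
    "CPI203",
    "Decitabine",
    "Givinostat",
    "Hesperidin",
    "JQ1",
    "ML228",
    "OTX015",
    "Rucaparib",
    "Tazemetostat",
    "Vorinostat",
]

EARLY_DOSES_M = [1e-6, 1e-5]  # day-3 doses
LATE_DOSES_M = [5e-7]  # day-28 dose
PANEL_DOSES_M = [1e-8, 1e-7, 1e-6, 1e-5]  # 7-day panel doses


def screen_truth_106(seed: int = 0, noise_sd: float = 0.05) -> ScreenTruth:
    """Stock truth for the 106-compound x 5-line primary screen.

    36 drug classes. The BET class (CPI203, JQ1, OTX015, IBET151) is planted
    as strongly delayed-action with IC-50s near the tested doses, so it has
    the largest delta AUC by construction. The BRPF class is inert (delta
    AUC 0) and, because every other class is at least mildly delayed
    (positive delta AUC), BRPF is the least effective class and the natural
    auto-selected reference. The remaining 31 classes are mildly delayed
    with high IC-50s (weak effects at tested doses).
    """
    rng = np.random.default_rng(seed)
    classes = ["BET", "BRPF"] + [f"T{i:02d}" for i in range(1, 35)]
    compounds = [(c, "BET") for c in ("CPI203", "JQ1", "OTX015", "IBET151")]
    compounds += [(f"BRPF-{i}", "BRPF") for i in range(1, 4)]
    sizes = [3] * 31 + [2] * 3  # 99 compounds over 34 classes
    for cls, n in zip(classes[2:], sizes):
        compounds += [(f"{cls}-{i}", cls) for i in range(1, n + 1)]
    assert len(compounds) == 106

    fourpl_params, kinetics = {}, {}
    for comp, cls in compounds:
        if cls == "BET":
            base = 10.0 ** rng.uniform(-6.3, -5.8)  # 0.5-1.6 uM
            kinetics[comp] = "delayed"
        elif cls == "BRPF":
            base = 1e-5
            kinetics[comp] = "inert"
        else:
            base = 10.0 ** rng.uniform(-4.7, -3.7)  # 20-200 uM: weak
            kinetics[comp] = "delayed"
        for line in PRIMARY_LINES:
            ic50 = base * 10.0 ** rng.normal(0.0, 0.15)
            fourpl_params[(line, comp)] = (1.0, 0.0, ic50, 1.0)
    return ScreenTruth(
        lines=list(PRIMARY_LINES),
        compounds=compounds,
        fourpl=fourpl_params,
        kinetics=kinetics,
        noise_sd=noise_sd,
    )


def screen_truth_panel(
    seed: int = 0,
    noise_sd: float = 0.05,
    resistant_lines=None,
    resistant_compounds=None,
    resistance_factor: float = 10.0,
) -> ScreenTruth:
    """Stock truth for the 12-line x 12-compound follow-up panel (day 7).

    Optionally plants a resistant line group: for ``resistant_compounds``
    the IC-50 of every line in ``resistant_lines`` is multiplied by
    ``resistance_factor`` (default 10x), emulating a drug-resistant
    baseline-expression cluster.
    """
    rng = np.random.default_rng(seed)
    resistant_lines = set(resistant_lines or [])
    resistant_compounds = set(resistant_compounds or [])
    fourpl_params, kinetics = {}, {}
    compounds = [(c, c) for c in PANEL_COMPOUNDS]  # class = compound here
    for comp, _ in compounds:
        # kept well inside the tested dose range so that even a 10x
        # resistance shift stays identifiable from a 10 nM - 10 uM assay
        base = 10.0 ** rng.uniform(-7.5, -6.5)  # 30 - 300 nM
        kinetics[comp] = "acute"  # single-timepoint assay; kinetics unused
        for line in PANEL_LINES:
            ic50 = base * 10.0 ** rng.normal(0.0, 0.15)
            if line in resistant_lines and comp in resistant_compounds:
                ic50 *= resistance_factor
            fourpl_params[(line, comp)] = (1.0, 0.0, ic50, 1.0)
    return ScreenTruth(
        lines=list(PANEL_LINES),
        compounds=compounds,
        fourpl=fourpl_params,
        kinetics=kinetics,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTruth:
    """Planted structure of a gene-expression experiment.

    All gene sets are ids into a universe of ``n_genes`` genes. Planted
    treatment effects have magnitude ``effect_log2fc`` (>= 1 so planted
    genes clear a 2-fold rule in expectation): ``consistent_down[c]`` genes
    drop in every line treated with compound ``c``; ``line_stress_up[l]``
    genes rise in line ``l`` under every compound; ``line_specific_sets``
    are (up, down) sets private to one (line, compound) cell. Cluster
    marker genes are elevated in cluster-1 lines at baseline. Modules are
    (id, gene set, hub) triples sharing a per-sample latent factor.
    """

    n_genes: int
    cluster_of_line: dict  # line -> 1 | 2
    cluster_marker_genes: set
    consistent_down: dict  # compound -> set (empty for all but one)
    line_stress_up: dict  # line -> set
    line_specific_sets: dict  # (line, compound) -> (up set, down set)
    modules: list  # list of (module id, set, hub)
    effect_log2fc: float = 2.0
    module_r: float = 0.7

    def __post_init__(self):
        if self.effect_log2fc < 1.0:
            raise ParameterError("effect_log2fc must be >= 1")
        for mid, genes, hub in self.modules:
            if len(genes) < 30:
                raise ParameterError(f"module {mid} has < 30 genes")
            if hub not in genes:
                raise ParameterError(f"hub {hub!r} not in module {mid}")
        planted = set().union(
            *[s for s in self.consistent_down.values()],
            *[s for s in self.line_stress_up.values()],
            set(),
        )
        if planted & self.cluster_marker_genes:
            raise ParameterError("planted effect sets overlap cluster markers")

    @property
    def gene_ids(self) -> list:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def expression_truth(
    lines=None,
    compounds=None,
    n_genes: int = 2600,
    seed: int = 0,
    effect_log2fc: float = 2.0,
    consistent_down_compound: str = "CPI203",
    consistent_down_size: int = 100,
    n_cluster_markers: int = 40,
    stress_set_size: int = 30,
    module_sizes=(30, 60, 120),
    module_r: float = 0.7,
    cluster2_lines=None,
    specific_down_size: int = 150,
    specific_up_size: int = 150,
    couple_sizes_to=None,
) -> ExpressionTruth:
    """Stock expression truth for a line x compound panel.

    Gene blocks are allocated disjointly in order: co-expression modules,
    cluster markers, the consistent down-set of the BET-like compound
    (which also covers the first module, so that compound down-shifts a
    whole module -- the biology of a BET inhibitor closing a cell-cycle
    program), per-line stress-up sets, then a background pool from which
    line-specific up/down sets are sampled per (line, compound) cell. The
    BET-like compound gets an almost purely down-regulating profile; other
    compounds are predominantly up-regulators.

    ``couple_sizes_to`` optionally maps compound -> potency score (e.g.
    -log10 IC-50); line-specific set sizes then scale linearly with potency,
    planting the "bigger transcriptome effect = more potent" correlation.
    """
    lines = list(lines) if lines is not None else list(PANEL_LINES)
    compounds = list(compounds) if compounds is not None else list(PANEL_COMPOUNDS)
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cursor = 0

    def take(n):
        nonlocal cursor
        if cursor + n > n_genes:
            raise ParameterError("n_genes too small for requested planted sets")
        block = genes[cursor : cursor + n]
        cursor += n
        return block

    modules = []
    for mid, size in enumerate(module_sizes, start=1):
        block = take(size)
        modules.append((mid, set(block), block[0]))  # first gene is the hub
    markers = set(take(n_cluster_markers))
    cons_extra = take(consistent_down_size)
    # the BET-like compound's consistent set includes module 1 wholesale
    consistent_down = {c: set() for c in compounds}
    if consistent_down_compound in consistent_down:
        module1 = modules[0][1] if modules else set()
        consistent_down[consistent_down_compound] = set(cons_extra) | module1
    stress = {line: set(take(stress_set_size)) for line in lines}
    pool = genes[cursor:]
    # potency coupling can scale cell sizes up to 1.75x
    max_draw = int(1.75 * (specific_down_size + specific_up_size)) + 10
    if len(pool) < max_draw:
        raise ParameterError(
            "n_genes too small for the line-specific background pool "
            f"(need >= {cursor + max_draw})"
        )

    if cluster2_lines is None:
        cluster2_lines = set(sorted(lines)[-max(1, len(lines) // 3) :])
    cluster_of_line = {
        line: (2 if line in set(cluster2_lines) else 1) for line in lines
    }

    scale = {c: 1.0 for c in compounds}
    if couple_sizes_to:
        pot = np.array([couple_sizes_to[c] for c in compounds], dtype=float)
        lo, hi = pot.min(), pot.max()
        rel = (pot - lo) / (hi - lo) if hi > lo else np.ones_like(pot)
        scale = {c: 0.25 + 1.5 * r for c, r in zip(compounds, rel)}

    line_specific = {}
    for line in lines:
        for comp in compounds:
            if comp == consistent_down_compound:
                n_up, n_down = 5, specific_down_size
            else:
                n_up, n_down = specific_up_size, 30
            n_up = max(0, int(round(n_up * scale[comp])))
            n_down = max(0, int(round(n_down * scale[comp])))
            chosen = rng.choice(len(pool), size=n_up + n_down, replace=False)
            up = {pool[i] for i in chosen[:n_up]}
            down = {pool[i] for i in chosen[n_up:]}
            line_specific[(line, comp)] = (up, down)

    return ExpressionTruth(
        n_genes=n_genes,
        cluster_of_line=cluster_of_line,
        cluster_marker_genes=markers,
        consistent_down=consistent_down,
        line_stress_up=stress,
        line_specific_sets=line_specific,
        modules=modules,
        effect_log2fc=effect_log2fc,
        module_r=module_r,
    )


@dataclass
class ExpressionBundle:
    """Counts plus sample metadata; ``norm`` is filled by normalization."""

    counts: pd.DataFrame  # genes x samples, nonnegative ints
    samples: pd.DataFrame  # index sample id; columns cell_line, compound, dose_nM
    norm: pd.DataFrame | None = field(default=None)

    def control_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["compound"] == "control"]


def generate_expression(
    truth: ExpressionTruth,
    lines,
    compounds,
    libsize_range=(1_500_000, 3_000_000),
    dispersion: float = 0.1,
    seed: int = 0,
    extra_log2_sd: float = 0.15,
    equal_libsize: bool = False,
) -> ExpressionBundle:
    """Negative-binomial counts for one control + one sample per compound per line.

    Per-gene baseline abundances are log-uniform (mean counts roughly
    100-4000 at the default library sizes, keeping shot noise small relative
    to biological noise). On the log2 mean scale each sample receives:
    module latent factors (genes in a module share a per-sample N(0,1)
    factor, loadings calibrated so the across-sample Pearson correlation of
    module partners is ``truth.module_r`` in expectation; the hub gets the
    largest loading), cluster-marker elevation by ``effect_log2fc`` in
    cluster-1 lines, planted treatment effects of +-``effect_log2fc``, and
    i.i.d. N(0, extra_log2_sd) sample-level biological noise. Counts are
    Gamma-Poisson with biological CV ``dispersion`` (see module docstring).
    """
    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0 (use a tiny value for ~Poisson)")
    lines = list(lines)
    compounds = list(compounds)
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    n_genes = truth.n_genes
    gene_idx = {g: i for i, g in enumerate(genes)}

    base_log2 = rng.uniform(np.log2(100.0), np.log2(4000.0), size=n_genes)
    denom = float(np.sum(2.0 ** base_log2))

    # latent-factor loading calibrated against total non-factor log2 variance
    mu_typ = float(np.mean(2.0 ** base_log2))
    nb_log2_var = (dispersion**2 + 1.0 / mu_typ) / (LN2**2)
    sigma2 = extra_log2_sd**2 + nb_log2_var
    r = truth.module_r
    lam = math.sqrt(r / (1.0 - r) * sigma2) / 0.85  # 0.85 = mean loading multiplier

    # loadings alternate in sign within a module (co- and anti-regulated
    # members): the module's total read mass is then nearly invariant to its
    # latent factor, so library-size factors do not absorb it; unsigned
    # adjacency (|r|) groups both signs into one module
    loading = np.zeros(n_genes)
    module_of_gene = np.full(n_genes, -1)
    for mid, mgenes, hub in truth.modules:
        members = [hub] + sorted(g for g in mgenes if g != hub)
        for pos, g in enumerate(members):
            i = gene_idx[g]
            module_of_gene[i] = mid
            mult = 1.0 if g == hub else rng.uniform(0.75, 0.95)
            sign = 1.0 if pos % 2 == 0 else -1.0
            loading[i] = sign * lam * mult

    marker_idx = np.array(sorted(gene_idx[g] for g in truth.cluster_marker_genes), int)

    sample_ids, meta_rows, cols = [], [], []
    shape = 1.0 / (dispersion**2)
    for line in lines:
        in_cluster1 = truth.cluster_of_line.get(line, 1) == 1
        for comp in ["control"] + compounds:
            sid = f"{line}|{comp}"
            sample_ids.append(sid)
            meta_rows.append((line, comp, 0 if comp == "control" else 500))
            log2mu = base_log2.copy()
            # module latent factor, one draw per module per sample
            for mid, _, _ in truth.modules:
                z = rng.standard_normal()
                log2mu[module_of_gene == mid] += loading[module_of_gene == mid] * z
            if in_cluster1 and marker_idx.size:
                log2mu[marker_idx] += truth.effect_log2fc
            if comp != "control":
                eff = truth.effect_log2fc
                for g in truth.consistent_down.get(comp, ()):
                    log2mu[gene_idx[g]] -= eff
                for g in truth.line_stress_up.get(line, ()):
                    log2mu[gene_idx[g]] += eff
                up, down = truth.line_specific_sets.get((line, comp), (set(), set()))
                for g in up:
                    log2mu[gene_idx[g]] += eff
                for g in down:
                    log2mu[gene_idx[g]] -= eff
            if extra_log2_sd > 0:
                log2mu = log2mu + rng.normal(0.0, extra_log2_sd, size=n_genes)
            libsize = (
                float(np.mean(libsize_range))
                if equal_libsize
                else rng.uniform(*libsize_range)
            )
            mu = (libsize / denom) * 2.0 ** log2mu
            lam_nb = rng.gamma(shape, mu / shape)
            cols.append(rng.poisson(lam_nb))

    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    samples = pd.DataFrame(
        meta_rows,
        index=pd.Index(sample_ids, name="sample"),
        columns=["cell_line", "compound", "dose_nM"],
    )
    return ExpressionBundle(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# Peak truth
# ---------------------------------------------------------------------------


@dataclass
class PeakTruth:
    """Generative description of a scored ATAC peak landscape.

    Intervals are 0-based half-open on a single synthetic chromosome of
    ``genome_length`` bp. Under treatment each peak is lost independently
    with probability ``lost_fraction_global``, boosted to
    ``lost_near_module_tss`` for peaks within ``link_window`` of a module
    gene's TSS (BET inhibition closes chromatin preferentially at the
    planted module).
    """

    genome_length: int
    peaks: pd.DataFrame  # chrom, start, end, score
    lost_fraction_global: float
    lost_near_module_tss: float
    tss_table: dict  # gene -> (chrom, pos, strand)
    module_genes: set
    link_window: int = 50_000

    def __post_init__(self):
        for frac in (self.lost_fraction_global, self.lost_near_module_tss):
            if not (0.0 <= frac <= 1.0):
                raise ParameterError("loss fractions must lie in [0, 1]")
        p = self.peaks
        if ((p["start"] >= p["end"]) | (p["start"] < 0) | (p["end"] > self.genome_length)).any():
            raise ParameterError("peak intervals must satisfy 0 <= start < end <= genome")


def peak_truth(
    genes,
    module_genes,
    genome_length: int = 50_000_000,
    n_background_peaks: int = 1500,
    peaks_per_gene: int = 3,
    lost_fraction_global: float = 0.15,
    lost_near_module_tss: float = 0.6,
    link_window: int = 50_000,
    seed: int = 0,
) -> PeakTruth:
    """Stock peak truth: every gene gets nearby peaks plus uniform background."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    module_genes = set(module_genes)
    margin = link_window + 1000
    tss_pos = np.sort(
        rng.choice(
            np.arange(margin, genome_length - margin, 2000), size=len(genes),
            replace=False,
        )
    )
    tss_table = {
        g: ("chr1", int(p), "+" if rng.random() < 0.5 else "-")
        for g, p in zip(genes, tss_pos)
    }
    starts, widths = [], []
    for g in genes:
        pos = tss_table[g][1]
        offs = rng.integers(-20_000, 20_000, size=peaks_per_gene)
        starts.extend(pos + offs)
        widths.extend(rng.integers(200, 800, size=peaks_per_gene))
    starts.extend(rng.integers(0, genome_length - 1000, size=n_background_peaks))
    widths.extend(rng.integers(200, 800, size=n_background_peaks))
    starts = np.clip(np.asarray(starts), 0, genome_length - 1000)
    ends = starts + np.asarray(widths)
    scores = rng.lognormal(mean=4.0, sigma=0.5, size=starts.size)
    peaks = (
        pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": ends, "score": scores}
        )
        .drop_duplicates(subset=["chrom", "start", "end"])
        .sort_values(["chrom", "start", "end"], ignore_index=True)
    )
    return PeakTruth(
        genome_length=genome_length,
        peaks=peaks,
        lost_fraction_global=lost_fraction_global,
        lost_near_module_tss=lost_near_module_tss,
        tss_table=tss_table,
        module_genes=module_genes,
        link_window=link_window,
    )


def generate_peaks(truth: PeakTruth, condition: str, seed: int = 0) -> pd.DataFrame:
    """Peak set for ``condition`` in {'control', 'treated'}.

    Control returns the truth peaks unchanged. Treated removes peaks
    independently (probability boosted near module-gene TSSs, see
    :class:`PeakTruth`) and jitters retained scores by a 2**N(0, 0.1)
    factor.
    """
    if condition not in ("control", "treated"):
        raise ParameterError("condition must be 'control' or 'treated'")
    peaks = truth.peaks.copy().reset_index(drop=True)
    if condition == "control":
        return peaks
    rng = np.random.default_rng(seed)
    module_tss = np.array(
        sorted(truth.tss_table[g][1] for g in truth.module_genes if g in truth.tss_table)
    )
    p_loss = np.full(len(peaks), truth.lost_fraction_global)
    if module_tss.size:
        w = truth.link_window
        starts = peaks["start"].to_numpy()
        ends = peaks["end"].to_numpy()
        # overlap [tss - w, tss + w): nearest-TSS distance test
        left = np.searchsorted(module_tss, starts - w, side="left")
        near = np.zeros(len(peaks), dtype=bool)
        for i in range(len(peaks)):
            j = left[i]
            if j < module_tss.size and module_tss[j] - w < ends[i]:
                near[i] = True
        p_loss[near] = truth.lost_near_module_tss
    keep = rng.random(len(peaks)) >= p_loss
    out = peaks.loc[keep].copy()
    out["score"] = out["score"] * 2.0 ** rng.normal(0.0, 0.1, size=len(out))
    return out.sort_values(["chrom", "start", "end"], ignore_index=True)
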