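"""Count normalization, fold-change gene sets, potency correlation,
baseline PCA clustering and cluster-level differential expression.

The expression design is one control sample plus one treated sample per
compound for every cell line. Fold changes are computed within line
(treated minus control on the normalized log2 scale), the >=2-fold gene
sets drive the overlap analysis, and the *untreated* (control) samples
drive PCA clustering of lines, cluster-level IC-50 comparison, and the
cluster differential-expression ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, MissingDataError, ParameterError
from .overlap import GeneSetGrid
from .synthetic import ExpressionBundle


@dataclass
class ClusterResult:
    """Two-way partition of cell lines from baseline expression.

    Cluster 1 is the cluster with more lines (tie: the one containing the
    lexicographically first line). ``de_table`` is filled by
    :func:`cluster_de`.
    """

    cluster_of_line: dict
    pc_scores: pd.DataFrame  # line x PCs
    de_table: pd.DataFrame | None = None


def normalize(
    counts: pd.DataFrame, method: str = "median_of_ratios_log2", pseudocount: float = 1.0
) -> pd.DataFrame:
    """Library-size normalization to the log2 scale.

    ``cpm_log2``: log2(1e6 * count / library size + pseudocount).
    ``median_of_ratios_log2``: per-sample size factor = median over genes
    (restricted to genes with a positive geometric mean, i.e. no zero
    counts) of count / geometric mean; norm = log2(count / sf + pseudocount).
    All-zero gene rows are retained, never silently dropped.
    """
    if (counts.to_numpy() < 0).any():
        raise ParameterError("counts must be nonnegative")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ParameterError(f"all-zero sample(s): {bad}")
    if method == "cpm_log2":
        scaled = counts * (1e6 / libsize)
    elif method == "median_of_ratios_log2":
        arr = counts.to_numpy(dtype=float)
        positive = (arr > 0).all(axis=1)
        if not positive.any():
            raise DegenerateInputError(
                "median-of-ratios undefined: no gene has nonzero counts in all samples"
            )
        ref = arr[positive]
        geomean = np.exp(np.mean(np.log(ref), axis=1))
        sf = np.median(ref / geomean[:, None], axis=0)
        scaled = counts / sf
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    return np.log2(scaled + pseudocount)


def fold_changes(bundle: ExpressionBundle, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2 fold change of every treated sample vs its line's control.

    Uses ``bundle.norm`` if present, otherwise normalizes the counts with the
    default method. Returns a long frame with columns
    ``gene, cell_line, compound, log2fc``.
    """
    norm = bundle.norm
    if norm is None:
        norm = normalize(bundle.counts, pseudocount=pseudocount)
    samples = bundle.samples
    blocks = []
    for line, grp in samples.groupby("cell_line", sort=True):
        controls = grp.index[grp["compound"] == "control"]
        if len(controls) == 0:
            raise MissingDataError(f"cell line {line!r} has no control sample")
        ctrl = norm[controls].mean(axis=1)
        treated = grp[grp["compound"] != "control"]
        for sid, row in treated.iterrows():
            fc = norm[sid] - ctrl
            blocks.append(
                pd.DataFrame(
                    {
                        "gene": norm.index,
                        "cell_line": line,
                        "compound": row["compound"],
                        "log2fc": fc.to_numpy(),
                    }
                )
            )
    return pd.concat(blocks, ignore_index=True)


def derive_gene_sets(fc: pd.DataFrame, threshold: float = 2.0) -> GeneSetGrid:
    """Up/down gene sets per (line, compound) at a fold-change threshold.

    ``up = {log2fc >= log2(threshold)}``, ``down = {log2fc <= -log2(threshold)}``
    (boundaries inclusive). ``threshold`` is a plain fold (must be > 1).
    """
    if threshold <= 1.0:
        raise ParameterError("threshold must be > 1 (a fold change)")
    cut = np.log2(threshold)
    lines = sorted(fc["cell_line"].unique())
    compounds = sorted(fc["compound"].unique())
    up_sets, down_sets = {}, {}
    for (line, comp), grp in fc.groupby(["cell_line", "compound"], sort=True):
        vals = grp["log2fc"].to_numpy()
        g = grp["gene"].to_numpy()
        up_sets[(line, comp)] = set(g[vals >= cut])
        down_sets[(line, comp)] = set(g[vals <= -cut])
    return GeneSetGrid(up_sets=up_sets, down_sets=down_sets, lines=lines, compounds=compounds)


def target_count_vs_ic50(grid: GeneSetGrid, ic50s: pd.DataFrame):
    """Pearson correlation of per-drug transcriptome effect vs potency.

    Per drug: the mean over lines of |up| + |down| and the mean over lines
    of -log10 IC-50 (``ic50s`` needs columns ``compound, cell_line,
    ic50_M``). Returns ``(r, p, n_drugs)``; if the target counts have zero
    variance the correlation is undefined and (nan, nan, n) is returned.
    """
    counts, potency = [], []
    pot_per = ic50s.assign(neglog=-np.log10(ic50s["ic50_M"]))
    pot_mean = pot_per.groupby("compound")["neglog"].mean()
    for comp in grid.compounds:
        if comp not in pot_mean.index:
            raise MissingDataError(f"no IC-50 for compound {comp!r}")
        sizes = [
            len(grid.up_sets.get((line, comp), ()))
            + len(grid.down_sets.get((line, comp), ()))
            for line in grid.lines
        ]
        counts.append(float(np.mean(sizes)))
        potency.append(float(pot_mean[comp]))
    if len(counts) < 3:
        raise ParameterError("need at least 3 drugs for a correlation")
    if np.std(counts) == 0.0 or np.std(potency) == 0.0:
        return float("nan"), float("nan"), len(counts)
    r, p = stats.pearsonr(counts, potency)
    return float(r), float(p), len(counts)


def baseline_clusters(
    bundle: ExpressionBundle,
    n_pcs: int = 2,
    seed: int = 0,
    n_top_genes: int = 2000,
) -> ClusterResult:
    """PCA + k-means(2) clustering of cell lines from control samples.

    Genes are restricted to the ``n_top_genes`` most variable across lines
    and centered; k-means (k=2, 10 restarts, seeded) runs on the first
    ``n_pcs`` PC scores. Deterministic given the seed and invariant to line
    order.
    """
    norm = bundle.norm if bundle.norm is not None else normalize(bundle.counts)
    ctrl = bundle.control_samples()
    if len(ctrl) < 4:
        raise ParameterError("need >= 4 control samples (one per line)")
    lines = sorted(ctrl["cell_line"])
    sid_of = {row["cell_line"]: sid for sid, row in ctrl.iterrows()}
    mat = norm[[sid_of[line] for line in lines]].to_numpy().T  # line x gene
    if np.unique(mat, axis=0).shape[0] < 2:
        raise DegenerateInputError("fewer than 2 distinct expression profiles")
    variances = mat.var(axis=0)
    keep = np.argsort(-variances, kind="stable")[: min(n_top_genes, mat.shape[1])]
    sub = mat[:, keep]
    sub = sub - sub.mean(axis=0)
    n_comp = min(n_pcs, len(lines) - 1, sub.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(sub)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(scores)
    labels = km.labels_
    members = {k: [l for l, lab in zip(lines, labels) if lab == k] for k in (0, 1)}
    if not members[0] or not members[1]:
        raise DegenerateInputError("k-means produced an empty cluster")
    # cluster 1 = more lines; tie -> cluster containing lexicographically first line
    if len(members[0]) != len(members[1]):
        one = 0 if len(members[0]) > len(members[1]) else 1
    else:
        first = min(lines)
        one = 0 if first in members[0] else 1
    cluster_of_line = {l: (1 if lab == one else 2) for l, lab in zip(lines, labels)}
    pc_scores = pd.DataFrame(
        scores, index=pd.Index(lines, name="cell_line"),
        columns=[f"PC{i+1}" for i in range(n_comp)],
    )
    return ClusterResult(cluster_of_line=cluster_of_line, pc_scores=pc_scores)


def cluster_drug_resistance(
    clusters: ClusterResult, ic50s: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-drug Welch t-test of log10 IC-50 between the two baseline clusters.

    Reports geometric-mean IC-50s per cluster, the two-sided p, whether
    cluster 2 is the more resistant (higher IC-50), and a significance flag.
    A cluster with fewer than 2 lines gives a missing p; means are still
    reported. The frame's ``attrs['n_significant_cluster2_higher']`` counts
    drugs with p < alpha and cluster-2-higher direction.
    """
    df = ic50s.copy()
    df["cluster"] = df["cell_line"].map(clusters.cluster_of_line)
    if df["cluster"].isna().any():
        missing = sorted(df.loc[df["cluster"].isna(), "cell_line"].unique())
        raise MissingDataError(f"lines without a cluster: {missing}")
    rows = []
    for comp, grp in df.groupby("compound", sort=True):
        g1 = np.log10(grp.loc[grp["cluster"] == 1, "ic50_M"].to_numpy())
        g2 = np.log10(grp.loc[grp["cluster"] == 2, "ic50_M"].to_numpy())
        if len(g1) >= 2 and len(g2) >= 2:
            p = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
        else:
            p = float("nan")
        m1, m2 = float(np.mean(g1)), float(np.mean(g2))
        rows.append(
            {
                "compound": comp,
                "mean_ic50_c1": 10.0 ** m1,
                "mean_ic50_c2": 10.0 ** m2,
                "p": p,
                "cluster2_higher": bool(m2 > m1),
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_significant_cluster2_higher"] = int(
        (out["significant"] & out["cluster2_higher"]).sum()
    )
    return out


def cluster_de(clusters: ClusterResult, bundle: ExpressionBundle) -> pd.DataFrame:
    """Gene ranking by differential expression between baseline clusters.

    Control samples only. Per gene: ``mean_diff`` (cluster 1 - cluster 2,
    log2 units), Welch p (genes with zero variance in a cluster get that
    cluster's variance floored at the smallest nonzero gene variance and are
    flagged), Benjamini-Hochberg q, and ``rank_score = |mean_diff| *
    -log10(p)``. Sorted by rank_score descending. The result is also stored
    on ``clusters.de_table``.
    """
    norm = bundle.norm if bundle.norm is not None else normalize(bundle.counts)
    ctrl = bundle.control_samples()
    sid_of = {row["cell_line"]: sid for sid, row in ctrl.iterrows()}
    lines1 = [l for l, c in clusters.cluster_of_line.items() if c == 1]
    lines2 = [l for l, c in clusters.cluster_of_line.items() if c == 2]
    m1 = norm[[sid_of[l] for l in sorted(lines1)]].to_numpy()
    m2 = norm[[sid_of[l] for l in sorted(lines2)]].to_numpy()
    n1, n2 = m1.shape[1], m2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ParameterError("each cluster needs >= 2 lines for a t-test")
    mu1, mu2 = m1.mean(axis=1), m2.mean(axis=1)
    v1, v2 = m1.var(axis=1, ddof=1), m2.var(axis=1, ddof=1)
    nonzero = np.concatenate([v1[v1 > 0], v2[v2 > 0]])
    if nonzero.size == 0:
        raise DegenerateInputError("all genes have zero variance within clusters")
    floor = float(nonzero.min())
    floored = (v1 == 0) | (v2 == 0)
    v1f = np.where(v1 == 0, floor, v1)
    v2f = np.where(v2 == 0, floor, v2)
    se2 = v1f / n1 + v2f / n2
    t = (mu1 - mu2) / np.sqrt(se2)
    df = se2**2 / ((v1f / n1) ** 2 / (n1 - 1) + (v2f / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 1e-300, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    diff = mu1 - mu2
    score = np.abs(diff) * (-np.log10(p))
    out = pd.DataFrame(
        {
            "gene": norm.index,
            "mean_diff": diff,
            "p": p,
            "q": q,
            "rank_score": score,
            "variance_floored": floored,
        }
    ).sort_values(["rank_score", "gene"], ascending=[False, True], ignore_index=True)
    clusters.de_table = out
    return out
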