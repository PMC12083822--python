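"""Weighted co-expression network analysis (WGCNA-style, self-contained).

Pipeline: Pearson correlation across all samples -> unsigned adjacency
``a_ij = |r_ij| ** beta`` with the soft-thresholding power ``beta`` chosen as
the smallest tested power giving an approximately scale-free connectivity
distribution -> topological overlap matrix (TOM) -> average-linkage
hierarchical clustering on ``1 - TOM`` with a deterministic height scan and a
minimum module size (default 30). Module 0 means unassigned.

The tree cut deliberately replaces the dynamic-tree-cut family with a fully
specified rule: the dendrogram is cut at every height on a fixed grid
(0.05..0.99, step 0.01) and the height producing the most clusters of at
least the minimum size wins (ties go to the lower height). This keeps module
detection deterministic and unit-testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, ParameterError, UnknownEntityError

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)

HEIGHT_GRID = np.round(np.arange(0.05, 0.995, 0.01), 2)


@dataclass
class CoexprNetwork:
    genes: list
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    module_of: dict  # gene -> module id (0 = unassigned)
    min_module_size: int
    fit_table: pd.DataFrame | None = None


def _drop_constant(norm: pd.DataFrame):
    arr = norm.to_numpy(dtype=float)
    keep = arr.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    return norm.loc[keep], n_dropped


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean connectivity) over k-bins."""
    k = np.asarray(k, dtype=float)
    if k.size < 3:
        raise DegenerateInputError("need >= 3 genes to assess scale-free fit")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def pick_soft_threshold(
    norm: pd.DataFrame, powers=DEFAULT_POWERS, fit_cut: float = 0.8
):
    """Smallest power whose connectivity distribution is ~scale-free.

    Returns ``(beta, fit_table)``; ``fit_table`` has one row per power with
    the scale-free R^2 and mean connectivity, and
    ``fit_table.attrs['converged']`` records whether any power reached
    ``fit_cut`` (otherwise beta maximizes R^2).
    Constant genes are removed first (their correlation is undefined);
    the dropped count is recorded in ``fit_table.attrs['n_constant_dropped']``.
    """
    powers = sorted(powers)
    if norm.shape[1] < 3:
        raise ParameterError("need >= 3 samples for correlations")
    clean, n_dropped = _drop_constant(norm)
    if clean.shape[0] < 3:
        raise DegenerateInputError("need >= 3 non-constant genes")
    cor = np.abs(np.corrcoef(clean.to_numpy(dtype=float)))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in powers:
        k = (cor**beta).sum(axis=1)
        rows.append(
            {"power": beta, "fit_r2": scale_free_fit(k), "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    ok = table[table["fit_r2"] >= fit_cut]
    if len(ok):
        beta = int(ok["power"].iloc[0])
        converged = True
    else:
        # no power reaches the cut (e.g. strongly modular rather than
        # scale-free data): take the best R^2 among powers that keep the
        # network connected (mean k >= 1) rather than a degenerate high power
        viable = table[table["mean_k"] >= 1.0]
        pick_from = viable if len(viable) else table
        beta = int(pick_from.loc[pick_from["fit_r2"].idxmax(), "power"])
        converged = False
    table.attrs["converged"] = converged
    table.attrs["n_constant_dropped"] = n_dropped
    return beta, table


def adjacency_matrix(norm: pd.DataFrame, beta: int, signed: bool = False):
    """Soft-thresholded adjacency from gene x sample expression.

    Unsigned (default): ``a_ij = |r_ij| ** beta``. Signed:
    ``a_ij = ((1 + r_ij) / 2) ** beta``. Diagonal is zero (self-edges are
    excluded from connectivity). Returns ``(genes, adjacency)`` with
    constant genes removed.
    """
    clean, _ = _drop_constant(norm)
    r = np.corrcoef(clean.to_numpy(dtype=float))
    adj = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(adj, 0.0)
    return list(clean.index), adj


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    ``tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    ``i != j`` with ``k_i = sum_{u != i} a_iu``; ``tom_ii = 1``. Input must
    be symmetric with entries in [0, 1] and zero diagonal (a unit diagonal
    is zeroed internally since self-edges do not count toward k).
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ParameterError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ParameterError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu * a_uj (diagonal contributes nothing)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom: np.ndarray, min_module_size: int = 30) -> np.ndarray:
    """Average-linkage module assignment from a TOM.

    Returns an integer label per gene: modules are numbered 1..m by
    decreasing size (ties broken by smallest member index); 0 means
    unassigned. Fewer genes than ``min_module_size`` leaves everything
    unassigned.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if n < min_module_size:
        return np.zeros(n, dtype=int)
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")

    # scan a fixed height grid: maximize the number of clusters reaching the
    # minimum size; among ties prefer the cut assigning more genes to valid
    # clusters (a low tie-broken cut can shatter a large module into
    # fragments that still clear the size bar), then the lower height
    best_labels, best_key = None, (-1, -1)
    for h in HEIGHT_GRID:
        labels = hierarchy.fcluster(link, t=h, criterion="distance")
        sizes = np.bincount(labels)
        valid = sizes[1:][sizes[1:] >= min_module_size]
        key = (int(valid.size), int(valid.sum()))
        if key > best_key:
            best_labels, best_key = labels, key
    if best_key[0] <= 0:
        return np.zeros(n, dtype=int)

    sizes = np.bincount(best_labels)
    keep = [c for c in range(1, sizes.size) if sizes[c] >= min_module_size]
    first_member = {c: int(np.argmax(best_labels == c)) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_member[c]))
    relabel = {c: i + 1 for i, c in enumerate(keep)}
    return np.array([relabel.get(c, 0) for c in best_labels], dtype=int)


def build_network(
    norm: pd.DataFrame,
    powers=DEFAULT_POWERS,
    fit_cut: float = 0.8,
    min_module_size: int = 30,
    signed: bool = False,
    beta: int | None = None,
) -> CoexprNetwork:
    """End-to-end: soft threshold, adjacency, TOM, module detection."""
    fit_table = None
    if beta is None:
        beta, fit_table = pick_soft_threshold(norm, powers=powers, fit_cut=fit_cut)
    genes, adj = adjacency_matrix(norm, beta, signed=signed)
    tom = tom_matrix(adj)
    labels = detect_modules(tom, min_module_size=min_module_size)
    return CoexprNetwork(
        genes=genes,
        beta=beta,
        adjacency=adj,
        tom=tom,
        module_of=dict(zip(genes, labels.tolist())),
        min_module_size=min_module_size,
        fit_table=fit_table,
    )


def hub_neighborhood(norm: pd.DataFrame, hub: str, k: int = 20) -> pd.DataFrame:
    """The k genes most correlated with a hub, across all samples.

    Correlations are Pearson over every sample in ``norm`` (all drugs, all
    lines). Returns a frame sorted by |r| descending (ties by gene id) with
    columns ``gene, r, spoke_length`` where ``spoke_length = 1 - |r|`` (a
    short spoke means a strong partner).
    """
    if hub not in norm.index:
        raise UnknownEntityError(f"hub gene {hub!r} not in expression matrix")
    others = norm.drop(index=hub)
    if len(others) < k:
        raise ParameterError(f"need >= {k} genes besides the hub")
    hub_vec = norm.loc[hub].to_numpy(dtype=float)
    if hub_vec.std() == 0:
        raise DegenerateInputError(f"hub gene {hub!r} is constant")
    arr = others.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    centered = arr - arr.mean(axis=1, keepdims=True)
    hc = hub_vec - hub_vec.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ hc) / (np.sqrt((centered**2).sum(axis=1)) * np.sqrt((hc**2).sum()))
    r = np.where(sd == 0, 0.0, r)
    out = pd.DataFrame({"gene": others.index, "r": r})
    out["abs_r"] = out["r"].abs()
    out = out.sort_values(["abs_r", "gene"], ascending=[False, True], kind="mergesort")
    out = out.head(k).drop(columns="abs_r").reset_index(drop=True)
    out["spoke_length"] = 1.0 - out["r"].abs()
    return out


def module_drug_effect(
    module_genes, fc: pd.DataFrame, expanded: bool = False
) -> pd.DataFrame:
    """Mean log2 fold change of a gene set per drug, across all lines.

    ``fc`` is the long fold-change table. With ``expanded=True`` returns the
    gene x drug matrix of per-gene means instead of the pooled per-drug
    mean.
    """
    module_genes = set(module_genes)
    if not module_genes:
        raise ParameterError("empty module")
    sub = fc[fc["gene"].isin(module_genes)]
    if sub.empty:
        raise UnknownEntityError("none of the module genes appear in the fold-change table")
    if expanded:
        return sub.pivot_table(index="gene", columns="compound", values="log2fc", aggfunc="mean")
    out = sub.groupby("compound")["log2fc"].mean().to_frame("mean_log2fc")
    out.index.name = "compound"
    return out
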