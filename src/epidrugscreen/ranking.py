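"""Compound ranking and drug-class rank aggregation for the primary screen.

Compounds are ranked by mean delta AUC across cell lines (rank 1 = highest,
i.e. most anti-tumor efficacy; ties receive average ranks). Each drug class
is summarized by the arithmetic mean of its members' global ranks, and
compared to a reference class -- by default the *least* effective class
(largest average rank) -- with a Welch two-sample t-test on member ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


@dataclass(frozen=True)
class ClassRankResult:
    drug_class: str
    member_compounds: list = field(default_factory=list)
    average_rank: float = float("nan")
    p_vs_reference: float = float("nan")
    class_rank: int = 0


def rank_compounds(delta) -> pd.DataFrame:
    """Global compound ranking from per-line delta-AUC records.

    ``delta`` is a DataFrame with columns ``compound, cell_line, delta_auc``
    (extra columns ignored) or an iterable of
    :class:`~epidrugscreen.dose_response.DeltaAucRecord`. Returns a frame
    indexed by compound with ``mean_delta_auc`` and ``rank`` (1 = best;
    ties averaged).
    """
    if not isinstance(delta, pd.DataFrame):
        delta = pd.DataFrame(
            [(r.compound, r.cell_line, r.delta_auc) for r in delta],
            columns=["compound", "cell_line", "delta_auc"],
        )
    if delta.empty:
        raise ParameterError("no delta-AUC records")
    mean = delta.groupby("compound")["delta_auc"].mean().sort_index()
    ranks = stats.rankdata(-mean.to_numpy(), method="average")
    return pd.DataFrame(
        {"mean_delta_auc": mean.to_numpy(), "rank": ranks}, index=mean.index
    )


def class_average_ranks(
    ranks: pd.DataFrame,
    class_of: dict,
    reference_class: str = "auto",
    on: str = "rank",
) -> pd.DataFrame:
    """Average rank per drug class plus a t-test against a reference class.

    ``class_of`` maps every compound to its class. With
    ``reference_class="auto"`` the class with the worst (largest) average
    rank is the reference, mirroring comparison against the least effective
    class. The p-value is a Welch t-test of member ranks against the
    reference class's member ranks (``on="delta"`` tests the mean delta AUCs
    instead); the reference class itself gets p = 1, and classes with a
    single member get a missing p (variance undefined) and a flag.

    Returns a frame sorted by ``average_rank`` ascending with columns
    ``drug_class, n_members, average_rank, p_vs_reference, single_member,
    class_rank``.
    """
    missing = [c for c in ranks.index if c not in class_of]
    if missing:
        raise ParameterError(f"compounds without a class: {missing[:5]}")
    df = ranks.copy()
    df["drug_class"] = [class_of[c] for c in df.index]
    values = df["rank"] if on == "rank" else df["mean_delta_auc"]
    if on not in ("rank", "delta"):
        raise ParameterError("on must be 'rank' or 'delta'")
    groups = {
        cls: values[df["drug_class"] == cls].to_numpy()
        for cls in sorted(df["drug_class"].unique())
    }
    avg_rank = df.groupby("drug_class")["rank"].mean()

    if reference_class == "auto":
        # worst class = largest average rank; ties -> lexicographically first
        reference_class = avg_rank[avg_rank == avg_rank.max()].index.min()
    elif reference_class not in groups:
        raise ParameterError(f"unknown reference class {reference_class!r}")
    ref_vals = groups[reference_class]

    rows = []
    for cls, vals in groups.items():
        single = len(vals) < 2
        if cls == reference_class:
            p = 1.0
        elif single or len(ref_vals) < 2:
            p = float("nan")
        else:
            p = float(stats.ttest_ind(vals, ref_vals, equal_var=False).pvalue)
        rows.append(
            {
                "drug_class": cls,
                "n_members": len(vals),
                "average_rank": float(avg_rank[cls]),
                "p_vs_reference": p,
                "single_member": single,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["average_rank", "drug_class"], kind="mergesort", ignore_index=True
    )
    out["class_rank"] = np.arange(1, len(out) + 1)
    out.attrs["reference_class"] = reference_class
    return out


def select_top(
    classes: pd.DataFrame, ranks: pd.DataFrame, class_of: dict, k: int
) -> pd.DataFrame:
    """Top-k classes by average rank with each class's best compound.

    The best compound is the member with the highest mean delta AUC;
    ties break lexicographically by compound id.
    """
    if k > len(classes):
        raise ParameterError(f"k={k} exceeds number of classes ({len(classes)})")
    top = classes.nsmallest(k, "class_rank")
    rows = []
    for _, row in top.iterrows():
        members = sorted(c for c in ranks.index if class_of[c] == row["drug_class"])
        sub = ranks.loc[members].sort_values(
            "mean_delta_auc", ascending=False, kind="mergesort"
        )
        best_val = sub["mean_delta_auc"].iloc[0]
        best = min(sub.index[sub["mean_delta_auc"] == best_val])
        rows.append(
            {
                "drug_class": row["drug_class"],
                "class_rank": int(row["class_rank"]),
                "average_rank": row["average_rank"],
                "best_compound": best,
                "best_mean_delta_auc": float(best_val),
            }
        )
    return pd.DataFrame(rows)
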