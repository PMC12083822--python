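"""Scored ATAC peak-set comparison between conditions.

Peaks are 0-based half-open BED intervals with a score. Peak identity across
conditions is established by greedy one-to-one matching on reciprocal
overlap (default 50% of *both* intervals, an ENCODE-style convention):
candidate pairs are ranked by reciprocal overlap (then overlap length, then
coordinates) and accepted while both partners are free. Unmatched control
peaks are *lost*, unmatched treated peaks are *gained*, and matched pairs
carry a log2 score ratio. The ranking key is symmetric in the two
conditions, so swapping control and treated swaps lost and gained exactly.

Peaks are linked to genes by TSS windows (default +-50 kb), and per-gene
summaries count lost/gained linked peaks and matched peaks whose |log2
score ratio| clears a threshold (default 1, i.e. 2-fold height change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

PEAK_COLUMNS = ["chrom", "start", "end", "score"]


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' so 'chr1' and '1' compare equal."""
    s = str(name)
    return s[3:] if s.lower().startswith("chr") else s


def validate_peaks(peaks: pd.DataFrame, name: str = "peaks") -> pd.DataFrame:
    """Sort, check half-open validity and reject exact duplicate intervals."""
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise FormatError(f"{name}: missing columns {missing}")
    bad = peaks.index[peaks["start"] >= peaks["end"]]
    if len(bad):
        raise FormatError(f"{name}: start >= end at row {int(bad[0])}")
    out = peaks.sort_values(["chrom", "start", "end"], ignore_index=True)
    if out.duplicated(subset=["chrom", "start", "end"]).any():
        raise FormatError(f"{name}: duplicate identical intervals")
    return out


@dataclass
class PeakDelta:
    """Outcome of matching a control against a treated peak set."""

    matched: pd.DataFrame  # control/treated coords + scores + log2_ratio
    lost: pd.DataFrame  # control-only intervals
    gained: pd.DataFrame  # treated-only intervals

    def summary(self) -> dict:
        return {
            "n_matched": int(len(self.matched)),
            "n_lost": int(len(self.lost)),
            "n_gained": int(len(self.gained)),
        }


def match_peaks(
    control: pd.DataFrame, treated: pd.DataFrame, min_reciprocal_overlap: float = 0.5
) -> PeakDelta:
    """One-to-one peak matching by reciprocal overlap.

    A control/treated pair is a candidate if the shared span covers at least
    ``min_reciprocal_overlap`` of *each* interval. Candidates are accepted
    greedily by descending reciprocal overlap (= the smaller of the two
    coverage fractions); ties prefer longer overlaps, then smaller starts.
    """
    if not (0.0 < min_reciprocal_overlap <= 1.0):
        raise ParameterError("min_reciprocal_overlap must lie in (0, 1]")
    ctrl = validate_peaks(control, "control")
    trt = validate_peaks(treated, "treated")
    ctrl_chrom = ctrl["chrom"].map(normalize_chrom)
    trt_chrom = trt["chrom"].map(normalize_chrom)

    matched_pairs = []
    used_c: set = set()
    used_t: set = set()
    for chrom in sorted(set(ctrl_chrom) & set(trt_chrom)):
        ci = np.flatnonzero((ctrl_chrom == chrom).to_numpy())
        ti = np.flatnonzero((trt_chrom == chrom).to_numpy())
        cs = ctrl["start"].to_numpy()[ci][:, None]
        ce = ctrl["end"].to_numpy()[ci][:, None]
        ts = trt["start"].to_numpy()[ti][None, :]
        te = trt["end"].to_numpy()[ti][None, :]
        ov = np.minimum(ce, te) - np.maximum(cs, ts)
        frac_c = ov / (ce - cs)
        frac_t = ov / (te - ts)
        recip = np.minimum(frac_c, frac_t)
        ok = (ov > 0) & (frac_c >= min_reciprocal_overlap) & (frac_t >= min_reciprocal_overlap)
        ii, jj = np.nonzero(ok)
        # symmetric ranking: reciprocal overlap desc, overlap length desc,
        # then coordinates (order-independent of which set is 'control')
        order = sorted(
            range(ii.size),
            key=lambda x: (
                -recip[ii[x], jj[x]],
                -ov[ii[x], jj[x]],
                min(cs[ii[x], 0], ts[0, jj[x]]),
                max(cs[ii[x], 0], ts[0, jj[x]]),
            ),
        )
        for x in order:
            a, b = int(ci[ii[x]]), int(ti[jj[x]])
            if a in used_c or b in used_t:
                continue
            used_c.add(a)
            used_t.add(b)
            matched_pairs.append((a, b))

    rows = []
    for a, b in matched_pairs:
        c_row, t_row = ctrl.iloc[a], trt.iloc[b]
        rows.append(
            {
                "chrom": c_row["chrom"],
                "c_start": int(c_row["start"]),
                "c_end": int(c_row["end"]),
                "c_score": float(c_row["score"]),
                "t_start": int(t_row["start"]),
                "t_end": int(t_row["end"]),
                "t_score": float(t_row["score"]),
                "log2_ratio": float(np.log2(t_row["score"] / c_row["score"])),
            }
        )
    matched = pd.DataFrame(
        rows,
        columns=[
            "chrom", "c_start", "c_end", "c_score",
            "t_start", "t_end", "t_score", "log2_ratio",
        ],
    )
    if len(matched):
        matched = matched.sort_values(["chrom", "c_start", "c_end"], ignore_index=True)
    lost = ctrl.loc[[i for i in range(len(ctrl)) if i not in used_c]].reset_index(drop=True)
    gained = trt.loc[[i for i in range(len(trt)) if i not in used_t]].reset_index(drop=True)
    return PeakDelta(matched=matched, lost=lost, gained=gained)


def link_peaks_to_genes(peaks: pd.DataFrame, tss: dict, window: int = 50_000) -> dict:
    """Map gene -> list of peak row indices within the TSS window.

    ``tss`` maps gene -> (chrom, position[, strand]). A peak links to a gene
    iff it overlaps ``[tss - window, tss + window)``; one peak may link to
    several genes. Chromosome names are normalized ('chr1' == '1').
    """
    if window < 0:
        raise ParameterError("window must be >= 0")
    peaks = validate_peaks(peaks)
    chrom_n = peaks["chrom"].map(normalize_chrom).to_numpy()
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    links: dict = {}
    for gene, entry in tss.items():
        chrom, pos = normalize_chrom(entry[0]), int(entry[1])
        lo, hi = pos - window, pos + window
        mask = (chrom_n == chrom) & (starts < hi) & (ends > lo)
        links[gene] = np.flatnonzero(mask).tolist()
    return links


def _interval_keys(df: pd.DataFrame, cols=("chrom", "start", "end")):
    return set(zip(df[cols[0]].map(normalize_chrom), df[cols[1]], df[cols[2]]))


def gene_set_peak_changes(
    delta: PeakDelta,
    links: dict,
    genes,
    peaks: pd.DataFrame,
    min_abs_log2: float = 1.0,
):
    """Per-gene lost/gained counts and significant matched-score changes.

    ``links`` must be computed on ``peaks`` = the union of control and
    treated intervals (control coordinates for matched peaks). For each
    gene in ``genes``: the number of linked peaks that were lost or gained,
    and the log2 score ratios of linked matched peaks with
    ``|log2 ratio| >= min_abs_log2`` (boundary inclusive). Genes absent from
    ``links`` get zero counts and a flag. Returns ``(per_gene, summary)``
    where summary pools significant decreases vs increases and total losses.
    """
    peaks = validate_peaks(peaks)
    lost_keys = _interval_keys(delta.lost)
    gained_keys = _interval_keys(delta.gained)
    matched_ratio = {
        (normalize_chrom(r["chrom"]), r["c_start"], r["c_end"]): r["log2_ratio"]
        for _, r in delta.matched.iterrows()
    }
    # treated coordinates of matched peaks also resolve (union peak lists)
    for _, r in delta.matched.iterrows():
        matched_ratio.setdefault(
            (normalize_chrom(r["chrom"]), r["t_start"], r["t_end"]), r["log2_ratio"]
        )
    rows = []
    for gene in genes:
        idxs = links.get(gene)
        missing = idxs is None
        idxs = idxs or []
        n_lost = n_gained = 0
        sig: list = []
        for i in idxs:
            key = (
                normalize_chrom(peaks.iloc[i]["chrom"]),
                int(peaks.iloc[i]["start"]),
                int(peaks.iloc[i]["end"]),
            )
            if key in lost_keys:
                n_lost += 1
            elif key in gained_keys:
                n_gained += 1
            elif key in matched_ratio:
                ratio = matched_ratio[key]
                if abs(ratio) >= min_abs_log2:
                    sig.append(float(ratio))
        rows.append(
            {
                "gene": gene,
                "n_linked": len(idxs),
                "n_lost": n_lost,
                "n_gained": n_gained,
                "significant_changes": sig,
                "n_sig_down": sum(1 for x in sig if x < 0),
                "n_sig_up": sum(1 for x in sig if x > 0),
                "missing_from_links": missing,
            }
        )
    per_gene = pd.DataFrame(rows)
    summary = {
        "total_lost": int(per_gene["n_lost"].sum()),
        "total_gained": int(per_gene["n_gained"].sum()),
        "total_sig_decreases": int(per_gene["n_sig_down"].sum()),
        "total_sig_increases": int(per_gene["n_sig_up"].sum()),
    }
    return per_gene, summary
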