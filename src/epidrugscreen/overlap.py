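"""Cross-line / cross-drug gene-set intersection analysis.

Given the grid of >=2-fold up/down gene sets per (cell line, compound):

* a gene is **consistent** for a compound if the compound moves it in the
  same direction in at least a fraction of lines (default 3/4, the
  quantification of "the vast majority of cell lines");
* a gene is **universal** ("stress response") for a line if essentially
  every compound moves it in that line (default: all of them);
* a gene is **exclusive** if it appears in exactly one (line, compound)
  cell for its direction -- the dominant pattern in heterogeneous panels;
* compounds are classified as up-regulators or down-regulators by the ratio
  of their median up- and down-set sizes.

Region sizes in :func:`intersection_matrix` follow exclusive (UpSet-style)
semantics: each gene belongs to exactly one region, so region sizes sum to
the size of the union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError

DIRECTIONS = ("up", "down")


@dataclass
class GeneSetGrid:
    """Up/down gene sets for every (cell line, compound) combination."""

    up_sets: dict  # (line, compound) -> set
    down_sets: dict
    lines: list = field(default_factory=list)
    compounds: list = field(default_factory=list)

    def sets(self, direction: str) -> dict:
        if direction not in DIRECTIONS:
            raise ParameterError(f"direction must be one of {DIRECTIONS}")
        return self.up_sets if direction == "up" else self.down_sets

    def count_matrix(self, direction: str) -> pd.DataFrame:
        """Line x compound matrix of set sizes (the screening heatmap)."""
        cells = self.sets(direction)
        return pd.DataFrame(
            [
                [len(cells.get((line, comp), ())) for comp in self.compounds]
                for line in self.lines
            ],
            index=pd.Index(self.lines, name="cell_line"),
            columns=self.compounds,
        )


def _check_fraction(min_fraction: float):
    if not (0.5 < min_fraction <= 1.0):
        raise ParameterError("min_fraction must lie in (0.5, 1]")


def consistent_sets(grid: GeneSetGrid, direction: str, min_fraction: float = 0.75):
    """Per-compound genes moved in >= ceil(min_fraction * n_lines) lines.

    Returns ``(consistent, support)`` where ``consistent`` maps compound ->
    gene set and ``support`` maps compound -> {gene: line count} restricted
    to genes supported by at least 2 lines.
    """
    _check_fraction(min_fraction)
    cells = grid.sets(direction)
    need = math.ceil(min_fraction * len(grid.lines))
    consistent, support = {}, {}
    for comp in grid.compounds:
        counts: dict = {}
        for line in grid.lines:
            for g in cells.get((line, comp), ()):
                counts[g] = counts.get(g, 0) + 1
        consistent[comp] = {g for g, n in counts.items() if n >= need}
        support[comp] = {g: n for g, n in counts.items() if n >= 2}
    return consistent, support


def universal_sets(grid: GeneSetGrid, direction: str, min_fraction: float = 1.0):
    """Per-line genes moved by >= ceil(min_fraction * n_compounds) drugs."""
    _check_fraction(min_fraction)
    cells = grid.sets(direction)
    need = math.ceil(min_fraction * len(grid.compounds))
    out = {}
    for line in grid.lines:
        counts: dict = {}
        for comp in grid.compounds:
            for g in cells.get((line, comp), ()):
                counts[g] = counts.get(g, 0) + 1
        out[line] = {g for g, n in counts.items() if n >= need}
    return out


def exclusive_sets(grid: GeneSetGrid, direction: str) -> dict:
    """Genes occurring in exactly one (line, compound) cell for a direction."""
    cells = grid.sets(direction)
    counts: dict = {}
    for key in cells:
        for g in cells[key]:
            counts[g] = counts.get(g, 0) + 1
    return {
        key: {g for g in cells[key] if counts[g] == 1}
        for key in cells
    }


def classify_regulators(grid: GeneSetGrid, ratio: float = 2.0) -> pd.DataFrame:
    """Per-compound classification as up-regulator, down-regulator or mixed.

    Uses the median across lines of |up| and |down|: up-regulator iff
    ``med_up >= ratio * med_down``, down-regulator iff
    ``med_down >= ratio * med_up``, else mixed. Both medians zero is an
    inert compound, reported as mixed with a flag.
    """
    up_m = grid.count_matrix("up").median(axis=0)
    down_m = grid.count_matrix("down").median(axis=0)
    rows = []
    for comp in grid.compounds:
        mu, md = float(up_m[comp]), float(down_m[comp])
        inert = mu == 0.0 and md == 0.0
        if inert:
            label = "mixed"
        elif mu >= ratio * md:
            label = "up-regulator"
        elif md >= ratio * mu:
            label = "down-regulator"
        else:
            label = "mixed"
        rows.append(
            {
                "compound": comp,
                "median_up": mu,
                "median_down": md,
                "classification": label,
                "inert": inert,
            }
        )
    return pd.DataFrame(rows)


def intersection_matrix(sets: dict, max_exhaustive: int = 20):
    """Membership matrix and exclusive intersection-region sizes.

    ``sets`` maps set name -> gene set. Returns ``(membership, regions)``:
    a boolean gene x set DataFrame and a dict mapping a tuple of member set
    names (the region signature) to its size. Regions are exclusive: each
    gene counts toward exactly the one region matching its full membership
    pattern, so region sizes sum to |union|.

    With more than ``max_exhaustive`` sets the exhaustive enumeration is
    refused and pairwise intersection sizes are returned instead, as
    ``(membership, pairwise)`` with ``pairwise[(a, b)] = |A & B|``.
    """
    names = list(sets)
    if len(names) != len(set(names)):
        raise ParameterError("duplicate set names")
    universe = sorted(set().union(*sets.values())) if sets else []
    membership = pd.DataFrame(
        {name: [g in sets[name] for g in universe] for name in names},
        index=pd.Index(universe, name="gene"),
        dtype=bool,
    )
    if len(names) > max_exhaustive:
        pairwise = {
            (a, b): len(sets[a] & sets[b])
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        }
        return membership, pairwise
    regions: dict = {}
    for g in universe:
        sig = tuple(name for name in names if g in sets[name])
        regions[sig] = regions.get(sig, 0) + 1
    return membership, regions


def consistency_report(
    grid: GeneSetGrid,
    min_fraction_consistent: float = 0.75,
    min_fraction_universal: float = 1.0,
) -> dict:
    """Full JSON-serializable overlap report for both directions."""
    report: dict = {"lines": list(grid.lines), "compounds": list(grid.compounds)}
    for direction in DIRECTIONS:
        cons, support = consistent_sets(grid, direction, min_fraction_consistent)
        univ = universal_sets(grid, direction, min_fraction_universal)
        excl = exclusive_sets(grid, direction)
        report[direction] = {
            "consistent": {c: sorted(s) for c, s in cons.items()},
            "support": {c: dict(sorted(s.items())) for c, s in support.items()},
            "universal": {l: sorted(s) for l, s in univ.items()},
            "n_exclusive": {
                f"{line}|{comp}": len(excl.get((line, comp), ()))
                for line in grid.lines
                for comp in grid.compounds
            },
        }
    report["regulator_classes"] = classify_regulators(grid).to_dict(orient="records")
    return report
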