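"""Viability AUC, the delta-AUC screening statistic, 4PL IC-50 fitting and
early-vs-late volcano statistics.

A viability table is a long-format :class:`pandas.DataFrame` with columns
``compound, drug_class, cell_line, dose_M, day, replicate, viability``;
viability is a fraction of the vehicle control, doses are molar.

The screening statistic is

    delta AUC = viability AUC at the early timepoint
              - viability AUC at the late timepoint,

so a compound whose effect builds up over prolonged exposure (the kinetics
expected of epigenetic reprogramming) has a positive delta AUC, while acute
non-specific toxicity that the culture recovers from is negative.

Because the early and late timepoints may be assayed at different dose sets
(e.g. two doses early, a single dose late), the AUC is defined as the
*normalized* trapezoid over log10 dose: the trapezoid integral divided by the
log10-dose span. This puts AUCs from any number of doses on a common 0-1
viability scale; a single-dose "curve" degenerates to the viability itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateInputError, MissingDataError, ParameterError

VIABILITY_COLUMNS = [
    "compound",
    "drug_class",
    "cell_line",
    "dose_M",
    "day",
    "replicate",
    "viability",
]


@dataclass(frozen=True)
class DeltaAucRecord:
    compound: str
    cell_line: str
    auc_early: float
    auc_late: float
    delta_auc: float


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a four-parameter logistic (4PL) fit.

    ``converged`` is False for flat or otherwise unidentifiable curves, in
    which case ``ic50`` is clamped to the nearest tested-dose boundary.
    ``ic50_in_range`` flags whether the IC-50 lies inside the tested dose
    range; extrapolated IC-50s should be treated as censored.
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    ic50_in_range: bool
    flat: bool = False


def fourpl(dose, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic viability curve ``V(d)``.

    ``V(d) = bottom + (top - bottom) / (1 + (d / ic50)**hill)``; at
    ``d = ic50`` the curve is halfway between top and bottom.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def viability_auc(doses, viabilities) -> float:
    """Normalized trapezoid of viability over log10 dose.

    Replicates must be pre-averaged per dose. Doses must be strictly
    increasing and positive. A single dose returns its viability unchanged.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.ndim != 1 or d.shape != v.shape:
        raise ParameterError("doses and viabilities must be 1-D and equal length")
    if d.size == 0:
        raise ParameterError("need at least one dose")
    if np.any(d <= 0):
        raise ParameterError("doses must be positive (molar)")
    if np.any(np.diff(d) <= 0):
        raise ParameterError("doses must be strictly increasing")
    if d.size == 1:
        return float(v[0])
    x = np.log10(d)
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def _auc_for_timepoint(sub: pd.DataFrame) -> float:
    per_dose = sub.groupby("dose_M")["viability"].mean().sort_index()
    return viability_auc(per_dose.index.to_numpy(), per_dose.to_numpy())


def delta_auc(
    table: pd.DataFrame,
    compound: str,
    cell_line: str,
    early_day: float,
    late_day: float,
) -> DeltaAucRecord:
    """Delta AUC for one compound on one cell line.

    Raises :class:`MissingDataError` if either timepoint is absent; missing
    data is never silently treated as zero.
    """
    sub = table[(table["compound"] == compound) & (table["cell_line"] == cell_line)]
    aucs = {}
    for day in (early_day, late_day):
        day_rows = sub[sub["day"] == day]
        if day_rows.empty:
            raise MissingDataError(
                f"no viability data for compound={compound!r}, "
                f"cell_line={cell_line!r} at day {day}"
            )
        aucs[day] = _auc_for_timepoint(day_rows)
    return DeltaAucRecord(
        compound=compound,
        cell_line=cell_line,
        auc_early=aucs[early_day],
        auc_late=aucs[late_day],
        delta_auc=aucs[early_day] - aucs[late_day],
    )


def delta_auc_table(
    table: pd.DataFrame, early_day: float, late_day: float
) -> pd.DataFrame:
    """Delta AUC for every (compound, cell line) pair present at both days.

    Returns a frame with columns ``compound, drug_class, cell_line,
    auc_early, auc_late, delta_auc``. A pair missing either timepoint raises
    :class:`MissingDataError`.
    """
    sub = table[table["day"].isin([early_day, late_day])]
    per_dose = (
        sub.groupby(["compound", "cell_line", "day", "dose_M"], sort=True)["viability"]
        .mean()
        .reset_index()
    )
    rows = []
    for (comp, line), grp in per_dose.groupby(["compound", "cell_line"], sort=True):
        aucs = {}
        for day, dgrp in grp.groupby("day"):
            dgrp = dgrp.sort_values("dose_M")
            aucs[day] = viability_auc(
                dgrp["dose_M"].to_numpy(), dgrp["viability"].to_numpy()
            )
        if early_day not in aucs or late_day not in aucs:
            missing = early_day if early_day not in aucs else late_day
            raise MissingDataError(
                f"no viability data for compound={comp!r}, cell_line={line!r} "
                f"at day {missing}"
            )
        rows.append((comp, line, aucs[early_day], aucs[late_day]))
    out = pd.DataFrame(
        rows, columns=["compound", "cell_line", "auc_early", "auc_late"]
    )
    out["delta_auc"] = out["auc_early"] - out["auc_late"]
    classes = table[["compound", "drug_class"]].drop_duplicates()
    return out.merge(classes, on="compound", how="left")[
        ["compound", "drug_class", "cell_line", "auc_early", "auc_late", "delta_auc"]
    ]


# --- 4PL fitting -----------------------------------------------------------

_HILL_BOUNDS = (1e-2, 20.0)
_TOP_MAX = 1.5  # generous headroom for growth-stimulated wells


def _fit_once(d, v, log_ic50_init):
    top0 = float(np.clip(np.max(v), 1e-6, _TOP_MAX))
    frac0 = float(np.clip(np.min(v) / top0, 0.0, 1.0))
    lo = np.log10(d.min()) - 3.0
    hi = np.log10(d.max()) + 3.0

    def resid(p):
        top, frac, logc, hill = p
        return fourpl(d, top, frac * top, 10.0 ** logc, hill) - v

    # tolerances sized for assay data: residuals are O(noise), not O(eps),
    # and the (hill, log ic50) valley is flat near the optimum
    return optimize.least_squares(
        resid,
        x0=[top0, frac0, float(np.clip(log_ic50_init, lo, hi)), 1.0],
        bounds=([0.0, 0.0, lo, 1e-2], [_TOP_MAX, 1.0, hi, _HILL_BOUNDS[1]]),
        method="trf",
        ftol=1e-6,
        xtol=1e-6,
        max_nfev=1000,
    )


def fit_ic50(doses, viabilities) -> DoseResponseFit:
    """Least-squares 4PL fit with a multi-start over the observed doses.

    Requires at least four dose levels. The bottom plateau is constrained to
    ``0 <= bottom <= top <= 1.5`` for identifiability. All-equal viabilities
    are a flat curve: the Hill slope is undefined (NaN) and the IC-50 is
    reported at the maximum tested dose with ``converged=False``.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.shape != v.shape or d.ndim != 1:
        raise ParameterError("doses and viabilities must be 1-D and equal length")
    if np.unique(d).size < 4:
        raise ParameterError("fit_ic50 requires at least 4 distinct dose levels")
    if np.any(d <= 0):
        raise ParameterError("doses must be positive")

    if np.ptp(v) == 0.0:
        return DoseResponseFit(
            top=float(v[0]),
            bottom=float(v[0]),
            ic50=float(d.max()),
            hill=float("nan"),
            rss=0.0,
            converged=False,
            ic50_in_range=True,
            flat=True,
        )

    best = None
    for logc0 in np.log10(np.unique(d)):
        try:
            res = _fit_once(d, v, logc0)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DoseResponseFit(
            top=float("nan"),
            bottom=float("nan"),
            ic50=float(d.max()),
            hill=float("nan"),
            rss=float("inf"),
            converged=False,
            ic50_in_range=False,
            flat=False,
        )
    top, frac, logc, hill = best.x
    ic50 = float(10.0 ** logc)
    converged = bool(best.success)
    in_range = bool(d.min() <= ic50 <= d.max())
    if not converged:
        ic50 = float(d.min()) if ic50 < d.min() else float(d.max())
        in_range = True
    return DoseResponseFit(
        top=float(top),
        bottom=float(frac * top),
        ic50=ic50,
        hill=float(hill),
        rss=float(2.0 * best.cost),
        converged=converged,
        ic50_in_range=in_range,
        flat=False,
    )


def fit_ic50_table(table: pd.DataFrame, day: float | None = None) -> pd.DataFrame:
    """Fit a 4PL per (compound, cell line), averaging replicates per dose.

    If ``day`` is given only that timepoint is used. Returns one row per pair
    with the fit fields plus ``log10_ic50``.
    """
    sub = table if day is None else table[table["day"] == day]
    rows = []
    for (comp, line), grp in sub.groupby(["compound", "cell_line"], sort=True):
        per_dose = grp.groupby("dose_M")["viability"].mean().sort_index()
        fit = fit_ic50(per_dose.index.to_numpy(), per_dose.to_numpy())
        rows.append(
            {
                "compound": comp,
                "cell_line": line,
                "ic50_M": fit.ic50,
                "log10_ic50": np.log10(fit.ic50),
                "top": fit.top,
                "bottom": fit.bottom,
                "hill": fit.hill,
                "rss": fit.rss,
                "converged": fit.converged,
                "ic50_in_range": fit.ic50_in_range,
                "flat": fit.flat,
            }
        )
    return pd.DataFrame(rows)


def inverse_fourpl(fit: DoseResponseFit, viability: float = 0.65) -> float:
    """Dose at which the fitted curve crosses ``viability``.

    Helper for choosing a sub-toxic working dose; raises
    :class:`DegenerateInputError` if the target lies outside (bottom, top).
    """
    if not (fit.bottom < viability < fit.top):
        raise DegenerateInputError(
            f"viability {viability} outside fitted range "
            f"({fit.bottom:.3g}, {fit.top:.3g})"
        )
    ratio = (fit.top - fit.bottom) / (viability - fit.bottom) - 1.0
    return float(fit.ic50 * ratio ** (1.0 / fit.hill))


# --- volcano ---------------------------------------------------------------


def volcano_stats(
    table: pd.DataFrame, early_day: float, late_day: float
) -> pd.DataFrame:
    """Per-compound early-vs-late effect size and Welch t-test p-value.

    x-axis: mean over cell lines of the per-line delta AUC. y-axis: Welch
    two-sample t-test between all early viability observations and all late
    observations (pooled over lines, doses and replicates). A compound whose
    two pooled groups both have zero variance is degenerate: identical groups
    get p = 1 by convention and are flagged.
    """
    deltas = delta_auc_table(table, early_day, late_day)
    mean_delta = deltas.groupby("compound")["delta_auc"].mean()
    rows = []
    for comp, grp in table.groupby("compound", sort=True):
        early = grp.loc[grp["day"] == early_day, "viability"].to_numpy()
        late = grp.loc[grp["day"] == late_day, "viability"].to_numpy()
        if early.size < 2 or late.size < 2:
            raise ParameterError(
                f"compound {comp!r} needs >=2 observations per timepoint"
            )
        degenerate = bool(np.var(early) == 0.0 and np.var(late) == 0.0)
        if degenerate:
            p = 1.0
        else:
            p = float(stats.ttest_ind(early, late, equal_var=False).pvalue)
        rows.append(
            {
                "compound": comp,
                "delta_auc_mean": float(mean_delta[comp]),
                "p_value": p,
                "n_early": int(early.size),
                "n_late": int(late.size),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
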