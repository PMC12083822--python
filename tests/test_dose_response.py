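import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epidrugscreen import synthetic as syn
from epidrugscreen.dose_response import (
    delta_auc,
    delta_auc_table,
    fit_ic50,
    fourpl,
    inverse_fourpl,
    viability_auc,
    volcano_stats,
)
from epidrugscreen.errors import MissingDataError, ParameterError


class TestViabilityAuc:
    @pytest.mark.parametrize(
        "doses, viab, expected",
        [
            ([1e-6, 1e-5], [1.0, 1.0], 1.0),  # constant curve
            ([1e-6, 1e-5], [1.0, 0.0], 0.5),  # linear in log dose
            ([1e-8, 1e-7, 1e-6], [0.9, 0.6, 0.3], 0.6),  # hand trapezoid
            ([5e-7], [0.42], 0.42),  # single dose degenerates to the value
        ],
    )
    def test_known_values(self, doses, viab, expected):
        assert viability_auc(doses, viab) == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_numeric_integration(self, rng):
        """The normalized trapezoid equals dense numeric integration of the
        piecewise-linear interpolant in log-dose space."""
        for _ in range(20):
            n = int(rng.integers(2, 8))
            logd = np.sort(rng.uniform(-9, -4, size=n))
            while np.any(np.diff(logd) < 1e-6):
                logd = np.sort(rng.uniform(-9, -4, size=n))
            v = rng.uniform(0, 1.2, size=n)
            dense_x = np.linspace(logd[0], logd[-1], 20001)
            dense_v = np.interp(dense_x, logd, v)
            oracle = np.trapezoid(dense_v, dense_x) / (logd[-1] - logd[0])
            assert viability_auc(10.0**logd, v) == pytest.approx(oracle, abs=1e-6)

    @given(
        logs=st.lists(
            st.floats(min_value=-9, max_value=-4, allow_nan=False),
            min_size=2,
            max_size=6,
            unique=True,
        ),
        viab=st.lists(st.floats(min_value=0, max_value=1.2), min_size=6, max_size=6),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_uniform_dose_rescaling(self, logs, viab, scale):
        doses = np.sort(np.power(10.0, logs))
        v = np.asarray(viab[: len(doses)])
        a = viability_auc(doses, v)
        b = viability_auc(doses * scale, v)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(ParameterError):
            viability_auc([1e-6, 1e-5], [1.0])
        with pytest.raises(ParameterError):
            viability_auc([0.0, 1e-5], [1.0, 1.0])
        with pytest.raises(ParameterError):
            viability_auc([1e-5, 1e-6], [1.0, 1.0])


class TestDeltaAuc:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["compound", "drug_class", "cell_line", "dose_M", "day", "replicate", "viability"],
        )

    def test_identical_response_gives_zero(self):
        rows = [
            ("X", "c", "L", 1e-6, d, 1, v)
            for d in (3.0, 28.0)
            for v in (0.8,)
        ] + [("X", "c", "L", 1e-5, d, 1, 0.4) for d in (3.0, 28.0)]
        rec = delta_auc(self._table(rows), "X", "L", 3.0, 28.0)
        assert rec.delta_auc == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic(self):
        rows = [
            ("X", "c", "L", 1e-6, 3.0, 1, 0.9),
            ("X", "c", "L", 5e-7, 28.0, 1, 0.4),
        ]
        rec = delta_auc(self._table(rows), "X", "L", 3.0, 28.0)
        assert rec.auc_early == pytest.approx(0.9)
        assert rec.auc_late == pytest.approx(0.4)
        assert rec.delta_auc == pytest.approx(0.5)

    def test_missing_timepoint_is_an_error_not_zero(self):
        rows = [("X", "c", "L", 1e-6, 3.0, 1, 0.9)]
        with pytest.raises(MissingDataError, match="day 28"):
            delta_auc(self._table(rows), "X", "L", 3.0, 28.0)

    def test_antisymmetric_under_timepoint_swap(self, tiny_screen_truth):
        table = syn.generate_screen(
            tiny_screen_truth,
            doses={3.0: [1e-6, 1e-5], 28.0: [5e-7]},
            timepoints=[3.0, 28.0],
            replicates=1,
            seed=0,
        )
        fwd = delta_auc_table(table, 3.0, 28.0)
        rev = delta_auc_table(table, 28.0, 3.0)
        merged = fwd.merge(rev, on=["compound", "cell_line"], suffixes=("_f", "_r"))
        assert np.allclose(merged["delta_auc_f"], -merged["delta_auc_r"])

    def test_kinetics_signs_match_analytic_curves(self, tiny_screen_truth):
        """Delayed-action compounds (IC-50 shrinking over exposure) must have
        positive delta AUC, acute ones negative -- checked against direct
        evaluation of the 4PL at both timepoints."""
        doses = {3.0: [1e-6, 1e-5], 28.0: [5e-7]}
        table = syn.generate_screen(
            tiny_screen_truth, doses=doses, timepoints=[3.0, 28.0], replicates=1, seed=1
        )
        out = delta_auc_table(table, 3.0, 28.0).set_index(["compound", "cell_line"])

        factor = tiny_screen_truth.kinetic_ic50_factor
        # analytic: early at base ic50, late at scaled ic50
        early = viability_auc([1e-6, 1e-5], fourpl([1e-6, 1e-5], 1, 0, 1e-6, 1))
        late_delayed = float(fourpl(5e-7, 1, 0, 1e-6 / factor, 1))
        late_acute = float(fourpl(5e-7, 1, 0, 1e-6 * factor, 1))
        assert out.loc[("DLY", "L1"), "delta_auc"] == pytest.approx(early - late_delayed)
        assert out.loc[("ACU", "L1"), "delta_auc"] == pytest.approx(early - late_acute)
        assert out.loc[("DLY", "L1"), "delta_auc"] > 0
        assert out.loc[("ACU", "L1"), "delta_auc"] < 0
        assert out.loc[("NIL", "L1"), "delta_auc"] == pytest.approx(0.0, abs=1e-12)


class TestFitIc50:
    def test_noiseless_recovery_within_one_percent(self):
        doses = np.array([1e-8, 1e-7, 1e-6, 1e-5])
        v = fourpl(doses, 1.0, 0.0, 1e-7, 1.0)
        fit = fit_ic50(doses, v)
        assert fit.converged
        assert fit.ic50 == pytest.approx(1e-7, rel=0.01)
        assert fit.hill == pytest.approx(1.0, rel=0.05)
        assert fit.ic50_in_range

    def test_flat_curve_flagged(self):
        fit = fit_ic50([1e-8, 1e-7, 1e-6, 1e-5], [1.0, 1.0, 1.0, 1.0])
        assert not fit.converged
        assert fit.flat
        assert fit.ic50 == pytest.approx(1e-5)
        assert np.isnan(fit.hill)

    def test_growth_stimulation_is_flagged(self):
        fit = fit_ic50([1e-8, 1e-7, 1e-6, 1e-5], [1.0, 1.05, 1.15, 1.3])
        assert (not fit.converged) or (not fit.ic50_in_range) or fit.rss > 1e-4

    def test_requires_four_dose_levels(self):
        with pytest.raises(ParameterError):
            fit_ic50([1e-7, 1e-6, 1e-5], [0.9, 0.5, 0.1])

    def test_inverse_fourpl_round_trip(self):
        doses = np.array([1e-8, 1e-7, 1e-6, 1e-5])
        fit = fit_ic50(doses, fourpl(doses, 1.0, 0.0, 2e-7, 1.0))
        d65 = inverse_fourpl(fit, 0.65)
        assert float(fourpl(d65, fit.top, fit.bottom, fit.ic50, fit.hill)) == pytest.approx(0.65, abs=1e-6)


class TestVolcano:
    def _table(self, early_vals, late_vals, compound="X"):
        rows = [
            (compound, "c", "L", 1e-6, 3.0, i + 1, v) for i, v in enumerate(early_vals)
        ] + [
            (compound, "c", "L", 5e-7, 28.0, i + 1, v) for i, v in enumerate(late_vals)
        ]
        return pd.DataFrame(
            rows,
            columns=["compound", "drug_class", "cell_line", "dose_M", "day", "replicate", "viability"],
        )

    def test_identical_groups(self):
        vals = [0.7, 0.8, 0.9]
        out = volcano_stats(self._table(vals, vals), 3.0, 28.0)
        assert out["delta_auc_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"].iloc[0] > 0.9

    def test_zero_variance_groups_flagged_degenerate(self):
        out = volcano_stats(self._table([1.0] * 10, [0.2] * 10), 3.0, 28.0)
        row = out.iloc[0]
        assert row["degenerate"]
        assert row["p_value"] == 1.0
        assert row["delta_auc_mean"] > 0  # viability dropped late -> positive delta

    def test_welch_p_matches_closed_form(self, rng):
        """Welch statistic computed from first principles agrees with the
        reported p-value."""
        early = rng.normal(0.9, 0.06, size=15)
        late = rng.normal(0.7, 0.1, size=12)
        out = volcano_stats(self._table(early, late), 3.0, 28.0)
        v1, v2 = early.var(ddof=1), late.var(ddof=1)
        n1, n2 = len(early), len(late)
        se2 = v1 / n1 + v2 / n2
        t = (early.mean() - late.mean()) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert out["p_value"].iloc[0] == pytest.approx(p_oracle, rel=1e-9)

    def test_separated_groups_are_significant_across_seeds(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            early = r.normal(0.9, 0.05, size=20)
            late = r.normal(0.5, 0.05, size=20)
            out = volcano_stats(self._table(early, late), 3.0, 28.0)
            assert out["p_value"].iloc[0] < 1e-6
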