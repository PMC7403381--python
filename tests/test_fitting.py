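"""Tests for chi-square fitting, joint fits and likelihood-ratio tests."""

import numpy as np
import pytest

from lineupsdt import fixtures
from lineupsdt.fitting import chi_square, fit_model, joint_fit, lr_test
from lineupsdt.models import category_probabilities
from lineupsdt.types import LineupDesign, OutcomeTable, SDTParams


def _table_from_probs(probs, design, n_tp, n_ta, k):
    """Expected frequencies rounded to counts (large N keeps rounding
    error negligible)."""
    tp = np.round(np.asarray(probs.tp_cells()) * n_tp).astype(int)
    ta = np.round(np.asarray(probs.ta_cells()) * n_ta).astype(int)
    kwargs = {}
    if probs.ta_mode == "suspect":
        kwargs = {"ta_foil_id": ta[k:2 * k]}
    return OutcomeTable(
        k=k,
        tp_target_id=tp[:k],
        tp_foil_id=tp[k:2 * k],
        tp_reject=int(tp[-1]),
        ta_id=ta[:k],
        ta_reject=int(ta[-1]),
        ta_mode=probs.ta_mode,
        design=design,
        **kwargs,
    )


class TestChiSquare:
    def test_exact_match_scores_zero(self):
        p = SDTParams(d_t=1.6, s_t=1.1, criteria=(0.9, 1.6))
        d = LineupDesign(n=6)
        probs = category_probabilities("max", p, d)
        table = _table_from_probs(probs, d, 1_000_000, 1_000_000, 2)
        assert chi_square(table, probs) < 1e-3

    def test_hand_computed_three_cell_example(self):
        # O = (30, 10, 60), N = 100, P = (.25, .15, .60):
        # 25/25 + (10-15)^2/15 + 0 = 1 + 5/3
        class Obs:
            def tp_cells(self):
                return np.array([30, 10, 60])

            def ta_cells(self):
                return np.array([0])

            n_tp = 100
            n_ta = 0

        class Exp:
            def tp_cells(self):
                return np.array([0.25, 0.15, 0.60])

            def ta_cells(self):
                return np.array([1.0])

        assert chi_square(Obs(), Exp()) == pytest.approx(1 + 5 / 3, abs=1e-9)

    def test_zero_probability_with_observations_diverges(self):
        class Obs:
            def tp_cells(self):
                return np.array([5, 95])

            def ta_cells(self):
                return np.array([100])

            n_tp = 100
            n_ta = 100

        class Exp:
            def tp_cells(self):
                return np.array([0.0, 1.0])

            def ta_cells(self):
                return np.array([1.0])

        with pytest.raises(ZeroDivisionError):
            chi_square(Obs(), Exp())

    def test_saturated_showup_model_fits_perfectly(self):
        table = fixtures.table7_showup()
        from lineupsdt.models import evsd_solve

        H = 15 / 28
        F = 19 / 281
        d_t, c = evsd_solve(H, F)
        probs = category_probabilities(
            "max", SDTParams(d_t=d_t, s_t=1.0, criteria=(c,)), table.design
        )
        assert chi_square(table, probs) == pytest.approx(0.0, abs=1e-9)


class TestFitModel:
    @pytest.mark.parametrize("model", ["max", "seq"])
    def test_self_consistency_recovers_generating_parameters(self, model):
        truth = SDTParams(d_t=1.7, s_t=1.2, criteria=(0.9, 1.4, 2.0))
        design = LineupDesign(n=6)
        probs = category_probabilities(model, truth, design)
        table = _table_from_probs(probs, design, 2_000_000, 2_000_000, 3)
        res = fit_model(model, table, n_starts=6, seed=4)
        assert res.chi2 < 0.05
        assert res.params[0].d_t == pytest.approx(1.7, abs=0.02)
        assert res.params[0].s_t == pytest.approx(1.2, abs=0.03)
        assert np.allclose(res.params[0].criteria, truth.criteria, atol=0.02)

    def test_df_bookkeeping(self):
        table = fixtures.exp1_simultaneous()
        free = fit_model("max", table, n_starts=2, seed=0, maxfev_per_dim=60)
        assert free.df == 8  # 15 free cells - 7 parameters
        fixed = fit_model(
            "max", table, constraints={"s_t": 1.0}, n_starts=2, seed=0,
            maxfev_per_dim=60,
        )
        assert fixed.df == 9

    def test_invalid_constraint_name_rejected(self):
        with pytest.raises(ValueError):
            fit_model("max", fixtures.exp1_simultaneous(), constraints={"zeta": 1})

    def test_oversaturated_fit_rejected(self):
        # show up with two free parameters per condition cell budget is
        # exactly saturated; freeing s_t as well over-saturates
        with pytest.raises(ValueError):
            fit_model("max", fixtures.table7_showup())

    def test_refit_from_winning_parameters_reproduces_minimum(self):
        table = fixtures.table7_simultaneous_collapsed()
        res = fit_model("max", table, constraints={"s_t": 1.0}, n_starts=6, seed=9)
        again = fit_model(
            "max", table, constraints={"s_t": 1.0}, n_starts=1, seed=1,
            init=res.params[0],
        )
        assert again.chi2 == pytest.approx(res.chi2, abs=1e-6)


class TestJointFit:
    def test_unshared_joint_fit_separates(self):
        sim = fixtures.exp1_simultaneous()
        seq = fixtures.exp1_sequential()
        a = fit_model("max", sim, n_starts=4, seed=1)
        b = fit_model("seq", seq, n_starts=4, seed=1)
        j = joint_fit([("max", sim), ("seq", seq)], n_starts=4, seed=1)
        assert j.chi2 == pytest.approx(a.chi2 + b.chi2, abs=0.02)
        assert j.df == a.df + b.df

    def test_equality_constraint_adds_exactly_one_df(self):
        sim = fixtures.exp1_simultaneous()
        seq = fixtures.exp1_sequential()
        free = joint_fit(
            [("max", sim), ("seq", seq)], n_starts=1, seed=0, maxfev_per_dim=40
        )
        tied = joint_fit(
            [("max", sim), ("seq", seq)], shared=("d_t",), n_starts=1, seed=0,
            maxfev_per_dim=40,
        )
        assert tied.df == free.df + 1

    def test_sharing_a_fixed_parameter_is_an_error(self):
        sim = fixtures.exp1_simultaneous()
        seq = fixtures.exp1_sequential()
        with pytest.raises(ValueError):
            joint_fit(
                [("max", sim), ("seq", seq)], shared=("s_t",),
                fixed={"s_t": 1.0}, n_starts=1,
            )


class TestLrTest:
    def test_constraining_at_the_optimum_changes_nothing(self):
        table = fixtures.table7_simultaneous_collapsed()
        free = fit_model("max", table, constraints={"s_t": 1.0}, n_starts=6, seed=2)
        pinned = fit_model(
            "max",
            table,
            constraints={"s_t": 1.0, "d_t": free.params[0].d_t},
            n_starts=6,
            seed=2,
        )
        delta, ddf, p = lr_test(free, pinned)
        assert delta == pytest.approx(0.0, abs=1e-4)
        assert ddf == 1
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_nesting_direction_enforced(self):
        table = fixtures.table7_simultaneous_collapsed()
        free = fit_model("max", table, constraints={"s_t": 1.0}, n_starts=2, seed=2)
        with pytest.raises(ValueError):
            lr_test(free, free)

    def test_worse_unconstrained_fit_warns(self):
        table = fixtures.table7_simultaneous_collapsed()
        free = fit_model("max", table, constraints={"s_t": 1.0}, n_starts=4, seed=2)
        better = fit_model(
            "max", table, constraints={"s_t": 1.0, "d_t": free.params[0].d_t},
            n_starts=4, seed=2,
        )
        fake_free = fit_model(
            "max", table, constraints={"s_t": 1.0, "d_t": 0.4}, n_starts=4, seed=2
        )
        # 'unconstrained' pinned far from the optimum, nested model at it
        fake_free.df = better.df - 1
        with pytest.warns(RuntimeWarning):
            lr_test(fake_free, better)
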