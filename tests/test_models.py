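"""Unit tests for the response-category probability machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr
from scipy.stats import norm

import lineupsdt.models as M
from lineupsdt.models import (
    category_probabilities,
    criterion_C,
    evsd_solve,
    truncated_normal_moments,
)
from lineupsdt.simulate import simulate_dataset
from lineupsdt.types import LineupDesign, SDTParams

from conftest import MODELS, cell_z_scores, random_config


class TestTruncatedNormalMoments:
    def test_truncation_vanishes_in_the_upper_limit(self):
        mu, sigma = truncated_normal_moments(8.0)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_half_normal_closed_form(self):
        mu, sigma = truncated_normal_moments(0.0)
        assert mu == pytest.approx(-np.sqrt(2 / np.pi), abs=1e-12)
        assert sigma == pytest.approx(np.sqrt(1 - 2 / np.pi), abs=1e-12)

    def test_deep_tail_against_monte_carlo(self, rng):
        draws = rng.standard_normal(10_000_000)
        tail = draws[draws <= -2.0]
        mu, sigma = truncated_normal_moments(-2.0)
        se_mu = tail.std() / np.sqrt(tail.size)
        assert mu == pytest.approx(tail.mean(), abs=3 * se_mu)
        assert sigma == pytest.approx(tail.std(), abs=3 * se_mu)

    def test_stable_far_into_the_tail(self):
        mu, sigma = truncated_normal_moments(-8.0)
        assert np.isfinite(mu) and np.isfinite(sigma)
        assert mu < -8.0 and 0 <= sigma < 0.2

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            truncated_normal_moments(np.inf)


class TestMaxRule:
    def test_showup_limit_matches_yes_no_form(self):
        p = SDTParams(d_t=1.2, s_t=0.8, criteria=(0.5,))
        for c in (-1.0, 0.3, 1.7):
            assert M.max_ptid(c, p, 1) == pytest.approx(
                1 - ndtr((c - 1.2) / 0.8), abs=1e-10
            )

    def test_exchangeable_target_equals_fair_foil_formula(self):
        p = SDTParams(d_t=0.0, s_t=1.0, criteria=(0.7,))
        for c in (-0.5, 0.7, 1.5):
            assert M.max_ptid(c, p, 6) == pytest.approx(
                (1 - ndtr(c) ** 6) / 6, abs=1e-9
            )
            assert M.max_pfid_tp(c, p, 6) == pytest.approx(
                5 / 6 * (1 - ndtr(c) ** 6), abs=1e-9
            )

    def test_fair_lenient_limit_is_one_over_n(self):
        p = SDTParams(d_t=1.0, criteria=(-8.0,))
        d = LineupDesign(n=6)
        assert M.max_psid(-8.0, p, d) == pytest.approx(1 / 6, abs=1e-6)

    def test_indistinct_suspect_matches_fair_branch(self):
        p = SDTParams(d_t=1.0, d_s=0.0, s_s=1.0, criteria=(0.4,))
        fair = LineupDesign(n=6)
        sus = LineupDesign(n=6, has_suspect=True)
        for c in (0.0, 1.0, 2.0):
            assert M.max_psid(c, p, sus) == pytest.approx(
                M.max_psid(c, p, fair), abs=1e-9
            )

    def test_unbeatable_target_leaves_no_foil_ids(self):
        p = SDTParams(d_t=12.0, s_t=0.5, criteria=(1.0,))
        assert M.max_pfid_tp(1.0, p, 6) == pytest.approx(0.0, abs=1e-8)

    def test_single_item_lineup_has_no_foils(self):
        p = SDTParams(d_t=1.0, criteria=(0.0,))
        assert M.max_pfid_tp(0.0, p, 1) == 0.0


class TestIntRule:
    def test_showup_limit(self):
        p = SDTParams(d_t=1.5, s_t=1.3, criteria=(0.2,))
        assert M.int_ptid(0.2, p, 1) == pytest.approx(
            1 - ndtr((0.2 - 1.5) / 1.3), abs=1e-10
        )

    def test_fair_ta_sum_is_exactly_normal(self):
        p = SDTParams(d_t=1.0, criteria=(0.0,))
        d = LineupDesign(n=6)
        assert M.int_psid(0.0, p, d) == pytest.approx(1 / 12, abs=1e-12)

    def test_tid_rate_equals_sid_rate_under_exchangeability(self):
        # with a null target the per-item choose probabilities coincide
        p = SDTParams(d_t=0.0, s_t=1.0, criteria=(1.0,))
        d = LineupDesign(n=6)
        tid = M.int_ptid(1.0, p, 6)
        sid = M.int_psid(1.0, p, d)
        assert tid == pytest.approx(sid, abs=2e-3)  # CLT approximation


class TestSeqRule:
    def test_showup_limit_is_the_yes_no_model(self):
        p = SDTParams(d_t=1.2, s_t=0.9, criteria=(0.6,))
        d = LineupDesign(n=1)
        assert M.seq_ptid(0.6, p, d) == pytest.approx(
            1 - ndtr((0.6 - 1.2) / 0.9), abs=1e-12
        )

    def test_exchangeability_matches_fair_suspect_rate(self):
        p = SDTParams(d_t=0.0, s_t=1.0, criteria=(0.4, 1.0))
        d = LineupDesign(n=6)
        for c in (0.4, 1.0, 1.8):
            assert M.seq_ptid(c, p, d) == pytest.approx(
                M.seq_psid(c, p, d), abs=1e-12
            )

    def test_confidence_below_choose_criterion_is_rejected(self):
        p = SDTParams(d_t=1.0, criteria=(0.5,))
        with pytest.raises(ValueError):
            M.seq_ptid(0.0, p, LineupDesign(n=6))

    def test_position_weights_enter_through_stopping_rule(self):
        # target guaranteed first: no foil can precede it
        p = SDTParams(d_t=1.5, s_t=1.1, criteria=(0.5,))
        first = LineupDesign(n=4, p=(1, 0, 0, 0))
        assert M.seq_ptid(0.5, p, first) == pytest.approx(
            1 - ndtr((0.5 - 1.5) / 1.1), abs=1e-12
        )
        # target guaranteed last: all n-1 foils must be rejected first
        last = LineupDesign(n=4, p=(0, 0, 0, 1))
        assert M.seq_ptid(0.5, p, last) == pytest.approx(
            (1 - ndtr((0.5 - 1.5) / 1.1)) * ndtr(0.5) ** 3, abs=1e-12
        )

    def test_tp_rejection_closed_form(self):
        p = SDTParams(d_t=1.3, s_t=0.9, criteria=(0.8, 1.4))
        d = LineupDesign(n=5, p=(0.4, 0.3, 0.2, 0.1, 0.0))
        expect = ndtr((0.8 - 1.3) / 0.9) * ndtr(0.8) ** 4
        assert M.seq_tp_reject(p, d) == pytest.approx(expect, abs=1e-12)


class TestEnsembleRule:
    def test_rejects_single_item_lineups(self):
        p = SDTParams(d_t=1.0, criteria=(0.0,))
        with pytest.raises(ValueError):
            M.ensemble_tid(0.0, p, 1)

    def test_exchangeability_tp_equals_ta(self):
        p = SDTParams(d_t=0.0, s_t=1.0, criteria=(0.3, 1.0))
        d = LineupDesign(n=6)
        probs = category_probabilities("ensemble", p, d)
        tp_choose = probs.tp_target_id + probs.tp_foil_id
        assert np.allclose(tp_choose, probs.ta_id, atol=1e-12)
        assert probs.tp_reject == pytest.approx(probs.ta_reject, abs=1e-12)

    def test_lenient_limit_always_chooses(self):
        p = SDTParams(d_t=1.0, criteria=(-9.0,))
        d = LineupDesign(n=6)
        probs = category_probabilities("ensemble", p, d)
        assert probs.tp_reject == pytest.approx(0.0, abs=1e-9)
        assert probs.ta_reject == pytest.approx(0.0, abs=1e-9)

    def test_any_foil_identity_under_exchangeability(self):
        # n * P(single item chosen) must agree with the combined per-draw
        # any-identification estimate
        for c in (0.0, 0.8, 1.6):
            any_id = M._ensemble_p_any(np.array([c]), 6)[0]
            single = M._ensemble_p_distinguished(np.array([c]), 0.0, 1.0, 6)[0]
            assert any_id == pytest.approx(6 * single, abs=2e-3)


class TestShowupClosedForm:
    def test_chance_performance(self):
        assert evsd_solve(0.5, 0.5) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_one_sigma_rates(self):
        d_t, c = evsd_solve(ndtr(1.0), ndtr(-1.0))
        assert d_t == pytest.approx(2.0, abs=1e-9)
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_boundary_rates_refused(self):
        for H, F in ((1.0, 0.1), (0.5, 0.0)):
            with pytest.raises(ValueError):
                evsd_solve(H, F)

    def test_bias_index(self):
        assert criterion_C(1.0, 2.0) == 0.0
        assert criterion_C(0.0, 1.0) == -0.5


class TestCategoryProbabilities:
    @pytest.mark.parametrize("model", MODELS)
    def test_single_criterion_gives_binary_split(self, model, rng):
        params, design = random_config(rng, model, n_range=(2, 7))
        params = SDTParams(
            d_t=params.d_t, s_t=params.s_t, d_s=params.d_s, s_s=params.s_s,
            criteria=(params.criteria[0],),
        )
        probs = category_probabilities(model, params, design)
        assert probs.tp_cells().size == 3
        assert probs.tp_cells().sum() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("model", MODELS)
    def test_normalisation_over_random_draws(self, model, rng):
        with M.ensemble_precision(10):
            for _ in range(40):
                params, design = random_config(rng, model)
                probs = category_probabilities(model, params, design)
                assert (probs.tp_cells() >= 0).all()
                assert (probs.ta_cells() >= 0).all()
                assert probs.tp_cells().sum() == pytest.approx(1.0, abs=1e-8)
                assert probs.ta_cells().sum() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("model", MODELS)
    def test_cumulative_curves_non_increasing(self, model, rng):
        params, design = random_config(rng, model)
        grid = np.linspace(params.criteria[0], params.criteria[0] + 4, 40)
        if model == "max":
            vals = M.max_ptid(grid, params, design.n)
        elif model == "int":
            vals = M.int_ptid(grid, params, design.n)
        elif model == "seq":
            vals = M.seq_ptid(grid, params, design)
        else:
            vals = M.ensemble_tid(grid, params, design.n)
        assert (np.diff(vals) <= 1e-9).all()

    def test_showup_tag_requires_size_one(self):
        p = SDTParams(d_t=1.0, criteria=(0.5,))
        with pytest.raises(ValueError):
            category_probabilities("evsd", p, LineupDesign(n=6))

    def test_unknown_model_rejected(self):
        p = SDTParams(d_t=1.0, criteria=(0.5,))
        with pytest.raises(ValueError):
            category_probabilities("bogus", p, LineupDesign(n=6))


@pytest.mark.parametrize("model", MODELS)
def test_analytic_probabilities_match_simulator(model, rng):
    """Quick law-of-large-numbers certification: the deeper 10^6-trial
    sweep lives in the acceptance suite."""
    sum_rule = "normal-approx" if model == "int" else "exact"
    for _ in range(4):
        params, design = random_config(rng, model)
        probs = category_probabilities(model, params, design)
        n = 150_000
        ds = simulate_dataset(
            model, params, design, n, n, seed=int(rng.integers(2**31)),
            sum_rule=sum_rule,
        )
        z = cell_z_scores(ds.table, probs, n, n)
        assert (z < 4.5).all(), f"max z {z.max():.2f}"


def test_int_rule_matches_exact_sum_simulator_loosely(rng):
    """The truncated-normal CLT approximation must land close to the
    exact-sum process: a relaxed absolute tolerance absorbs the documented
    approximation error."""
    params = SDTParams(d_t=2.56, s_t=2.02, criteria=(-0.54, 0.79, 1.56, 3.41, 5.17))
    design = LineupDesign(n=6)
    probs = category_probabilities("int", params, design)
    n = 400_000
    ds = simulate_dataset("int", params, design, n, n, seed=11, sum_rule="exact")
    for o_cells, p_cells, nn in (
        (ds.table.tp_cells(), probs.tp_cells(), n),
        (ds.table.ta_cells(), probs.ta_cells(), n),
    ):
        obs = np.asarray(o_cells) / nn
        assert np.abs(obs - np.asarray(p_cells)).max() < 0.01


@settings(max_examples=50, deadline=None)
@given(
    d_t=st.floats(-3, 3),
    s_t=st.floats(0.3, 3),
    c1=st.floats(-2, 2),
    incr=st.lists(st.floats(0.05, 1.0), min_size=0, max_size=4),
    n=st.integers(1, 8),
)
def test_max_rule_probabilities_always_admissible(d_t, s_t, c1, incr, n):
    params = SDTParams(d_t=d_t, s_t=s_t, criteria=tuple(np.concatenate([[c1], c1 + np.cumsum(incr)])))
    probs = category_probabilities("max", params, LineupDesign(n=n))
    cells = np.concatenate([probs.tp_cells(), probs.ta_cells()])
    assert (cells >= 0).all() and (cells <= 1).all()
    assert probs.tp_cells().sum() == pytest.approx(1.0, abs=1e-8)
    assert probs.ta_cells().sum() == pytest.approx(1.0, abs=1e-8)


def test_quadrature_matches_adaptive_quad():
    """Fixed-order Gauss-Legendre agrees with scipy's adaptive quadrature
    to far below the precision any fitted statistic needs."""
    from scipy.integrate import quad

    p = SDTParams(d_t=1.83, s_t=0.94, criteria=(1.16,))
    ref, _ = quad(
        lambda x: norm.pdf(x, 1.83, 0.94) * norm.cdf(x) ** 5, 1.16, 12, epsabs=1e-13
    )
    assert M.max_ptid(1.16, p, 6) == pytest.approx(ref, abs=1e-10)
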