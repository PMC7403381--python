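"""Trial-level simulation of lineup decisions.

Each trial draws one familiarity value per lineup member (foils standard
normal, target N(d_t, s_t) at a position sampled from the design's ``p``,
designated suspect N(d_s, s_s) at a position from ``q``) and applies the
literal decision rule of the requested model.  This is the brute-force
oracle against which the closed-form / quadrature probabilities in
:mod:`lineupsdt.models` are certified, and the data generator for the
cross-fitting study.

For the integration rule two generative variants exist: ``sum_rule='exact'``
uses the true summed familiarity, while ``'normal-approx'`` replaces the
conditional sum of the non-maximal items by its truncated-normal
approximation — i.e. the exact generative counterpart of the model's
probability formulas.
"""

from __future__ import annotations

import numpy as np

from .models import _truncated_moments_general, truncated_normal_moments
from .types import LineupDesign, OutcomeTable, SDTParams, SimulatedDataset

__all__ = ["simulate_trial", "simulate_dataset", "simulate_condition"]

TARGET, FOIL, SUSPECT, REJECT = 0, 1, 2, 3
_KIND_NAMES = {TARGET: "target", FOIL: "foil", SUSPECT: "suspect", REJECT: "reject"}


def _draw_lineup(params, design, condition, size, rng):
    """Familiarity matrix (size, n) plus the odd-item position (or -1)."""
    n = design.n
    x = rng.standard_normal((size, n))
    if condition == "TP":
        pos = rng.choice(n, size=size, p=np.asarray(design.p))
        x[np.arange(size), pos] = params.d_t + params.s_t * rng.standard_normal(size)
    elif condition == "TA":
        if design.has_suspect:
            pos = rng.choice(n, size=size, p=np.asarray(design.q))
            x[np.arange(size), pos] = (
                params.d_s + params.s_s * rng.standard_normal(size)
            )
        else:
            pos = np.full(size, -1)
    else:
        raise ValueError("condition must be 'TP' or 'TA'")
    return x, pos


def _bin_of(values, criteria):
    """0-based ascending confidence bin of each value (value >= c_1 assumed)."""
    return np.searchsorted(np.asarray(criteria), values, side="right") - 1


def _odd_kind(condition):
    return TARGET if condition == "TP" else SUSPECT


def simulate_condition(
    model: str,
    params: SDTParams,
    design: LineupDesign,
    condition: str,
    size: int,
    rng: np.random.Generator,
    sum_rule: str = "exact",
):
    """Vectorised outcome draw: returns (kinds, bins) integer arrays.

    ``bins`` is -1 for rejections.  ``kinds`` uses the module constants
    TARGET/FOIL/SUSPECT/REJECT; on fair TA lineups every identification is
    a FOIL.
    """
    model = model.lower()
    crit = np.asarray(params.criteria)
    c1 = crit[0]
    n = design.n
    x, pos = _draw_lineup(params, design, condition, size, rng)
    odd = _odd_kind(condition)

    if model in ("max", "evsd"):
        arg = np.argmax(x, axis=1)
        val = x[np.arange(size), arg]
        choose = val >= c1
        evidence = val
    elif model == "int":
        arg = np.argmax(x, axis=1)
        if sum_rule == "exact":
            total = x.sum(axis=1)
        elif sum_rule == "normal-approx":
            # fair-TA sums are exactly normal in the model too; the
            # truncated-normal approximation only enters with an odd item
            if (pos < 0).all():
                total = x.sum(axis=1)
            else:
                total = _approx_sum(x, pos, params, condition, rng)
        else:
            raise ValueError("sum_rule must be 'exact' or 'normal-approx'")
        choose = total >= c1
        evidence = total
    elif model == "seq":
        hit = x >= c1
        any_hit = hit.any(axis=1)
        arg = np.argmax(hit, axis=1)  # first position at/above c_1
        evidence = x[np.arange(size), arg]
        choose = any_hit
    elif model == "ensemble":
        if n < 2:
            raise ValueError("ensemble rule requires n >= 2")
        arg = np.argmax(x, axis=1)
        val = x[np.arange(size), arg]
        evidence = val - (x.sum(axis=1) - val) / (n - 1)
        choose = evidence >= c1
    else:
        raise ValueError(f"unknown model {model!r}")

    kinds = np.full(size, REJECT, dtype=np.int64)
    kinds[choose & (arg == pos)] = odd
    kinds[choose & (arg != pos)] = FOIL
    bins = np.full(size, -1, dtype=np.int64)
    bins[choose] = _bin_of(evidence[choose], crit)
    return kinds, bins


def _approx_sum(x, pos, params, condition, rng):
    """Summed familiarity with the non-maximal items replaced by their
    truncated-normal approximation (the integration model's own CLT form)."""
    size, n = x.shape
    arg = np.argmax(x, axis=1)
    vmax = x[np.arange(size), arg]
    mu_x, sigma_x = truncated_normal_moments(vmax)
    odd_is_max = arg == pos
    if condition == "TP" or (pos >= 0).any():
        d = params.d_t if condition == "TP" else params.d_s
        s = params.s_t if condition == "TP" else params.s_s
    else:
        d, s = 0.0, 1.0
    has_odd = pos >= 0
    mu_o, sigma_o = _truncated_moments_general(vmax, d, s)
    m = np.where(
        ~has_odd | odd_is_max,
        (n - 1) * mu_x,
        (n - 2) * mu_x + mu_o,
    )
    v = np.where(
        ~has_odd | odd_is_max,
        (n - 1) * sigma_x**2,
        (n - 2) * sigma_x**2 + sigma_o**2,
    )
    return vmax + m + np.sqrt(v) * rng.standard_normal(size)


def simulate_trial(
    model: str,
    params: SDTParams,
    design: LineupDesign,
    condition: str,
    rng: np.random.Generator,
    sum_rule: str = "exact",
):
    """Single trial: returns ``(kind, bin)`` with kind in
    {'target', 'foil', 'suspect', 'reject'} and bin the 0-based ascending
    confidence bin (None for rejections)."""
    kinds, bins = simulate_condition(model, params, design, condition, 1, rng, sum_rule)
    kind = _KIND_NAMES[int(kinds[0])]
    return kind, (None if kind == "reject" else int(bins[0]))


def _tabulate(kinds, bins, k, kind):
    sel = kinds == kind
    return np.bincount(bins[sel], minlength=k)[:k]


def simulate_dataset(
    model: str,
    params: SDTParams,
    design: LineupDesign,
    n_tp: int,
    n_ta: int,
    seed: int,
    sum_rule: str = "exact",
) -> SimulatedDataset:
    """Aggregate ``n_tp`` + ``n_ta`` simulated trials into an OutcomeTable.

    Bit-reproducible for a given (model, params, design, counts, seed).
    """
    rng = np.random.default_rng(seed)
    k = params.k
    tp_kinds, tp_bins = simulate_condition(
        model, params, design, "TP", n_tp, rng, sum_rule
    )
    ta_kinds, ta_bins = simulate_condition(
        model, params, design, "TA", n_ta, rng, sum_rule
    )
    ta_mode = "suspect" if design.has_suspect else "any-foil"
    table = OutcomeTable(
        k=k,
        tp_target_id=_tabulate(tp_kinds, tp_bins, k, TARGET),
        tp_foil_id=_tabulate(tp_kinds, tp_bins, k, FOIL),
        tp_reject=int((tp_kinds == REJECT).sum()),
        ta_id=_tabulate(ta_kinds, ta_bins, k, SUSPECT if ta_mode == "suspect" else FOIL),
        ta_reject=int((ta_kinds == REJECT).sum()),
        ta_mode=ta_mode,
        ta_foil_id=(
            _tabulate(ta_kinds, ta_bins, k, FOIL) if ta_mode == "suspect" else None
        ),
        design=design,
    )
    return SimulatedDataset(
        design=design, n_tp=n_tp, n_ta=n_ta, table=table, seed=seed, model=model
    )
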