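"""Response-category probabilities for lineup signal-detection models.

Four decision rules for an n-item lineup are implemented, all built on the
unequal-variance Gaussian familiarity framework (foils N(0,1), target
N(d_t, s_t), optional designated innocent suspect N(d_s, s_s)):

``max``
    Simultaneous lineup, independent-observations rule: identify the most
    familiar item iff its familiarity exceeds the lowest criterion.
``int``
    Simultaneous lineup, integration rule: identify the most familiar item
    iff the *sum* of all familiarities exceeds the criterion.  Uses the
    truncated-normal central-limit approximation for the conditional sum
    of the non-maximal items, so criteria live on the summed scale.
``seq``
    Stopping-rule sequential lineup: items are viewed in position order
    and the first item whose familiarity reaches the choose criterion c_1
    is identified; confidence comes from the chosen item's familiarity.
``ensemble``
    Simultaneous lineup, ensemble rule: the most familiar item is compared
    with the *mean* of the remaining items; identify iff the difference
    exceeds the criterion.

A show-up (n = 1) is the common limit of ``max``, ``int`` and ``seq``; the
equal-variance show-up model has the closed-form solution
:func:`evsd_solve`.

Cumulative identification probabilities P(. >= c) are evaluated with
fixed-order Gauss-Legendre quadrature on a standard-normal support window;
the ensemble rule, whose decision variable mixes the maximum and the mean,
is evaluated by scrambled-Sobol quasi-Monte Carlo over the foil draws with
the remaining dimension integrated analytically (deterministic given the
internal seed).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import erfcx, ndtr, ndtri
from scipy.stats import qmc

from .types import CategoryProbabilities, LineupDesign, SDTParams

__all__ = [
    "truncated_normal_moments",
    "max_ptid",
    "max_psid",
    "max_pfid_tp",
    "int_ptid",
    "int_psid",
    "int_pfid_tp",
    "seq_ptid",
    "seq_psid",
    "seq_pfid_tp",
    "ensemble_probs",
    "evsd_solve",
    "category_probabilities",
    "criterion_C",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_GL_POINTS = 128
# QMC settings for the ensemble rule: 2^16 scrambled Sobol points over
# the foil dimensions by default (worst-cell error ~2e-4, well inside the
# simulator-agreement tolerance).  Bulk simulation studies and the inner
# loops of optimisation may lower the precision via ensemble_precision().
_ENSEMBLE_LOG2_M = 16
_ENSEMBLE_SEED = 20200804


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(x)) / _SQRT_2PI


def _hazard_lower(x: np.ndarray) -> np.ndarray:
    """phi(x) / Phi(x), stable far into the lower tail (x << 0)."""
    x = np.asarray(x, dtype=float)
    return np.sqrt(2.0 / np.pi) / erfcx(-x / np.sqrt(2.0))


def truncated_normal_moments(x):
    """Mean and SD of a standard normal truncated to the interval (-inf, x].

    Returns ``(mu_x, sigma_x)``; both broadcast over array input.  Stable
    down to x = -8 and far beyond via the scaled complementary error
    function.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("truncation point must be finite")
    lam = _hazard_lower(x)
    mu = -lam
    var = 1.0 - x * lam - lam * lam
    sigma = np.sqrt(np.clip(var, 0.0, None))
    if x.ndim == 0:
        return float(mu), float(sigma)
    return mu, sigma


def _truncated_moments_general(x, mu, sigma):
    """Moments of N(mu, sigma) truncated to (-inf, x]."""
    alpha = (np.asarray(x, dtype=float) - mu) / sigma
    lam = _hazard_lower(alpha)
    m = mu - sigma * lam
    var = sigma**2 * np.clip(1.0 - alpha * lam - lam * lam, 0.0, None)
    return m, np.sqrt(var)


@lru_cache(maxsize=8)
def _gl_nodes(npts: int):
    x, w = np.polynomial.legendre.leggauss(npts)
    return x, w


def _integrate_upper(f, lo, hi, npts: int = _GL_POINTS):
    """integral_{lo_i}^{hi} f(x) dx for an array of lower limits lo_i.

    ``f`` must accept a 2-D array of abscissae and return values of the
    same shape.  Gauss-Legendre on each [lo_i, hi] interval.
    """
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    x, w = _gl_nodes(npts)
    half = (hi - lo) / 2.0  # (m,)
    mid = (hi + lo) / 2.0
    xs = mid[:, None] + half[:, None] * x[None, :]  # (m, npts)
    vals = f(xs)
    out = (vals * w[None, :]).sum(axis=1) * half
    return np.clip(out, 0.0, 1.0)


def _support(params: SDTParams, width: float = 8.0):
    """Integration window covering foil, target and suspect densities."""
    lo = min(-width, params.d_t - width * params.s_t, params.d_s - width * params.s_s)
    hi = max(width, params.d_t + width * params.s_t, params.d_s + width * params.s_s)
    return lo, hi


def _as_scalar(out, c):
    if np.ndim(c) == 0:
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# SDT-MAX (independent observations)
# ---------------------------------------------------------------------------

def max_ptid(c, params: SDTParams, n: int):
    """P(correct target ID with confidence >= c) under the max rule.

    integral_c^inf phi(x; d_t, s_t) Phi(x)^(n-1) dx — the target has the
    largest familiarity and that familiarity clears the criterion.
    """
    if n < 1:
        raise ValueError("lineup size must be >= 1")
    d, s = params.d_t, params.s_t
    if n == 1:
        out = 1.0 - ndtr((np.atleast_1d(np.asarray(c, float)) - d) / s)
        return _as_scalar(out, c)
    _, hi = _support(params)

    def f(x):
        return _phi((x - d) / s) / s * ndtr(x) ** (n - 1)

    out = _integrate_upper(f, c, hi)
    return _as_scalar(out, c)


def max_psid(c, params: SDTParams, design: LineupDesign):
    """P(innocent-suspect ID with confidence >= c) under the max rule.

    Designated-suspect lineups integrate the suspect density against
    Phi(x)^(n-1); fair lineups use the exchangeable closed form
    (1/n)(1 - Phi(c)^n), the per-foil share of the any-foil rate.
    """
    n = design.n
    if design.has_suspect:
        d, s = params.d_s, params.s_s
        if n == 1:
            out = 1.0 - ndtr((np.atleast_1d(np.asarray(c, float)) - d) / s)
            return _as_scalar(out, c)
        _, hi = _support(params)

        def f(x):
            return _phi((x - d) / s) / s * ndtr(x) ** (n - 1)

        out = _integrate_upper(f, c, hi)
        return _as_scalar(out, c)
    out = (1.0 - ndtr(np.atleast_1d(np.asarray(c, float))) ** n) / n
    return _as_scalar(out, c)


def _max_pfid(c, d, s, n, support):
    """P(the maximum is one of n-1 foils and exceeds c); the odd item out
    (target or designated suspect) is N(d, s)."""
    if n < 2:
        out = np.zeros_like(np.atleast_1d(np.asarray(c, float)))
        return _as_scalar(out, c)
    _, hi = support

    def f(x):
        return (n - 1) * _phi(x) * ndtr(x) ** (n - 2) * ndtr((x - d) / s)

    out = _integrate_upper(f, c, hi)
    return _as_scalar(out, c)


def max_pfid_tp(c, params: SDTParams, n: int):
    """P(foil ID with confidence >= c) on a target-present lineup (max rule)."""
    return _max_pfid(c, params.d_t, params.s_t, n, _support(params))


def max_pfid_ta_suspect(c, params: SDTParams, design: LineupDesign):
    """P(foil ID, confidence >= c) on a TA lineup with a designated suspect."""
    return _max_pfid(c, params.d_s, params.s_s, design.n, _support(params))


# ---------------------------------------------------------------------------
# SDT-INT (integration / summed familiarity)
# ---------------------------------------------------------------------------

def _int_pdistinguished(c, d, s, n, support):
    """P(distinguished item is the maximum and sum(X) >= c).

    The distinguished item is N(d, s); the n-1 foils, conditioned below its
    value x, contribute a sum approximated as normal with the truncated
    standard-normal moments (mu_x, sigma_x).
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if n == 1:
        return 1.0 - ndtr((c - d) / s)
    lo, hi = support
    x, w = _gl_nodes(_GL_POINTS)
    half, mid = (hi - lo) / 2.0, (hi + lo) / 2.0
    xs = mid + half * x  # (npts,)
    mu_x, sigma_x = truncated_normal_moments(xs)
    m_sum = (n - 1) * mu_x
    s_sum = np.sqrt(n - 1) * sigma_x
    dens = _phi((xs - d) / s) / s * ndtr(xs) ** (n - 1) * w * half  # (npts,)
    z = (c[:, None] - xs[None, :] - m_sum[None, :]) / s_sum[None, :]
    tail = 1.0 - ndtr(z)
    return np.clip(tail @ dens, 0.0, 1.0)


def int_ptid(c, params: SDTParams, n: int):
    """P(target ID with confidence >= c) under the integration rule."""
    if n < 1:
        raise ValueError("lineup size must be >= 1")
    out = _int_pdistinguished(c, params.d_t, params.s_t, n, _support(params))
    return _as_scalar(out, c)


def int_psid(c, params: SDTParams, design: LineupDesign):
    """P(suspect ID with confidence >= c) under the integration rule.

    Fair lineups: the summed familiarity of n foils is exactly N(0, sqrt n),
    giving (1/n)(1 - Phi(c; 0, sqrt n)) per foil.
    """
    n = design.n
    if design.has_suspect:
        out = _int_pdistinguished(c, params.d_s, params.s_s, n, _support(params))
        return _as_scalar(out, c)
    cc = np.atleast_1d(np.asarray(c, float))
    out = (1.0 - ndtr(cc / np.sqrt(n))) / n
    return _as_scalar(out, c)


def _int_pfid(c, d, s, n, support):
    """P(a foil is the maximum and sum(X) >= c), odd item N(d, s).

    Conditional on the maximal foil's value x, the sum adds n-2 foils
    truncated at x plus the odd item truncated at x, each replaced by its
    normal approximation.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if n < 2:
        return np.zeros_like(c)
    lo, hi = support
    x, w = _gl_nodes(_GL_POINTS)
    half, mid = (hi - lo) / 2.0, (hi + lo) / 2.0
    xs = mid + half * x
    mu_x, sigma_x = truncated_normal_moments(xs)
    mu_o, sigma_o = _truncated_moments_general(xs, d, s)
    m_sum = (n - 2) * mu_x + mu_o
    s_sum = np.sqrt((n - 2) * sigma_x**2 + sigma_o**2)
    dens = (n - 1) * _phi(xs) * ndtr(xs) ** (n - 2) * ndtr((xs - d) / s) * w * half
    z = (c[:, None] - xs[None, :] - m_sum[None, :]) / s_sum[None, :]
    tail = 1.0 - ndtr(z)
    return np.clip(tail @ dens, 0.0, 1.0)


def int_pfid_tp(c, params: SDTParams, n: int):
    """P(foil ID with confidence >= c) on a TP lineup (integration rule)."""
    out = _int_pfid(c, params.d_t, params.s_t, n, _support(params))
    return _as_scalar(out, c)


def int_pfid_ta_suspect(c, params: SDTParams, design: LineupDesign):
    """P(foil ID, confidence >= c) on a designated-suspect TA lineup (int rule)."""
    out = _int_pfid(c, params.d_s, params.s_s, design.n, _support(params))
    return _as_scalar(out, c)


# ---------------------------------------------------------------------------
# SDT-SEQ (stopping rule)
# ---------------------------------------------------------------------------

def _check_seq_c(c, params: SDTParams):
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if (c < params.criteria[0] - 1e-12).any():
        raise ValueError("sequential confidence criteria must be >= c_1")
    return c


def seq_ptid(c, params: SDTParams, design: LineupDesign):
    """P(target ID with confidence >= c) under the stopping rule.

    (1 - Phi(c; d_t, s_t)) * sum_i p_i Phi(c_1)^(i-1): every item before
    the target must fall below the choose criterion, and the target's own
    familiarity must reach c.
    """
    cc = _check_seq_c(c, params)
    c1 = params.criteria[0]
    n = design.n
    w = ndtr(c1) ** np.arange(n)
    out = (1.0 - ndtr((cc - params.d_t) / params.s_t)) * float(np.dot(design.p, w))
    return _as_scalar(out, c)


def seq_psid(c, params: SDTParams, design: LineupDesign):
    """P(suspect ID with confidence >= c) under the stopping rule."""
    cc = _check_seq_c(c, params)
    c1 = params.criteria[0]
    n = design.n
    w = ndtr(c1) ** np.arange(n)
    if design.has_suspect:
        out = (1.0 - ndtr((cc - params.d_s) / params.s_s)) * float(np.dot(design.q, w))
    else:
        out = (1.0 - ndtr(cc)) * float(w.sum()) / n
    return _as_scalar(out, c)


def _seq_pfid(c, d, s, positions, params: SDTParams, n: int):
    """P(a foil is chosen with confidence >= c) when the odd item N(d, s)
    occupies position i with probability positions[i]."""
    cc = _check_seq_c(c, params)
    c1 = params.criteria[0]
    g = ndtr(c1)  # P(a foil stays below the choose criterion)
    g_odd = ndtr((c1 - d) / s)
    tail = 1.0 - ndtr(cc)
    out = np.zeros_like(cc)
    for i, pi in enumerate(positions, start=1):
        if pi == 0.0:
            continue
        before = sum(g ** (j - 1) for j in range(1, i))
        after = sum(g ** (j - 2) for j in range(i + 1, n + 1))
        out = out + pi * tail * (before + g_odd * after)
    return _as_scalar(out, c)


def seq_pfid_tp(c, params: SDTParams, design: LineupDesign):
    """P(foil ID with confidence >= c) on a TP sequential lineup.

    A foil ahead of the target needs only the preceding foils to stay
    below c_1; a foil after the target additionally needs the target
    itself rejected at c_1.
    """
    return _seq_pfid(c, params.d_t, params.s_t, design.p, params, design.n)


def seq_pfid_ta_suspect(c, params: SDTParams, design: LineupDesign):
    """P(foil ID, confidence >= c) on a designated-suspect TA sequential lineup."""
    return _seq_pfid(c, params.d_s, params.s_s, design.q, params, design.n)


def seq_tp_reject(params: SDTParams, design: LineupDesign) -> float:
    """P(reject) on a TP sequential lineup: every item falls below c_1."""
    c1 = params.criteria[0]
    return float(
        ndtr((c1 - params.d_t) / params.s_t) * ndtr(c1) ** (design.n - 1)
    )


def seq_ta_reject(params: SDTParams, design: LineupDesign) -> float:
    c1 = params.criteria[0]
    if design.has_suspect:
        return float(
            ndtr((c1 - params.d_s) / params.s_s) * ndtr(c1) ** (design.n - 1)
        )
    return float(ndtr(c1) ** design.n)


# ---------------------------------------------------------------------------
# Ensemble (max minus mean of remaining)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _ensemble_foil_draws_cached(n_foils: int, log2_m: int):
    sob = qmc.Sobol(d=n_foils, scramble=True, seed=_ENSEMBLE_SEED)
    u = sob.random_base2(m=log2_m)
    z = ndtri(np.clip(u, 1e-15, 1.0 - 1e-15))
    return z.max(axis=1), z.sum(axis=1)


def _ensemble_foil_draws(n_foils: int):
    """Scrambled-Sobol standard-normal draws for n_foils foil familiarities.

    Returns (z_max, z_sum) per draw; cached per (lineup size, precision).
    """
    return _ensemble_foil_draws_cached(n_foils, _ENSEMBLE_LOG2_M)


class ensemble_precision:
    """Context manager lowering/raising the ensemble QMC sample size.

    ``with ensemble_precision(12): ...`` evaluates ensemble probabilities
    from 2^12 Sobol points — useful for bulk simulation studies where the
    default precision is unnecessarily fine.
    """

    def __init__(self, log2_m: int):
        self.log2_m = int(log2_m)

    def __enter__(self):
        global _ENSEMBLE_LOG2_M
        self._saved = _ENSEMBLE_LOG2_M
        _ENSEMBLE_LOG2_M = self.log2_m
        return self

    def __exit__(self, *exc):
        global _ENSEMBLE_LOG2_M
        _ENSEMBLE_LOG2_M = self._saved
        return False


def _ensemble_p_distinguished(c, d, s, n):
    """P(the N(d, s) item is chosen with ensemble confidence >= c) among
    n-1 standard-normal foils, integrating the item's value analytically."""
    c = np.atleast_1d(np.asarray(c, dtype=float))
    z_max, z_sum = _ensemble_foil_draws(n - 1)
    # chosen iff t > max(foils) and t - z_sum/(n-1) >= c
    thresh = np.maximum(z_max[None, :], c[:, None] + z_sum[None, :] / (n - 1))
    return (1.0 - ndtr((thresh - d) / s)).mean(axis=1)


def _ensemble_p_foil(c, d, s, n):
    """P(the maximal foil is chosen with ensemble confidence >= c)."""
    c = np.atleast_1d(np.asarray(c, dtype=float))
    z_max, z_sum = _ensemble_foil_draws(n - 1)
    # chosen iff t < z_max and z_max - (z_sum - z_max + t)/(n-1) >= c
    upper = np.minimum(
        z_max[None, :],
        n * z_max[None, :] - (n - 1) * c[:, None] - z_sum[None, :],
    )
    return ndtr((upper - d) / s).mean(axis=1)


def ensemble_tid(c, params: SDTParams, n: int):
    """P(target ID with ensemble confidence >= c) on a TP lineup."""
    if n < 2:
        raise ValueError("ensemble rule requires n >= 2")
    out = _ensemble_p_distinguished(c, params.d_t, params.s_t, n)
    return _as_scalar(out, c)


def ensemble_fid_tp(c, params: SDTParams, n: int):
    """P(foil ID with ensemble confidence >= c) on a TP lineup."""
    if n < 2:
        raise ValueError("ensemble rule requires n >= 2")
    out = _ensemble_p_foil(c, params.d_t, params.s_t, n)
    return _as_scalar(out, c)


def _ensemble_p_any(c, n):
    """P(any of n exchangeable standard-normal items is chosen, conf >= c).

    Conditioning on n-1 items and integrating the last analytically, the
    per-draw 'last item chosen' and 'max conditioned item chosen' terms
    partition the choose event, so their sum has low variation across
    draws and the complementary rejection probability keeps full relative
    accuracy (unlike n times the single-item probability, whose
    quasi-Monte Carlo error would be amplified n-fold).
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    z_max, z_sum = _ensemble_foil_draws(n - 1)
    thresh = np.maximum(z_max[None, :], c[:, None] + z_sum[None, :] / (n - 1))
    upper = np.minimum(
        z_max[None, :],
        n * z_max[None, :] - (n - 1) * c[:, None] - z_sum[None, :],
    )
    return ((1.0 - ndtr(thresh)) + ndtr(upper)).mean(axis=1)


def ensemble_ta_id(c, params: SDTParams, design: LineupDesign):
    """Suspect-ID (designated suspect) or any-foil-ID probability on TA."""
    n = design.n
    if n < 2:
        raise ValueError("ensemble rule requires n >= 2")
    if design.has_suspect:
        out = _ensemble_p_distinguished(c, params.d_s, params.s_s, n)
    else:
        out = _ensemble_p_any(c, n)
    return _as_scalar(out, c)


def ensemble_fid_ta_suspect(c, params: SDTParams, design: LineupDesign):
    if design.n < 2:
        raise ValueError("ensemble rule requires n >= 2")
    out = _ensemble_p_foil(c, params.d_s, params.s_s, design.n)
    return _as_scalar(out, c)


# ---------------------------------------------------------------------------
# Show-up closed form and assembly
# ---------------------------------------------------------------------------

def evsd_solve(H: float, F: float) -> tuple[float, float]:
    """Equal-variance show-up solution: d_t = Phi^-1(H) - Phi^-1(F),
    c = Phi^-1(1 - F).  Saturated (0 df): the model reproduces (H, F)
    exactly.  Raises on boundary rates rather than applying a correction.
    """
    if not (0.0 < H < 1.0) or not (0.0 < F < 1.0):
        raise ValueError(
            "hit and false-alarm rates must lie strictly inside (0, 1); "
            "apply an explicit correction for boundary frequencies first"
        )
    return float(ndtri(H) - ndtri(F)), float(-ndtri(F))


def criterion_C(c: float, d_t: float) -> float:
    """Bias index C = c - d_t/2: distance of the criterion from the
    equal-variance unbiased midpoint (meaningful only when s_t = 1)."""
    return float(c) - float(d_t) / 2.0


def _diff_bins(cum: np.ndarray) -> np.ndarray:
    """Per-bin probabilities from cumulative P(. >= c_l), ascending bins."""
    ext = np.append(cum, 0.0)
    return np.clip(ext[:-1] - ext[1:], 0.0, None)


def category_probabilities(
    model: str, params: SDTParams, design: LineupDesign
) -> CategoryProbabilities:
    """Full multinomial outcome probabilities for one model.

    Per-bin probabilities are successive differences of the cumulative
    P(. >= c_l) curves; rejection is one minus the total identification
    probability per condition.
    """
    model = model.lower()
    c = np.asarray(params.criteria, dtype=float)
    n = design.n
    ta_mode = "suspect" if design.has_suspect else "any-foil"
    ta_foil = None

    if model in ("max", "evsd"):
        if model == "evsd" and n != 1:
            raise ValueError("the show-up model requires a lineup of size 1")
        tid = np.atleast_1d(max_ptid(c, params, n))
        fid = np.atleast_1d(max_pfid_tp(c, params, n))
        if design.has_suspect:
            sid = np.atleast_1d(max_psid(c, params, design))
            ta_f = np.atleast_1d(max_pfid_ta_suspect(c, params, design))
        else:
            sid = np.atleast_1d(max_psid(c, params, design)) * n  # any foil
            ta_f = None
    elif model == "int":
        tid = np.atleast_1d(int_ptid(c, params, n))
        fid = np.atleast_1d(int_pfid_tp(c, params, n))
        if design.has_suspect:
            sid = np.atleast_1d(int_psid(c, params, design))
            ta_f = np.atleast_1d(int_pfid_ta_suspect(c, params, design))
        else:
            sid = np.atleast_1d(int_psid(c, params, design)) * n
            ta_f = None
    elif model == "seq":
        tid = np.atleast_1d(seq_ptid(c, params, design))
        fid = np.atleast_1d(seq_pfid_tp(c, params, design))
        if design.has_suspect:
            sid = np.atleast_1d(seq_psid(c, params, design))
            ta_f = np.atleast_1d(seq_pfid_ta_suspect(c, params, design))
        else:
            sid = np.atleast_1d(seq_psid(c, params, design)) * n
            ta_f = None
    elif model == "ensemble":
        tid = np.atleast_1d(ensemble_tid(c, params, n))
        fid = np.atleast_1d(ensemble_fid_tp(c, params, n))
        if design.has_suspect:
            sid = np.atleast_1d(ensemble_ta_id(c, params, design))
            ta_f = np.atleast_1d(ensemble_fid_ta_suspect(c, params, design))
        else:
            sid = np.atleast_1d(ensemble_ta_id(c, params, design))
            ta_f = None
    else:
        raise ValueError(f"unknown model {model!r}")

    tp_target = _diff_bins(tid)
    tp_foil = _diff_bins(fid)
    tp_reject = max(0.0, 1.0 - float(tid[0]) - float(fid[0]))
    ta_id = _diff_bins(sid)
    if ta_f is not None:
        ta_foil = _diff_bins(ta_f)
        ta_reject = max(0.0, 1.0 - float(sid[0]) - float(ta_f[0]))
    else:
        ta_reject = max(0.0, 1.0 - float(sid[0]))

    return CategoryProbabilities(
        tp_target_id=tp_target,
        tp_foil_id=tp_foil,
        tp_reject=tp_reject,
        ta_id=ta_id,
        ta_reject=ta_reject,
        ta_mode=ta_mode,
        ta_foil_id=ta_foil,
    )
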