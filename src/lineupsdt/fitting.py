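"""Chi-square minimisation of lineup models, joint fits and LR tests.

Parameters are estimated by minimising the Pearson chi-square between
observed outcome frequencies and the model-implied multinomial
probabilities, summed over the target-present and target-absent
conditions (and over datasets, for joint fits).  Equality constraints —
fixing a parameter to a value, or sharing it across datasets — are imposed
directly in the parameter mapping, so nested models differ by exactly one
free parameter per constraint and the difference in minimised chi-square
is a 1-df likelihood-ratio-type statistic.

Optimisation uses Nelder-Mead from multiple dispersed, seeded starting
points (local minima are a documented hazard for these models); standard
deviations are searched on the log scale and criterion ordering is
enforced by a smooth penalty that is inactive at any admissible solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from .models import category_probabilities
from .types import FitResult, OutcomeTable, SDTParams

__all__ = ["chi_square", "fit_model", "joint_fit", "lr_test"]

_FLOOR = 1e-12
_PENALTY = 1e8

# generous bounds relative to every printed estimate
_BOUNDS = {"d_t": (-5.0, 5.0), "d_s": (-5.0, 5.0), "s": (0.1, 5.0), "c": (-5.0, 8.0)}


def chi_square(observed: OutcomeTable, expected) -> float:
    """Pearson chi-square: sum over all cells of (O - N P)^2 / (N P),
    with N the per-condition trial total; TP and TA contributions summed.
    """
    total = 0.0
    for o_cells, p_cells, n in (
        (observed.tp_cells(), expected.tp_cells(), observed.n_tp),
        (observed.ta_cells(), expected.ta_cells(), observed.n_ta),
    ):
        o = np.asarray(o_cells, dtype=float)
        p = np.asarray(p_cells, dtype=float)
        if ((p <= 0.0) & (o > 0)).any():
            raise ZeroDivisionError(
                "expected probability is zero on a cell with observed counts"
            )
        e = np.maximum(n * p, _FLOOR)
        total += float(((o - e) ** 2 / e).sum())
    return total


# ---------------------------------------------------------------------------
# Parameter mapping
# ---------------------------------------------------------------------------

def _relevant_names(model: str, table: OutcomeTable) -> list[str]:
    names = ["d_t"]
    if model != "evsd":
        names.append("s_t")
    if table.design.has_suspect:
        names += ["d_s", "s_s"]
    names += [f"c{i}" for i in range(1, table.k + 1)]
    return names


def _is_log_scale(name: str) -> bool:
    return name in ("s_t", "s_s")


@dataclass
class _ParamMap:
    """Maps a free vector to one SDTParams per dataset, honouring fixed
    values and cross-dataset sharing."""

    specs: list[tuple[str, OutcomeTable]]
    fixed: list[dict]
    shared: tuple[str, ...]

    def __post_init__(self):
        self.slots: list[tuple] = []  # (spec_index | 'shared', name)
        self.assign: list[dict] = []  # per spec: name -> ('free', j) | ('fixed', v)
        slot_index: dict[tuple, int] = {}
        for i, (model, table) in enumerate(self.specs):
            a = {}
            for name in _relevant_names(model, table):
                if name in self.fixed[i]:
                    a[name] = ("fixed", float(self.fixed[i][name]))
                    continue
                key = ("shared", name) if name in self.shared else (i, name)
                if key not in slot_index:
                    slot_index[key] = len(self.slots)
                    self.slots.append(key)
                a[name] = ("free", slot_index[key])
            self.assign.append(a)
        for name in self.shared:
            if ("shared", name) not in slot_index:
                raise ValueError(f"shared parameter {name!r} is not free in any dataset")

    @property
    def n_free(self) -> int:
        return len(self.slots)

    def unpack(self, theta: np.ndarray):
        """Free vector -> list of SDTParams (None if criteria unordered)."""
        out = []
        penalty = 0.0
        for i, (model, table) in enumerate(self.specs):
            vals = {}
            for name, spec in self.assign[i].items():
                kind, v = spec
                x = theta[v] if kind == "free" else v
                if kind == "free" and _is_log_scale(name):
                    x = float(np.exp(x))
                vals[name] = float(x)
            crit = np.array([vals[f"c{j}"] for j in range(1, table.k + 1)])
            d = np.diff(crit)
            if (d <= 0).any():
                penalty += float((np.maximum(0.0, -d) + 1e-3).sum())
                out.append(None)
                continue
            out.append(
                SDTParams(
                    d_t=vals["d_t"],
                    s_t=vals.get("s_t", 1.0),
                    d_s=vals.get("d_s", 0.0),
                    s_s=vals.get("s_s", 1.0),
                    criteria=tuple(crit),
                )
            )
        return out, penalty

    def pack(self, params_list: list[SDTParams]) -> np.ndarray:
        """Initial free vector from per-dataset parameter values (shared
        slots take the mean across datasets)."""
        acc: dict[int, list[float]] = {}
        for i, (model, table) in enumerate(self.specs):
            pp = params_list[i]
            vals = {
                "d_t": pp.d_t,
                "s_t": pp.s_t,
                "d_s": pp.d_s,
                "s_s": pp.s_s,
            }
            vals.update({f"c{j + 1}": c for j, c in enumerate(pp.criteria)})
            for name, spec in self.assign[i].items():
                kind, v = spec
                if kind != "free":
                    continue
                x = vals[name]
                acc.setdefault(v, []).append(
                    float(np.log(x)) if _is_log_scale(name) else float(x)
                )
        return np.array([np.mean(acc[j]) for j in range(self.n_free)])


def _random_start(pmap: _ParamMap, rng: np.random.Generator) -> np.ndarray:
    """Dispersed admissible starting point (ordered criteria per dataset)."""
    theta = np.empty(pmap.n_free)
    crit_draws: dict[int, np.ndarray] = {}
    for i, (model, table) in enumerate(pmap.specs):
        k = table.k
        scale = 2.0 if model == "int" else 1.0
        c1 = rng.uniform(-1.0, 2.0) * scale
        incr = rng.uniform(0.05, 0.8, size=max(k - 1, 0)) * scale
        draws = np.concatenate([[c1], c1 + np.cumsum(incr)])
        # stay inside the criterion bounds even on the stretched sum scale
        if draws[-1] > 8.0:
            draws = draws[0] + (draws - draws[0]) * (8.0 - draws[0]) / (
                draws[-1] - draws[0]
            )
        crit_draws[i] = draws
    for j, key in enumerate(pmap.slots):
        owner, name = key
        i = 0 if owner == "shared" else owner
        if name.startswith("c"):
            theta[j] = crit_draws[i][int(name[1:]) - 1]
        elif name in ("d_t", "d_s"):
            theta[j] = rng.uniform(0.0, 3.0)
        else:  # log sd
            theta[j] = rng.uniform(np.log(0.5), np.log(2.0))
    return theta


def _objective(pmap: _ParamMap):
    def f(theta):
        params_list, penalty = pmap.unpack(theta)
        if penalty > 0:
            return _PENALTY * (1.0 + penalty)
        total = 0.0
        for (model, table), pp in zip(pmap.specs, params_list):
            # keep the search inside the documented bounds
            if not (-5.0 <= pp.d_t <= 5.0 and -5.0 <= pp.d_s <= 5.0):
                return _PENALTY
            if not (0.05 <= pp.s_t <= 8.0 and 0.05 <= pp.s_s <= 8.0):
                return _PENALTY
            if pp.criteria[0] < -6.0 or pp.criteria[-1] > 10.0:
                return _PENALTY
            probs = category_probabilities(
                "max" if model == "evsd" else model, pp, table.design
            )
            total += _chi_square_floored(table, probs)
        return total

    return f


def _chi_square_floored(observed: OutcomeTable, expected) -> float:
    total = 0.0
    for o_cells, p_cells, n in (
        (observed.tp_cells(), expected.tp_cells(), observed.n_tp),
        (observed.ta_cells(), expected.ta_cells(), observed.n_ta),
    ):
        o = np.asarray(o_cells, dtype=float)
        e = np.maximum(n * np.asarray(p_cells, dtype=float), _FLOOR)
        total += float(((o - e) ** 2 / e).sum())
    return total


def _minimise(f, x0: np.ndarray, maxfev_per_dim: int = 700):
    res = optimize.minimize(
        f,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": maxfev_per_dim * max(len(x0), 1),
            "xatol": 1e-7,
            "fatol": 1e-9,
            "adaptive": len(x0) > 6,
        },
    )
    # restart once from the incumbent: Nelder-Mead can stall on a shrunk simplex
    res2 = optimize.minimize(
        f,
        res.x,
        method="Nelder-Mead",
        options={
            "maxfev": maxfev_per_dim // 2 * max(len(x0), 1),
            "xatol": 1e-8,
            "fatol": 1e-10,
        },
    )
    return res2 if res2.fun <= res.fun else res


def joint_fit(
    specs: list[tuple[str, OutcomeTable]],
    shared: tuple[str, ...] | set = (),
    fixed: dict | list[dict] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    init: list[SDTParams] | None = None,
    maxfev_per_dim: int = 700,
) -> FitResult:
    """Minimise the summed chi-square across datasets with shared/fixed
    parameter constraints; df = total free cells - total free parameters.

    ``specs`` pairs a model tag ('max', 'int', 'seq', 'ensemble', 'evsd')
    with its OutcomeTable.  ``fixed`` may be one dict applied to every
    dataset or a per-dataset list.  ``init``, when given, seeds one start
    from those parameter values in addition to the dispersed restarts.
    The show-up tag 'evsd' fixes s_t = 1 implicitly.  ``maxfev_per_dim``
    caps simplex evaluations per free parameter (bulk simulation studies
    lower it).
    """
    shared = tuple(sorted(shared))
    if fixed is None:
        fixed_list = [{} for _ in specs]
    elif isinstance(fixed, dict):
        fixed_list = [dict(fixed) for _ in specs]
    else:
        fixed_list = [dict(d) for d in fixed]
    for (model, table), fx in zip(specs, fixed_list):
        for name in fx:
            if name not in _relevant_names(model, table):
                raise ValueError(f"cannot fix unknown parameter {name!r}")
    pmap = _ParamMap(list(specs), fixed_list, shared)

    free_cells = sum(t.free_cells for _, t in specs)
    df = free_cells - pmap.n_free
    if df < 0:
        raise ValueError(
            f"model is over-saturated: {pmap.n_free} free parameters for "
            f"{free_cells} free cells"
        )

    f = _objective(pmap)
    rng = np.random.default_rng(seed)
    best = None
    best_start = -1
    converged = False
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(pmap.pack(init))
    attempts = 0
    while len(starts) < max(n_starts, 1) and attempts < 100 * max(n_starts, 1):
        attempts += 1
        x0 = _random_start(pmap, rng)
        if np.isfinite(f(x0)) and f(x0) < _PENALTY:
            starts.append(x0)
    for i, x0 in enumerate(starts):
        if not np.isfinite(f(x0)) or f(x0) >= _PENALTY:
            continue
        res = _minimise(f, x0, maxfev_per_dim)
        if best is None or res.fun < best.fun - 1e-12:
            best, best_start = res, i
            converged = bool(res.success and res.fun < _PENALTY)
    if best is None:
        raise RuntimeError("no admissible starting point found")

    params_list, _ = pmap.unpack(best.x)
    chi2 = float(best.fun)
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else float("nan")
    return FitResult(
        params=params_list,
        chi2=chi2,
        df=df,
        p=p,
        converged=converged,
        n_starts=len(starts),
        best_start=best_start,
        model=[m for m, _ in specs],
        fixed={i: fx for i, fx in enumerate(fixed_list) if fx},
        shared=shared,
    )


def fit_model(
    model: str,
    data: OutcomeTable,
    constraints: dict | None = None,
    n_starts: int = 10,
    seed: int = 0,
    init: SDTParams | None = None,
    maxfev_per_dim: int = 700,
) -> FitResult:
    """Fit one model to one outcome table by chi-square minimisation.

    ``constraints`` fixes named parameters, e.g. ``{'s_t': 1.0}`` for the
    equal-variance restriction.  Returns a :class:`FitResult`; a fit that
    never converged is flagged, not raised.
    """
    return joint_fit(
        [(model, data)],
        shared=(),
        fixed=constraints or {},
        n_starts=n_starts,
        seed=seed,
        init=None if init is None else [init],
        maxfev_per_dim=maxfev_per_dim,
    )


def lr_test(unconstrained: FitResult, constrained: FitResult):
    """Likelihood-ratio-type test from two nested chi-square fits.

    Returns ``(delta_chi2, delta_df, p)``.  A negative difference beyond
    optimiser tolerance indicates the 'unconstrained' fit found a worse
    local minimum and warrants a refit.
    """
    delta_df = constrained.df - unconstrained.df
    if delta_df < 1:
        raise ValueError("constrained model must have more degrees of freedom")
    delta = constrained.chi2 - unconstrained.chi2
    if delta < -1e-6:
        import warnings

        warnings.warn(
            "constrained fit beats the unconstrained fit; the unconstrained "
            "optimum is likely a local minimum — refit with more starts",
            RuntimeWarning,
            stacklevel=2,
        )
    delta = max(delta, 0.0)
    return delta, delta_df, float(chi2_dist.sf(delta, delta_df))
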