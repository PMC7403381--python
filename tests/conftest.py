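"""Shared fixtures: random model configurations and cell-level comparison
helpers used by the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
import pytest

from lineupsdt.types import LineupDesign, SDTParams

MODELS = ("max", "int", "seq", "ensemble")


def random_config(rng: np.random.Generator, model: str, n_range=(2, 7)):
    """A random admissible (params, design) pair for one model.

    Criteria for the integration rule are stretched onto the
    summed-familiarity scale.
    """
    k = int(rng.integers(1, 6))
    scale = 2.0 if model == "int" else 1.0
    c1 = rng.uniform(-0.5, 1.5) * scale
    crit = np.concatenate([[c1], c1 + np.cumsum(rng.uniform(0.1, 0.7, k - 1) * scale)])
    params = SDTParams(
        d_t=rng.uniform(0.0, 2.5),
        s_t=rng.uniform(0.7, 1.8),
        d_s=rng.uniform(0.0, 1.0),
        s_s=rng.uniform(0.7, 1.5),
        criteria=tuple(crit),
    )
    n = int(rng.integers(*n_range))
    has_suspect = bool(rng.integers(0, 2))
    design = LineupDesign(n=n, has_suspect=has_suspect)
    return params, design


def cell_z_scores(table, probs, n_tp, n_ta):
    """|observed/N - p| in units of the binomial standard error, per cell."""
    zs = []
    for o_cells, p_cells, n in (
        (table.tp_cells(), probs.tp_cells(), n_tp),
        (table.ta_cells(), probs.ta_cells(), n_ta),
    ):
        p = np.asarray(p_cells, dtype=float)
        o = np.asarray(o_cells, dtype=float) / n
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        zs.append(np.abs(o - p) / np.maximum(se, 1e-9))
    return np.concatenate(zs)


@pytest.fixture
def rng():
    return np.random.default_rng(20200804)
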