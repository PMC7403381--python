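"""Core domain types for lineup signal-detection modelling.

All familiarity values live on a standard-normal ("foil") scale: foils are
N(0, 1), the target is N(d_t, s_t) and an optional designated innocent
suspect is N(d_s, s_s).  Decision criteria are strictly increasing; the
lowest criterion separates identification from rejection and the higher
ones define confidence levels.  Confidence bins are stored in ascending
order internally: bin ``l`` (0-based) covers evidence in [c_{l+1}, c_{l+2})
and the last bin covers [c_k, inf).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SDTParams",
    "LineupDesign",
    "CategoryProbabilities",
    "OutcomeTable",
    "FitResult",
    "SimulatedDataset",
]

_TOL = 1e-9


@dataclass(frozen=True)
class SDTParams:
    """Gaussian familiarity-distribution parameters plus decision criteria.

    Parameters
    ----------
    d_t, s_t
        Mean and standard deviation of the target familiarity distribution.
    d_s, s_s
        Mean and standard deviation of the designated-suspect distribution
        (defaults make the suspect indistinguishable from a foil).
    criteria
        Ordered decision criteria ``c_1 < c_2 < ... < c_k`` (k >= 1).
    """

    d_t: float
    s_t: float = 1.0
    d_s: float = 0.0
    s_s: float = 1.0
    criteria: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(float(c) for c in self.criteria))
        if not np.isfinite([self.d_t, self.s_t, self.d_s, self.s_s]).all():
            raise ValueError("non-finite SDT parameters")
        if self.s_t <= 0 or self.s_s <= 0:
            raise ValueError("standard deviations must be positive")
        c = np.asarray(self.criteria, dtype=float)
        if c.size < 1:
            raise ValueError("at least one decision criterion is required")
        if not np.isfinite(c).all():
            raise ValueError("non-finite criterion")
        if c.size > 1 and not (np.diff(c) > 0).all():
            raise ValueError("criteria must be strictly increasing")

    @property
    def k(self) -> int:
        """Number of criteria (= number of confidence bins)."""
        return len(self.criteria)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["criteria"] = list(self.criteria)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SDTParams":
        return cls(
            d_t=float(d["d_t"]),
            s_t=float(d.get("s_t", 1.0)),
            d_s=float(d.get("d_s", 0.0)),
            s_s=float(d.get("s_s", 1.0)),
            criteria=tuple(d.get("criteria", (0.0,))),
        )


def _normalise_positions(p: Sequence[float] | None, n: int) -> tuple[float, ...]:
    if p is None:
        return tuple([1.0 / n] * n)
    arr = np.asarray(p, dtype=float)
    if arr.size != n:
        raise ValueError(f"position vector has length {arr.size}, expected {n}")
    if (arr < -_TOL).any():
        raise ValueError("position probabilities must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError("position probabilities must sum to 1")
    if abs(arr.sum() - 1.0) > 1e-12:
        arr = arr / arr.sum()
    return tuple(float(x) for x in arr)


@dataclass(frozen=True)
class LineupDesign:
    """Lineup structure: size, position distributions, suspect designation.

    ``p`` is the probability that the target sits at each position of a
    target-present lineup; ``q`` likewise for the designated innocent
    suspect on target-absent lineups (only used when ``has_suspect``).
    Position vectors matter only to the sequential (stopping-rule) model;
    the simultaneous models ignore them.
    """

    n: int
    p: tuple[float, ...] = None  # type: ignore[assignment]
    has_suspect: bool = False
    q: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("lineup size n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "p", _normalise_positions(self.p, self.n))
        object.__setattr__(self, "q", _normalise_positions(self.q, self.n))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p": list(self.p),
            "has_suspect": self.has_suspect,
            "q": list(self.q),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineupDesign":
        return cls(
            n=int(d["n"]),
            p=d.get("p"),
            has_suspect=bool(d.get("has_suspect", False)),
            q=d.get("q"),
        )


@dataclass
class CategoryProbabilities:
    """Model-predicted outcome probabilities for one parameter set.

    Vectors are indexed by confidence bin in ascending order (lowest
    confidence first).  On target-absent lineups ``ta_id`` is either the
    designated-suspect identification probability (``ta_mode='suspect'``,
    in which case ``ta_foil_id`` carries the foil identifications) or the
    any-foil identification probability (``ta_mode='any-foil'``).
    """

    tp_target_id: np.ndarray
    tp_foil_id: np.ndarray
    tp_reject: float
    ta_id: np.ndarray
    ta_reject: float
    ta_mode: str = "any-foil"
    ta_foil_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tp_target_id = np.asarray(self.tp_target_id, dtype=float)
        self.tp_foil_id = np.asarray(self.tp_foil_id, dtype=float)
        self.ta_id = np.asarray(self.ta_id, dtype=float)
        if self.ta_foil_id is not None:
            self.ta_foil_id = np.asarray(self.ta_foil_id, dtype=float)
        if self.ta_mode not in ("suspect", "any-foil"):
            raise ValueError("ta_mode must be 'suspect' or 'any-foil'")

    def tp_cells(self) -> np.ndarray:
        """Target-present multinomial cells: target bins, foil bins, reject."""
        return np.concatenate(
            [self.tp_target_id, self.tp_foil_id, [self.tp_reject]]
        )

    def ta_cells(self) -> np.ndarray:
        """Target-absent multinomial cells (layout depends on ta_mode)."""
        if self.ta_mode == "suspect":
            assert self.ta_foil_id is not None
            return np.concatenate([self.ta_id, self.ta_foil_id, [self.ta_reject]])
        return np.concatenate([self.ta_id, [self.ta_reject]])


@dataclass
class OutcomeTable:
    """Observed decision-outcome frequencies for one lineup condition pair.

    Counts are stored ascending by confidence (index 0 = lowest bin), the
    same layout as :class:`CategoryProbabilities`.  ``k = 1`` covers binary
    choose/no-choose studies.
    """

    k: int
    tp_target_id: np.ndarray
    tp_foil_id: np.ndarray
    tp_reject: int
    ta_id: np.ndarray
    ta_reject: int
    ta_mode: str = "any-foil"
    ta_foil_id: np.ndarray | None = None
    design: LineupDesign = field(default_factory=lambda: LineupDesign(n=6))

    def __post_init__(self) -> None:
        self.tp_target_id = np.asarray(self.tp_target_id, dtype=int)
        self.tp_foil_id = np.asarray(self.tp_foil_id, dtype=int)
        self.ta_id = np.asarray(self.ta_id, dtype=int)
        if self.ta_foil_id is not None:
            self.ta_foil_id = np.asarray(self.ta_foil_id, dtype=int)
        for arr in (self.tp_target_id, self.tp_foil_id, self.ta_id):
            if arr.size != self.k:
                raise ValueError("count vectors must have length k")
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        if self.tp_reject < 0 or self.ta_reject < 0:
            raise ValueError("counts must be non-negative")
        if self.ta_mode == "suspect" and self.ta_foil_id is None:
            raise ValueError("suspect mode requires ta_foil_id counts")

    @property
    def n_tp(self) -> int:
        return int(self.tp_target_id.sum() + self.tp_foil_id.sum() + self.tp_reject)

    @property
    def n_ta(self) -> int:
        extra = 0 if self.ta_foil_id is None else int(self.ta_foil_id.sum())
        return int(self.ta_id.sum() + extra + self.ta_reject)

    def tp_cells(self) -> np.ndarray:
        return np.concatenate([self.tp_target_id, self.tp_foil_id, [self.tp_reject]])

    def ta_cells(self) -> np.ndarray:
        if self.ta_mode == "suspect":
            assert self.ta_foil_id is not None
            return np.concatenate([self.ta_id, self.ta_foil_id, [self.ta_reject]])
        return np.concatenate([self.ta_id, [self.ta_reject]])

    @property
    def free_cells(self) -> int:
        """Free multinomial cells: (categories - 1) per condition.

        Show-up tables (n = 1) have no foils, so their structurally-empty
        TP foil cells do not count.
        """
        tp = self.tp_cells().size - (self.k if self.design.n == 1 else 0)
        return (tp - 1) + (self.ta_cells().size - 1)

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "tp_target_id": self.tp_target_id.tolist(),
            "tp_foil_id": self.tp_foil_id.tolist(),
            "tp_reject": int(self.tp_reject),
            "ta_id": self.ta_id.tolist(),
            "ta_reject": int(self.ta_reject),
            "ta_mode": self.ta_mode,
            "design": self.design.to_dict(),
        }
        if self.ta_foil_id is not None:
            d["ta_foil_id"] = self.ta_foil_id.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeTable":
        return cls(
            k=int(d["k"]),
            tp_target_id=d["tp_target_id"],
            tp_foil_id=d["tp_foil_id"],
            tp_reject=int(d["tp_reject"]),
            ta_id=d["ta_id"],
            ta_reject=int(d["ta_reject"]),
            ta_mode=d.get("ta_mode", "any-foil"),
            ta_foil_id=d.get("ta_foil_id"),
            design=LineupDesign.from_dict(d["design"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "OutcomeTable":
        return cls.from_dict(json.loads(s))


@dataclass
class FitResult:
    """Outcome of a chi-square minimisation.

    ``params`` holds one :class:`SDTParams` per fitted dataset (a single
    fit stores a length-1 list).  ``fixed`` and ``shared`` record the
    constraints active during the fit.
    """

    params: list[SDTParams]
    chi2: float
    df: int
    p: float
    converged: bool
    n_starts: int
    best_start: int
    model: list[str] = field(default_factory=list)
    fixed: dict = field(default_factory=dict)
    shared: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "params": [pp.to_dict() for pp in self.params],
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "best_start": self.best_start,
            "model": list(self.model),
            "fixed": dict(self.fixed),
            "shared": list(self.shared),
        }


@dataclass
class SimulatedDataset:
    """A simulated outcome table plus the provenance needed to redo it."""

    design: LineupDesign
    n_tp: int
    n_ta: int
    table: OutcomeTable
    seed: int
    model: str
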