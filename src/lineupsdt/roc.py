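"""ROC construction, AUC and diagnosticity ratios for lineup procedures.

An ROC point pairs the innocent-suspect identification rate (SID, x) with
the correct target identification rate (TID, y) at one level of response
bias.  Model-parametric curves sweep a decision criterion; empirical
curves cumulate observed counts from the highest confidence bin downward.
Because an n-item fair lineup caps the SID rate at 1/n, curves from
different procedures terminate at different points and are compared by
*partial* AUC over a common SID range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .types import LineupDesign, OutcomeTable, SDTParams

__all__ = ["ROCCurve", "model_roc", "empirical_roc", "auc", "diagnosticity_ratio"]

_ISO_RATIOS = (1.0, 1.5, 2.5, 5.0, 10.0)


@dataclass
class ROCCurve:
    """Ordered (sid_rate, tid_rate) operating points."""

    points: np.ndarray  # (m, 2) columns: sid, tid
    source: str = "model-parametric"
    terminal_sid: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if ((self.points < -1e-12) | (self.points > 1 + 1e-12)).any():
            raise ValueError("ROC rates must lie in [0, 1]")
        if self.terminal_sid is None:
            self.terminal_sid = float(self.points[:, 0].max(initial=0.0))

    @property
    def sid(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tid(self) -> np.ndarray:
        return self.points[:, 1]


def _cumulative_rates(model: str, params: SDTParams, design: LineupDesign, c):
    """(sid, tid) at confidence-criterion c, innocent-suspect convention.

    Fair lineups report the per-foil (any-foil / n) suspect rate.
    """
    c = np.asarray(c, dtype=float)
    n = design.n
    m = model.lower()
    if m in ("max", "evsd"):
        tid = models.max_ptid(c, params, n)
        sid = models.max_psid(c, params, design)
    elif m == "int":
        tid = models.int_ptid(c, params, n)
        sid = models.int_psid(c, params, design)
    elif m == "seq":
        tid = models.seq_ptid(c, params, design)
        sid = models.seq_psid(c, params, design)
    elif m == "ensemble":
        tid = models.ensemble_tid(c, params, n)
        sid = models.ensemble_ta_id(c, params, design)
        if not design.has_suspect:
            sid = np.asarray(sid) / n
    else:
        raise ValueError(f"unknown model {model!r}")
    return np.asarray(sid, float), np.asarray(tid, float)


def model_roc(
    model: str,
    params: SDTParams,
    design: LineupDesign,
    criterion_grid,
    sweep: str = "confidence",
) -> ROCCurve:
    """Model-implied ROC along a criterion grid.

    ``sweep='confidence'`` varies the confidence criterion with the choose
    criterion c_1 held at ``params.criteria[0]`` (grid values below c_1 are
    clipped up to it for the sequential model, whose confidence cannot be
    reported below the choose threshold).  ``sweep='bias'`` varies c_1
    itself — the between-participant manipulation, which for the
    sequential stopping rule traces a non-monotonic curve.
    """
    grid = np.sort(np.asarray(criterion_grid, dtype=float))
    pts = []
    m = model.lower()
    for c in grid:
        if sweep == "bias" or m in ("max", "evsd", "int", "ensemble"):
            pp = SDTParams(
                d_t=params.d_t, s_t=params.s_t, d_s=params.d_s, s_s=params.s_s,
                criteria=(c,),
            )
            sid, tid = _cumulative_rates(m, pp, design, c)
        else:  # sequential confidence sweep at fixed c_1
            c_eff = max(c, params.criteria[0])
            pp = SDTParams(
                d_t=params.d_t, s_t=params.s_t, d_s=params.d_s, s_s=params.s_s,
                criteria=(params.criteria[0],),
            )
            sid, tid = _cumulative_rates(m, pp, design, c_eff)
        pts.append((float(sid), float(tid)))
    source = "model-parametric" if sweep == "confidence" else "between-participant-bias"
    return ROCCurve(points=np.array(pts), source=source)


def empirical_roc(data: OutcomeTable) -> ROCCurve:
    """Observed ROC: cumulative rates from the highest confidence bin down.

    For fair (any-foil) target-absent lineups the innocent-suspect rate is
    estimated as the any-foil rate divided by the lineup size — the
    standard designated-innocent-suspect proxy.
    """
    if data.n_tp == 0 or data.n_ta == 0:
        raise ValueError("both conditions need at least one trial")
    tid = np.cumsum(data.tp_target_id[::-1]) / data.n_tp
    ta_counts = data.ta_id[::-1].astype(float)
    sid = np.cumsum(ta_counts) / data.n_ta
    if data.ta_mode == "any-foil":
        sid = sid / data.design.n
    return ROCCurve(points=np.column_stack([sid, tid]), source="empirical-confidence")


def auc(curve: ROCCurve, max_sid: float | None = None) -> float:
    """Trapezoidal area under the ROC, anchored at the origin.

    ``max_sid`` restricts the integral to SID rates up to that cutoff
    (partial AUC), the appropriate comparison when curves terminate at
    different false-positive ceilings.  Points are sorted by SID rate; a
    curve ending short of the cutoff is extended horizontally.
    """
    pts = curve.points
    if pts.shape[0] < 2 and max_sid is None:
        raise ValueError("need at least two points for an area")
    order = np.argsort(pts[:, 0], kind="stable")
    x, y = pts[order, 0], pts[order, 1]
    if x[0] > 0:
        x, y = np.insert(x, 0, 0.0), np.insert(y, 0, 0.0)
    if max_sid is not None:
        hi = float(max_sid)
        keep = x <= hi + 1e-12
        xk, yk = x[keep], y[keep]
        if xk[-1] < hi:
            inside = x <= hi
            if inside.all():
                xk, yk = np.append(xk, hi), np.append(yk, yk[-1])
            else:
                j = int(np.argmax(~inside))
                t = (hi - x[j - 1]) / (x[j] - x[j - 1])
                xk = np.append(xk, hi)
                yk = np.append(yk, y[j - 1] + t * (y[j] - y[j - 1]))
        x, y = xk, yk
    return float(np.trapezoid(y, x))


def diagnosticity_ratio(tid_rate: float, sid_rate: float) -> float:
    """TID rate over SID rate — a response-bias-dependent index.

    Returns ``inf`` when the SID rate is zero (no false identifications).
    """
    if sid_rate < 0 or tid_rate < 0:
        raise ValueError("rates must be non-negative")
    if sid_rate == 0:
        return float("inf")
    return float(tid_rate) / float(sid_rate)


def iso_diagnosticity_lines(ratios=_ISO_RATIOS, max_sid: float = 1.0):
    """Reference lines tid = ratio * sid for overlaying on ROC plots."""
    out = {}
    for r in ratios:
        hi = min(max_sid, 1.0 / r)
        out[r] = np.array([[0.0, 0.0], [hi, r * hi]])
    return out
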