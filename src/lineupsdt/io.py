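"""Readers and writers for outcome tables, raw responses and results.

Outcome tables travel as comma-separated text with a JSON header block in
comment lines (design and TA mode), one row per cell::

    # design: {"n": 6, "p": [...], "has_suspect": false, "q": [...]}
    # ta_mode: any-foil
    condition,outcome,bin,count
    TP,target,1,11
    ...
    TA,reject,,61

Bins are numbered ascending (1 = lowest confidence).  Raw response
records use plain columns (condition, outcome, confidence) and are binned
into outcome tables with pooled even-as-possible frequency quantiles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LineupDesign, OutcomeTable

__all__ = [
    "read_outcome_table",
    "write_outcome_table",
    "bin_confidence",
    "pooled_bin_edges",
]


def write_outcome_table(table: OutcomeTable, path) -> None:
    """Serialise an OutcomeTable to delimited text (lossless round trip)."""
    rows = []
    for b in range(table.k):
        rows.append(("TP", "target", b + 1, int(table.tp_target_id[b])))
    for b in range(table.k):
        rows.append(("TP", "foil", b + 1, int(table.tp_foil_id[b])))
    rows.append(("TP", "reject", "", int(table.tp_reject)))
    ta_label = "suspect" if table.ta_mode == "suspect" else "foil"
    for b in range(table.k):
        rows.append(("TA", ta_label, b + 1, int(table.ta_id[b])))
    if table.ta_mode == "suspect":
        for b in range(table.k):
            rows.append(("TA", "foil", b + 1, int(table.ta_foil_id[b])))
    rows.append(("TA", "reject", "", int(table.ta_reject)))
    df = pd.DataFrame(rows, columns=["condition", "outcome", "bin", "count"])
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# design: {json.dumps(table.design.to_dict())}\n")
        fh.write(f"# ta_mode: {table.ta_mode}\n")
        df.to_csv(fh, index=False)


def read_outcome_table(path) -> OutcomeTable:
    """Parse an outcome table written by :func:`write_outcome_table`."""
    path = Path(path)
    design = None
    ta_mode = "any-foil"
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "design":
                design = LineupDesign.from_dict(json.loads(val))
            elif key.strip() == "ta_mode":
                ta_mode = val.strip()
    if design is None:
        raise ValueError(f"{path}: missing '# design:' header line")
    if ta_mode not in ("suspect", "any-foil"):
        raise ValueError(f"{path}: bad ta_mode {ta_mode!r}")

    df = pd.read_csv(path, comment="#")
    required = {"condition", "outcome", "bin", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must name columns {sorted(required)}")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")

    binned = df[df["outcome"] != "reject"]
    k = int(binned["bin"].astype(float).max())

    def cells(cond, outcome):
        sel = df[(df.condition == cond) & (df.outcome == outcome) & (df.outcome != "reject")]
        out = np.zeros(k, dtype=int)
        seen = set()
        for _, row in sel.iterrows():
            b = int(float(row["bin"]))
            if not 1 <= b <= k:
                raise ValueError(f"{path}: bin {b} out of range 1..{k}")
            if b in seen:
                raise ValueError(f"{path}: duplicate bin {b} for {cond}/{outcome}")
            seen.add(b)
            out[b - 1] = int(row["count"])
        return out

    def reject(cond):
        sel = df[(df.condition == cond) & (df.outcome == "reject")]
        return int(sel["count"].sum())

    ta_label = "suspect" if ta_mode == "suspect" else "foil"
    return OutcomeTable(
        k=k,
        tp_target_id=cells("TP", "target"),
        tp_foil_id=cells("TP", "foil"),
        tp_reject=reject("TP"),
        ta_id=cells("TA", ta_label),
        ta_reject=reject("TA"),
        ta_mode=ta_mode,
        ta_foil_id=cells("TA", "foil") if ta_mode == "suspect" else None,
        design=design,
    )


def pooled_bin_edges(confidences, n_bins: int) -> np.ndarray:
    """Upper bin edges giving even-as-possible frequency bins.

    Edges are the pooled l/n_bins quantiles (l = 1..n_bins) of the
    observed confidence values; a value v belongs to the first bin whose
    upper edge is >= v.
    """
    conf = np.asarray(confidences, dtype=float)
    if conf.size == 0:
        raise ValueError("no confidence values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > np.unique(conf).size:
        raise ValueError("more bins than distinct confidence values")
    qs = np.quantile(conf, np.arange(1, n_bins + 1) / n_bins, method="inverted_cdf")
    edges = np.unique(qs)
    if edges.size != n_bins:
        raise ValueError("confidence distribution too lumpy for that many bins")
    return edges


def bin_confidence(records: pd.DataFrame, n_bins: int, design: LineupDesign) -> OutcomeTable:
    """Tabulate raw response records into a confidence-binned OutcomeTable.

    ``records`` needs columns ``condition`` (TP/TA), ``outcome``
    (target-id / foil-id / reject) and ``confidence`` (0-100).  Bin edges
    come from the confidence values of *identifications* pooled over both
    conditions, partitioned into even-as-possible frequency bins.
    """
    rec = pd.DataFrame(records)
    for col in ("condition", "outcome", "confidence"):
        if col not in rec.columns:
            raise ValueError(f"records need a {col!r} column")
    if ((rec.confidence < 0) | (rec.confidence > 100)).any():
        raise ValueError("confidence must lie in [0, 100]")
    if ((rec.condition == "TA") & (rec.outcome == "target-id")).any():
        raise ValueError("target identifications cannot occur on TA lineups")

    ids = rec[rec.outcome != "reject"]
    edges = pooled_bin_edges(ids.confidence.to_numpy(), n_bins)

    def tab(cond, outcome):
        sel = ids[(ids.condition == cond) & (ids.outcome == outcome)]
        bins = np.searchsorted(edges, sel.confidence.to_numpy(), side="left")
        return np.bincount(bins, minlength=n_bins)[:n_bins]

    return OutcomeTable(
        k=n_bins,
        tp_target_id=tab("TP", "target-id"),
        tp_foil_id=tab("TP", "foil-id"),
        tp_reject=int(((rec.condition == "TP") & (rec.outcome == "reject")).sum()),
        ta_id=tab("TA", "foil-id"),
        ta_reject=int(((rec.condition == "TA") & (rec.outcome == "reject")).sum()),
        ta_mode="any-foil",
        design=design,
    )
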