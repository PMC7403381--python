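"""Packaged outcome-frequency tables from the lineup experiment.

Four tables are provided, all from the same 589-participant experiment
comparing a 6-item simultaneous lineup with a 6-item stopping-rule
sequential lineup (target position randomised, no designated innocent
suspect, confidence reported on a 0-100 scale and partitioned into
pooled frequency quintiles):

* ``exp1_simultaneous`` / ``exp1_sequential`` — decision outcomes by
  confidence quintile (TP N = 139 / 161, TA N = 141 / 148).
* ``table7_showup`` — sequential serial position 1 reclassified as a
  show up (identify/reject only; TP1 N = 28, TA1 N = 281).
* ``table7_simultaneous_collapsed`` — the simultaneous condition
  collapsed over confidence.

Counts are stored ascending by confidence (lowest bin first); the
published tables print them highest-confidence-first.
"""

from __future__ import annotations

from .types import LineupDesign, OutcomeTable

__all__ = [
    "exp1_simultaneous",
    "exp1_sequential",
    "table7_showup",
    "table7_simultaneous_collapsed",
    "confidence_bin_edges",
    "FIXTURES",
]

# pooled frequency-quintile bin edges on the 0-100 confidence scale,
# ascending to match the internal bin order
_BIN_EDGES = ((0, 50), (51, 65), (66, 80), (81, 90), (91, 100))


def confidence_bin_edges() -> tuple[tuple[int, int], ...]:
    """Ascending (low, high) confidence-bin edges used by the experiment."""
    return _BIN_EDGES


def exp1_simultaneous() -> OutcomeTable:
    """Simultaneous-lineup outcome frequencies by confidence quintile."""
    return OutcomeTable(
        k=5,
        # printed highest-first: target 24,25,30,9,11; foil 0,1,5,4,11
        tp_target_id=[11, 9, 30, 25, 24],
        tp_foil_id=[11, 4, 5, 1, 0],
        tp_reject=19,
        ta_id=[24, 16, 25, 11, 4],  # printed 4,11,25,16,24
        ta_reject=61,
        ta_mode="any-foil",
        design=LineupDesign(n=6),
    )


def exp1_sequential() -> OutcomeTable:
    """Sequential-lineup outcome frequencies by confidence quintile."""
    return OutcomeTable(
        k=5,
        # printed highest-first: target 32,22,21,13,6; foil 0,3,7,9,7
        tp_target_id=[6, 13, 21, 22, 32],
        tp_foil_id=[7, 9, 7, 3, 0],
        tp_reject=41,
        ta_id=[14, 11, 31, 5, 3],  # printed 3,5,31,11,14
        ta_reject=84,
        ta_mode="any-foil",
        design=LineupDesign(n=6),  # uniform target position (randomised)
    )


def table7_showup() -> OutcomeTable:
    """Sequential serial position 1 treated as a show up (binary outcome).

    A TP1 trial is one whose first sequential item was the target; a TA1
    trial is one whose first item was a foil (including TP lineups whose
    target sat later).
    """
    return OutcomeTable(
        k=1,
        tp_target_id=[15],
        tp_foil_id=[0],
        tp_reject=13,
        ta_id=[19],
        ta_reject=262,
        ta_mode="any-foil",
        design=LineupDesign(n=1),
    )


def table7_simultaneous_collapsed() -> OutcomeTable:
    """The simultaneous condition collapsed over confidence (k = 1)."""
    return OutcomeTable(
        k=1,
        tp_target_id=[99],
        tp_foil_id=[21],
        tp_reject=19,
        ta_id=[80],
        ta_reject=61,
        ta_mode="any-foil",
        design=LineupDesign(n=6),
    )


FIXTURES = {
    "exp1_simultaneous": exp1_simultaneous,
    "exp1_sequential": exp1_sequential,
    "table7_showup": table7_showup,
    "table7_simultaneous_collapsed": table7_simultaneous_collapsed,
}
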