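"""Cross-line expression patterns and the Relative Fold Change statistic.

A transcript differentially expressed in both the heat-sensitive (HS)
and heat-tolerant (HT) lines is either *concordant* (same direction in
both) or *discordant* (opposite directions).  The Relative Fold Change
(RFC) quantifies how differently the two lines respond, via a
three-case dispatch on the fold-change magnitudes a = |HT log2 FC| and
b = |HS log2 FC|:

    formula A (concordant, a > b):   RFC = (a - b) / b
    formula B (concordant, a < b):   RFC = (b - a) / a
    formula C (discordant):          RFC = (a + b) / 2

Concordant transcripts with equal magnitudes get RFC = 0 (labelled B by
convention).  All three formulas operate on magnitudes: with signed
values a discordant (+3, -2) pair would score 0.5 under C and could
never clear the selection threshold, whereas on magnitudes the three
cases rank "how unequal (or opposite) are the responses" consistently.
Transcripts with RFC >= 2.0 are the cross-line high night temperature
response transcripts (HTRTs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from ricehnt.expression import DEResult

Pattern = Literal[
    "up_both",
    "down_both",
    "upT_downS",
    "downT_upS",
    "HS_only_up",
    "HS_only_down",
    "HT_only_up",
    "HT_only_down",
    "neither",
]

#: The nine cross-line classes, tally order.
PATTERNS: tuple[str, ...] = (
    "up_both",
    "down_both",
    "upT_downS",
    "downT_upS",
    "HS_only_up",
    "HS_only_down",
    "HT_only_up",
    "HT_only_down",
    "neither",
)

# (dir_HS, dir_HT) -> pattern; naming: T = heat-tolerant, S = heat-sensitive
_PATTERN_MAP: dict[tuple[str, str], str] = {
    ("up", "up"): "up_both",
    ("down", "down"): "down_both",
    ("down", "up"): "upT_downS",
    ("up", "down"): "downT_upS",
    ("up", "none"): "HS_only_up",
    ("down", "none"): "HS_only_down",
    ("none", "up"): "HT_only_up",
    ("none", "down"): "HT_only_down",
    ("none", "none"): "neither",
}


@dataclass
class PatternRecord:
    transcript_id: str
    dir_HS: str
    dir_HT: str
    pattern: str


@dataclass
class RFCRecord:
    transcript_id: str
    hs_log2: float
    ht_log2: float
    pattern: str
    formula: Literal["A", "B", "C"]
    rfc: float
    selected: bool


def classify_pattern(de_hs: DEResult, de_ht: DEResult) -> PatternRecord:
    """Map a transcript's per-line DE directions to one of nine classes.

    Both results must refer to the same transcript; ``de_hs`` is the
    heat-sensitive call, ``de_ht`` the heat-tolerant one.
    """
    if de_hs.transcript_id != de_ht.transcript_id:
        raise ValueError(
            f"transcript mismatch: {de_hs.transcript_id!r} vs {de_ht.transcript_id!r}"
        )
    key = (de_hs.direction, de_ht.direction)
    if key not in _PATTERN_MAP:
        raise ValueError(f"unrecognised direction pair {key}")
    return PatternRecord(de_hs.transcript_id, de_hs.direction, de_ht.direction, _PATTERN_MAP[key])


def rfc_value(hs_log2: float, ht_log2: float, concordant: bool) -> tuple[str, float]:
    """Relative Fold Change of one transcript from its two log2 fold changes.

    Returns ``(formula, rfc)`` where formula is ``"A"``, ``"B"`` or
    ``"C"``.  Magnitudes are taken internally, so callers may pass
    signed log2 fold changes.
    """
    a = abs(ht_log2)
    b = abs(hs_log2)
    if not concordant:
        return "C", (a + b) / 2.0
    if a == 0.0 or b == 0.0:
        raise ValueError("concordant RFC requires non-zero log2 fold changes in both lines")
    if a > b:
        return "A", (a - b) / b
    if a < b:
        return "B", (b - a) / a
    return "B", 0.0


def select_htrts(
    de_hs: Iterable[DEResult],
    de_ht: Iterable[DEResult],
    threshold: float = 2.0,
    candidates: Literal["intersection", "union"] = "intersection",
) -> list[RFCRecord]:
    """Score candidate transcripts by RFC and flag those at or above threshold.

    The default candidate set is the intersection of the two lines'
    significant transcripts (the cross-line overlap classes are defined
    on transcripts regulated in both lines); ``candidates="union"``
    scores every transcript significant in at least one line, using the
    other line's sub-threshold log2 fold change.  Concordance is the
    sign agreement of the two log2 fold changes; a zero on either side
    counts as discordant (no shared direction).  Output is sorted by
    transcript id.
    """
    hs_by_id = {r.transcript_id: r for r in de_hs}
    ht_by_id = {r.transcript_id: r for r in de_ht}
    shared = set(hs_by_id) & set(ht_by_id)
    if candidates == "intersection":
        cand = {t for t in shared if hs_by_id[t].significant and ht_by_id[t].significant}
    elif candidates == "union":
        cand = {t for t in shared if hs_by_id[t].significant or ht_by_id[t].significant}
    else:
        raise ValueError("candidates must be 'intersection' or 'union'")

    records: list[RFCRecord] = []
    for tid in sorted(cand):
        hs, ht = hs_by_id[tid], ht_by_id[tid]
        concordant = hs.log2fc * ht.log2fc > 0
        formula, rfc = rfc_value(hs.log2fc, ht.log2fc, concordant)
        pattern = classify_pattern(hs, ht).pattern
        records.append(
            RFCRecord(
                transcript_id=tid,
                hs_log2=hs.log2fc,
                ht_log2=ht.log2fc,
                pattern=pattern,
                formula=formula,
                rfc=rfc,
                selected=rfc >= threshold,
            )
        )
    return records


def tally_patterns(records: Iterable[PatternRecord | RFCRecord | str]) -> dict[str, int]:
    """Count records per cross-line class (all nine classes, zeros kept)."""
    tally = {p: 0 for p in PATTERNS}
    for rec in records:
        pattern = rec if isinstance(rec, str) else rec.pattern
        if pattern not in tally:
            raise ValueError(f"unknown pattern class {pattern!r}")
        tally[pattern] += 1
    return tally


def rfc_frame(records: list[RFCRecord]) -> pd.DataFrame:
    """Tabulate RFC records (4-dp floats, transcript order) for TSV output."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "hs_log2": [round(r.hs_log2, 4) for r in records],
            "ht_log2": [round(r.ht_log2, 4) for r in records],
            "pattern": [r.pattern for r in records],
            "formula": [r.formula for r in records],
            "rfc": [round(r.rfc, 4) for r in records],
            "selected": [int(r.selected) for r in records],
        }
    )


def tally_frame(tally: Mapping[str, int]) -> pd.DataFrame:
    return pd.DataFrame({"pattern": list(tally), "count": list(tally.values())})
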