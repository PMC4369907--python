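"""Read quality filtering and per-sample QC tallies.

A read is discarded when, after optional adapter trimming, it is empty,
its N fraction is strictly over 5%, or strictly more than 20% of its
bases have a Phred quality below 20.  Both fraction rules are strict
inequalities ("over" / "more than"), so a 100-bp read with exactly five
Ns survives the N rule.  Qualities are Phred+33 by default (HiSeq 2000
CASAVA >= 1.8); a Phred+64 offset is configurable.  Paired-end policy:
a pair is kept only if both mates pass, keeping the two FASTQ files in
sync.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from ricehnt.design import round_half_up
from ricehnt.simulate import ReadRecord

Reason = Literal["adapter_empty", "n_fraction", "lowq_fraction"]
DISCARD_REASONS: tuple[str, ...] = ("adapter_empty", "n_fraction", "lowq_fraction")


@dataclass
class QCThresholds:
    """Filtering thresholds; defaults are the study rules."""

    max_n_fraction: float = 0.05
    lowq_q_cutoff: int = 20
    max_lowq_fraction: float = 0.20
    adapter: Optional[str] = None
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_n_fraction <= 1.0 and 0.0 <= self.max_lowq_fraction <= 1.0):
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if self.lowq_q_cutoff < 0:
            raise ValueError("quality cutoff must be >= 0")
        if self.phred_offset not in (33, 64):
            raise ValueError("phred_offset must be 33 or 64")


@dataclass
class QCSummary:
    """Per-sample filtering tallies in the read-statistics table layout."""

    sample_id: str
    raw_reads: int
    high_quality_reads: int
    hq_percent: float
    discard_reasons: dict[str, int] = field(default_factory=dict)


def q_from_char(c: str, offset: int = 33) -> int:
    """Decode one quality character to its Phred score (default Phred+33)."""
    if len(c) != 1:
        raise ValueError("q_from_char expects a single character")
    if c < "!":
        raise ValueError(f"quality character {c!r} below '!' is not printable FASTQ")
    return ord(c) - offset


def trim_adapter(read: ReadRecord, adapter: str) -> ReadRecord:
    """Clip from the first exact adapter occurrence to the read end."""
    pos = read.sequence.find(adapter)
    if pos < 0:
        return read
    return ReadRecord(read.read_id, read.sequence[:pos], read.quality[:pos], read.mate)


def filter_read(read: ReadRecord, t: QCThresholds) -> tuple[str, Optional[str]]:
    """Apply the filtering rules to one read.

    Returns ``("keep", None)`` or ``("discard", reason)`` with reason in
    ``adapter_empty`` (empty after trimming), ``n_fraction`` or
    ``lowq_fraction``.  Rule order: trim -> empty -> N rule -> quality
    rule.
    """
    if len(read.sequence) != len(read.quality):
        raise ValueError(f"{read.read_id}: sequence/quality length mismatch")
    if t.adapter:
        read = trim_adapter(read, t.adapter)
    n_bases = len(read.sequence)
    if n_bases == 0:
        return "discard", "adapter_empty"
    if read.sequence.count("N") / n_bases > t.max_n_fraction:
        return "discard", "n_fraction"
    lowq = sum(1 for c in read.quality if ord(c) - t.phred_offset < t.lowq_q_cutoff)
    if lowq / n_bases > t.max_lowq_fraction:
        return "discard", "lowq_fraction"
    return "keep", None


def filter_pair(r1: ReadRecord, r2: ReadRecord, t: QCThresholds) -> bool:
    """True iff both mates of a pair pass the filter."""
    if _stem(r1.read_id) != _stem(r2.read_id):
        raise ValueError(f"mate mismatch: {r1.read_id!r} vs {r2.read_id!r}")
    return filter_read(r1, t)[0] == "keep" and filter_read(r2, t)[0] == "keep"


def _stem(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def qc_summarize(decisions: Iterable[tuple[str, Optional[str]]], sample_id: str) -> QCSummary:
    """Tally keep/discard decisions into a per-sample summary row.

    ``hq_percent`` is recomputed from the tallies at 2 decimals
    (half-up), matching the printed-table convention.
    """
    reasons = {r: 0 for r in DISCARD_REASONS}
    raw = kept = 0
    for decision, reason in decisions:
        raw += 1
        if decision == "keep":
            kept += 1
        elif decision == "discard":
            if reason not in reasons:
                raise ValueError(f"unknown discard reason {reason!r}")
            reasons[reason] += 1
        else:
            raise ValueError(f"unknown decision {decision!r}")
    if raw == 0:
        raise ValueError("qc_summarize requires at least one read")
    return QCSummary(
        sample_id=sample_id,
        raw_reads=raw,
        high_quality_reads=kept,
        hq_percent=round_half_up(100.0 * kept / raw, 2),
        discard_reasons=reasons,
    )
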