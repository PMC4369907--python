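"""Descriptive statistics: read/mapping totals, region tallies, assembly N50.

These reproduce the arithmetic behind the per-sample summary tables of
an RNA-seq experiment report: column totals with percentages recomputed
from the summed numerators and denominators (never averaged across
samples), genic/intergenic position tallies, and assembly statistics
(mean length, N50, known/novel transcript split).

Rounding convention throughout: half away from zero, 2 decimals for
percentages and 1 decimal for the average transcript size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ricehnt.design import percent, round_half_up

REGION_CATEGORIES: tuple[str, ...] = ("exon", "intron", "intergenic", "spliced")


@dataclass
class AssemblySummary:
    n_transcripts: int
    average_size: float
    n50: int
    known_count: int
    known_pct: float
    known_genes: int
    novel_count: int
    novel_pct: float
    novel_genes: int


@dataclass
class RegionTally:
    total_positions: int
    counts: dict[str, int]
    percents: dict[str, float]


def n50(lengths: Sequence[int]) -> int:
    """Largest length L such that transcripts of length >= L hold at least
    half of all assembled bases.

    Computed by sorting descending and accumulating until the running
    total reaches half the grand total.
    """
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    if (arr <= 0).any():
        raise ValueError("all lengths must be positive")
    half = arr.sum() / 2.0
    cumulative = np.cumsum(arr)
    return int(arr[np.searchsorted(cumulative, half)])


def assembly_summary(
    lengths: Sequence[int],
    known_flags: Sequence[bool],
    gene_ids: Sequence[str],
) -> AssemblySummary:
    """Summarise an assembly: size statistics and the known/novel split.

    ``known_flags[i]`` marks transcript i as matching an annotated gene;
    gene counts are distinct ``gene_ids`` within each class.
    """
    if not (len(lengths) == len(known_flags) == len(gene_ids)):
        raise ValueError("lengths, known_flags and gene_ids must be aligned")
    n = len(lengths)
    if n == 0:
        raise ValueError("assembly_summary requires at least one transcript")
    known = np.asarray(known_flags, dtype=bool)
    genes = np.asarray(gene_ids)
    known_count = int(known.sum())
    novel_count = n - known_count
    return AssemblySummary(
        n_transcripts=n,
        average_size=round_half_up(float(np.mean(lengths)), 1),
        n50=n50(lengths),
        known_count=known_count,
        known_pct=percent(known_count, n),
        known_genes=int(pd.unique(genes[known]).size),
        novel_count=novel_count,
        novel_pct=percent(novel_count, n),
        novel_genes=int(pd.unique(genes[~known]).size),
    )


def aggregate_read_stats(stats: pd.DataFrame) -> dict[str, float]:
    """Totals row for a per-sample read-statistics table.

    ``stats`` needs columns ``raw_reads``, ``hq_reads`` and
    ``mapped_reads`` (one row per sample).  Percentages are recomputed
    from the summed counts: high-quality % against raw reads, mapping %
    against high-quality reads.
    """
    required = {"raw_reads", "hq_reads", "mapped_reads"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(stats) == 0:
        raise ValueError("aggregate_read_stats requires at least one sample")
    raw = int(stats["raw_reads"].sum())
    hq = int(stats["hq_reads"].sum())
    mapped = int(stats["mapped_reads"].sum())
    return {
        "raw_reads": raw,
        "hq_reads": hq,
        "hq_percent": percent(hq, raw),
        "mapped_reads": mapped,
        "mapped_percent": percent(mapped, hq),
    }


def region_tally(positions: Mapping[str, int] | Iterable[str]) -> RegionTally:
    """Tally mapped positions by genomic region category.

    Accepts either a mapping ``category -> count`` or an iterable of
    per-position category labels over {exon, intron, intergenic,
    spliced}; percentages are of the grand total at 2 decimals.
    """
    if isinstance(positions, Mapping):
        counts = {k: int(v) for k, v in positions.items()}
    else:
        counts = dict(Counter(positions))
    unknown = set(counts) - set(REGION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown region categories: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("region counts must be non-negative")
    full = {cat: counts.get(cat, 0) for cat in REGION_CATEGORIES}
    total = sum(full.values())
    if total == 0:
        raise ValueError("region_tally requires at least one mapped position")
    percents = {cat: percent(v, total) for cat, v in full.items()}
    return RegionTally(total_positions=total, counts=full, percents=percents)
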