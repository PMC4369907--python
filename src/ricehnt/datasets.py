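"""Published per-sample summary statistics of the rice high night
temperature study (2 lines x treatment/control x 3 biological replicates).

These are the per-sample sequencing, mapping, region and assembly
tallies of the original 12-library experiment (HiSeq 2000, 2 x 101 bp;
heat-sensitive line XN0437S, heat-tolerant line XN0437T), together with
the per-line differential-expression direction counts and the cross-line
HTRT pattern counts.  They serve as fixed inputs for the table
arithmetic in :mod:`ricehnt.summaries` and :func:`ricehnt.cross_line.tally_patterns`;
totals and percentages are deliberately NOT stored — they are recomputed.
"""

from __future__ import annotations

import pandas as pd

# sample, raw read count, high-quality read count, genome-mapped read count
_READ_STATS = [
    ("SC1", 110_445_132, 102_110_944, 81_760_543),
    ("SC2", 118_361_874, 109_714_376, 87_250_440),
    ("SC3", 108_124_090, 99_783_462, 79_232_619),
    ("ST1", 122_256_502, 114_109_402, 88_945_294),
    ("ST2", 109_367_326, 102_743_400, 80_030_194),
    ("ST3", 106_564_594, 99_517_680, 77_090_356),
    ("TC1", 108_790_978, 102_039_304, 79_933_511),
    ("TC2", 105_514_112, 99_385_790, 80_911_686),
    ("TC3", 102_595_286, 96_561_142, 76_501_404),
    ("TT1", 117_028_020, 108_822_936, 84_948_725),
    ("TT2", 117_708_038, 109_660_302, 85_938_332),
    ("TT3", 114_845_464, 106_774_882, 83_835_866),
]

# sample, mapped positions in exon / intron / intergenic / spliced regions
_REGION_STATS = [
    ("SC1", 92_309_005, 860_430, 4_794_472, 22_640_310),
    ("SC2", 84_173_841, 1_248_829, 5_752_705, 29_313_902),
    ("SC3", 83_651_248, 1_110_422, 7_031_767, 23_246_057),
    ("ST1", 131_590_789, 1_479_338, 21_420_452, 37_464_213),
    ("ST2", 84_829_641, 1_075_848, 11_366_864, 24_377_618),
    ("ST3", 76_909_155, 1_401_805, 9_872_787, 23_937_350),
    ("TC1", 84_405_467, 1_029_079, 14_506_377, 24_313_109),
    ("TC2", 85_954_481, 510_469, 4_602_925, 19_033_092),
    ("TC3", 73_161_750, 1_069_136, 6_573_728, 24_894_367),
    ("TT1", 76_581_286, 1_747_207, 6_621_542, 28_822_010),
    ("TT2", 100_277_333, 1_518_413, 15_045_184, 30_589_258),
    ("TT3", 75_782_160, 1_472_869, 6_061_655, 27_041_871),
]

# sample, n transcripts, known transcripts, known genes, novel transcripts, novel genes
_ASSEMBLY_STATS = [
    ("SC1", 35_975, 33_235, 21_914, 2_740, 2_194),
    ("SC2", 39_333, 36_022, 23_528, 3_311, 2_663),
    ("SC3", 38_489, 35_178, 22_720, 3_311, 2_641),
    ("ST1", 40_989, 37_256, 23_998, 3_733, 2_987),
    ("ST2", 40_125, 36_540, 23_780, 3_585, 2_837),
    ("ST3", 40_972, 37_026, 23_759, 3_946, 3_191),
    ("TC1", 38_268, 35_268, 23_205, 3_000, 2_398),
    ("TC2", 35_272, 32_639, 22_862, 2_633, 2_179),
    ("TC3", 38_507, 35_518, 23_539, 2_989, 2_397),
    ("TT1", 42_377, 38_090, 24_419, 4_287, 3_458),
    ("TT2", 40_585, 36_939, 23_603, 3_646, 2_896),
    ("TT3", 41_515, 37_273, 24_214, 4_242, 3_443),
]

#: Per-line DEG direction counts at p <= 0.05 and |log2 FC| >= 1.
DEG_DIRECTION_COUNTS = {
    "HS": {"up": 3_226, "down": 2_158},
    "HT": {"up": 2_755, "down": 2_772},
}

#: Cross-line overlap of the two DEG sets (all transcripts regulated in both lines).
DEG_OVERLAP_COUNTS = {
    "up_both": 843,
    "down_both": 769,
    "downT_upS": 33,  # up in sensitive, down in tolerant
    "upT_downS": 16,  # down in sensitive, up in tolerant
}

#: Pattern counts of the 35 cross-line HTRTs selected at RFC >= 2.0.
HTRT_PATTERN_COUNTS = {
    "up_both": 19,
    "down_both": 4,
    "upT_downS": 4,
    "downT_upS": 8,
}


def read_stats() -> pd.DataFrame:
    """Per-sample raw / high-quality / mapped read counts."""
    return pd.DataFrame(
        _READ_STATS, columns=["sample", "raw_reads", "hq_reads", "mapped_reads"]
    )


def region_stats() -> pd.DataFrame:
    """Per-sample mapped-position counts by genomic region."""
    return pd.DataFrame(
        _REGION_STATS, columns=["sample", "exon", "intron", "intergenic", "spliced"]
    )


def assembly_stats() -> pd.DataFrame:
    """Per-sample assembled-transcript counts, known/novel split."""
    return pd.DataFrame(
        _ASSEMBLY_STATS,
        columns=[
            "sample",
            "n_transcripts",
            "known_transcripts",
            "known_genes",
            "novel_transcripts",
            "novel_genes",
        ],
    )
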