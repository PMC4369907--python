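"""Synthetic inputs with planted ground truth for the whole pipeline.

Three generators emulate the study's raw materials:

* :func:`simulate_experiment` — a fragment-count matrix for the
  12-sample design (2 lines x treatment/control x 3 biological
  replicates), with transcripts planted in four cross-line classes:

  ``null``                  no response in either line;
  ``concordant_equal``      same direction and equal |log2 FC| in both lines;
  ``concordant_divergent``  same direction, different |log2 FC|;
  ``discordant``            opposite directions in the two lines.

  Counts are negative binomial around per-transcript baselines shifted
  by the planted signed log2 effects.

* :func:`simulate_reads` — paired-end reads with a controllable
  N-base rate and low-quality-base rate, each read labelled with
  whether it should survive the QC rules (the label is computed by
  direct arithmetic on the generated bases, independent of the QC
  module).

* :func:`simulate_ct` — qPCR cycle-threshold tables under ideal
  amplification efficiency: the target gene's treatment Ct shifts by
  minus the planted log2 effect (one cycle per doubling), the
  reference gene stays flat, and Gaussian noise models technical
  replicate scatter.

All generators are deterministic given their seed; independent numpy
``SeedSequence`` streams keyed by generator name keep the stages
decoupled, so adding draws to one generator does not shift another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ricehnt import design
from ricehnt.cross_line import rfc_value
from ricehnt.expression import CountMatrix

#: Canonical order in which transcript classes are allocated.
CLASSES = ("concordant_equal", "concordant_divergent", "discordant", "null")

_STREAMS = {"experiment": 0, "reads": 1, "ct": 2}

# Spread of per-transcript baseline abundance on the natural-log scale.
# RNA-seq baselines span orders of magnitude; 0.8 gives a ~5-fold
# interquartile range while keeping planted effects recoverable.
_BASELINE_LOG_SD = 0.8


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """Configuration of the synthetic count-matrix experiment.

    ``class_proportions`` must sum to 1; transcripts are allocated
    ``floor(p * n_transcripts)`` per class with the remainder assigned
    to the null class.  ``effect_log2`` maps each responding class to
    the planted (|log2 FC| in HS, |log2 FC| in HT) magnitude pair; signs
    are drawn per transcript, equal across lines for concordant classes
    and opposite for the discordant class.
    """

    n_transcripts: int = 2000
    n_reps: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.85,
            "concordant_equal": 0.05,
            "concordant_divergent": 0.05,
            "discordant": 0.05,
        }
    )
    base_mean: float = 500.0
    dispersion: float = 0.05
    effect_log2: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "concordant_equal": (1.5, 1.5),
            "concordant_divergent": (3.2, 1.0),
            "discordant": (2.4, 1.8),
        }
    )
    transcript_length_range: tuple[int, int] = (200, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown transcript classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class_proportions must be non-negative")
        for cls, (a, b) in self.effect_log2.items():
            if a < 0 or b < 0:
                raise ValueError(f"effect_log2 magnitudes must be >= 0 ({cls})")
        lo, hi = self.transcript_length_range
        if lo < 1 or hi < lo:
            raise ValueError("transcript_length_range must satisfy 1 <= lo <= hi")


def _allocate_classes(config: SimConfig) -> list[str]:
    """Floor-allocate class labels; the remainder goes to null."""
    n = config.n_transcripts
    counts = {
        cls: int(np.floor(config.class_proportions.get(cls, 0.0) * n))
        for cls in CLASSES
        if cls != "null"
    }
    counts["null"] = n - sum(counts.values())
    labels: list[str] = []
    for cls in CLASSES:
        labels.extend([cls] * counts[cls])
    return labels


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion * mean**2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a fragment-count matrix and its ground-truth table.

    Returns the count matrix (12 columns ``SC1`` .. ``TT3`` for
    ``n_reps=3``) and a truth table with one row per transcript:
    ``transcript_id``, ``class``, ``planted_log2_HS``,
    ``planted_log2_HT`` (signed) and ``true_rfc`` (the RFC implied by
    the planted magnitudes; NaN for null transcripts).
    """
    config.validate()
    rng = _rng(config.seed, "experiment")
    n = config.n_transcripts

    transcript_ids = [f"TX{i:06d}" for i in range(1, n + 1)]
    labels = _allocate_classes(config)

    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    # lognormal baselines with mean equal to base_mean
    baselines = config.base_mean * rng.lognormal(
        mean=-0.5 * _BASELINE_LOG_SD**2, sigma=_BASELINE_LOG_SD, size=n
    )

    signs = rng.choice([-1.0, 1.0], size=n)
    planted_hs = np.zeros(n)
    planted_ht = np.zeros(n)
    true_rfc = np.full(n, np.nan)
    for i, cls in enumerate(labels):
        if cls == "null":
            continue
        mag_hs, mag_ht = config.effect_log2.get(cls, (0.0, 0.0))
        planted_hs[i] = signs[i] * mag_hs
        planted_ht[i] = (signs[i] if cls != "discordant" else -signs[i]) * mag_ht
        if mag_hs > 0 and mag_ht > 0:
            _, true_rfc[i] = rfc_value(planted_hs[i], planted_ht[i], concordant=cls != "discordant")

    columns: dict[str, np.ndarray] = {}
    effects = {"HS": planted_hs, "HT": planted_ht}
    for line in "ST":
        line_label = design._LINE_CODE[line]
        for cond in "CT":
            shift = 2.0 ** effects[line_label] if cond == "T" else 1.0
            mean = baselines * shift
            for rep in range(1, config.n_reps + 1):
                columns[f"{line}{cond}{rep}"] = _negative_binomial(rng, mean, config.dispersion)

    counts = pd.DataFrame(columns, index=pd.Index(transcript_ids, name="transcript_id"))
    length_series = pd.Series(lengths, index=counts.index, name="length_bp")
    truth = pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "class": labels,
            "planted_log2_HS": planted_hs,
            "planted_log2_HT": planted_ht,
            "true_rfc": true_rfc,
        }
    )
    return CountMatrix(counts=counts, lengths=length_series), truth


@dataclass
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, Phred+33 qualities."""

    read_id: str
    sequence: str
    quality: str
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence and quality lengths differ")
        if self.quality and min(self.quality) < "!":
            raise ValueError(f"{self.read_id}: quality characters must be >= '!'")


def simulate_reads(
    n_pairs: int,
    read_len: int = 101,
    n_base_rate: float = 0.0,
    lowq_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[tuple[bool, bool]]]:
    """Generate paired-end reads plus per-read QC truth labels.

    Each base is replaced by ``N`` with probability ``n_base_rate``;
    each base's quality is drawn below Q20 (uniform on 2..19) with
    probability ``lowq_rate`` and on 20..40 otherwise.  The
    ``should_pass`` label per mate applies the filtering rules directly:
    a read passes iff its N fraction is not over 5% and not more than
    20% of its bases have Q < 20.
    """
    if not (0.0 <= n_base_rate <= 1.0 and 0.0 <= lowq_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")

    rng = _rng(seed, "reads")
    n_reads = 2 * n_pairs
    base_idx = rng.integers(0, 4, size=(n_reads, read_len))
    n_mask = rng.random((n_reads, read_len)) < n_base_rate
    lowq_mask = rng.random((n_reads, read_len)) < lowq_rate
    quals = np.where(
        lowq_mask,
        rng.integers(2, 20, size=(n_reads, read_len)),
        rng.integers(20, 41, size=(n_reads, read_len)),
    )

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)[base_idx]
    bases[n_mask] = ord("N")
    qual_bytes = (quals + 33).astype(np.uint8)

    n_frac = n_mask.sum(axis=1) / read_len
    lowq_frac = (quals < 20).sum(axis=1) / read_len
    passes = (n_frac <= 0.05) & (lowq_frac <= 0.20)

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    labels: list[tuple[bool, bool]] = []
    for p in range(n_pairs):
        i, j = 2 * p, 2 * p + 1
        stem = f"read{p + 1:07d}"
        r1 = ReadRecord(stem, bases[i].tobytes().decode(), qual_bytes[i].tobytes().decode(), mate=1)
        r2 = ReadRecord(stem, bases[j].tobytes().decode(), qual_bytes[j].tobytes().decode(), mate=2)
        pairs.append((r1, r2))
        labels.append((bool(passes[i]), bool(passes[j])))
    return pairs, labels


def simulate_ct(
    truth: pd.DataFrame,
    line: str = "HS",
    base_ct: float = 24.0,
    reference_ct: float = 18.0,
    noise_sd: float = 0.0,
    n_bio_reps: int = 3,
    n_tech_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for the transcripts in a truth table.

    Under ideal efficiency (exact doubling per cycle) a transcript
    planted at signed log2 effect ``e`` in the chosen line amplifies
    ``2**e``-fold in treatment, i.e. its treatment Ct is ``base_ct - e``;
    the reference gene sits at ``reference_ct`` in both conditions.
    Gaussian noise with sd ``noise_sd`` cycles is added independently to
    every technical-replicate measurement.

    Returns a long table with columns ``gene_id, condition, bio_rep,
    tech_rep, target_ct, reference_ct``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if line not in design.LINES:
        raise ValueError(f"line must be one of {design.LINES}")
    rng = _rng(seed, "ct")

    effect_col = f"planted_log2_{line}"
    rows: list[dict] = []
    for _, rec in truth.iterrows():
        effect = float(rec[effect_col])
        for condition in design.CONDITIONS:
            target_mean = base_ct - (effect if condition == "treatment" else 0.0)
            for bio in range(1, n_bio_reps + 1):
                for tech in range(1, n_tech_reps + 1):
                    noise = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else (0.0, 0.0)
                    rows.append(
                        {
                            "gene_id": rec["transcript_id"],
                            "condition": condition,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "target_ct": target_mean + noise[0],
                            "reference_ct": reference_ct + noise[1],
                        }
                    )
    return pd.DataFrame(rows)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy a configuration with a different seed."""
    return replace(config, seed=seed)
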