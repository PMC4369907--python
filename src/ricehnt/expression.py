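"""FPKM quantification and per-line differential-expression calling.

Fragment counts are normalised to FPKM (fragments per kilobase of
transcript per million mapped fragments),

    FPKM[t, s] = count[t, s] * 1e9 / (length[t] * library_size[s]),

with the library size taken as the column sum of the count matrix.
Differential expression within one line contrasts the three treatment
replicates against the three control replicates: the reported effect is
the log2 ratio of replicate-mean FPKM (with a pseudocount), and the
p-value comes from a two-sample t-test on log2(FPKM + pseudocount)
across replicates.  The default is the pooled-variance (Student) test:
with three replicates per group the Welch degrees-of-freedom estimate
is so noisy that the test runs conservative (empirical size ~3% at
nominal 5%), whereas the pooled test is exact under normal errors with
equal group variances — which the common-dispersion noise model
satisfies by construction.  ``var_mode="welch"`` switches to the
unequal-variance form.  A transcript is called significant when
p <= alpha and |log2 FC| >= lfc_min; the study thresholds are
alpha = 0.05 and lfc_min = 1.0, applied to raw p-values without
multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from ricehnt import design

Direction = Literal["up", "down", "none"]


@dataclass
class CountMatrix:
    """Integer fragment counts, transcripts x samples, plus transcript lengths.

    ``counts`` is indexed by transcript id with one column per sample code
    (``SC1`` .. ``TT3``); ``lengths`` gives transcript length in bp on the
    same index.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths must share the same transcript index")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("fragment counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, line: str, condition: str) -> list[str]:
        cols = [s for s in design.samples_for(line, condition) if s in self.counts.columns]
        if not cols:
            raise ValueError(f"no sample columns for line={line}, condition={condition}")
        return cols


@dataclass
class FPKMMatrix:
    """Length- and depth-normalised expression values on the count index."""

    values: pd.DataFrame
    library_sizes: pd.Series
    lengths: pd.Series

    def samples_for(self, line: str, condition: str) -> list[str]:
        cols = [s for s in design.samples_for(line, condition) if s in self.values.columns]
        if not cols:
            raise ValueError(f"no sample columns for line={line}, condition={condition}")
        return cols


@dataclass
class DEResult:
    transcript_id: str
    line: str
    log2fc: float
    p_value: float
    significant: bool
    direction: Direction = field(default="none")


def compute_fpkm(counts: CountMatrix) -> FPKMMatrix:
    """Normalise a fragment-count matrix to FPKM.

    Library size per sample is the total fragment count of that sample.
    Raises on a zero library size (a degenerate sample carries no
    normalisable signal).
    """
    library_sizes = counts.counts.sum(axis=0).astype(float)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"zero library size in sample(s) {bad}")
    lengths = counts.lengths.astype(float)
    values = counts.counts.astype(float).mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    return FPKMMatrix(values=values, library_sizes=library_sizes, lengths=lengths)


def log2_fold_change(mean_treat: float, mean_ctl: float, pseudocount: float = 1.0) -> float:
    """Signed log2 ratio of treatment over control mean expression.

    The pseudocount regularises transcripts with zero expression on one
    side; with ``pseudocount=0`` both means must be positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (mean_treat <= 0 or mean_ctl <= 0):
        raise ValueError("log2 fold change undefined for zero mean without a pseudocount")
    return float(np.log2((mean_treat + pseudocount) / (mean_ctl + pseudocount)))


def de_test(
    fpkm: FPKMMatrix,
    line: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
    var_mode: Literal["pooled", "welch"] = "pooled",
) -> list[DEResult]:
    """Call treatment-vs-control differential expression within one line.

    Returns one :class:`DEResult` per transcript.  The effect size is
    log2((mean FPKM_treat + pc) / (mean FPKM_ctl + pc)) over replicate
    means; the p-value is a two-sample t-test on log2(FPKM + pc) across
    the replicates (pooled variance by default, see module docstring).
    Transcripts whose replicates are identical in both groups (zero
    variance, zero difference) get p = 1.
    """
    treat_cols = fpkm.samples_for(line, "treatment")
    ctl_cols = fpkm.samples_for(line, "control")
    if len(treat_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError("de_test requires >= 2 replicates per condition")

    treat = fpkm.values[treat_cols].to_numpy(dtype=float)
    ctl = fpkm.values[ctl_cols].to_numpy(dtype=float)

    lfc = np.log2((treat.mean(axis=1) + pseudocount) / (ctl.mean(axis=1) + pseudocount))

    log_treat = np.log2(treat + pseudocount)
    log_ctl = np.log2(ctl + pseudocount)
    if var_mode not in ("pooled", "welch"):
        raise ValueError("var_mode must be 'pooled' or 'welch'")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_treat, log_ctl, axis=1, equal_var=var_mode == "pooled")
        pvals = np.asarray(res.pvalue, dtype=float)
    # 0/0 t-statistics (identical constant groups) carry no evidence
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    out: list[DEResult] = []
    for tid, fc, p in zip(fpkm.values.index, lfc, pvals):
        sig = bool(p <= alpha and abs(fc) >= lfc_min)
        direction: Direction = "none"
        if sig:
            direction = "up" if fc > 0 else "down"
        out.append(DEResult(str(tid), line, float(fc), float(p), sig, direction))
    return out


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    """Tabulate DE results (one row per transcript) for TSV output."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "log2fc": [round(r.log2fc, 4) for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [int(r.significant) for r in results],
            "direction": [r.direction for r in results],
        }
    )
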