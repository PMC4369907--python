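"""qPCR relative expression, RNA-seq concordance and grain plumpness.

Relative expression follows the 2^-ddCt method with ideal amplification
efficiency: for a target gene normalised against the ACT1 reference,

    ddCt = (Ct_target,treat - Ct_ref,treat) - (Ct_target,ctl - Ct_ref,ctl)
    RQ   = 2 ** (-ddCt)

Technical replicates are averaged on the Ct scale before the
difference-of-differences.  Direction concordance between qPCR and
RNA-seq compares sign(log2 RQ) with sign(log2 FC), treating magnitudes
below a small tolerance as no change.  Grain plumpness is the treated
1000-grain weight as a percentage of the control's:
GP (%) = 100 * GWt / GWc.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import copysign, log2
from typing import Mapping

import pandas as pd


@dataclass
class CtSet:
    """Mean cycle thresholds of one gene (over technical replicates)."""

    gene_id: str
    ct_target_treat: float
    ct_actin_treat: float
    ct_target_ctl: float
    ct_actin_ctl: float
    n_tech_reps: int = 3

    def __post_init__(self) -> None:
        for name in ("ct_target_treat", "ct_actin_treat", "ct_target_ctl", "ct_actin_ctl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.gene_id}: {name} must be positive")


def delta_delta_ct(s: CtSet) -> float:
    """Difference-of-differences of cycle thresholds, treatment vs control."""
    return (s.ct_target_treat - s.ct_actin_treat) - (s.ct_target_ctl - s.ct_actin_ctl)


def relative_quantity(ddct: float) -> float:
    """Fold change implied by a ddCt under ideal doubling: 2**(-ddCt)."""
    return 2.0 ** (-ddct)


def ct_sets_from_table(ct_table: pd.DataFrame) -> list[CtSet]:
    """Build per-gene, per-biological-replicate CtSets from a long Ct table.

    Expects columns ``gene_id, condition, bio_rep, tech_rep, target_ct,
    reference_ct`` (the layout :func:`ricehnt.simulate.simulate_ct`
    writes); technical replicates are averaged on the Ct scale.
    """
    sets: list[CtSet] = []
    grouped = ct_table.groupby(["gene_id", "bio_rep"], sort=True)
    for (gene, bio), grp in grouped:
        treat = grp[grp["condition"] == "treatment"]
        ctl = grp[grp["condition"] == "control"]
        if treat.empty or ctl.empty:
            raise ValueError(f"{gene} bio_rep {bio}: need both treatment and control Cts")
        sets.append(
            CtSet(
                gene_id=str(gene),
                ct_target_treat=float(treat["target_ct"].mean()),
                ct_actin_treat=float(treat["reference_ct"].mean()),
                ct_target_ctl=float(ctl["target_ct"].mean()),
                ct_actin_ctl=float(ctl["reference_ct"].mean()),
                n_tech_reps=int(len(treat)),
            )
        )
    return sets


def relative_quantities(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene relative quantities: mean and sd of RQ over biological reps."""
    rows = [
        {"gene_id": s.gene_id, "rq": relative_quantity(delta_delta_ct(s))}
        for s in ct_sets_from_table(ct_table)
    ]
    per_rep = pd.DataFrame(rows)
    out = per_rep.groupby("gene_id", sort=True)["rq"].agg(["mean", "std"]).reset_index()
    return out.rename(columns={"mean": "rq_mean", "std": "rq_sd"})


def _sign_with_tolerance(log2_value: float, tol: float) -> float:
    return 0.0 if abs(log2_value) < tol else copysign(1.0, log2_value)


def direction_concordance(
    qpcr: Mapping[str, float],
    rnaseq: Mapping[str, float],
    tol: float = 0.1,
) -> float:
    """Fraction of shared genes whose qPCR and RNA-seq directions agree.

    ``qpcr`` maps gene to relative quantity (fold ratio); ``rnaseq``
    maps gene to log2 fold change.  Directions are compared on the log2
    scale with |log2| < ``tol`` treated as no change on either side.
    """
    shared = sorted(set(qpcr) & set(rnaseq))
    if not shared:
        raise ValueError("no shared genes between qPCR and RNA-seq results")
    agree = 0
    for gene in shared:
        rq = qpcr[gene]
        if rq <= 0:
            raise ValueError(f"{gene}: relative quantity must be positive")
        if _sign_with_tolerance(log2(rq), tol) == _sign_with_tolerance(rnaseq[gene], tol):
            agree += 1
    return agree / len(shared)


def grain_plumpness(gwt: float, gwc: float) -> float:
    """GP (%) = 100 * GWt / GWc for 1000-grain weights (g)."""
    if gwc <= 0:
        raise ValueError("control 1000-grain weight must be positive")
    if gwt < 0:
        raise ValueError("treated 1000-grain weight must be non-negative")
    return 100.0 * gwt / gwc
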