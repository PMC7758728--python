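"""Depletion summaries: percent miRNA content remaining, family shares,
ranked abundance tables, and the small closed-form statistics used alongside
(standard error of a proportion; delta-delta-Cq fold change).

Percentages are computed over calibrated molecules-per-embryo totals of
annotated miRNAs only — spike-ins and piRNAs never enter content totals —
and replicates are averaged as the arithmetic mean of per-replicate totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .quant import SampleQuant


def _mean_total(samples: Sequence[SampleQuant]) -> float:
    if not samples:
        raise ValueError("empty sample set")
    return sum(s.total_mirna_molecules for s in samples) / len(samples)


def _mean_molecules(samples: Sequence[SampleQuant]) -> dict[str, float]:
    acc: dict[str, float] = {}
    for s in samples:
        for rid, v in s.molecules_per_embryo.items():
            acc[rid] = acc.get(rid, 0.0) + v
    return {rid: v / len(samples) for rid, v in acc.items()}


def percent_remaining(cond: Sequence[SampleQuant], wt: Sequence[SampleQuant]) -> float:
    """100 x mean total miRNA molecules/embryo in the condition over WT."""
    wt_total = _mean_total(wt)
    if wt_total <= 0:
        raise ValueError("WT total miRNA content is zero")
    return 100.0 * _mean_total(cond) / wt_total


def family_share(samples: Sequence[SampleQuant], members: Sequence[str]) -> float:
    """Percent of miRNA molecules carried by the given family members."""
    mean_mol = _mean_molecules(samples)
    total = sum(mean_mol.values())
    if total <= 0:
        raise ValueError("total miRNA content is zero")
    fam = sum(mean_mol.get(m, 0.0) for m in members)
    return 100.0 * fam / total


def top_table(wt: Sequence[SampleQuant],
              conds: Mapping[str, Sequence[SampleQuant]],
              n: int = 100,
              family_members: Sequence[str] = ()) -> pd.DataFrame:
    """Rank miRNAs by mean WT abundance and tabulate condition abundances.

    The top ``n`` WT miRNAs are listed first (ties broken lexicographically
    by id); family members outside the top ``n`` are appended and flagged in
    the ``family_extra`` column, mirroring plots that grey out remaining
    family members below the top-100 cut.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    wt_mean = _mean_molecules(wt)
    cond_means = {label: _mean_molecules(samples) for label, samples in conds.items()}
    ranked = sorted(wt_mean, key=lambda rid: (-wt_mean[rid], rid))
    head = ranked[:n]
    extras = [rid for rid in sorted(set(family_members)) if rid not in head]
    rows = []
    for rid in head + extras:
        row = {"ref_id": rid, "wt_molecules": wt_mean.get(rid, 0.0),
               "family_extra": rid in extras}
        for label, means in cond_means.items():
            row[f"{label}_molecules"] = means.get(rid, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def se_proportion(k: int, n: int) -> float:
    """Standard error of a proportion: sqrt(p(1-p)/n) with p = k/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    return math.sqrt(p * (1.0 - p) / n)


def ddcq(cq_target_s: float, cq_ref_s: float,
         cq_target_c: float, cq_ref_c: float) -> float:
    """Relative expression by the delta-delta-Cq method.

    Sample and control Cq values for a target gene are each normalized to a
    reference gene; the fold change is 2^-ddCq.
    """
    for v in (cq_target_s, cq_ref_s, cq_target_c, cq_ref_c):
        if not math.isfinite(v):
            raise ValueError("Cq values must be finite")
    ddcq_val = (cq_target_s - cq_ref_s) - (cq_target_c - cq_ref_c)
    return 2.0 ** (-ddcq_val)


@dataclass
class DepletionSummary:
    stage: str | None
    condition: str | None
    pct_remaining: float
    family_share_of_remaining: dict[str, float] = field(default_factory=dict)
    top_table: pd.DataFrame | None = None


def summarize_depletion(wt: Sequence[SampleQuant], cond: Sequence[SampleQuant],
                        families: Mapping[str, Sequence[str]],
                        n: int = 100) -> DepletionSummary:
    """Assemble the per-condition summary: % remaining vs WT, the share of
    the remaining content carried by each family, and the ranked table."""
    pct = percent_remaining(cond, wt)
    shares = {fam: family_share(cond, members) for fam, members in families.items()}
    all_members = [m for members in families.values() for m in members]
    sample0 = cond[0]
    table = top_table(wt, {sample0.condition or "cond": cond}, n=n,
                      family_members=all_members)
    return DepletionSummary(stage=sample0.stage, condition=sample0.condition,
                            pct_remaining=pct,
                            family_share_of_remaining=shares, top_table=table)
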