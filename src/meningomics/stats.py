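"""Cohort-level association statistics and the TERT promoter screen.

Grade-genotype associations are reported as exact Fisher p-values together
with the relative risk of being atypical given a genotype; co-occurrence and
mutual exclusivity of driver genes use one-sided Fisher tests; multiplicity
is controlled with Benjamini-Hochberg.  The TERT promoter hotspots (C228T at
offset -124, C250T at offset -146) are mapped between promoter offsets and
genomic coordinates relative to the minus-strand TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "ContingencyTable",
    "TertCall",
    "fisher_rr",
    "cooccurrence_test",
    "bh_fdr",
    "tert_offset_to_coord",
    "tert_coord_to_offset",
    "tert_recurrence_report",
]

#: Default TERT transcription-start site (hg19, minus strand), chr5.
TERT_TSS = 1_295_104
TERT_STRAND = "-"


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 exposure-by-outcome count table.

    Rows are the exposure (e.g. NF2-mutant vs non-NF2), columns the outcome
    (e.g. atypical vs benign), so ``a`` counts exposed samples with the
    outcome.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("outcome", "no_outcome")

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"contingency cell {name!r} must be a non-negative integer, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TertCall:
    """One TERT promoter mutation call in one sample."""

    sample_id: str
    recurrence: str  # "primary" or "recurrent"
    offset: int  # signed bp from the TSS; negative = upstream
    genomic_pos: int
    substitution: str = ""  # e.g. "C228T"


def fisher_rr(
    table: ContingencyTable,
    sided: str = "two-sided",
    continuity: bool = False,
) -> tuple[float, float, float]:
    """Exact Fisher p, odds ratio and relative risk for a 2x2 table.

    RR is oriented as P(outcome | exposed) / P(outcome | unexposed); with
    ``continuity`` zero cells are offset by 0.5 before forming OR/RR.
    """
    arr = table.as_array().astype(float)
    if arr.sum(axis=1).min() == 0 and arr.sum(axis=0).min() == 0:
        raise ValidationError("contingency table has an all-zero margin; statistics undefined")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}.get(sided)
    if alternative is None:
        raise ValidationError(f"sided must be two-sided/greater/less, got {sided!r}")
    _, p = sps.fisher_exact(table.as_array(), alternative=alternative)
    a, b, c, d = arr.ravel()
    if continuity and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_ratio = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        risk_exposed = a / (a + b) if a + b > 0 else np.nan
        risk_unexposed = c / (c + d) if c + d > 0 else np.nan
        rr = risk_exposed / risk_unexposed if risk_unexposed and risk_unexposed > 0 else np.inf
    return float(p), float(odds_ratio), float(rr)


def cooccurrence_test(
    gene_a_hits: Iterable[str],
    gene_b_hits: Iterable[str],
    n_samples: int,
    direction: str = "cooccurrence",
) -> float:
    """One-sided Fisher p for co-occurrence (enrichment of the overlap) or
    mutual exclusivity (depletion) of two genes' mutated-sample sets."""
    a_set, b_set = set(gene_a_hits), set(gene_b_hits)
    if len(a_set) > n_samples or len(b_set) > n_samples:
        raise ValidationError("hit sets larger than the cohort")
    k = len(a_set & b_set)
    table = np.array(
        [
            [k, len(a_set) - k],
            [len(b_set) - k, n_samples - len(a_set) - len(b_set) + k],
        ]
    )
    if table.min() < 0:
        raise ValidationError("hit sets inconsistent with n_samples")
    alternative = {"cooccurrence": "greater", "exclusivity": "less"}.get(direction)
    if alternative is None:
        raise ValidationError(f"direction must be cooccurrence or exclusivity, got {direction!r}")
    _, p = sps.fisher_exact(table, alternative=alternative)
    return float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tert_offset_to_coord(tss_pos: int, strand: str, offset: int) -> int:
    """Map a signed promoter offset (negative = upstream of the TSS) to a
    1-based genomic coordinate.

    On the minus strand upstream means larger coordinates, so offset -124
    from the TERT TSS at chr5:1,295,104 lands on chr5:1,295,228.
    """
    if strand not in {"+", "-"}:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        return tss_pos - offset
    return tss_pos + offset


def tert_coord_to_offset(tss_pos: int, strand: str, genomic_pos: int) -> int:
    """Inverse of :func:`tert_offset_to_coord` (bijection per strand)."""
    if strand not in {"+", "-"}:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        return tss_pos - genomic_pos
    return genomic_pos - tss_pos


def tert_recurrence_report(
    calls: Sequence[TertCall],
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Frequency of TERT promoter mutations by recurrence status.

    ``sample_sheet`` needs columns ``sample_id`` and ``recurrence``.  Returns
    one row per status with mutated/total counts, the pooled fraction and the
    percentage rounded half-up to the nearest integer.
    """
    if "sample_id" not in sample_sheet or "recurrence" not in sample_sheet:
        raise ValidationError("sample sheet requires sample_id and recurrence columns")
    known = set(sample_sheet["sample_id"])
    for call in calls:
        if call.sample_id not in known:
            raise ValidationError(f"TERT call for unknown sample {call.sample_id!r}")
    hit_samples = {c.sample_id for c in calls}
    rows = []
    for status, group in sample_sheet.groupby("recurrence", sort=True):
        total = len(group)
        mutated = int(group["sample_id"].isin(hit_samples).sum())
        fraction = mutated / total if total else float("nan")
        # round half-up so 4/31 = 12.9% reports as 13%
        percent = int(np.floor(100 * fraction + 0.5)) if total else 0
        rows.append(
            {"recurrence": status, "mutated": mutated, "total": total, "fraction": fraction, "percent": percent}
        )
    return pd.DataFrame(rows)
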