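"""H3K27ac super-enhancers and H3K27me3 broad-domain differential signal.

H3K27ac peaks are stitched into enhancer regions (gap <= 12.5 kb) after
excluding promoter-proximal peaks (midpoint within 2 kb of a TSS).
Super-enhancers are separated from typical enhancers geometrically: regions
are ranked by background-subtracted signal, both axes scaled to [0, 1], and
the cutoff placed where a line of slope 1 is tangent to the rank curve;
regions above the cutoff signal are super-enhancers.  Differential binding
between grades reuses the moderated-t engine on log2 signal, and
super-enhancer changes are matched to expression changes at the nearest
gene for concordance calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import DEResult, moderated_de

__all__ = [
    "Peak",
    "StitchedEnhancer",
    "stitch_peaks",
    "call_super_enhancers",
    "differential_binding",
    "expression_concordance",
    "broad_domain_differential",
]

log = logging.getLogger(__name__)

STITCH_BP = 12_500
TSS_EXCLUDE_BP = 2_000


@dataclass(frozen=True)
class Peak:
    """One enrichment peak (0-based half-open) with ChIP and input signal in rpm."""

    chrom: str
    start: int
    end: int
    signal: float
    input_signal: float = 0.0
    peak_id: str = ""

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def net_signal(self) -> float:
        return max(0.0, self.signal - self.input_signal)


@dataclass
class StitchedEnhancer:
    chrom: str
    start: int
    end: int
    constituents: tuple[str, ...]
    signal: float  # background-subtracted, summed over constituents
    rank: int = 0
    is_super: bool = False
    nearest_gene: str = ""


def stitch_peaks(
    peaks: Sequence[Peak],
    tss: Sequence[tuple[str, int]],
    stitch_bp: int = STITCH_BP,
    tss_exclude_bp: int = TSS_EXCLUDE_BP,
) -> list[StitchedEnhancer]:
    """Merge peaks into enhancer regions, excluding promoter-proximal peaks.

    A peak whose midpoint lies within +/-``tss_exclude_bp`` of any TSS on
    its chromosome is removed before stitching; remaining peaks on a
    chromosome are merged whenever the gap between them is <=
    ``stitch_bp``.  Stitching is idempotent.
    """
    tss_lists: dict[str, list[int]] = {}
    for chrom, pos in tss:
        tss_lists.setdefault(chrom, []).append(pos)
    tss_by_chrom = {c: np.sort(np.asarray(p)) for c, p in tss_lists.items()}

    def near_tss(peak: Peak) -> bool:
        arr = tss_by_chrom.get(peak.chrom)
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, peak.midpoint)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(peak.midpoint - arr[j]) <= tss_exclude_bp:
                return True
        return False

    kept = sorted((p for p in peaks if not near_tss(p)), key=lambda p: (p.chrom, p.start, p.end))
    regions: list[StitchedEnhancer] = []
    i = 0
    while i < len(kept):
        chrom = kept[i].chrom
        start, end = kept[i].start, kept[i].end
        members = [kept[i]]
        j = i + 1
        while j < len(kept) and kept[j].chrom == chrom and kept[j].start - end <= stitch_bp:
            end = max(end, kept[j].end)
            members.append(kept[j])
            j += 1
        regions.append(
            StitchedEnhancer(
                chrom=chrom,
                start=start,
                end=end,
                constituents=tuple(p.peak_id or f"{p.chrom}:{p.start}-{p.end}" for p in members),
                signal=float(sum(p.net_signal for p in members)),
            )
        )
        i = j
    return regions


def call_super_enhancers(regions: Sequence[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Flag super-enhancers by the scaled rank-curve tangent rule.

    Regions are sorted ascending by signal; rank and signal are both scaled
    to [0, 1] and the cutoff index is where the unit-slope line is tangent
    to the curve from below (the minimiser of scaled signal minus scaled
    rank, first index on ties).  Regions with signal strictly above the
    cutoff signal are super-enhancers.
    """
    if len(regions) == 0:
        return []
    order = np.argsort([r.signal for r in regions], kind="mergesort")
    signals = np.array([regions[i].signal for i in order], dtype=float)
    n = len(signals)
    for rank, idx in enumerate(order):
        regions[idx].rank = rank
        regions[idx].is_super = False
    if n < 2 or signals[-1] == signals[0]:
        log.warning("all region signals equal; no super-enhancers called")
        return list(regions)
    x = np.arange(n) / (n - 1)
    y = (signals - signals[0]) / (signals[-1] - signals[0])
    cut_idx = int(np.argmin(y - x))
    cutoff = signals[cut_idx]
    for rank, idx in enumerate(order):
        regions[idx].is_super = bool(signals[rank] > cutoff)
    return list(regions)


def _region_index(regions: Sequence[StitchedEnhancer]) -> list[str]:
    return [f"{r.chrom}:{r.start}-{r.end}" for r in regions]


def differential_binding(
    signal_matrix: pd.DataFrame,
    grades: Mapping[str, str],
    alpha: float = 0.05,
) -> DEResult:
    """Moderated two-group test on log2(signal + 1) per region.

    Regions with zero signal in every sample are dropped with a warning.
    """
    values = signal_matrix.to_numpy(dtype=float)
    nonzero = values.sum(axis=1) > 0
    if not nonzero.all():
        log.warning("dropping %d all-zero regions", int((~nonzero).sum()))
    kept = signal_matrix.loc[signal_matrix.index[nonzero]]
    logm = np.log2(kept.to_numpy(dtype=float) + 1.0)
    return moderated_de(pd.DataFrame(logm, index=kept.index, columns=kept.columns), grades, alpha=alpha)


def assign_nearest_gene(
    regions: Sequence[StitchedEnhancer],
    gene_tss: pd.DataFrame,
) -> list[StitchedEnhancer]:
    """Nearest gene by TSS distance to the region centre (same chromosome).

    ``gene_tss`` is indexed by gene with columns chrom, tss.
    """
    for region in regions:
        sub = gene_tss[gene_tss["chrom"] == region.chrom]
        if sub.empty:
            region.nearest_gene = ""
            continue
        centre = (region.start + region.end) / 2.0
        dist = (sub["tss"] - centre).abs()
        region.nearest_gene = str(dist.idxmin())
    return list(regions)


def expression_concordance(
    region_de: DEResult,
    expression_de: DEResult,
    region_genes: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Super-enhancer / expression concordance calls.

    A region is concordant when both its differential-binding adjusted p and
    its nearest gene's expression adjusted p are below ``alpha`` and the
    fold changes share a sign.  Regions whose gene is absent from the
    expression table are skipped with a warning.
    """
    rows = []
    for region, gene in region_genes.items():
        if region not in region_de.table.index:
            continue
        if gene not in expression_de.table.index:
            log.warning("gene %s absent from expression DE; skipping region %s", gene, region)
            continue
        r = region_de.table.loc[region]
        g = expression_de.table.loc[gene]
        concordant = (
            r["fdr"] < alpha and g["fdr"] < alpha and np.sign(r["logfc"]) == np.sign(g["logfc"])
        )
        rows.append(
            {
                "region": region,
                "gene": gene,
                "region_logfc": float(r["logfc"]),
                "region_fdr": float(r["fdr"]),
                "gene_logfc": float(g["logfc"]),
                "gene_fdr": float(g["fdr"]),
                "concordant": bool(concordant),
            }
        )
    return pd.DataFrame(rows)


def broad_domain_differential(
    bin_matrix: pd.DataFrame,
    grades: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[DEResult, float]:
    """Binned broad-mark (H3K27me3) differential signal and its global shift.

    Runs the moderated test on log2(signal + 1) per fixed-width bin and
    summarises the genome-wide direction as the fraction of significant
    bins with positive fold change (NaN when nothing is significant).
    """
    de = differential_binding(bin_matrix, grades, alpha=alpha)
    sig = de.table[de.table["fdr"] < alpha]
    summary = float((sig["logfc"] > 0).mean()) if len(sig) else float("nan")
    return de, summary
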