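"""CNV segment post-processing: purity, event classes, genomic instability.

Segments arrive pre-segmented (SEG-like: chrom, start, end, logR) together
with per-segment mean heterozygous-SNP BAF deviation.  This module applies
the BAF false-positive correction, classifies events into large-scale /
focal loss or gain and copy-neutral LOH against a chromosome-arm table,
computes the percentage of genome altered (PGA), labels samples CNV-high or
CNV-low, estimates tumour purity from copy-loss BAF deviation, and runs the
arm-event and per-gene grade associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CoordinateError, EstimationError, ValidationError
from .stats import ContingencyTable, bh_fdr, fisher_rr

__all__ = [
    "CnvSegment",
    "ArmTable",
    "InstabilityProfile",
    "ClassThresholds",
    "estimate_purity",
    "expected_baf_deviation",
    "classify_segment",
    "classify_segments",
    "split_at_arm_boundaries",
    "compute_pga",
    "cnv_status",
    "arm_event_association",
    "gene_cnv_association",
    "REFERENCE_MEAN_PGA",
]

log = logging.getLogger(__name__)

#: Cohort-mean PGA reported across 208 meningiomas, usable as a fixed threshold.
REFERENCE_MEAN_PGA = 4.8

EVENT_CLASSES = ("large_loss", "large_gain", "focal_loss", "focal_gain", "cn_loh", "none")
ALTERED_CLASSES = ("large_loss", "large_gain", "focal_loss", "focal_gain")


@dataclass(frozen=True)
class ClassThresholds:
    """Event-classification cutoffs (printed values as defaults)."""

    logr_gain: float = 0.1
    logr_loss: float = -0.1
    baf_dev_min: float = 0.05
    large_fraction: float = 1.0 / 3.0
    focal_fraction: float = 1.0 / 10.0


@dataclass(frozen=True)
class CnvSegment:
    """A genomic interval with logR and BAF evidence (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    logr: float
    baf_dev: float = 0.0
    n_snps: int = 0
    event_class: str = "none"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("segment start must be <= end")
        if not 0 <= self.baf_dev <= 0.5:
            raise ValidationError("baf_dev must lie in [0, 0.5]")
        if self.event_class not in EVENT_CLASSES:
            raise ValidationError(f"unknown event class {self.event_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InstabilityProfile:
    sample_id: str
    pga: float
    cnv_status: str  # "high" or "low"
    events: tuple[tuple[str, str, str], ...]  # (chrom, arm, class)


class ArmTable:
    """Chromosome-arm boundaries of the genome model.

    Built from a DataFrame with columns chrom, arm, start, end (1-based
    inclusive).  Arms must not overlap within a chromosome.
    """

    def __init__(self, arms: pd.DataFrame, autosomes_only: bool = True):
        required = {"chrom", "arm", "start", "end"}
        if not required <= set(arms.columns):
            raise ValidationError(f"arm table requires columns {sorted(required)}")
        df = arms.copy()
        if autosomes_only:
            df = df[~df["chrom"].astype(str).str.replace("chr", "", regex=False).isin(["X", "Y"])]
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom"):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if np.any(starts[1:] <= ends[:-1]):
                raise ValidationError(f"overlapping arms on {chrom}")
        self.arms = df
        self.genome_total_bp = int((df["end"] - df["start"] + 1).sum())

    def arm_of(self, chrom: str, start: int, end: int) -> tuple[str, int, int]:
        """Return (arm, arm_start, arm_end) containing the interval, or raise."""
        sub = self.arms[self.arms["chrom"] == chrom]
        if sub.empty:
            raise CoordinateError(f"chromosome {chrom!r} not in arm table")
        hit = sub[(sub["start"] <= start) & (sub["end"] >= end)]
        if hit.empty:
            raise CoordinateError(f"segment {chrom}:{start}-{end} does not lie within a single arm")
        row = hit.iloc[0]
        return str(row["arm"]), int(row["start"]), int(row["end"])


def expected_baf_deviation(purity: float, tumour_cn: int = 1) -> float:
    """Expected |BAF - 0.5| at blood-heterozygous SNPs in a loss region.

    Under single-copy loss the retained-allele fraction in the tumour/normal
    mixture is (1-p)/(2-p) for the deleted allele, hence deviation
    0.5 - (1-p)/(2-p).
    """
    if tumour_cn != 1:
        raise ValidationError("closed form defined for single-copy loss (cn=1)")
    return 0.5 - (1 - purity) / (2 - purity)


def estimate_purity(
    loss_segments: Sequence[CnvSegment],
    min_snps: int = 10,
) -> float:
    """Tumour purity from BAF deviation in copy-loss segments.

    With mean deviation d over qualifying loss segments (weighted by SNP
    count), inverting d = 0.5 - (1-p)/(2-p) gives p = 4d/(1+2d), clamped to
    (0, 1].
    """
    qual = [s for s in loss_segments if s.event_class in {"large_loss", "focal_loss"} and s.n_snps >= min_snps]
    if not qual:
        raise EstimationError("no copy-loss segments with sufficient SNPs; cannot estimate purity")
    weights = np.array([s.n_snps for s in qual], dtype=float)
    devs = np.array([s.baf_dev for s in qual], dtype=float)
    d = float(np.average(devs, weights=weights))
    p = 4.0 * d / (1.0 + 2.0 * d)
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def classify_segment(
    seg: CnvSegment,
    arms: ArmTable,
    thresholds: ClassThresholds | None = None,
) -> str:
    """Event class of one segment against its chromosome arm.

    Any segment whose BAF deviation is below the 0.05 floor is called
    ``none`` regardless of logR (the false-positive correction).  Otherwise
    loss/gain requires logR beyond +/-0.1, large-scale means the segment
    covers strictly more than one-third of the arm, focal more than
    one-tenth; |logR| <= 0.1 with qualifying BAF deviation over more than
    one-third of the arm is copy-neutral LOH.
    """
    th = thresholds or ClassThresholds()
    arm, arm_start, arm_end = arms.arm_of(seg.chrom, seg.start, seg.end)
    overlap = min(seg.end, arm_end) - max(seg.start, arm_start) + 1
    frac = overlap / (arm_end - arm_start + 1)

    if seg.baf_dev < th.baf_dev_min:
        return "none"
    if seg.logr < th.logr_loss or seg.logr > th.logr_gain:
        kind = "loss" if seg.logr < th.logr_loss else "gain"
        if frac > th.large_fraction:
            return f"large_{kind}"
        if frac > th.focal_fraction:
            return f"focal_{kind}"
        return "none"
    if frac > th.large_fraction:
        return "cn_loh"
    return "none"


def split_at_arm_boundaries(segments: Iterable[CnvSegment], arms: ArmTable) -> list[CnvSegment]:
    """Split segments spanning an arm boundary (e.g. the centromere).

    Portions falling outside any arm (centromeric gaps, excluded sex
    chromosomes) are dropped.
    """
    out: list[CnvSegment] = []
    for seg in segments:
        sub = arms.arms[arms.arms["chrom"] == seg.chrom]
        for _, arm_row in sub.iterrows():
            lo = max(seg.start, int(arm_row["start"]))
            hi = min(seg.end, int(arm_row["end"]))
            if lo <= hi:
                out.append(replace(seg, start=lo, end=hi))
    return out


def classify_segments(
    segments: Iterable[CnvSegment],
    arms: ArmTable,
    thresholds: ClassThresholds | None = None,
) -> list[CnvSegment]:
    """Split at arm boundaries then classify every segment."""
    pieces = split_at_arm_boundaries(segments, arms)
    return [replace(s, event_class=classify_segment(s, arms, thresholds)) for s in pieces]


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by 1-based inclusive intervals, overlaps counted once."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    total += cur_hi - cur_lo + 1
    return total


def compute_pga(
    segments: Sequence[CnvSegment],
    arms: ArmTable,
    include_cn_loh: bool = False,
) -> float:
    """Percentage of the genome in copy-loss or copy-gain segments.

    Copy-neutral LOH carries no net dosage change and is excluded by
    default; overlapping altered segments are counted once.
    """
    keep = set(ALTERED_CLASSES) | ({"cn_loh"} if include_cn_loh else set())
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.event_class in keep:
            by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    altered = sum(_merged_length(iv) for iv in by_chrom.values())
    return 100.0 * altered / arms.genome_total_bp


def cnv_status(
    pga_by_sample: Mapping[str, float],
    threshold: float | str = "cohort_mean",
) -> dict[str, str]:
    """Label samples CNV-high/CNV-low by strict comparison of PGA to a
    threshold: a fixed percentage or the cohort mean."""
    if isinstance(threshold, str):
        if threshold != "cohort_mean":
            raise ValidationError(f"threshold must be a number or 'cohort_mean', got {threshold!r}")
        if len(pga_by_sample) < 2:
            raise ValidationError("cohort_mean threshold requires >= 2 samples")
        cut = float(np.mean(list(pga_by_sample.values())))
    else:
        cut = float(threshold)
    return {s: ("high" if pga > cut else "low") for s, pga in pga_by_sample.items()}


def arm_event_association(
    profiles: Sequence[InstabilityProfile],
    grades: Mapping[str, str],
) -> pd.DataFrame:
    """Per (arm, event-class) Fisher test of atypical vs benign frequency.

    Returns a table with counts, two-sided exact p and BH FDR, ordered by p.
    """
    atypical = [p for p in profiles if grades[p.sample_id] == "atypical"]
    benign = [p for p in profiles if grades[p.sample_id] == "benign"]
    if len(atypical) < 2 or len(benign) < 2:
        raise ValidationError("need >= 2 samples per grade")
    events = sorted({(c, a, k) for p in profiles for (c, a, k) in p.events})
    rows = []
    for chrom, arm, klass in events:
        def _has(p: InstabilityProfile) -> bool:
            return (chrom, arm, klass) in set(p.events)
        a = sum(map(_has, atypical))
        c = sum(map(_has, benign))
        table = ContingencyTable(a, len(atypical) - a, c, len(benign) - c)
        p_val, _, _ = fisher_rr(table, sided="two-sided")
        rows.append({"chrom": chrom, "arm": arm, "event_class": klass,
                     "n_atypical": a, "n_benign": c, "p": p_val})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df


def gene_logr_matrix(
    genes: pd.DataFrame,
    segments_by_sample: Mapping[str, Sequence[CnvSegment]],
) -> pd.DataFrame:
    """Per-gene, per-sample logR as the length-weighted mean over overlapping
    segments; genes with no overlap get neutral 0 with a warning."""
    required = {"gene", "chrom", "start", "end"}
    if not required <= set(genes.columns):
        raise ValidationError(f"gene table requires columns {sorted(required)}")
    out = pd.DataFrame(0.0, index=genes["gene"], columns=list(segments_by_sample))
    warned: set[str] = set()
    for sample, segs in segments_by_sample.items():
        for _, g in genes.iterrows():
            weights, values = [], []
            for seg in segs:
                if seg.chrom != g["chrom"]:
                    continue
                lo = max(seg.start, int(g["start"]))
                hi = min(seg.end, int(g["end"]))
                if lo <= hi:
                    weights.append(hi - lo + 1)
                    values.append(seg.logr)
            if weights:
                out.loc[g["gene"], sample] = float(np.average(values, weights=weights))
            elif g["gene"] not in warned:
                warned.add(g["gene"])
                log.warning("gene %s has no overlapping segment in %s; logR set to 0", g["gene"], sample)
    return out


def gene_cnv_association(
    gene_logr: pd.DataFrame,
    grades: Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum of logR between grades, with BH
    FDR and the median difference (atypical - benign) as direction."""
    atyp = [s for s in gene_logr.columns if grades[s] == "atypical"]
    ben = [s for s in gene_logr.columns if grades[s] == "benign"]
    if not atyp or not ben:
        raise ValidationError("both grades must be present")
    rows = []
    for gene, row in gene_logr.iterrows():
        x, y = row[atyp].to_numpy(float), row[ben].to_numpy(float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            method = "exact" if len(x) + len(y) <= 25 else "asymptotic"
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        rows.append({"gene": gene, "median_diff": float(np.median(x) - np.median(y)), "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)
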