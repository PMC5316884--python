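"""Somatic variant filtering, annotation and clonality.

Implements the tumour/normal post-calling cascade: a genotype-likelihood
somatic score, site-quality and context filters (repeats, homopolymers,
mutation clusters, strand bias, clipped-read bias), population and internal
cohort frequency filters, consequence-severity selection, the six-category
substitution signature, driver-subgroup assignment and cancer-cell-fraction
(clonality) estimation from VAF, purity and local copy number.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError

__all__ = [
    "FilterThresholds",
    "VariantRecord",
    "FilterVerdict",
    "ClonalityEstimate",
    "somatic_score",
    "apply_filter_cascade",
    "cluster_variants",
    "select_consequence",
    "mutational_signature",
    "assign_driver_subgroup",
    "clonality",
    "SIGNATURE_CATEGORIES",
    "CONSEQUENCE_SEVERITY",
    "DELETERIOUS_CONSEQUENCES",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable cutoffs of the somatic filter cascade.

    Defaults follow the published cascade where a number is printed
    (somatic score 20, qual 30, QD 1, homopolymer 10, cluster size 2,
    clipping rank +/-3, population AF 1%, 150 internal alleles); strand-bias
    and MQ0 cutoffs are conventional values since only the filter names are
    published.
    """

    somatic_score_min: float = 20.0
    qual_min: float = 30.0
    qd_min: float = 1.0
    mq0_max: int = 4
    strand_bias_max: float = 60.0
    cluster_size_max: int = 2
    homopolymer_min_len: int = 10
    homopolymer_window: int = 5
    clipping_rank_abs: float = 3.0
    pop_af_max: float = 0.01
    internal_allele_max: int = 150
    score_cap: float = 255.0


@dataclass
class VariantRecord:
    """One somatic call with the annotations the cascade consumes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumour_ref_depth: int
    tumour_alt_depth: int
    normal_ref_depth: int
    normal_alt_depth: int
    tumour_gl: tuple[float, float, float]  # log10 likelihoods (hom-ref, het, hom-alt)
    normal_gl: tuple[float, float, float]
    qual: float
    qd: float
    mq0: int = 0
    strand_bias_phred: float = 0.0
    clipping_rank_sum: float = 0.0
    repeat_masked: bool = False
    segdup: bool = False
    context_seq: str = ""
    pop_af_max: float = 0.0
    internal_gene_allele_count: int = 0
    consequence_terms: tuple[str, ...] = ()
    gene: str = ""
    protein_change: str = ""
    sample_id: str = ""
    cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError("pos must be 1-based (>= 1)")
        for name in ("tumour_ref_depth", "tumour_alt_depth", "normal_ref_depth", "normal_alt_depth"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.context_seq and len(self.context_seq) % 2 == 0:
            raise ValidationError("context_seq length must be odd with the variant at the centre")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_filters: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_filters) == 0):
            raise ValidationError("passed flag inconsistent with failed_filters")


@dataclass(frozen=True)
class ClonalityEstimate:
    vaf: float
    purity: float
    tumour_cn: int
    multiplicity: int
    ccf: float


def _posterior(gl: Sequence[float]) -> np.ndarray:
    arr = np.asarray(gl, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ValidationError("genotype likelihoods must be 3 finite log10 values")
    arr = arr - arr.max()
    post = 10.0 ** arr
    return post / post.sum()


def somatic_score(
    tumour_gl: Sequence[float],
    normal_gl: Sequence[float],
    cap: float = 255.0,
) -> float:
    """Phred-scaled probability that tumour and normal genotypes agree.

    Both log10-likelihood triplets are normalised to posteriors under a flat
    prior; assuming independence, P(same genotype) = sum_g Pt(g) * Pn(g) and
    the score is -10*log10 of that, capped at ``cap``.
    """
    pt = _posterior(tumour_gl)
    pn = _posterior(normal_gl)
    p_same = float(np.dot(pt, pn))
    if p_same <= 0.0:
        return float(cap)
    return float(min(-10.0 * np.log10(p_same), cap))


def _homopolymer_hit(context: str, min_len: int, window: int) -> bool:
    """True if a homopolymer run of >= min_len overlaps the +/-window bp
    around the variant or starts immediately to its right.

    Both readings of the disjunctive rule are applied as a union; the
    centre of ``context`` is the variant base.
    """
    if not context:
        return False
    centre = len(context) // 2
    for m in re.finditer(r"(A+|C+|G+|T+|a+|c+|g+|t+)", context):
        if m.end() - m.start() < min_len:
            continue
        # overlap with [centre - window, centre + window]
        if m.start() <= centre + window and m.end() - 1 >= centre - window:
            return True
        if m.start() == centre + 1:  # anchored immediately right of the variant
            return True
    return False


def apply_filter_cascade(
    record: VariantRecord,
    thresholds: FilterThresholds | None = None,
) -> FilterVerdict:
    """Evaluate every cascade filter and record all failures (no short-circuit)."""
    th = thresholds or FilterThresholds()
    failed: list[str] = []

    score = somatic_score(record.tumour_gl, record.normal_gl, cap=th.score_cap)
    if score < th.somatic_score_min:
        failed.append("somatic_score")
    if record.repeat_masked or record.segdup:
        failed.append("repeat_segdup")
    if record.qual < th.qual_min or record.qd < th.qd_min:
        failed.append("low_quality")
    if record.mq0 > th.mq0_max:
        failed.append("mapping_quality_zero")
    if record.strand_bias_phred > th.strand_bias_max:
        failed.append("strand_bias")
    if record.cluster_size > th.cluster_size_max:
        failed.append("mutation_cluster")
    if _homopolymer_hit(record.context_seq, th.homopolymer_min_len, th.homopolymer_window):
        failed.append("homopolymer")
    if abs(record.clipping_rank_sum) > th.clipping_rank_abs:
        failed.append("clipping_rank_sum")
    if record.pop_af_max > th.pop_af_max:
        failed.append("population_frequency")
    if record.internal_gene_allele_count > th.internal_allele_max:
        failed.append("internal_cohort_frequency")

    return FilterVerdict(passed=not failed, failed_filters=tuple(failed))


def cluster_variants(records: Sequence[VariantRecord], window_bp: int = 100) -> list[VariantRecord]:
    """Annotate each record with the size of its same-sample mutation cluster.

    A cluster is a maximal run of a sample's variants on one chromosome with
    consecutive gaps <= ``window_bp``.  Records must be sorted by
    (chrom, pos) within each sample.
    """
    by_key: dict[tuple[str, str], list[VariantRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.chrom), []).append(rec)
    for key, group in by_key.items():
        positions = [r.pos for r in group]
        if positions != sorted(positions):
            raise ValidationError(f"records for {key} are not position-sorted")
        start = 0
        for i in range(1, len(group) + 1):
            if i == len(group) or group[i].pos - group[i - 1].pos > window_bp:
                size = i - start
                for r in group[start:i]:
                    r.cluster_size = size
                start = i
    return list(records)


# Severity ordering, most deleterious first.  Everything at or above
# "inframe_insertion" counts as deleterious.
CONSEQUENCE_SEVERITY: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "splice_region_variant",
    "initiator_codon_variant",
    "missense_variant_damaging",
    "inframe_deletion",
    "inframe_insertion",
    # --- below here: not deleterious ---
    "missense_variant",
    "splice_donor_region_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "5_prime_utr_variant",
    "3_prime_utr_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intron_variant",
    "non_coding_transcript_variant",
    "intergenic_variant",
)

DELETERIOUS_CONSEQUENCES = frozenset(CONSEQUENCE_SEVERITY[: CONSEQUENCE_SEVERITY.index("inframe_insertion") + 1])

_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY)}


def select_consequence(consequence_terms: Sequence[str]) -> tuple[str, bool]:
    """Pick the most severe consequence term and flag whether it is deleterious."""
    if not consequence_terms:
        raise ValidationError("consequence term list is empty")
    unknown = [t for t in consequence_terms if t not in _SEVERITY_RANK]
    if unknown:
        raise ValidationError(f"unknown consequence terms: {unknown}")
    top = min(consequence_terms, key=_SEVERITY_RANK.__getitem__)
    return top, top in DELETERIOUS_CONSEQUENCES


#: The six collapsed substitution categories, complementary pairs folded.
SIGNATURE_CATEGORIES: tuple[str, ...] = (
    "T>C/A>G",
    "A>C/T>G",
    "G>C/C>G",
    "C>T/G>A",
    "A>T/T>A",
    "G>T/C>A",
)

_SUBSTITUTION_TO_CATEGORY = {
    ("T", "C"): 0, ("A", "G"): 0,
    ("A", "C"): 1, ("T", "G"): 1,
    ("G", "C"): 2, ("C", "G"): 2,
    ("C", "T"): 3, ("G", "A"): 3,
    ("A", "T"): 4, ("T", "A"): 4,
    ("G", "T"): 5, ("C", "A"): 5,
}


def mutational_signature(records: Iterable[VariantRecord]) -> np.ndarray:
    """Fractions of filtered SNVs over the six folded substitution categories.

    Indels are ignored; with no SNVs the zero vector is returned.
    """
    counts = np.zeros(6, dtype=float)
    for rec in records:
        if len(rec.ref) != 1 or len(rec.alt) != 1:
            continue
        key = (rec.ref.upper(), rec.alt.upper())
        if key in _SUBSTITUTION_TO_CATEGORY:
            counts[_SUBSTITUTION_TO_CATEGORY[key]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


_SMARCB1_HOTSPOTS = {"p.Arg383Gln", "p.Arg386His"}
_PI3K_HOTSPOT_GENES = {"PIK3CA", "PIK3R1"}
_HEDGEHOG_GENES = {"SMO", "SUFU", "PRKAR1A"}
_POLR2A_HOTSPOTS = {"p.Gln403Lys", "p.Leu438_His439del"}


def assign_driver_subgroup(
    variants: pd.DataFrame,
    chr22_loss: bool = False,
    nf2_loss: bool = False,
) -> str:
    """Assign a sample to one of the mutually exclusive driver subgroups.

    ``variants`` holds the sample's deleterious-filtered calls with columns
    ``gene`` and ``protein_change``.  Priority (highest first):
    NF2/SMARCB1 > NF2 > TRAF7/PI3K > TRAF7/KLF4 > Hedgehog > POLR2A > unknown.
    NF2 status is met either by a deleterious NF2 variant or by NF2 loss on a
    deleted chromosome 22.
    """
    genes = set(variants["gene"]) if len(variants) else set()

    def _hotspot(gene: str, changes: set[str]) -> bool:
        if gene not in genes:
            return False
        sub = variants.loc[variants["gene"] == gene, "protein_change"]
        return bool(set(sub) & changes)

    nf2_hit = "NF2" in genes or (nf2_loss and chr22_loss)
    labels_matched = []
    if nf2_hit and _hotspot("SMARCB1", _SMARCB1_HOTSPOTS):
        labels_matched.append("NF2/SMARCB1")
    if nf2_hit:
        labels_matched.append("NF2")
    if "TRAF7" in genes and ("AKT1" in genes and _hotspot("AKT1", {"p.Glu17Lys"}) or genes & _PI3K_HOTSPOT_GENES):
        labels_matched.append("TRAF7/PI3K")
    if "TRAF7" in genes and _hotspot("KLF4", {"p.Lys409Gln"}):
        labels_matched.append("TRAF7/KLF4")
    if genes & _HEDGEHOG_GENES:
        labels_matched.append("Hedgehog")
    if _hotspot("POLR2A", _POLR2A_HOTSPOTS):
        labels_matched.append("POLR2A")
    if not labels_matched:
        return "unknown"
    if len(labels_matched) > 1:
        log.info("conflicting subgroup evidence %s; keeping %s by priority", labels_matched, labels_matched[0])
    return labels_matched[0]


def clonality(record: VariantRecord, purity: float, tumour_cn: int) -> ClonalityEstimate:
    """Cancer-cell fraction from VAF, purity and local copy number.

    Effective copies per cell D = purity*cn + (1-purity)*2; the mutated-copy
    multiplicity is round(VAF*D/purity) clamped to [1, cn]; the CCF is
    VAF*D/(purity*m) clamped to [0, 1.05].
    """
    if not 0 < purity <= 1:
        raise EstimationError(f"purity must lie in (0, 1], got {purity}")
    if tumour_cn < 1:
        raise ValidationError("tumour copy number must be >= 1")
    depth = record.tumour_ref_depth + record.tumour_alt_depth
    if depth <= 0:
        raise ValidationError("tumour depth must be > 0")
    vaf = record.tumour_alt_depth / depth
    eff_copies = purity * tumour_cn + (1 - purity) * 2
    multiplicity = int(np.clip(round(vaf * eff_copies / purity), 1, tumour_cn))
    ccf = float(np.clip(vaf * eff_copies / (purity * multiplicity), 0.0, 1.05))
    return ClonalityEstimate(vaf=vaf, purity=purity, tumour_cn=tumour_cn, multiplicity=multiplicity, ccf=ccf)
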