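"""miRNA quantification, differential expression and regulatory networks.

Counts are normalised to log2 reads-per-million (5p and 3p strands are
distinct features, library totals per sample).  Differential miRNAs use the
shared moderated-t engine.  miRNA:mRNA regulatory edges require a
significant negative Spearman correlation (raw p < 0.05) plus target
prediction support in at least three of six databases; per-miRNA counts of
negatively vs positively correlated targets are compared with a paired
Wilcoxon signed-rank test.  The chromosome 14q32 miRNA cluster is analysed
for copy-loss-driven downregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .expression import DEResult, moderated_de

__all__ = [
    "RegulatoryEdge",
    "rpm_log",
    "mirna_de",
    "infer_network",
    "neg_vs_pos_counts",
    "band_cluster",
    "pair_correlation",
]

log = logging.getLogger(__name__)

TARGET_DATABASES = ("miranda", "mirbase", "mirtarget2", "pictar", "tarbase", "targetscan")


@dataclass(frozen=True)
class RegulatoryEdge:
    mirna_id: str
    gene_id: str
    spearman_rho: float
    p: float
    n_supporting_dbs: int

    def __post_init__(self) -> None:
        if not (self.spearman_rho < 0 and self.n_supporting_dbs >= 3):
            raise ValidationError("regulatory edge violates the sign/support constraints")


def rpm_log(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(reads-per-million + 1) per sample (column)."""
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        raise ValidationError("counts must be non-negative integers")
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        bad = counts.columns[totals <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero total counts")
    rpm = values / totals * 1e6
    return pd.DataFrame(np.log2(rpm + 1.0), index=counts.index, columns=counts.columns)


def mirna_de(log_rpm: pd.DataFrame, grades: Mapping[str, str], alpha: float = 0.05) -> DEResult:
    """Moderated two-group differential miRNA expression (no stratum term).

    Zero-variance miRNAs are excluded with a warning before fitting.
    """
    variances = log_rpm.to_numpy(dtype=float).var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = list(log_rpm.index[~keep])
        log.warning("excluding %d constant miRNAs from DE: %s...", len(dropped), dropped[:3])
    return moderated_de(log_rpm.loc[log_rpm.index[keep]], grades, strata=None, alpha=alpha)


def _shared_samples(mirna: pd.DataFrame, genes: pd.DataFrame, min_shared: int = 5) -> list[str]:
    shared = [s for s in mirna.columns if s in set(genes.columns)]
    if len(shared) < min_shared:
        raise ValidationError(f"only {len(shared)} shared samples; need >= {min_shared}")
    return shared


def infer_network(
    mirna_log_rpm: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    evidence: pd.DataFrame,
    min_dbs: int = 3,
    alpha: float = 0.05,
) -> list[RegulatoryEdge]:
    """Regulatory edges: negative Spearman correlation with database support.

    ``evidence`` has columns mirna_id, gene_id, source_db; a pair is tested
    only when supported by >= ``min_dbs`` distinct databases, and retained
    when rho < 0 with p < ``alpha`` over the shared samples.
    """
    shared = _shared_samples(mirna_log_rpm, gene_matrix)
    support = (
        evidence.drop_duplicates(["mirna_id", "gene_id", "source_db"])
        .groupby(["mirna_id", "gene_id"])
        .size()
    )
    edges: list[RegulatoryEdge] = []
    for (mirna_id, gene_id), n_dbs in support.items():
        if n_dbs < min_dbs:
            continue
        if mirna_id not in mirna_log_rpm.index or gene_id not in gene_matrix.index:
            continue
        x = mirna_log_rpm.loc[mirna_id, shared].to_numpy(dtype=float)
        y = gene_matrix.loc[gene_id, shared].to_numpy(dtype=float)
        rho, p = sps.spearmanr(x, y)
        if np.isnan(rho):
            continue
        if rho < 0 and p < alpha:
            edges.append(RegulatoryEdge(mirna_id, gene_id, float(rho), float(p), int(n_dbs)))
    return edges


def neg_vs_pos_counts(
    mirna_log_rpm: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    evidence: pd.DataFrame,
    min_dbs: int = 3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float | None]:
    """Per-miRNA counts of significantly negative vs positive targets.

    For each miRNA with database-supported targets, count targets whose
    Spearman correlation is significant (raw p < alpha) split by sign, then
    compare the two counts across miRNAs with a paired Wilcoxon signed-rank
    test (one-sided: negative exceeds positive).
    """
    shared = _shared_samples(mirna_log_rpm, gene_matrix)
    support = (
        evidence.drop_duplicates(["mirna_id", "gene_id", "source_db"])
        .groupby(["mirna_id", "gene_id"])
        .size()
    )
    rows: dict[str, dict[str, int]] = {}
    for (mirna_id, gene_id), n_dbs in support.items():
        if n_dbs < min_dbs:
            continue
        if mirna_id not in mirna_log_rpm.index or gene_id not in gene_matrix.index:
            continue
        x = mirna_log_rpm.loc[mirna_id, shared].to_numpy(dtype=float)
        y = gene_matrix.loc[gene_id, shared].to_numpy(dtype=float)
        rho, p = sps.spearmanr(x, y)
        entry = rows.setdefault(mirna_id, {"negative": 0, "positive": 0})
        if np.isnan(rho) or p >= alpha:
            continue
        entry["negative" if rho < 0 else "positive"] += 1
    counts = pd.DataFrame.from_dict(rows, orient="index").rename_axis("mirna_id")
    if len(counts) < 2 or (counts["negative"] == counts["positive"]).all():
        log.warning("too few informative miRNAs for the paired test; skipped")
        return counts, None
    stat = sps.wilcoxon(
        counts["negative"], counts["positive"], alternative="greater", zero_method="wilcox"
    )
    return counts, float(stat.pvalue)


def band_cluster(
    mirna_coords: pd.DataFrame,
    band_chrom: str,
    band_start: int,
    band_end: int,
    mirna_log_rpm: pd.DataFrame | None = None,
    band_loss_status: Mapping[str, bool] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """miRNAs inside a cytogenetic band, optionally flagged as CNV-driven.

    ``mirna_coords`` has columns chrom, start, end indexed by miRNA id.  A
    member is CNV-driven when its expression differs between samples with
    and without the band loss (two-sided rank-sum p < alpha).
    """
    in_band = (
        (mirna_coords["chrom"] == band_chrom)
        & (mirna_coords["start"] <= band_end)
        & (mirna_coords["end"] >= band_start)
    )
    members = mirna_coords.index[in_band]
    out = pd.DataFrame(index=members)
    out["cnv_driven"] = False
    out["p"] = np.nan
    if mirna_log_rpm is None or band_loss_status is None:
        return out
    lost = [s for s in mirna_log_rpm.columns if band_loss_status.get(s, False)]
    intact = [s for s in mirna_log_rpm.columns if not band_loss_status.get(s, False)]
    if not lost or not intact:
        return out
    for m in members:
        if m not in mirna_log_rpm.index:
            continue
        x = mirna_log_rpm.loc[m, lost].to_numpy(dtype=float)
        y = mirna_log_rpm.loc[m, intact].to_numpy(dtype=float)
        if np.var(np.concatenate([x, y])) == 0:
            continue
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        out.loc[m, "p"] = p
        out.loc[m, "cnv_driven"] = p < alpha
    return out


def pair_correlation(
    mirna_id: str,
    gene_id: str,
    mirna_log_rpm: pd.DataFrame,
    gene_matrix: pd.DataFrame,
) -> tuple[float, float]:
    """Spearman correlation of one miRNA/gene pair over shared samples."""
    shared = _shared_samples(mirna_log_rpm, gene_matrix)
    x = mirna_log_rpm.loc[mirna_id, shared].to_numpy(dtype=float)
    y = gene_matrix.loc[gene_id, shared].to_numpy(dtype=float)
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
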