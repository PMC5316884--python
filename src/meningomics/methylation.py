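"""DNA methylation QC, differential methylation, consensus clustering and
regulatory-domain gene-set enrichment.

Beta values (methylated fraction per CpG) are QC-filtered, tested on the
variance-stabilising M-value scale with the shared moderated-t engine and
called differential only when both the adjusted p (< 0.05) and the median
beta difference (> 0.1) thresholds are met.  Sample subgroups come from
consensus clustering: repeated 80%-subsampled average-linkage hierarchical
clustering on Pearson-correlation distance, with the co-clustering
frequency matrix clustered for the final labels.  Site sets are tested for
enrichment with a GREAT-style basal-plus-extension regulatory-domain
hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError
from .expression import moderated_de
from .stats import bh_fdr

__all__ = [
    "ConsensusResult",
    "RegionGeneSet",
    "site_qc",
    "diff_methylation",
    "consensus_cluster",
    "hypermeth_pga_correlation",
    "region_enrichment",
    "region_mask_sensitivity",
    "build_regulatory_domains",
]

log = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame  # samples x samples, co-clustering frequency
    labels: pd.Series  # sample -> cluster id for the chosen k
    k: int
    per_k: pd.DataFrame  # k, mean within-cluster consensus


@dataclass(frozen=True)
class RegionGeneSet:
    """A named gene set with per-gene regulatory domains (0-based half-open)."""

    name: str
    genes: tuple[str, ...]
    domains: tuple[tuple[str, int, int], ...]  # (chrom, start, end) per gene


def site_qc(
    beta: pd.DataFrame,
    site_info: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    detection_alpha: float = 0.05,
    fail_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter CpG sites: missing values, SNP overlap, sex chromosomes and
    sites failing detection (p > 0.05) in at least half the samples.

    ``site_info`` is indexed by site id with columns chrom and, optionally,
    the boolean flag snp_overlap.  Returns the filtered matrix and removal
    counts by reason (a site is counted under the first rule it fails).
    """
    report = {"missing": 0, "snp_overlap": 0, "sex_chrom": 0, "detection": 0, "retained": 0}
    keep: list[str] = []
    snp_flags = site_info.get("snp_overlap")
    for site in beta.index:
        row = beta.loc[site]
        if row.isna().any():
            report["missing"] += 1
            continue
        if snp_flags is not None and bool(snp_flags.get(site, False)):
            report["snp_overlap"] += 1
            continue
        if str(site_info.loc[site, "chrom"]) in SEX_CHROMS:
            report["sex_chrom"] += 1
            continue
        if detection_p is not None:
            frac_fail = float((detection_p.loc[site] > detection_alpha).mean())
            if frac_fail >= fail_fraction:
                report["detection"] += 1
                continue
        keep.append(site)
    report["retained"] = len(keep)
    return beta.loc[keep], report


def m_values(beta: pd.DataFrame, clip: tuple[float, float] = (0.01, 0.99)) -> pd.DataFrame:
    """Logit transform log2(beta/(1-beta)) with beta clipped away from 0/1."""
    b = np.clip(beta.to_numpy(dtype=float), clip[0], clip[1])
    return pd.DataFrame(np.log2(b / (1.0 - b)), index=beta.index, columns=beta.columns)


def diff_methylation(
    beta: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    min_delta_beta: float = 0.1,
) -> pd.DataFrame:
    """Differentially methylated sites with the dual threshold.

    The test runs on M-values; the effect-size gate is the difference of
    group median beta values.  A site is called hyper/hypo (relative to the
    first group level alphabetically) only when adjusted p < alpha AND
    |delta median beta| > min_delta_beta.
    """
    de = moderated_de(m_values(beta), groups, strata=None, alpha=alpha)
    levels = sorted(set(groups[s] for s in beta.columns))
    g1 = [s for s in beta.columns if groups[s] == levels[0]]
    g2 = [s for s in beta.columns if groups[s] == levels[1]]
    delta = beta[g1].median(axis=1) - beta[g2].median(axis=1)
    out = de.table.copy()
    out["delta_beta"] = delta
    called = (out["fdr"] < alpha) & (delta.abs() > min_delta_beta)
    out["call"] = np.where(~called, "none", np.where(delta > 0, "hyper", "hypo"))
    return out


def _pearson_distance(columns: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distance between columns of a matrix."""
    corr = np.corrcoef(columns.T)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return squareform(dist, checks=False)


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4),
    n_iter: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    chosen_k: int | None = None,
) -> ConsensusResult:
    """Consensus clustering by subsampled hierarchical clustering.

    Per iteration a fraction of samples is drawn without replacement and
    clustered by average linkage on 1 - Pearson correlation distance; the
    consensus entry for a sample pair is the co-cluster count divided by the
    co-sampling count.  Final labels come from average-linkage clustering of
    1 - consensus.  ``chosen_k`` defaults to the k with the highest mean
    within-cluster consensus.
    """
    samples = list(matrix.columns)
    n = len(samples)
    k_range = sorted(set(int(k) for k in k_range))
    if max(k_range) > n:
        raise ValidationError(f"k={max(k_range)} exceeds sample count {n}")
    if n < 2 * max(k_range):
        raise ValidationError("need >= 2*k samples for consensus clustering")
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float)
    m = max(2, int(round(subsample * n)))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1
        dist = _pearson_distance(values[:, idx])
        link = average(dist)
        for k in k_range:
            labels = fcluster(link, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    results: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    per_k_rows = []
    for k in k_range:
        with np.errstate(invalid="ignore"):
            consensus = np.where(co_sampled > 0, co_cluster[k] / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        link = average(squareform(1.0 - consensus, checks=False))
        labels = fcluster(link, t=k, criterion="maxclust")
        within = []
        for c in np.unique(labels):
            members = np.where(labels == c)[0]
            if len(members) > 1:
                block = consensus[np.ix_(members, members)]
                within.append(block[np.triu_indices(len(members), 1)].mean())
        mean_within = float(np.mean(within)) if within else 1.0
        per_k_rows.append({"k": k, "mean_within_consensus": mean_within})
        results[k] = (consensus, labels, mean_within)

    per_k = pd.DataFrame(per_k_rows)
    if chosen_k is None:
        chosen_k = int(per_k.loc[per_k["mean_within_consensus"].idxmax(), "k"])
    consensus, labels, _ = results[chosen_k]
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        labels=pd.Series(labels, index=samples, name="cluster"),
        k=chosen_k,
        per_k=per_k,
    )


def hypermeth_pga_correlation(
    beta: pd.DataFrame,
    reference_samples: Sequence[str],
    pga: Mapping[str, float],
    delta: float = 0.1,
) -> tuple[pd.Series, float, float]:
    """Couple genome-wide hypermethylation to chromosomal instability.

    The per-sample hypermethylation fraction is the share of QC-passing
    sites with beta exceeding the reference-group median by more than
    ``delta``; it is Pearson-correlated with PGA across samples.  Returns
    (fractions, rho, p); rho/p are NaN when either variable is constant.
    """
    ref = [s for s in reference_samples if s in beta.columns]
    if not ref:
        raise ValidationError("reference group is empty")
    ref_median = beta[ref].median(axis=1)
    frac = (beta.gt(ref_median + delta, axis=0)).mean(axis=0)
    frac.name = "hypermethylation_fraction"
    samples = [s for s in beta.columns if s in pga]
    x = frac[samples].to_numpy(dtype=float)
    y = np.array([pga[s] for s in samples], dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        log.warning("constant hypermethylation fraction or PGA; correlation undefined")
        return frac, float("nan"), float("nan")
    rho, p = sps.pearsonr(x, y)
    return frac, float(rho), float(p)


def build_regulatory_domains(
    gene_coords: pd.DataFrame,
    basal_upstream: int = 5_000,
    basal_downstream: int = 1_000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domain per gene.

    ``gene_coords`` has columns chrom, start, end, strand (0-based
    half-open) indexed by gene.  The basal domain spans 5 kb upstream to
    1 kb downstream of the TSS; it is extended in both directions up to
    1 Mb but not into the neighbouring gene's basal domain.
    """
    rows = []
    for gene, g in gene_coords.iterrows():
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"])
        if g["strand"] == "+":
            basal = (tss - basal_upstream, tss + basal_downstream)
        else:
            basal = (tss - basal_downstream, tss + basal_upstream)
        rows.append({"gene": gene, "chrom": g["chrom"], "basal_start": max(0, basal[0]), "basal_end": basal[1]})
    basal_df = pd.DataFrame(rows).set_index("gene")
    ext_start = basal_df["basal_start"].copy()
    ext_end = basal_df["basal_end"].copy()
    for chrom, grp in basal_df.groupby("chrom"):
        order = grp.sort_values("basal_start").index
        for i, gene in enumerate(order):
            left_limit = basal_df.loc[gene, "basal_start"] - max_extension
            right_limit = basal_df.loc[gene, "basal_end"] + max_extension
            if i > 0:
                left_limit = max(left_limit, basal_df.loc[order[i - 1], "basal_end"])
            if i < len(order) - 1:
                right_limit = min(right_limit, basal_df.loc[order[i + 1], "basal_start"])
            # extension never shrinks the basal domain itself
            ext_start[gene] = max(0, min(left_limit, basal_df.loc[gene, "basal_start"]))
            ext_end[gene] = max(right_limit, basal_df.loc[gene, "basal_end"])
    out = basal_df.copy()
    out["domain_start"] = ext_start
    out["domain_end"] = ext_end
    return out


def _sites_in_domains(sites: pd.DataFrame, domains: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    """Boolean mask over ``sites`` (chrom, pos) hitting any gene's domain."""
    sub = domains.loc[[g for g in genes if g in domains.index]]
    mask = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sub.groupby("chrom"):
        site_sel = sites["chrom"] == chrom
        if not site_sel.any():
            continue
        pos = sites.loc[site_sel, "pos"].to_numpy(dtype=int)
        hit = np.zeros(len(pos), dtype=bool)
        for _, d in grp.iterrows():
            hit |= (pos >= d["domain_start"]) & (pos < d["domain_end"])
        mask[np.asarray(site_sel)] = hit
    return mask


def region_enrichment(
    query_sites: pd.DataFrame,
    background_sites: pd.DataFrame,
    gene_sets: Sequence[RegionGeneSet] | Mapping[str, Sequence[str]],
    gene_domains: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hypergeometric regulatory-domain enrichment of query vs background sites.

    Sites are (chrom, pos) tables with the query a subset of the
    background.  A site hits a set when it falls inside any member gene's
    regulatory domain.  Gene sets may be RegionGeneSet objects (carrying
    their own domains) or a name -> gene-list mapping with ``gene_domains``
    from :func:`build_regulatory_domains`.
    """
    if len(background_sites) == 0:
        raise ValidationError("background site set is empty")
    n_query, n_bg = len(query_sites), len(background_sites)
    rows = []
    if isinstance(gene_sets, Mapping):
        if gene_domains is None:
            raise ValidationError("gene_domains required when gene_sets is a mapping")
        items = [(name, tuple(genes), None) for name, genes in gene_sets.items()]
    else:
        items = [(gs.name, gs.genes, gs.domains) for gs in gene_sets]
    for name, genes, explicit_domains in items:
        if explicit_domains is not None:
            dom = pd.DataFrame(
                [{"chrom": c, "domain_start": s, "domain_end": e} for c, s, e in explicit_domains],
                index=pd.Index(genes[: len(explicit_domains)], name="gene"),
            )
        else:
            dom = gene_domains
        q_hits = int(_sites_in_domains(query_sites, dom, genes).sum())
        b_hits = int(_sites_in_domains(background_sites, dom, genes).sum())
        # P(X >= q_hits) drawing n_query from n_bg with b_hits marked
        p = float(sps.hypergeom.sf(q_hits - 1, n_bg, b_hits, n_query))
        fold = (q_hits / n_query) / (b_hits / n_bg) if n_query and b_hits else float("nan")
        rows.append({"set": name, "query_hits": q_hits, "background_hits": b_hits, "fold": fold, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def region_mask_sensitivity(
    beta: pd.DataFrame,
    site_info: pd.DataFrame,
    excluded_chroms: Sequence[str],
    reference_labels: pd.Series,
    k: int,
    n_iter: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
) -> tuple[float, ConsensusResult]:
    """Robustness of clustering to removing CNV-affected chromosomes.

    Re-runs consensus clustering after dropping sites on the excluded
    chromosomes and reports the adjusted Rand index against the reference
    labels.
    """
    excluded = set(excluded_chroms)
    keep = [s for s in beta.index if str(site_info.loc[s, "chrom"]) not in excluded]
    if len(keep) < 0.1 * len(beta.index):
        log.warning("masking removed >90%% of sites (%d of %d retained)", len(keep), len(beta))
    masked = beta.loc[keep]
    result = consensus_cluster(masked, k_range=(k,), n_iter=n_iter, subsample=subsample, seed=seed, chosen_k=k)
    ari = float(adjusted_rand_score(reference_labels[result.labels.index], result.labels))
    return ari, result
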