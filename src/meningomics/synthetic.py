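"""Seeded synthetic meningioma cohorts with planted ground truth.

The generator emits every input the pipeline consumes — sample sheet,
somatic variant table, CNV segments and per-SNP BAFs, expression / miRNA /
methylation matrices with coordinate sidecars, and H3K27ac peak sets — on a
reduced toy genome (22 autosomes, two arms each, 130 Mb per chromosome).
Planted structure mirrors the biology of primary atypical meningioma:
mutually exclusive driver subgroups with NF2/chr22 loss dominant in
atypical samples, arm-level instability concentrated in CNV-high samples
(14q loss enriched in atypical), admixture-diluted BAFs, a down-regulated
chr14q32 miRNA cluster with anti-correlated targets, a hypermethylated
sample cluster coupled to CNV burden, let-7 loss coupled to EZH2 gain, and
enhancer signal coupled to expression.  All randomness flows from one seed;
identical (config, seed) gives byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "PlantedEffects",
    "GroundTruth",
    "default_arm_table",
    "generate_cohort",
    "simulate_baf",
    "simulate_regulator_decoy",
]

CHROM_LENGTH = 130_000_000
P_ARM_END = 60_000_000
_FLOAT_FMT = "%.6g"

# fixed clean 31-mer context (variant at centre, no homopolymer)
_CLEAN_CONTEXT = ("ACGT" * 8)[:31]


def default_arm_table() -> pd.DataFrame:
    """Toy genome: 22 autosomes, p arm 1-60 Mb, q arm 60 Mb-130 Mb."""
    rows = []
    for i in range(1, 23):
        chrom = f"chr{i}"
        rows.append({"chrom": chrom, "arm": "p", "start": 1, "end": P_ARM_END})
        rows.append({"chrom": chrom, "arm": "q", "start": P_ARM_END + 1, "end": CHROM_LENGTH})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlantedEffects:
    """Effect sizes planted per assay (defaults are the study conditions)."""

    # expression
    n_genes: int = 2000
    n_de_genes: int = 50
    expression_logfc: float = 2.0
    expression_sd: float = 0.5
    batch_shift: float = 1.0
    # miRNA
    n_mirnas: int = 150
    n_cluster_mirnas: int = 28  # chr14q32 members
    mirna_cluster_logfc: float = -1.0
    n_up_mirnas: int = 13
    mirna_up_logfc: float = 1.0
    mirna_sd: float = 0.4
    # methylation
    n_meth_sites: int = 2000
    n_dm_sites: int = 300
    delta_beta: float = 0.3
    beta_sd: float = 0.05
    # enhancers
    n_enhancer_loci: int = 60
    n_super_loci: int = 5
    n_diff_super: int = 3
    enhancer_multiplier: float = 4.0
    chip_noise_sd: float = 0.25
    # H3K27me3
    n_broad_bins: int = 300
    broad_shift: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    n_atypical: int = 20
    n_benign: int = 20
    seed: int = 0
    purity_range: tuple[float, float] = (0.5, 0.9)
    arm_table: pd.DataFrame = field(default_factory=default_arm_table)
    planted_effects: PlantedEffects = field(default_factory=PlantedEffects)
    fraction_cnv_high: Mapping[str, float] = field(
        default_factory=lambda: {"atypical": 0.7, "benign": 0.2}
    )
    p_14q_loss: Mapping[str, float] = field(
        default_factory=lambda: {"atypical": 0.6, "benign": 0.1}
    )
    n_batches: int = 2
    snp_per_bp: float = 1.0 / 250_000  # het-SNP density for BAF tables
    snp_depth: int = 500

    def validate(self) -> None:
        if self.n_atypical < 2:
            raise ConfigurationError("n_atypical must be >= 2")
        if self.n_benign < 2:
            raise ConfigurationError("n_benign must be >= 2")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("purity_range values must lie in (0, 1] with lo <= hi")
        for grade, frac in self.fraction_cnv_high.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"fraction_cnv_high[{grade!r}] must lie in [0, 1]")
        arm = self.arm_table
        for chrom, grp in arm.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ConfigurationError(f"arm_table has overlapping arms on {chrom}")


@dataclass
class GroundTruth:
    """Planted truth, reproducible from (CohortConfig, seed)."""

    samples: pd.DataFrame  # sample_id, grade, batch, subgroup, purity, cnv_high, pga, meth_cluster, loss_14q
    events: dict[str, list[tuple[str, str, str]]]  # sample -> (chrom, arm, class)
    de_genes: dict[str, int]  # gene -> +1/-1 (atypical - benign direction)
    de_mirnas: dict[str, int]
    mirna_targets: list[tuple[str, str]]
    dm_sites: dict[str, int]
    meth_clusters: pd.Series  # sample -> cluster label
    super_loci: list[str]
    diff_super_loci: list[str]


def simulate_baf(
    depth: int,
    purity: float,
    tumour_cn: int,
    n_snps: int,
    seed: int,
) -> np.ndarray:
    """Binomial BAF draws at blood-heterozygous SNPs in a CNV region.

    Each SNP is heterozygous in the normal; the tumour carries
    ``tumour_cn`` copies with the imbalanced allele chosen at random per
    SNP.  The read-level B-allele fraction is the admixture-weighted allele
    fraction; BAFs are Binomial(depth, f)/depth.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    if tumour_cn not in {0, 1, 2, 3, 4}:
        raise ConfigurationError("tumour_cn must be in {0,1,2,3,4}")
    if not 0 <= purity <= 1:
        raise ConfigurationError("purity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    b_copies_options = {0: [0], 1: [0, 1], 2: [1], 3: [1, 2], 4: [1, 3]}[tumour_cn]
    b = rng.choice(b_copies_options, size=n_snps)
    denom = purity * tumour_cn + (1 - purity) * 2
    if denom == 0:  # pure tumour with total loss: no reads from the locus
        return np.full(n_snps, np.nan)
    f = (purity * b + (1 - purity) * 1) / denom
    return rng.binomial(depth, f) / depth


# ---------------------------------------------------------------------------
# subgroup planting

_ATYPICAL_SUBGROUPS = [("NF2", 0.55), ("NF2/SMARCB1", 0.20), ("TRAF7/PI3K", 0.15), ("unknown", 0.10)]
_BENIGN_SUBGROUPS = [
    ("NF2", 0.40),
    ("TRAF7/PI3K", 0.15),
    ("TRAF7/KLF4", 0.15),
    ("Hedgehog", 0.10),
    ("POLR2A", 0.10),
    ("unknown", 0.10),
]

_DRIVER_VARIANTS: dict[str, list[dict]] = {
    # gene, chrom, pos, consequence, protein change; NF2 sits on the lost 22q arm
    "NF2": [dict(gene="NF2", chrom="chr22", pos=65_000_000, consequence="frameshift_variant", protein="p.Trp60fs")],
    "NF2/SMARCB1": [
        dict(gene="NF2", chrom="chr22", pos=65_000_000, consequence="frameshift_variant", protein="p.Trp60fs"),
        dict(gene="SMARCB1", chrom="chr22", pos=24_000_000, consequence="missense_variant_damaging", protein="p.Arg383Gln"),
    ],
    "TRAF7/PI3K": [
        dict(gene="TRAF7", chrom="chr16", pos=2_200_000, consequence="missense_variant_damaging", protein="p.Asn520Ser"),
        dict(gene="PIK3CA", chrom="chr3", pos=110_000_000, consequence="missense_variant_damaging", protein="p.His1047Arg"),
    ],
    "TRAF7/KLF4": [
        dict(gene="TRAF7", chrom="chr16", pos=2_200_000, consequence="missense_variant_damaging", protein="p.Asn520Ser"),
        dict(gene="KLF4", chrom="chr9", pos=80_000_000, consequence="missense_variant_damaging", protein="p.Lys409Gln"),
    ],
    "Hedgehog": [dict(gene="SMO", chrom="chr7", pos=100_000_000, consequence="missense_variant_damaging", protein="p.Leu412Phe")],
    "POLR2A": [dict(gene="POLR2A", chrom="chr17", pos=7_400_000, consequence="missense_variant_damaging", protein="p.Gln403Lys")],
    "unknown": [],
}

_BASES = np.array(list("ACGT"))


def _allocate(labels_fracs: Sequence[tuple[str, float]], n: int) -> list[str]:
    """Deterministic largest-remainder allocation of n samples to labels."""
    raw = [(label, frac * n) for label, frac in labels_fracs]
    counts = {label: int(np.floor(x)) for label, x in raw}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda lf: (-(lf[1] - np.floor(lf[1])), lf[0]))
    for label, _ in by_frac[:remainder]:
        counts[label] += 1
    out: list[str] = []
    for label, _ in labels_fracs:
        out.extend([label] * counts[label])
    return out


def _loss_logr(purity: float) -> float:
    return float(np.log2((purity * 1 + (1 - purity) * 2) / 2.0))


def _expected_dev(purity: float) -> float:
    return 0.5 - (1 - purity) / (2 - purity)


def _plant_samples(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for grade, n, prefix, fracs in (
        ("atypical", config.n_atypical, "AT", _ATYPICAL_SUBGROUPS),
        ("benign", config.n_benign, "BN", _BENIGN_SUBGROUPS),
    ):
        subgroups = _allocate(fracs, n)
        n_high = int(round(config.fraction_cnv_high.get(grade, 0.0) * n))
        for i in range(n):
            sample_id = f"{prefix}{i + 1:03d}"
            purity = float(rng.uniform(*config.purity_range))
            loss_14q = bool(rng.random() < config.p_14q_loss.get(grade, 0.0))
            rows.append(
                {
                    "sample_id": sample_id,
                    "grade": grade,
                    "recurrence": "primary",
                    "batch": f"batch{i % config.n_batches + 1}",
                    "subgroup": subgroups[i],
                    "purity": purity,
                    "cnv_high": i < n_high,
                    "loss_14q": loss_14q,
                }
            )
    return pd.DataFrame(rows)


_HIGH_INSTABILITY_ARMS = [("chr1", "p"), ("chr10", "p"), ("chr10", "q"), ("chr6", "q")]


def _plant_events(samples: pd.DataFrame, arm_table: pd.DataFrame) -> dict[str, list[tuple[str, str, str]]]:
    events: dict[str, list[tuple[str, str, str]]] = {}
    for _, s in samples.iterrows():
        ev: list[tuple[str, str, str]] = []
        if s["subgroup"].startswith("NF2"):
            ev.append(("chr22", "q", "large_loss"))
        if s["loss_14q"]:
            ev.append(("chr14", "q", "large_loss"))
        if s["cnv_high"]:
            for chrom, arm in _HIGH_INSTABILITY_ARMS:
                ev.append((chrom, arm, "large_loss"))
        events[s["sample_id"]] = ev
    return events


def _arm_bounds(arm_table: pd.DataFrame, chrom: str, arm: str) -> tuple[int, int]:
    row = arm_table[(arm_table["chrom"] == chrom) & (arm_table["arm"] == arm)].iloc[0]
    return int(row["start"]), int(row["end"])


def _true_pga(events: Sequence[tuple[str, str, str]], arm_table: pd.DataFrame) -> float:
    total = int((arm_table["end"] - arm_table["start"] + 1).sum())
    altered = 0
    for chrom, arm, klass in events:
        if klass in {"large_loss", "large_gain", "focal_loss", "focal_gain"}:
            lo, hi = _arm_bounds(arm_table, chrom, arm)
            altered += hi - lo + 1
    return 100.0 * altered / total


def _make_segments_and_baf(
    samples: pd.DataFrame,
    events: Mapping[str, Sequence[tuple[str, str, str]]],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    seg_rows, baf_rows = [], []
    arm_table = config.arm_table
    for _, s in samples.iterrows():
        sample, purity = s["sample_id"], s["purity"]
        lost = {(c, a) for c, a, _ in events[sample]}
        for _, arm_row in arm_table.iterrows():
            chrom, arm = arm_row["chrom"], arm_row["arm"]
            lo, hi = int(arm_row["start"]), int(arm_row["end"])
            is_loss = (chrom, arm) in lost
            cn = 1 if is_loss else 2
            logr = _loss_logr(purity) if is_loss else 0.0
            logr += float(rng.normal(0, 0.02))
            seg_rows.append({"sample_id": sample, "chrom": chrom, "start": lo, "end": hi, "logr": logr})
            n_snps = max(20, int((hi - lo + 1) * config.snp_per_bp))
            bafs = simulate_baf(config.snp_depth, purity, cn, n_snps, seed=int(rng.integers(2**31)))
            positions = np.linspace(lo, hi, n_snps, dtype=int)
            for pos, baf in zip(positions, bafs):
                baf_rows.append({"sample_id": sample, "chrom": chrom, "pos": int(pos), "baf": float(baf)})
    return pd.DataFrame(seg_rows), pd.DataFrame(baf_rows)


def _make_variants(
    samples: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Driver plus passenger somatic calls with clean cascade annotations."""
    rows = []
    substitutions = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
    for _, s in samples.iterrows():
        sample, purity = s["sample_id"], s["purity"]
        planted = [dict(d, clonal=True) for d in _DRIVER_VARIANTS[s["subgroup"]]]
        n_passengers = int(rng.poisson(30))
        for _ in range(n_passengers):
            chrom = f"chr{rng.integers(1, 23)}"
            ref, alt = substitutions[rng.integers(len(substitutions))]
            planted.append(
                dict(
                    gene=f"PSG{rng.integers(1, 500):04d}",
                    chrom=chrom,
                    pos=int(rng.integers(1, CHROM_LENGTH)),
                    consequence="missense_variant" if rng.random() < 0.7 else "synonymous_variant",
                    protein="p.?",
                    ref=ref,
                    alt=alt,
                    clonal=bool(rng.random() < 0.7),
                )
            )
        for v in planted:
            cn = 1 if (v["chrom"] == "chr22" and s["subgroup"].startswith("NF2")) else 2
            ccf = 1.0 if v["clonal"] else 0.5
            denom = purity * cn + (1 - purity) * 2
            vaf = ccf * purity * 1 / denom
            depth = int(rng.integers(120, 250))
            alt_depth = int(rng.binomial(depth, vaf))
            normal_depth = int(rng.integers(80, 160))
            # log10 genotype likelihoods from read counts under f in {.001,.5,.999}
            def gl(alt_k: int, n: int) -> tuple[float, float, float]:
                out = []
                for fgeno in (0.001, 0.5, 0.999):
                    out.append(alt_k * np.log10(fgeno) + (n - alt_k) * np.log10(1 - fgeno))
                m = max(out)
                return tuple(round(x - m, 3) for x in out)
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": v["chrom"],
                    "pos": v["pos"],
                    "ref": v.get("ref", "C"),
                    "alt": v.get("alt", "T"),
                    "tumour_ref_depth": depth - alt_depth,
                    "tumour_alt_depth": alt_depth,
                    "normal_ref_depth": normal_depth,
                    "normal_alt_depth": 0,
                    "tumour_gl": ",".join(f"{x:.3f}" for x in gl(alt_depth, depth)),
                    "normal_gl": ",".join(f"{x:.3f}" for x in gl(0, normal_depth)),
                    "qual": 100.0,
                    "qd": 5.0,
                    "mq0": 0,
                    "strand_bias_phred": 1.0,
                    "clipping_rank_sum": 0.0,
                    "repeat_masked": False,
                    "segdup": False,
                    "context_seq": _CLEAN_CONTEXT,
                    "pop_af_max": 0.0,
                    "internal_gene_allele_count": 5,
                    "consequence_terms": v["consequence"],
                    "gene": v["gene"],
                    "protein_change": v["protein"],
                    "true_clonal": v["clonal"],
                    "true_cn": cn,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["sample_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _make_expression(
    samples: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int], np.ndarray]:
    fx = config.planted_effects
    genes = [f"GENE{i + 1:04d}" for i in range(fx.n_genes)]
    genes[0] = "EZH2"  # planted up-regulated PRC2 catalytic subunit
    n = len(samples)
    base = rng.normal(8.0, 1.0, size=fx.n_genes)
    values = base[:, None] + rng.normal(0, fx.expression_sd, size=(fx.n_genes, n))
    is_atypical = (samples["grade"] == "atypical").to_numpy()
    de_genes: dict[str, int] = {"EZH2": 1}
    # the last 100 genes are reserved for miRNA-target coupling
    de_idx = [0] + list(rng.choice(np.arange(1, fx.n_genes - 100), size=fx.n_de_genes - 1, replace=False))
    for rank, gi in enumerate(de_idx):
        direction = 1 if rank % 2 == 0 else -1
        de_genes[genes[gi]] = direction
        values[gi, is_atypical] += direction * fx.expression_logfc
    # additive batch shift (mirrors the simplified correction downstream)
    batch2 = (samples["batch"] == "batch2").to_numpy()
    values[:, batch2] += fx.batch_shift
    coords = pd.DataFrame(
        {
            "gene": genes,
            "chrom": [f"chr{(i % 22) + 1}" for i in range(fx.n_genes)],
            "start": [1_000_000 + (i // 22) * 200_000 for i in range(fx.n_genes)],
            "end": [1_000_000 + (i // 22) * 200_000 + 20_000 for i in range(fx.n_genes)],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(fx.n_genes)],
        }
    ).set_index("gene")
    matrix = pd.DataFrame(values, index=genes, columns=samples["sample_id"])
    return matrix, coords, de_genes, base


def _make_mirna(
    samples: pd.DataFrame,
    expression: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int], list[tuple[str, str]]]:
    fx = config.planted_effects
    n = len(samples)
    is_atypical = (samples["grade"] == "atypical").to_numpy()
    loss_14q = samples["loss_14q"].to_numpy()

    cluster = [f"mir-14q32-{i + 1}" for i in range(fx.n_cluster_mirnas)]
    let7 = ["let-7a-5p", "let-7b-5p", "let-7c-5p", "let-7d-5p", "let-7e-5p"]
    n_other = fx.n_mirnas - len(cluster) - len(let7)
    others = [f"mir-{i + 1:04d}-5p" for i in range(n_other)]
    mirnas = cluster + let7 + others

    latent = rng.normal(6.0, 1.0, size=len(mirnas))[:, None] + rng.normal(0, fx.mirna_sd, size=(len(mirnas), n))
    de_mirnas: dict[str, int] = {}
    for i, m in enumerate(cluster):
        latent[i, is_atypical] += fx.mirna_cluster_logfc
        latent[i, loss_14q] += -0.5  # copy-loss driving on top of the grade shift
        de_mirnas[m] = -1
    # let-7c/d/e down in atypical (let-7a unchanged, let-7b mildly down)
    let7_shifts = {"let-7b-5p": -0.4, "let-7c-5p": -0.6, "let-7d-5p": -0.7, "let-7e-5p": -0.8}
    for m, shift in let7_shifts.items():
        i = mirnas.index(m)
        latent[i, is_atypical] += shift
        de_mirnas[m] = -1
    up_idx = rng.choice(np.arange(len(cluster) + len(let7), len(mirnas)), size=fx.n_up_mirnas, replace=False)
    for i in up_idx:
        latent[i, is_atypical] += fx.mirna_up_logfc
        de_mirnas[mirnas[i]] = 1

    # EZH2 anti-coupled to let-7c
    i_let7c = mirnas.index("let-7c-5p")
    ezh2 = 10.0 - 0.8 * (latent[i_let7c] - latent[i_let7c].mean()) + rng.normal(0, 0.3, size=n)
    expression.loc["EZH2"] = ezh2

    # counts: negative binomial around RPM implied by the latent log2 scale
    totals = rng.integers(1_500_000, 2_500_000, size=n)
    mean_rpm = 2.0**latent
    mean_counts = mean_rpm * totals[None, :] / 1e6
    dispersion = 20.0
    p_nb = dispersion / (dispersion + mean_counts)
    counts = rng.negative_binomial(dispersion, p_nb)
    counts_df = pd.DataFrame(counts, index=mirnas, columns=samples["sample_id"])

    coords_rows = []
    for i, m in enumerate(mirnas):
        if m in cluster:
            start = 100_000_000 + cluster.index(m) * 150_000
            coords_rows.append({"mirna_id": m, "chrom": "chr14", "start": start, "end": start + 100})
        elif m == "let-7a-5p" or m == "let-7b-5p":
            coords_rows.append({"mirna_id": m, "chrom": "chr22", "start": 70_000_000, "end": 70_000_100})
        elif m == "let-7c-5p":
            coords_rows.append({"mirna_id": m, "chrom": "chr21", "start": 30_000_000, "end": 30_000_100})
        elif m == "let-7d-5p":
            coords_rows.append({"mirna_id": m, "chrom": "chr9", "start": 95_000_000, "end": 95_000_100})
        elif m == "let-7e-5p":
            coords_rows.append({"mirna_id": m, "chrom": "chr19", "start": 50_000_000, "end": 50_000_100})
        else:
            coords_rows.append(
                {"mirna_id": m, "chrom": f"chr{(i % 22) + 1}", "start": 5_000_000 + i * 10_000, "end": 5_000_100 + i * 10_000}
            )
    coords = pd.DataFrame(coords_rows).set_index("mirna_id")

    # evidence table: planted anti-coupled targets (4 dbs) + low-support decoys
    from .mirna import TARGET_DATABASES

    evidence_rows = []
    truth_pairs: list[tuple[str, str]] = []
    target_genes = list(expression.index[-40:-20])
    for k, m in enumerate(cluster[:10]):
        i = mirnas.index(m)
        for t in range(2):
            gene = target_genes[2 * k + t]
            coupled = 9.0 - 0.8 * (latent[i] - latent[i].mean()) + rng.normal(0, 0.3, size=n)
            expression.loc[gene] = coupled
            truth_pairs.append((m, gene))
            for db in TARGET_DATABASES[:4]:
                evidence_rows.append({"mirna_id": m, "gene_id": gene, "source_db": db})
    # decoys: independent expression, 2-db support only
    decoy_genes = list(expression.index[-20:])
    for k, gene in enumerate(decoy_genes):
        m = mirnas[len(cluster) + len(let7) + k]
        for db in TARGET_DATABASES[:2]:
            evidence_rows.append({"mirna_id": m, "gene_id": gene, "source_db": db})
    evidence = pd.DataFrame(evidence_rows)
    return counts_df, coords, evidence, de_mirnas, truth_pairs


def _make_methylation(
    samples: pd.DataFrame,
    pga: Mapping[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int], pd.Series]:
    fx = config.planted_effects
    n = len(samples)
    sites = [f"cg{i + 1:07d}" for i in range(fx.n_meth_sites)]
    base = rng.uniform(0.15, 0.55, size=fx.n_meth_sites)
    beta = base[:, None] + rng.normal(0, fx.beta_sd, size=(fx.n_meth_sites, n))

    hyper_cluster = (samples["cnv_high"] | (samples["subgroup"] == "NF2/SMARCB1")).to_numpy()
    meth_clusters = pd.Series(
        np.where(hyper_cluster, "hypermethylated", "low-methylation"),
        index=samples["sample_id"],
        name="meth_cluster",
    )
    # DM/cluster-driver sites kept off chr1/14/22 so masking those chromosomes
    # leaves the clustering intact
    non_masked_chroms = [f"chr{i}" for i in range(2, 22) if i != 14]
    chroms = [non_masked_chroms[i % len(non_masked_chroms)] if i < fx.n_dm_sites else f"chr{(i % 22) + 1}" for i in range(fx.n_meth_sites)]
    dm_sites = {sites[i]: 1 for i in range(fx.n_dm_sites)}
    beta[: fx.n_dm_sites][:, hyper_cluster] += fx.delta_beta

    # CNV-burden coupling: a second block elevated proportionally to PGA
    pga_arr = np.array([pga[s] for s in samples["sample_id"]])
    coupling = slice(fx.n_dm_sites, fx.n_dm_sites + 200)
    scale = pga_arr / max(pga_arr.max(), 1e-9)
    beta[coupling] += 0.25 * scale[None, :]

    beta = np.clip(beta, 0.0, 1.0)
    beta_df = pd.DataFrame(beta, index=sites, columns=samples["sample_id"])

    site_info = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": [2_000_000 + i * 50_000 for i in range(fx.n_meth_sites)],
            "snp_overlap": [i % 97 == 96 for i in range(fx.n_meth_sites)],
        },
        index=pd.Index(sites, name="site_id"),
    )
    detection = pd.DataFrame(
        rng.uniform(0, 0.04, size=(fx.n_meth_sites, n)), index=sites, columns=samples["sample_id"]
    )
    # plant a handful of detection failures (>=50% of samples failing)
    fail_sites = sites[-10:]
    n_fail = int(np.ceil(0.6 * n))
    detection.loc[fail_sites, detection.columns[:n_fail]] = 0.5
    return beta_df, site_info, detection, dm_sites, meth_clusters


def _make_chip(
    samples: pd.DataFrame,
    expression: pd.DataFrame,
    de_genes: dict[str, int],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str], list[str]]:
    """H3K27ac peak sets and signal matrix, TSS table, H3K27me3 bin matrix."""
    fx = config.planted_effects
    n = len(samples)
    is_atypical = (samples["grade"] == "atypical").to_numpy()

    loci = []
    for i in range(fx.n_enhancer_loci):
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000_000 + (i // 22) * 2_000_000
        n_peaks = 1 + i % 3
        loci.append((chrom, start, n_peaks))
    base_signal = rng.uniform(3.0, 8.0, size=fx.n_enhancer_loci)
    super_idx = list(rng.choice(fx.n_enhancer_loci, size=fx.n_super_loci, replace=False))
    for i in super_idx:
        base_signal[i] = rng.uniform(60.0, 90.0)
    diff_idx = super_idx[: fx.n_diff_super]

    locus_ids, region_rows = [], []
    peak_tables: dict[str, list[dict]] = {s: [] for s in samples["sample_id"]}
    signal = np.zeros((fx.n_enhancer_loci, n))
    for li, (chrom, start, n_peaks) in enumerate(loci):
        locus_id = f"{chrom}:{start}"
        locus_ids.append(locus_id)
        per_sample = base_signal[li] * 2.0 ** rng.normal(0, fx.chip_noise_sd, size=n)
        if li in diff_idx:
            per_sample = np.where(is_atypical, per_sample * fx.enhancer_multiplier, per_sample)
        signal[li] = per_sample
        for si, sample in enumerate(samples["sample_id"]):
            for pk in range(n_peaks):
                p_start = start + pk * 5_000
                peak_tables[sample].append(
                    {
                        "chrom": chrom,
                        "start": p_start,
                        "end": p_start + 1_500,
                        "signal": per_sample[si] / n_peaks,
                        "input_signal": 0.5,
                        "peak_id": f"{locus_id}.pk{pk}",
                    }
                )
    signal_df = pd.DataFrame(signal, index=locus_ids, columns=samples["sample_id"])

    # nearest genes: planted differential loci point at planted up genes
    up_genes = [g for g, d in de_genes.items() if d > 0 and g != "EZH2"]
    tss_rows = []
    for li, (chrom, start, _) in enumerate(loci):
        if li in diff_idx:
            gene = up_genes[diff_idx.index(li) % len(up_genes)]
        else:
            gene = f"NEARBY{li:03d}"
        tss_rows.append({"gene": gene, "chrom": chrom, "tss": start - 20_000})
    tss = pd.DataFrame(tss_rows).set_index("gene")

    # H3K27me3: global positive shift in atypical
    bins = [f"bin{i + 1:04d}" for i in range(fx.n_broad_bins)]
    broad_base = rng.uniform(2.0, 5.0, size=fx.n_broad_bins)
    broad = broad_base[:, None] * 2.0 ** rng.normal(0, 0.2, size=(fx.n_broad_bins, n))
    broad[:, is_atypical] *= 2.0**fx.broad_shift
    broad_df = pd.DataFrame(broad, index=bins, columns=samples["sample_id"])

    peak_dfs = {s: pd.DataFrame(rows) for s, rows in peak_tables.items()}
    super_ids = [locus_ids[i] for i in super_idx]
    diff_ids = [locus_ids[i] for i in diff_idx]
    return peak_dfs, signal_df, tss, broad_df, super_ids, diff_ids


def generate_cohort(config: CohortConfig, outdir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Write a full synthetic cohort to ``outdir`` and return paths + truth."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    samples = _plant_samples(config, rng)
    events = _plant_events(samples, config.arm_table)
    samples["pga"] = [_true_pga(events[s], config.arm_table) for s in samples["sample_id"]]

    segments, baf = _make_segments_and_baf(samples, events, config, rng)
    variants = _make_variants(samples, config, rng)
    expression, gene_coords, de_genes, _ = _make_expression(samples, config, rng)
    mirna_counts, mirna_coords, evidence, de_mirnas, truth_pairs = _make_mirna(
        samples, expression, config, rng
    )
    pga_map = dict(zip(samples["sample_id"], samples["pga"]))
    beta, site_info, detection, dm_sites, meth_clusters = _make_methylation(samples, pga_map, config, rng)
    peaks, chip_signal, tss, broad, super_ids, diff_ids = _make_chip(
        samples, expression, de_genes, config, rng
    )

    paths: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kwargs)
        paths[name] = path

    sheet = samples[["sample_id", "grade", "recurrence", "batch"]]
    write("samples.tsv", sheet, index=False)
    write("variants.tsv", variants, index=False)
    write("segments.seg", segments, index=False)
    write("baf.tsv", baf, index=False)
    write("expression.tsv", expression)
    write("expression_coords.tsv", gene_coords)
    write("mirna_counts.tsv", mirna_counts)
    write("mirna_coords.tsv", mirna_coords)
    write("mirna_evidence.tsv", evidence, index=False)
    write("methylation_beta.tsv", beta)
    write("methylation_sites.tsv", site_info)
    write("methylation_detection_p.tsv", detection)
    write("chip_signal.tsv", chip_signal)
    write("h3k27me3_bins.tsv", broad)
    write("tss.tsv", tss)
    for sample, df in peaks.items():
        bed = df[["chrom", "start", "end", "peak_id", "signal", "input_signal"]]
        path = outdir / f"peaks_{sample}.bed"
        bed.to_csv(path, sep="\t", header=False, index=False, float_format=_FLOAT_FMT)
        paths[f"peaks_{sample}.bed"] = path

    truth = GroundTruth(
        samples=samples,
        events=events,
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        mirna_targets=truth_pairs,
        dm_sites=dm_sites,
        meth_clusters=meth_clusters,
        super_loci=super_ids,
        diff_super_loci=diff_ids,
    )
    return paths, truth


def simulate_regulator_decoy(
    n_samples: int = 22,
    n_regulators: int = 3,
    n_decoys: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Planted miRNA-target instance for network precision/recall checks.

    Each regulator miRNA has one target gene equal to minus the miRNA plus
    Gaussian noise; each decoy pair is independent.  All pairs carry 4-of-6
    database support so only the correlation rule separates them.
    """
    from .mirna import TARGET_DATABASES

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    mirna_rows, gene_rows, evid_rows, truth = {}, {}, [], []
    for r in range(n_regulators):
        m, g = f"mir-reg-{r + 1}", f"TGT{r + 1:03d}"
        x = rng.normal(6, 1, size=n_samples)
        mirna_rows[m] = x
        gene_rows[g] = 9.0 - x + rng.normal(0, noise_sd, size=n_samples)
        truth.append((m, g))
        evid_rows += [{"mirna_id": m, "gene_id": g, "source_db": db} for db in TARGET_DATABASES[:4]]
    for d in range(n_decoys):
        m, g = f"mir-decoy-{d + 1}", f"DCY{d + 1:03d}"
        mirna_rows[m] = rng.normal(6, 1, size=n_samples)
        gene_rows[g] = rng.normal(9, 1, size=n_samples)
        evid_rows += [{"mirna_id": m, "gene_id": g, "source_db": db} for db in TARGET_DATABASES[:4]]
    mirna_df = pd.DataFrame(mirna_rows, index=samples).T
    gene_df = pd.DataFrame(gene_rows, index=samples).T
    return mirna_df, gene_df, pd.DataFrame(evid_rows), truth
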