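"""End-to-end orchestration of the analysis stages on a config file.

Stages run in dependency order: synthesize (optional) -> variant filtering
-> CNV/purity -> clonality -> driver subgroups -> expression -> miRNA ->
methylation -> ChIP/super-enhancers -> TERT screen.  Every output file is
declared in a manifest together with the seed and every threshold actually
used; re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import enhancers as chip_mod
from . import expression as expr_mod
from . import methylation as meth_mod
from . import mirna as mirna_mod
from . import stats as stats_mod
from . import synthetic
from . import variants as var_mod
from .errors import ConfigurationError, DependencyError, EstimationError

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_ORDER"]

log = logging.getLogger(__name__)

STAGE_ORDER = (
    "synthesize",
    "variants",
    "cnv",
    "clonality",
    "subgroup",
    "expression",
    "mirna",
    "methylation",
    "chip",
    "tert",
)

_STAGE_DEPS = {
    "clonality": ("variants", "cnv"),
    "subgroup": ("variants", "cnv"),
    "expression": (),
    "mirna": ("expression", "cnv"),
    "methylation": ("cnv",),
    "chip": ("expression",),
    "tert": (),
}


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    synthesize: dict | None = None  # CohortConfig overrides; None = inputs exist
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    thresholds: dict[str, Any] = field(default_factory=dict)

    DEFAULT_THRESHOLDS = {
        "purity_default": 0.7,
        "cnv_status_threshold": "cohort_mean",
        "de_alpha": 0.05,
        "min_target_dbs": 3,
        "network_alpha": 0.05,
        "dm_delta_beta": 0.1,
        "consensus_iterations": 1000,
        "consensus_subsample": 0.8,
        "consensus_k": 2,
        "rf_trees": 1000,
        "rf_top_genes": 25,
        "stitch_bp": 12_500,
        "tss_exclude_bp": 2_000,
        "band_14q32": ["chr14", 95_000_000, 107_000_000],
        "mask_chroms": ["chr1", "chr14", "chr22"],
        "tert_tss": stats_mod.TERT_TSS,
        "tert_strand": "-",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.input_dir:
            raise ConfigurationError("input_dir is required")
        if not self.output_dir:
            raise ConfigurationError("output_dir is required")
        for stage in self.stages:
            if stage not in STAGE_ORDER:
                raise ConfigurationError(f"unknown stage {stage!r}")
        unknown = set(self.thresholds) - set(self.DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigurationError(f"unknown thresholds: {sorted(unknown)}")
        if self.synthesize is None and not Path(self.input_dir).exists():
            raise ConfigurationError(f"input_dir {self.input_dir!r} does not exist")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def threshold(self, name: str):
        return self.thresholds.get(name, self.DEFAULT_THRESHOLDS[name])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _records_from_table(df: pd.DataFrame) -> list[var_mod.VariantRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            var_mod.VariantRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                tumour_ref_depth=int(row["tumour_ref_depth"]),
                tumour_alt_depth=int(row["tumour_alt_depth"]),
                normal_ref_depth=int(row["normal_ref_depth"]),
                normal_alt_depth=int(row["normal_alt_depth"]),
                tumour_gl=tuple(float(x) for x in str(row["tumour_gl"]).split(",")),
                normal_gl=tuple(float(x) for x in str(row["normal_gl"]).split(",")),
                qual=float(row["qual"]),
                qd=float(row["qd"]),
                mq0=int(row["mq0"]),
                strand_bias_phred=float(row["strand_bias_phred"]),
                clipping_rank_sum=float(row["clipping_rank_sum"]),
                repeat_masked=bool(row["repeat_masked"]),
                segdup=bool(row["segdup"]),
                context_seq=str(row["context_seq"]),
                pop_af_max=float(row["pop_af_max"]),
                internal_gene_allele_count=int(row["internal_gene_allele_count"]),
                consequence_terms=tuple(str(row["consequence_terms"]).split(",")),
                gene=str(row["gene"]),
                protein_change=str(row["protein_change"]),
                sample_id=str(row["sample_id"]),
            )
        )
    return records


class _Context:
    """Mutable in-memory state passed between stages."""

    def __init__(self) -> None:
        self.sheet: pd.DataFrame | None = None
        self.grades: dict[str, str] = {}
        self.passing: list[var_mod.VariantRecord] = []
        self.segments: dict[str, list[cnv_mod.CnvSegment]] = {}
        self.purity: dict[str, float] = {}
        self.pga: dict[str, float] = {}
        self.status: dict[str, str] = {}
        self.loss_14q: dict[str, bool] = {}
        self.subgroups: dict[str, str] = {}
        self.expression: pd.DataFrame | None = None
        self.expression_de: expr_mod.DEResult | None = None


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict[str, Any]:
    """Run enabled stages and return (and write) the manifest."""
    config.validate()
    enabled = [s for s in STAGE_ORDER if config.enabled(s)]
    if config.synthesize is None and "synthesize" in enabled:
        enabled.remove("synthesize")
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise DependencyError(f"stage {stage!r} requires stage {dep!r} to be enabled")
    if dry_run:
        return {"plan": enabled, "seed": config.seed}

    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": enabled,
        "thresholds": {k: config.threshold(k) for k in PipelineConfig.DEFAULT_THRESHOLDS},
        "inputs": str(indir),
        "outputs": {},
    }
    ctx = _Context()

    def emit(name: str, df: pd.DataFrame, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.6g", **kwargs)
        manifest["outputs"][name] = _sha256(path)

    if "synthesize" in enabled:
        overrides = dict(config.synthesize or {})
        overrides.setdefault("seed", config.seed)
        cohort_cfg = synthetic.CohortConfig(**overrides)
        synthetic.generate_cohort(cohort_cfg, indir)

    ctx.sheet = pd.read_csv(indir / "samples.tsv", sep="\t")
    ctx.grades = dict(zip(ctx.sheet["sample_id"], ctx.sheet["grade"]))
    arms = cnv_mod.ArmTable(synthetic.default_arm_table())

    if "variants" in enabled:
        table = pd.read_csv(indir / "variants.tsv", sep="\t")
        records = _records_from_table(table)
        var_mod.cluster_variants(records)
        verdicts = [var_mod.apply_filter_cascade(r) for r in records]
        ctx.passing = [r for r, v in zip(records, verdicts) if v.passed]
        out = table.loc[:, [c for c in table.columns if not c.startswith("true_")]].copy()
        out["passed"] = [v.passed for v in verdicts]
        out["failed_filters"] = [";".join(v.failed_filters) for v in verdicts]
        tops = [var_mod.select_consequence(r.consequence_terms) for r in records]
        out["top_consequence"] = [t[0] for t in tops]
        out["deleterious"] = [t[1] for t in tops]
        emit("filtered_variants.tsv", out, index=False)
        sig_rows = {}
        for sample in ctx.sheet["sample_id"]:
            recs = [r for r in ctx.passing if r.sample_id == sample]
            sig_rows[sample] = var_mod.mutational_signature(recs)
        emit(
            "signatures.tsv",
            pd.DataFrame(sig_rows, index=var_mod.SIGNATURE_CATEGORIES).T.rename_axis("sample_id"),
        )

    if "cnv" in enabled:
        seg_table = pd.read_csv(indir / "segments.seg", sep="\t")
        baf = pd.read_csv(indir / "baf.tsv", sep="\t")
        profiles = []
        class_rows = []
        for sample, sub in seg_table.groupby("sample_id"):
            sub_baf = baf[baf["sample_id"] == sample]
            segs = []
            for _, r in sub.iterrows():
                snps = sub_baf[
                    (sub_baf["chrom"] == r["chrom"])
                    & (sub_baf["pos"] >= r["start"])
                    & (sub_baf["pos"] <= r["end"])
                ]["baf"].dropna()
                segs.append(
                    cnv_mod.CnvSegment(
                        chrom=r["chrom"],
                        start=int(r["start"]),
                        end=int(r["end"]),
                        logr=float(r["logr"]),
                        baf_dev=float((snps - 0.5).abs().mean()) if len(snps) else 0.0,
                        n_snps=int(len(snps)),
                        sample_id=sample,
                    )
                )
            classified = cnv_mod.classify_segments(segs, arms)
            ctx.segments[sample] = classified
            try:
                ctx.purity[sample] = cnv_mod.estimate_purity(classified)
            except EstimationError:
                ctx.purity[sample] = float(config.threshold("purity_default"))
            ctx.pga[sample] = cnv_mod.compute_pga(classified, arms)
            events = []
            for seg in classified:
                if seg.event_class != "none":
                    arm, _, _ = arms.arm_of(seg.chrom, seg.start, seg.end)
                    events.append((seg.chrom, arm, seg.event_class))
                class_rows.append(dataclasses.asdict(seg))
            ctx.loss_14q[sample] = ("chr14", "q", "large_loss") in events
            profiles.append((sample, sorted(set(events))))
        ctx.status = cnv_mod.cnv_status(ctx.pga, config.threshold("cnv_status_threshold"))
        emit("segments_classified.tsv", pd.DataFrame(class_rows), index=False)
        profile_objs = [
            cnv_mod.InstabilityProfile(s, ctx.pga[s], ctx.status[s], tuple(ev)) for s, ev in profiles
        ]
        emit(
            "instability_profiles.tsv",
            pd.DataFrame(
                {
                    "sample_id": [p.sample_id for p in profile_objs],
                    "purity": [ctx.purity[p.sample_id] for p in profile_objs],
                    "pga": [p.pga for p in profile_objs],
                    "cnv_status": [p.cnv_status for p in profile_objs],
                    "events": [";".join("|".join(e) for e in p.events) for p in profile_objs],
                }
            ),
            index=False,
        )
        assoc = cnv_mod.arm_event_association(profile_objs, ctx.grades)
        emit("arm_association.tsv", assoc, index=False)

    if "clonality" in enabled:
        rows = []
        for rec in ctx.passing:
            top, deleterious = var_mod.select_consequence(rec.consequence_terms)
            if not deleterious:
                continue
            cn = 2
            for seg in ctx.segments.get(rec.sample_id, []):
                if seg.chrom == rec.chrom and seg.start <= rec.pos <= seg.end:
                    cn = 1 if seg.event_class in {"large_loss", "focal_loss"} else 2
                    break
            est = var_mod.clonality(rec, ctx.purity[rec.sample_id], cn)
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "gene": rec.gene,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "vaf": est.vaf,
                    "multiplicity": est.multiplicity,
                    "ccf": est.ccf,
                }
            )
        emit("clonality.tsv", pd.DataFrame(rows), index=False)

    if "subgroup" in enabled:
        rows = []
        for sample in ctx.sheet["sample_id"]:
            recs = [r for r in ctx.passing if r.sample_id == sample]
            dele = [
                r
                for r in recs
                if var_mod.select_consequence(r.consequence_terms)[1]
            ]
            df = pd.DataFrame(
                {"gene": [r.gene for r in dele], "protein_change": [r.protein_change for r in dele]}
            )
            chr22_loss = any(
                s.chrom == "chr22" and s.event_class == "large_loss" for s in ctx.segments.get(sample, [])
            )
            label = var_mod.assign_driver_subgroup(df, chr22_loss=chr22_loss, nf2_loss=chr22_loss)
            ctx.subgroups[sample] = label
            rows.append({"sample_id": sample, "subgroup": label})
        emit("subgroups.tsv", pd.DataFrame(rows), index=False)

    if "expression" in enabled:
        matrix = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
        matrix = expr_mod.quantile_normalize(matrix)
        batches = dict(zip(ctx.sheet["sample_id"], ctx.sheet["batch"]))
        matrix = expr_mod.batch_adjust(matrix, batches)
        ctx.expression = matrix
        strata = None
        if ctx.subgroups:
            strata = {
                s: ("NF2" if ctx.subgroups.get(s, "unknown").startswith("NF2") else "non-NF2")
                for s in matrix.columns
            }
        de = expr_mod.moderated_de(matrix, ctx.grades, strata=strata, alpha=config.threshold("de_alpha"))
        ctx.expression_de = de
        emit("expression_de.tsv", de.table.rename_axis("gene"))
        signature, coords, sil = expr_mod.signature_and_pca(de, matrix, ctx.grades)
        manifest["expression"] = {
            "n_signature_genes": len(signature),
            "grade_silhouette": sil,
            "d0": de.d0,
            "s0_sq": de.s0_sq,
        }
        if coords is not None:
            emit("expression_pca.tsv", coords.rename_axis("sample_id"))
        if len(signature) >= config.threshold("rf_top_genes"):
            _, oob, _ = expr_mod.rf_grade_classifier(
                matrix,
                ctx.grades,
                de,
                n_top=config.threshold("rf_top_genes"),
                n_trees=config.threshold("rf_trees"),
                seed=config.seed,
            )
            manifest["expression"]["rf_oob_error"] = oob

    if "mirna" in enabled:
        counts = pd.read_csv(indir / "mirna_counts.tsv", sep="\t", index_col=0)
        coords = pd.read_csv(indir / "mirna_coords.tsv", sep="\t", index_col=0)
        evidence = pd.read_csv(indir / "mirna_evidence.tsv", sep="\t")
        log_rpm = mirna_mod.rpm_log(counts)
        de = mirna_mod.mirna_de(log_rpm, ctx.grades)
        emit("mirna_de.tsv", de.table.rename_axis("mirna_id"))
        edges = mirna_mod.infer_network(
            log_rpm,
            ctx.expression,
            evidence,
            min_dbs=config.threshold("min_target_dbs"),
            alpha=config.threshold("network_alpha"),
        )
        emit(
            "mirna_edges.tsv",
            pd.DataFrame([dataclasses.asdict(e) for e in edges]),
            index=False,
        )
        band_chrom, band_start, band_end = config.threshold("band_14q32")
        band = mirna_mod.band_cluster(
            coords, band_chrom, band_start, band_end, log_rpm, ctx.loss_14q
        )
        emit("mirna_14q32.tsv", band.rename_axis("mirna_id"))
        counts_np, p_np = mirna_mod.neg_vs_pos_counts(log_rpm, ctx.expression, evidence)
        manifest["mirna"] = {"neg_vs_pos_p": p_np, "n_edges": len(edges)}
        if "let-7c-5p" in log_rpm.index and "EZH2" in ctx.expression.index:
            rho, p = mirna_mod.pair_correlation("let-7c-5p", "EZH2", log_rpm, ctx.expression)
            manifest["mirna"]["let7c_ezh2_rho"] = rho
            manifest["mirna"]["let7c_ezh2_p"] = p

    if "methylation" in enabled:
        beta = pd.read_csv(indir / "methylation_beta.tsv", sep="\t", index_col=0)
        site_info = pd.read_csv(indir / "methylation_sites.tsv", sep="\t", index_col=0)
        detection = pd.read_csv(indir / "methylation_detection_p.tsv", sep="\t", index_col=0)
        beta_qc, qc_report = meth_mod.site_qc(beta, site_info, detection)
        manifest["methylation"] = {"qc": qc_report}
        dm = meth_mod.diff_methylation(
            beta_qc, ctx.grades, alpha=config.threshold("de_alpha"),
            min_delta_beta=config.threshold("dm_delta_beta"),
        )
        emit("dm_sites.tsv", dm.rename_axis("site_id"))
        k = int(config.threshold("consensus_k"))
        consensus = meth_mod.consensus_cluster(
            beta_qc,
            k_range=(k,),
            n_iter=int(config.threshold("consensus_iterations")),
            subsample=float(config.threshold("consensus_subsample")),
            seed=config.seed,
            chosen_k=k,
        )
        emit("consensus_labels.tsv", consensus.labels.to_frame().rename_axis("sample_id"))
        benign_ref = [s for s in beta_qc.columns if ctx.grades[s] == "benign"]
        frac, rho, p = meth_mod.hypermeth_pga_correlation(beta_qc, benign_ref, ctx.pga)
        emit("hypermethylation_fraction.tsv", frac.to_frame().rename_axis("sample_id"))
        manifest["methylation"]["pga_correlation"] = {"rho": rho, "p": p}
        ari, _ = meth_mod.region_mask_sensitivity(
            beta_qc,
            site_info,
            config.threshold("mask_chroms"),
            consensus.labels,
            k=k,
            n_iter=int(config.threshold("consensus_iterations")),
            seed=config.seed + 1,
        )
        manifest["methylation"]["mask_ari"] = ari

    if "chip" in enabled:
        signal = pd.read_csv(indir / "chip_signal.tsv", sep="\t", index_col=0)
        tss = pd.read_csv(indir / "tss.tsv", sep="\t", index_col=0)
        de = chip_mod.differential_binding(signal, ctx.grades, alpha=config.threshold("de_alpha"))
        emit("chip_de.tsv", de.table.rename_axis("region"))
        regions = [
            chip_mod.StitchedEnhancer(
                chrom=rid.split(":")[0],
                start=int(rid.split(":")[1]),
                end=int(rid.split(":")[1]) + 10_000,
                constituents=(),
                signal=float(signal.loc[rid].mean()),
            )
            for rid in signal.index
        ]
        chip_mod.call_super_enhancers(regions)
        gene_tss = tss.rename(columns={"tss": "tss"})
        chip_mod.assign_nearest_gene(regions, gene_tss)
        se_table = pd.DataFrame(
            {
                "region": signal.index,
                "mean_signal": [r.signal for r in regions],
                "rank": [r.rank for r in regions],
                "is_super": [r.is_super for r in regions],
                "nearest_gene": [r.nearest_gene for r in regions],
            }
        )
        emit("super_enhancers.tsv", se_table, index=False)
        region_genes = {
            f"{r.chrom}:{r.start}": r.nearest_gene for r in regions if r.is_super and r.nearest_gene
        }
        concord = chip_mod.expression_concordance(de, ctx.expression_de, region_genes)
        emit("concordance.tsv", concord, index=False)
        manifest["chip"] = {
            "n_super": int(se_table["is_super"].sum()),
            "n_concordant": int(concord["concordant"].sum()) if len(concord) else 0,
        }
        broad_path = indir / "h3k27me3_bins.tsv"
        if broad_path.exists():
            bins = pd.read_csv(broad_path, sep="\t", index_col=0)
            broad_de, shift = chip_mod.broad_domain_differential(bins, ctx.grades)
            emit("h3k27me3_de.tsv", broad_de.table.rename_axis("bin"))
            manifest["chip"]["broad_positive_fraction"] = shift

    if "tert" in enabled:
        calls_path = indir / "tert_calls.tsv"
        calls = []
        if calls_path.exists():
            raw = pd.read_csv(calls_path, sep="\t")
            rec_map = dict(zip(ctx.sheet["sample_id"], ctx.sheet["recurrence"]))
            for _, r in raw.iterrows():
                offset = int(r["offset"])
                calls.append(
                    stats_mod.TertCall(
                        sample_id=str(r["sample_id"]),
                        recurrence=rec_map.get(str(r["sample_id"]), "primary"),
                        offset=offset,
                        genomic_pos=stats_mod.tert_offset_to_coord(
                            int(config.threshold("tert_tss")), config.threshold("tert_strand"), offset
                        ),
                        substitution=str(r.get("substitution", "")),
                    )
                )
        report = stats_mod.tert_recurrence_report(calls, ctx.sheet)
        emit("tert_report.tsv", report, index=False)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest
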