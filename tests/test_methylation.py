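"""Methylation QC, differential sites, consensus clustering and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from meningomics.errors import ValidationError
from meningomics.methylation import (
    RegionGeneSet,
    build_regulatory_domains,
    consensus_cluster,
    diff_methylation,
    hypermeth_pga_correlation,
    region_enrichment,
    region_mask_sensitivity,
    site_qc,
)


def planted_beta(n_sites=400, n_per_group=10, delta=0.3, sd=0.05, seed=0, n_dm=60):
    rng = np.random.default_rng(seed)
    samples = [f"H{i}" for i in range(n_per_group)] + [f"L{i}" for i in range(n_per_group)]
    base = rng.uniform(0.2, 0.5, size=n_sites)
    beta = base[:, None] + rng.normal(0, sd, size=(n_sites, 2 * n_per_group))
    beta[:n_dm, :n_per_group] += delta
    beta = np.clip(beta, 0, 1)
    sites = [f"cg{i:05d}" for i in range(n_sites)]
    return pd.DataFrame(beta, index=sites, columns=samples)


class TestSiteQC:
    def _inputs(self):
        sites = ["s_clean", "s_det", "s_x", "s_snp", "s_na"]
        samples = [f"p{i}" for i in range(10)]
        beta = pd.DataFrame(0.3, index=sites, columns=samples)
        beta.loc["s_na", "p0"] = np.nan
        info = pd.DataFrame(
            {"chrom": ["chr2", "chr3", "chrX", "chr4", "chr5"],
             "pos": [1, 2, 3, 4, 5],
             "snp_overlap": [False, False, False, True, False]},
            index=sites,
        )
        det = pd.DataFrame(0.01, index=sites, columns=samples)
        det.loc["s_det", samples[:6]] = 0.5  # fails detection in 6/10
        return beta, info, det

    def test_each_rule(self):
        beta, info, det = self._inputs()
        out, report = site_qc(beta, info, det)
        assert list(out.index) == ["s_clean"]
        assert report == {"missing": 1, "snp_overlap": 1, "sex_chrom": 1, "detection": 1, "retained": 1}

    def test_exact_half_failure_removed(self):
        beta, info, det = self._inputs()
        det.loc["s_det"] = 0.01
        det.loc["s_det", beta.columns[:5]] = 0.5  # exactly 50%
        out, _ = site_qc(beta, info, det)
        assert "s_det" not in out.index


class TestDiffMethylation:
    def test_planted_sensitivity(self):
        beta = planted_beta(seed=1)
        groups = {s: ("hyper" if s.startswith("H") else "low") for s in beta.columns}
        out = diff_methylation(beta, groups)
        planted = out.iloc[:60]
        assert (planted["call"] == "hyper").mean() >= 0.9

    def test_effect_size_gate(self):
        """Tiny but ultra-consistent differences stay uncalled."""
        rng = np.random.default_rng(2)
        samples = [f"H{i}" for i in range(10)] + [f"L{i}" for i in range(10)]
        beta = pd.DataFrame(
            0.30 + rng.normal(0, 0.003, size=(50, 20)), index=[f"cg{i}" for i in range(50)], columns=samples
        )
        beta.iloc[0, :10] += 0.05  # significant p, delta below 0.1
        groups = {s: ("hyper" if s.startswith("H") else "low") for s in samples}
        out = diff_methylation(beta, groups)
        assert out.iloc[0]["fdr"] < 0.05
        assert out.iloc[0]["call"] == "none"

    def test_null_no_calls_beyond_nominal(self):
        beta = planted_beta(delta=0.0, n_dm=0, seed=3)
        groups = {s: ("hyper" if s.startswith("H") else "low") for s in beta.columns}
        out = diff_methylation(beta, groups)
        assert (out["call"] != "none").mean() <= 0.01

    def test_sample_order_invariance(self):
        beta = planted_beta(seed=4)
        groups = {s: ("hyper" if s.startswith("H") else "low") for s in beta.columns}
        out1 = diff_methylation(beta, groups)
        out2 = diff_methylation(beta[beta.columns[::-1]], groups)
        assert np.allclose(out1["delta_beta"], out2["delta_beta"])
        assert list(out1["call"]) == list(out2["call"])


class TestConsensusCluster:
    def test_planted_two_clusters_recovered(self):
        beta = planted_beta(seed=5)
        result = consensus_cluster(beta, k_range=(2,), n_iter=100, seed=0, chosen_k=2)
        truth = [0 if s.startswith("H") else 1 for s in beta.columns]
        assert adjusted_rand_score(truth, result.labels) == 1.0
        within = result.consensus.to_numpy()[np.ix_(range(10), range(10))]
        between = result.consensus.to_numpy()[np.ix_(range(10), range(10, 20))]
        assert within.mean() > 0.95
        assert between.mean() < 0.05

    def test_duplicated_samples_always_cocluster(self):
        beta = planted_beta(seed=6)
        beta["H0_dup"] = beta["H0"] + 1e-9
        result = consensus_cluster(beta, k_range=(2,), n_iter=100, seed=0, chosen_k=2)
        assert result.consensus.loc["H0", "H0_dup"] == pytest.approx(1.0)

    def test_seed_determinism(self):
        beta = planted_beta(seed=7)
        r1 = consensus_cluster(beta, k_range=(2, 3), n_iter=50, seed=3)
        r2 = consensus_cluster(beta, k_range=(2, 3), n_iter=50, seed=3)
        assert np.array_equal(r1.consensus, r2.consensus)
        assert list(r1.labels) == list(r2.labels)

    def test_matrix_properties(self):
        beta = planted_beta(seed=8)
        r = consensus_cluster(beta, k_range=(2,), n_iter=50, seed=1, chosen_k=2)
        c = r.consensus.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert c.min() >= 0 and c.max() <= 1

    def test_more_iterations_stabilise_consensus(self):
        """Run-to-run variance of consensus entries shrinks with iterations."""
        beta = planted_beta(delta=0.1, n_dm=30, sd=0.08, seed=9)

        def spread(n_iter):
            mats = [
                consensus_cluster(beta, k_range=(2,), n_iter=n_iter, seed=s, chosen_k=2).consensus.to_numpy()
                for s in range(4)
            ]
            return np.var(np.stack(mats), axis=0).mean()

        assert spread(200) < spread(20)

    def test_k_exceeding_samples_rejected(self):
        beta = planted_beta(n_per_group=3, seed=10)
        with pytest.raises(ValidationError):
            consensus_cluster(beta, k_range=(7,), n_iter=10, seed=0)


class TestHypermethPGA:
    def test_reference_sample_fraction_zero(self):
        beta = planted_beta(delta=0.0, n_dm=0, sd=0.0, seed=11)
        frac, rho, p = hypermeth_pga_correlation(
            beta, [s for s in beta.columns if s.startswith("L")], {s: 1.0 + i for i, s in enumerate(beta.columns)}
        )
        assert frac.max() == 0.0
        assert np.isnan(rho)

    def test_planted_coupling_recovered(self):
        rng = np.random.default_rng(12)
        n = 50
        samples = [f"s{i}" for i in range(n)]
        pga = {s: float(rng.uniform(0, 15)) for s in samples}
        n_sites = 800
        base = rng.uniform(0.2, 0.4, size=n_sites)
        beta = base[:, None] + rng.normal(0, 0.02, size=(n_sites, n))
        scale = np.array([pga[s] for s in samples]) / 15.0
        beta[:400] += 0.3 * scale[None, :]
        frame = pd.DataFrame(np.clip(beta, 0, 1), index=[f"cg{i}" for i in range(n_sites)], columns=samples)
        ref = [s for s in samples if pga[s] < 3]
        frac, rho, p = hypermeth_pga_correlation(frame, ref, pga)
        assert rho > 0.7 and p < 0.01

    def test_constant_pga_undefined(self):
        beta = planted_beta(seed=13)
        frac, rho, p = hypermeth_pga_correlation(beta, list(beta.columns[:5]), {s: 5.0 for s in beta.columns})
        assert np.isnan(rho) and np.isnan(p)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestRegionEnrichment:
    def _sites(self, n, chrom="chr2", start=0, step=1000):
        return pd.DataFrame({"chrom": chrom, "pos": [start + i * step for i in range(n)]})

    def test_query_equals_background(self):
        bg = self._sites(100)
        gs = RegionGeneSet("set", ("g1",), (("chr2", 0, 200_000),))
        out = region_enrichment(bg, bg, [gs])
        assert out.iloc[0]["fold"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        # 1,000 background sites, 100 in the domain; query of 50 hits 40
        bg_in = self._sites(100, start=0)
        bg_out = self._sites(900, chrom="chr3", start=0)
        background = pd.concat([bg_in, bg_out], ignore_index=True)
        query = pd.concat([bg_in.iloc[:40], bg_out.iloc[:10]], ignore_index=True)
        gs = RegionGeneSet("set", ("g1",), (("chr2", 0, 200_000),))
        out = region_enrichment(query, background, [gs])
        assert out.iloc[0]["query_hits"] == 40
        assert out.iloc[0]["background_hits"] == 100
        assert out.iloc[0]["p"] == pytest.approx(hypergeom_tail_oracle(40, 1000, 100, 50), rel=1e-9)

    def test_planted_set_ranks_first(self):
        background = pd.concat(
            [self._sites(200, "chr2"), self._sites(200, "chr3"), self._sites(200, "chr4")],
            ignore_index=True,
        )
        query = pd.concat([self._sites(60, "chr2"), self._sites(5, "chr3")], ignore_index=True)
        sets = [
            RegionGeneSet("planted", ("a",), (("chr2", 0, 300_000),)),
            RegionGeneSet("decoy1", ("b",), (("chr3", 0, 300_000),)),
            RegionGeneSet("decoy2", ("c",), (("chr4", 0, 300_000),)),
        ]
        out = region_enrichment(query, background, sets)
        assert out.iloc[0]["set"] == "planted"

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            region_enrichment(self._sites(1), self._sites(0), [])

    def test_basal_plus_extension_domains(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr2", "chr2"],
                "start": [1_000_000, 1_050_000],
                "end": [1_010_000, 1_060_000],
                "strand": ["+", "+"],
            },
            index=["gA", "gB"],
        )
        dom = build_regulatory_domains(genes)
        # basal: TSS-5kb .. TSS+1kb
        assert dom.loc["gA", "basal_start"] == 995_000
        assert dom.loc["gA", "basal_end"] == 1_001_000
        # gA's rightward extension stops at gB's basal start
        assert dom.loc["gA", "domain_end"] == 1_045_000
        # gB's leftward extension stops at gA's basal end
        assert dom.loc["gB", "domain_start"] == 1_001_000
        # free directions extend by up to 1 Mb beyond the basal domain
        assert dom.loc["gA", "domain_start"] == 0
        assert dom.loc["gB", "domain_end"] == 1_051_000 + 1_000_000


class TestMaskSensitivity:
    def _cohort(self, driver_chrom, seed=14):
        rng = np.random.default_rng(seed)
        samples = [f"H{i}" for i in range(8)] + [f"L{i}" for i in range(8)]
        n_sites = 300
        chroms = [driver_chrom if i < 80 else "chr9" for i in range(n_sites)]
        base = rng.uniform(0.2, 0.5, size=n_sites)
        beta = base[:, None] + rng.normal(0, 0.05, size=(n_sites, 16))
        beta[:80, :8] += 0.3  # cluster signal lives on driver_chrom
        frame = pd.DataFrame(np.clip(beta, 0, 1), index=[f"cg{i}" for i in range(n_sites)], columns=samples)
        info = pd.DataFrame({"chrom": chroms, "pos": range(n_sites)}, index=frame.index)
        labels = pd.Series([1] * 8 + [2] * 8, index=samples)
        return frame, info, labels

    def test_empty_mask_identity(self):
        frame, info, labels = self._cohort("chr5")
        ref = consensus_cluster(frame, k_range=(2,), n_iter=60, seed=0, chosen_k=2)
        ari, _ = region_mask_sensitivity(frame, info, [], ref.labels, k=2, n_iter=60, seed=0)
        assert ari == 1.0

    def test_uninvolved_chromosome_mask_robust(self):
        frame, info, labels = self._cohort("chr5")
        ari, _ = region_mask_sensitivity(frame, info, ["chr1", "chr14", "chr22"], labels, k=2, n_iter=60, seed=1)
        assert ari >= 0.9

    def test_driver_chromosome_mask_destroys_clusters(self):
        frame, info, labels = self._cohort("chr14")
        ari, _ = region_mask_sensitivity(frame, info, ["chr1", "chr14", "chr22"], labels, k=2, n_iter=60, seed=2)
        assert ari < 0.3
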