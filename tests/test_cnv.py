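"""CNV classification, purity, PGA and instability associations."""

import math

import numpy as np
import pandas as pd
import pytest

from meningomics.cnv import (
    ArmTable,
    CnvSegment,
    InstabilityProfile,
    arm_event_association,
    classify_segment,
    classify_segments,
    cnv_status,
    compute_pga,
    estimate_purity,
    expected_baf_deviation,
    gene_cnv_association,
    gene_logr_matrix,
)
from meningomics.errors import CoordinateError, EstimationError, ValidationError
from meningomics.synthetic import default_arm_table, simulate_baf


@pytest.fixture(scope="module")
def arms():
    return ArmTable(default_arm_table())


def loss_seg(baf_dev, n_snps=100, **kw):
    base = dict(chrom="chr22", start=60_000_001, end=130_000_000, logr=-0.5,
                event_class="large_loss", baf_dev=baf_dev, n_snps=n_snps)
    base.update(kw)
    return CnvSegment(**base)


class TestPurity:
    @pytest.mark.parametrize("dev,expected", [(0.5, 1.0), (0.25, 2 / 3), (0.1, 1 / 3)])
    def test_closed_form(self, dev, expected):
        assert estimate_purity([loss_seg(dev)]) == pytest.approx(expected, rel=1e-9)

    def test_weighted_mean(self):
        segs = [loss_seg(0.1, n_snps=100), loss_seg(0.3, n_snps=300)]
        d = (0.1 * 100 + 0.3 * 300) / 400
        assert estimate_purity(segs) == pytest.approx(4 * d / (1 + 2 * d))

    def test_no_loss_segments(self):
        with pytest.raises(EstimationError):
            estimate_purity([loss_seg(0.2, event_class="large_gain")])

    def test_sparse_snps_excluded(self):
        with pytest.raises(EstimationError):
            estimate_purity([loss_seg(0.2, n_snps=5)])

    @pytest.mark.parametrize("purity", [0.3, 0.5, 0.8])
    def test_recovery_from_simulated_baf(self, purity):
        """Round trip: simulate loss-region BAFs, estimate purity back."""
        bafs = simulate_baf(depth=500, purity=purity, tumour_cn=1, n_snps=200, seed=42)
        dev = float(np.abs(bafs - 0.5).mean())
        est = estimate_purity([loss_seg(dev, n_snps=200)])
        assert abs(est - purity) <= 0.05

    def test_expected_deviation_consistency(self):
        # closed form is the inverse of the deviation model
        for p in (0.2, 0.5, 0.9):
            d = expected_baf_deviation(p)
            assert estimate_purity([loss_seg(d)]) == pytest.approx(p, rel=1e-9)


ARM_Q_START, ARM_Q_END = 60_000_001, 130_000_000  # 70 Mb q arm
Q_LEN = ARM_Q_END - ARM_Q_START + 1


def q_seg(frac, logr, baf_dev):
    end = ARM_Q_START + int(frac * Q_LEN) - 1
    return CnvSegment(chrom="chr5", start=ARM_Q_START, end=end, logr=logr, baf_dev=baf_dev)


class TestClassify:
    @pytest.mark.parametrize(
        "frac,logr,baf_dev,expected",
        [
            (0.40, -0.3, 0.20, "large_loss"),
            (0.20, 0.15, 0.08, "focal_gain"),
            (0.40, -0.3, 0.02, "none"),  # BAF false-positive correction
            (0.40, 0.3, 0.20, "large_gain"),
            (0.20, -0.3, 0.08, "focal_loss"),
            (1.0 / 3.0, -0.3, 0.2, "focal_loss"),  # boundary: strict > one-third
            (0.05, -0.3, 0.2, "none"),  # below one-tenth
            (0.10, -0.3, 0.2, "none"),  # boundary: strict > one-tenth
            (0.40, 0.0, 0.20, "cn_loh"),
            (0.40, 0.1, 0.20, "cn_loh"),  # |logR| <= 0.1 inclusive
            (0.40, -0.1, 0.20, "cn_loh"),
            (0.20, 0.0, 0.20, "none"),  # cn-LOH requires large-scale extent
            (0.40, 0.0, 0.02, "none"),
            (0.95, -0.5, 0.45, "large_loss"),
            (0.12, 0.5, 0.05, "focal_gain"),  # baf_dev boundary inclusive
            (0.12, 0.5, 0.049, "none"),
        ],
    )
    def test_rule_table(self, arms, frac, logr, baf_dev, expected):
        assert classify_segment(q_seg(frac, logr, baf_dev), arms) == expected

    def test_unknown_chrom(self, arms):
        seg = CnvSegment(chrom="chrZ", start=1, end=10, logr=-1, baf_dev=0.2)
        with pytest.raises(CoordinateError):
            classify_segment(seg, arms)

    def test_centromere_spanning_split(self, arms):
        seg = CnvSegment(chrom="chr5", start=1, end=130_000_000, logr=-0.5, baf_dev=0.2)
        out = classify_segments([seg], arms)
        assert len(out) == 2
        assert {(s.start, s.end) for s in out} == {(1, 60_000_000), (60_000_001, 130_000_000)}
        assert all(s.event_class == "large_loss" for s in out)


class TestPGA:
    def _arms(self, genome_mb=3000):
        # a toy genome made of 10 equal 300 Mb arms
        rows = [
            {"chrom": f"chr{i}", "arm": "p", "start": 1, "end": 300_000_000}
            for i in range(1, 11)
        ]
        return ArmTable(pd.DataFrame(rows))

    def test_single_loss(self):
        arms = self._arms()
        seg = CnvSegment("chr1", 1, 300_000_000, -0.5, 0.2, event_class="large_loss")
        assert compute_pga([seg], arms) == pytest.approx(10.0)

    def test_no_events(self):
        assert compute_pga([], self._arms()) == 0.0

    def test_cn_loh_excluded(self):
        arms = self._arms()
        segs = [
            CnvSegment("chr1", 1, 100_000_000, -0.5, 0.2, event_class="large_loss"),
            CnvSegment("chr2", 1, 50_000_000, 0.5, 0.2, event_class="focal_gain"),
            CnvSegment("chr3", 1, 200_000_000, 0.0, 0.2, event_class="cn_loh"),
        ]
        assert compute_pga(segs, arms) == pytest.approx(5.0)
        assert compute_pga(segs, arms, include_cn_loh=True) == pytest.approx(5.0 + 200 / 30)

    def test_overlap_counted_once(self):
        arms = self._arms()
        segs = [
            CnvSegment("chr1", 1, 100_000_000, -0.5, 0.2, event_class="large_loss"),
            CnvSegment("chr1", 50_000_001, 100_000_000, -0.5, 0.2, event_class="focal_loss"),
        ]
        assert compute_pga(segs, arms) == pytest.approx(100 / 3000 * 100)

    def test_split_invariance(self):
        arms = self._arms()
        whole = [CnvSegment("chr1", 1, 200_000_000, -0.5, 0.2, event_class="large_loss")]
        halves = [
            CnvSegment("chr1", 1, 100_000_000, -0.5, 0.2, event_class="large_loss"),
            CnvSegment("chr1", 100_000_001, 200_000_000, -0.5, 0.2, event_class="large_loss"),
        ]
        assert compute_pga(whole, arms) == compute_pga(halves, arms)


class TestStatus:
    def test_fixed_threshold(self):
        status = cnv_status({"a": 10, "b": 0, "c": 2, "d": 8}, threshold=5)
        assert status == {"a": "high", "b": "low", "c": "low", "d": "high"}

    def test_cohort_mean(self):
        status = cnv_status({"a": 10, "b": 0, "c": 2, "d": 8}, threshold="cohort_mean")
        assert status == {"a": "high", "b": "low", "c": "low", "d": "high"}

    def test_all_equal_all_low(self):
        status = cnv_status({"a": 3.0, "b": 3.0, "c": 3.0}, threshold="cohort_mean")
        assert set(status.values()) == {"low"}

    def test_mean_requires_two(self):
        with pytest.raises(ValidationError):
            cnv_status({"a": 1.0}, threshold="cohort_mean")


def make_profile(sample, events):
    return InstabilityProfile(sample, 5.0, "high", tuple(events))


class TestArmAssociation:
    def test_extreme_separation(self):
        profiles = [make_profile(f"a{i}", [("chr14", "q", "large_loss")]) for i in range(10)]
        profiles += [make_profile(f"b{i}", []) for i in range(10)]
        grades = {p.sample_id: ("atypical" if p.sample_id.startswith("a") else "benign") for p in profiles}
        df = arm_event_association(profiles, grades)
        assert df.iloc[0]["p"] == pytest.approx(2 / math.comb(20, 10), rel=1e-6)

    def test_identical_frequencies(self):
        profiles = [make_profile(f"a{i}", [("chr1", "p", "large_loss")]) for i in range(5)]
        profiles += [make_profile(f"b{i}", [("chr1", "p", "large_loss")]) for i in range(5)]
        grades = {p.sample_id: ("atypical" if p.sample_id.startswith("a") else "benign") for p in profiles}
        df = arm_event_association(profiles, grades)
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_planted_14q_enrichment_ranks_first(self, rng):
        profiles = []
        grades = {}
        for i in range(30):
            ev = [("chr14", "q", "large_loss")] if rng.random() < 0.6 else []
            if rng.random() < 0.3:
                ev.append(("chr3", "p", "large_gain"))
            profiles.append(make_profile(f"a{i}", ev))
            grades[f"a{i}"] = "atypical"
        for i in range(30):
            ev = [("chr14", "q", "large_loss")] if rng.random() < 0.1 else []
            if rng.random() < 0.3:
                ev.append(("chr3", "p", "large_gain"))
            profiles.append(make_profile(f"b{i}", ev))
            grades[f"b{i}"] = "benign"
        df = arm_event_association(profiles, grades)
        assert df.iloc[0][["chrom", "arm"]].tolist() == ["chr14", "q"]


class TestGeneAssociation:
    def test_complete_separation_exact_p(self):
        mat = pd.DataFrame(
            {"a1": [-0.3], "a2": [-0.3], "a3": [-0.3], "b1": [0.0], "b2": [0.0], "b3": [0.0]},
            index=["PTEN"],
        )
        grades = {s: ("atypical" if s.startswith("a") else "benign") for s in mat.columns}
        df = gene_cnv_association(mat, grades)
        assert df.iloc[0]["p"] == pytest.approx(0.1, rel=1e-9)
        assert df.iloc[0]["median_diff"] == pytest.approx(-0.3)

    def test_identical_groups(self):
        mat = pd.DataFrame({"a1": [0.1], "a2": [0.1], "b1": [0.1], "b2": [0.1]}, index=["G"])
        grades = {s: ("atypical" if s.startswith("a") else "benign") for s in mat.columns}
        assert gene_cnv_association(mat, grades).iloc[0]["p"] == 1.0

    def test_gene_logr_length_weighting(self):
        genes = pd.DataFrame([{"gene": "PTEN", "chrom": "chr10", "start": 100, "end": 400}])
        segs = {
            "s1": [
                CnvSegment("chr10", 1, 200, -0.4, 0.2),  # covers 100-200 (101 bp)
                CnvSegment("chr10", 201, 1000, 0.0, 0.0),  # covers 201-400 (200 bp)
            ]
        }
        mat = gene_logr_matrix(genes, segs)
        expected = (-0.4 * 101 + 0.0 * 200) / 301
        assert mat.loc["PTEN", "s1"] == pytest.approx(expected)

    def test_planted_deletion_ranks_high(self, rng):
        genes = [f"G{i}" for i in range(50)] + ["PTEN"]
        n = 12
        data = rng.normal(0, 0.05, size=(51, 2 * n))
        data[50, :n] -= 0.5  # PTEN deleted in atypicals
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        mat = pd.DataFrame(data, index=genes, columns=cols)
        grades = {s: ("atypical" if s.startswith("a") else "benign") for s in cols}
        df = gene_cnv_association(mat, grades)
        assert df.iloc[0]["gene"] == "PTEN"
        assert df.iloc[0]["fdr"] < 0.05
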