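"""Normalisation, moderated differential expression and grade prediction."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import two_group_matrix
from meningomics.errors import DesignError, ValidationError
from meningomics.expression import (
    batch_adjust,
    moderated_de,
    quantile_normalize,
    rf_grade_classifier,
    signature_and_pca,
)


class TestQuantileNormalize:
    def test_identical_rank_orders_give_identical_columns(self):
        m = pd.DataFrame({"s1": [1.0, 5.0, 3.0], "s2": [10.0, 50.0, 30.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["s1"], out["s2"])

    def test_column_means_equal(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = quantile_normalize(m)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])

    def test_three_by_three_reference(self):
        # columns (1,2,3), (4,5,6), (7,8,9): mean of sorted columns = (4,5,6)
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0], "s3": [7.0, 8.0, 9.0]})
        out = quantile_normalize(m)
        for col in m.columns:
            assert np.allclose(out[col], [4.0, 5.0, 6.0])

    def test_ties_share_mean_quantile(self):
        m = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 3.0, 4.0]})
        out = quantile_normalize(m)
        assert out["s1"].iloc[0] == out["s1"].iloc[1]

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            quantile_normalize(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestBatchAdjust:
    def test_constant_shift_removed(self, rng):
        m, _ = two_group_matrix(30, 6, seed=1)
        batches = {s: ("x" if i % 2 else "y") for i, s in enumerate(m.columns)}
        shifted = m.copy()
        xs = [s for s in m.columns if batches[s] == "x"]
        shifted[xs] += 2.0
        out = batch_adjust(shifted, batches)
        ys = [s for s in m.columns if batches[s] == "y"]
        assert np.allclose(out[xs].mean(axis=1), out[ys].mean(axis=1), atol=1e-9)

    def test_single_batch_identity(self, rng):
        m, _ = two_group_matrix(10, 4, seed=2)
        out = batch_adjust(m, {s: "only" for s in m.columns})
        assert np.allclose(out, m)

    def test_singleton_batch_rejected(self):
        m, _ = two_group_matrix(10, 4, seed=3)
        batches = {s: "a" for s in m.columns}
        batches[m.columns[0]] = "lonely"
        with pytest.raises(ValidationError, match="lonely"):
            batch_adjust(m, batches)

    def test_planted_shift_does_not_inflate_de(self):
        """A balanced batch shift must not create grade false positives."""
        m, grades = two_group_matrix(500, 10, sd=0.5, seed=4)
        batches = {s: ("b1" if i % 2 else "b2") for i, s in enumerate(m.columns)}
        shifted = m.copy()
        b1 = [s for s in m.columns if batches[s] == "b1"]
        shifted[b1] += 1.0
        de = moderated_de(batch_adjust(shifted, batches), grades)
        assert (de.table["fdr"] < 0.05).sum() == 0


class TestModeratedDE:
    def test_null_pvalues_uniform(self):
        m, grades = two_group_matrix(2000, 10, seed=5)
        de = moderated_de(m, grades)
        ks = sps.kstest(de.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_power(self):
        idx = list(range(50))
        m, grades = two_group_matrix(1000, 10, effect_idx=idx, effect=2.0, sd=0.5, seed=6)
        de = moderated_de(m, grades)
        hits = de.significant(0.05)
        recovered = len(set(f"f{i}" for i in idx) & set(hits))
        assert recovered >= 0.95 * 50

    def test_stratum_only_effect_not_significant(self, rng):
        samples = [f"s{i}" for i in range(16)]
        grades = {s: ("atypical" if i < 8 else "benign") for i, s in enumerate(samples)}
        strata = {s: ("NF2" if i % 2 else "non-NF2") for i, s in enumerate(samples)}
        values = rng.normal(0, 0.3, size=(100, 16))
        stratum_vec = np.array([2.0 if strata[s] == "NF2" else 0.0 for s in samples])
        values[0] += stratum_vec
        m = pd.DataFrame(values, index=[f"f{i}" for i in range(100)], columns=samples)
        de = moderated_de(m, grades, strata=strata)
        assert abs(de.table.loc["f0", "logfc"]) < 0.5
        assert de.table.loc["f0", "fdr"] > 0.05

    def test_confounded_design_rejected(self):
        m, grades = two_group_matrix(10, 4, seed=7)
        strata = {s: grades[s] for s in m.columns}  # stratum == grade
        with pytest.raises(DesignError):
            moderated_de(m, grades, strata=strata)

    def test_sample_permutation_invariance(self):
        m, grades = two_group_matrix(50, 6, effect_idx=[0], effect=1.5, seed=8)
        de1 = moderated_de(m, grades)
        perm = list(m.columns[::-1])
        de2 = moderated_de(m[perm], grades)
        assert np.allclose(de1.table["t"], de2.table["t"])

    def test_equal_variances_infinite_prior(self, rng):
        """When every feature has identical residual variance the prior
        dominates and the moderated t matches the pooled-variance t."""
        samples = [f"s{i}" for i in range(8)]
        grades = {s: ("atypical" if i < 4 else "benign") for i, s in enumerate(samples)}
        base = rng.normal(size=8)
        values = np.vstack([base + i * 10 for i in range(60)])  # same residuals per feature
        m = pd.DataFrame(values, index=[f"f{i}" for i in range(60)], columns=samples)
        de = moderated_de(m, grades)
        assert np.isinf(de.d0)

    def test_heavy_tailed_variances_finite_prior(self, rng):
        m, grades = two_group_matrix(300, 6, seed=9)
        scales = rng.uniform(0.1, 10.0, size=300)
        m = m.mul(scales, axis=0)
        de = moderated_de(m, grades)
        assert np.isfinite(de.d0) and de.d0 > 0
        # moderated t shrinks toward the ordinary t as the prior weakens:
        # per-feature ordinary t must correlate strongly with moderated t
        X = np.array([[1.0, 1.0]] * 6 + [[1.0, 0.0]] * 6)
        ordinary_t = []
        for f in m.index:
            y = m.loc[f].to_numpy()
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            s2 = res[0] / (12 - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            ordinary_t.append(beta[1] / se)
        assert np.corrcoef(ordinary_t, de.table["t"])[0, 1] > 0.95


@pytest.mark.parametrize("with_stratum", [False, True])
def test_matches_limma_reference(tmp_path, with_stratum):
    """Cross-check the moderated t against the Bioconductor reference
    implementation on a shared random dataset."""
    rng = np.random.default_rng(11)
    n_feat, n_per = 80, 6
    samples = [f"s{i}" for i in range(2 * n_per)]
    grades = {s: ("atypical" if i < n_per else "benign") for i, s in enumerate(samples)}
    strata = {s: ("NF2" if i % 2 else "nonNF2") for i, s in enumerate(samples)}
    values = rng.normal(8, 1, size=(n_feat, 2 * n_per)) * rng.uniform(0.5, 2.0, size=(n_feat, 1))
    m = pd.DataFrame(values, index=[f"f{i}" for i in range(n_feat)], columns=samples)
    m.to_csv(tmp_path / "m.tsv", sep="\t")
    grade_vec = ",".join("1" if grades[s] == "atypical" else "0" for s in samples)
    stratum_vec = ",".join("1" if strata[s] == "NF2" else "0" for s in samples)
    design = "cbind(1, grade, stratum)" if with_stratum else "cbind(1, grade)"
    script = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
        grade <- c({grade_vec}); stratum <- c({stratum_vec})
        design <- {design}
        fit <- eBayes(lmFit(m, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s0=fit$s2.prior)
        write.csv(out, "{tmp_path}/limma.csv")
        """
    )
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    de = moderated_de(m, grades, strata=strata if with_stratum else None)
    assert np.allclose(de.table["t"], ref["t"], rtol=1e-4)
    assert np.allclose(de.table["p"], ref["p"], rtol=1e-4)
    assert de.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-3)
    assert de.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-3)


class TestSignaturePCA:
    def test_planted_signature_fdr_controlled(self):
        """Observed false-discovery fraction near the nominal 5% (averaged
        over replicates to tame single-run Monte-Carlo noise), with strong
        grade separation on the signature PCs."""
        idx = list(range(50))
        truth = {f"f{i}" for i in idx}
        fracs = []
        for rep in range(10):
            m, grades = two_group_matrix(2000, 10, effect_idx=idx, effect=2.0, sd=0.5, seed=100 + rep)
            de = moderated_de(m, grades)
            signature, coords, sil = signature_and_pca(de, m, grades)
            fracs.append(len(set(signature) - truth) / max(len(signature), 1))
            if rep == 0:
                assert len(truth & set(signature)) >= 48
                assert sil is not None and sil > 0.3
        assert np.mean(fracs) <= 0.07

    def test_unrelated_labels_silhouette_near_zero(self):
        """Grade separation vanishes when the evaluated labels carry no
        signal (signature chosen on real labels, silhouette on permuted)."""
        idx = list(range(50))
        m, grades = two_group_matrix(2000, 10, effect_idx=idx, effect=2.0, sd=0.5, seed=21)
        de = moderated_de(m, grades)
        rng = np.random.default_rng(22)
        permuted = dict(zip(m.columns, rng.permutation([grades[s] for s in m.columns])))
        _, _, sil = signature_and_pca(de, m, permuted)
        assert sil is not None and abs(sil) < 0.25

    def test_empty_signature_skips_pca(self):
        m, grades = two_group_matrix(100, 5, seed=14)
        de = moderated_de(m, grades)
        signature, coords, sil = signature_and_pca(de, m, grades, alpha=1e-12)
        assert signature == [] and coords is None and sil is None


class TestRandomForest:
    def _planted(self, seed=15):
        idx = list(range(30))
        return two_group_matrix(200, 12, effect_idx=idx, effect=3.0, sd=0.5, seed=seed)

    def test_separable_data_low_oob(self):
        m, grades = self._planted()
        de = moderated_de(m, grades)
        _, oob, _ = rf_grade_classifier(m, grades, de, n_top=25, n_trees=500, seed=0)
        assert oob <= 0.05

    def test_permuted_labels_high_oob(self, rng):
        m, grades = self._planted(seed=16)
        de = moderated_de(m, grades)
        shuffled = rng.permutation(list(grades.values())).tolist()
        bad = dict(zip(grades.keys(), shuffled))
        # keep both classes present and balanced as in the real labels
        _, oob, _ = rf_grade_classifier(m, bad, de, n_top=25, n_trees=500, seed=0)
        assert oob >= 0.25

    def test_seed_reproducibility(self):
        m, grades = self._planted(seed=17)
        de = moderated_de(m, grades)
        _, oob1, _ = rf_grade_classifier(m, grades, de, n_top=25, n_trees=300, seed=5)
        _, oob2, _ = rf_grade_classifier(m, grades, de, n_top=25, n_trees=300, seed=5)
        assert oob1 == oob2

    def test_external_accuracy(self):
        m, grades = self._planted(seed=18)
        de = moderated_de(m, grades)
        mt, gt = self._planted(seed=19)
        _, _, acc = rf_grade_classifier(m, grades, de, n_top=25, n_trees=500, seed=0,
                                        test_matrix=mt, test_grades=gt)
        assert acc is not None and acc >= 0.9

    def test_single_class_rejected(self):
        m, grades = self._planted(seed=20)
        de = moderated_de(m, grades)
        with pytest.raises(DesignError):
            rf_grade_classifier(m, {s: "benign" for s in m.columns}, de, n_top=10, n_trees=50, seed=0)
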