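"""TMM normalization, two-stage robust enrichment z-scores, group contrasts."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pqtlx.enrichment import (
    CountMatrix,
    contrast_by_group,
    cpm,
    enrichment_z,
    filter_genes,
    tissue_medians,
    tmm_factors,
)

from oracles import pearson_chi2_2x2


def _cm(counts, tissues=None):
    counts = np.asarray(counts)
    g, s = counts.shape
    genes = [f"g{i}" for i in range(g)]
    samples = [f"s{j}" for j in range(s)]
    tissue_of = {f"s{j}": (tissues[j] if tissues else "t0") for j in range(s)}
    return CountMatrix(genes, samples, tissue_of, counts)


class TestFilterGenes:
    def test_detection_thresholds_inclusive(self):
        # gene 0: count 5 in exactly 20% of 10 samples -> kept
        # gene 1: count 4 everywhere -> removed; gene 2: all zero -> removed
        counts = np.vstack(
            [
                [5, 5, 0, 0, 0, 0, 0, 0, 0, 0],
                [4] * 10,
                [0] * 10,
            ]
        )
        kept = filter_genes(_cm(counts))
        assert kept.genes == ["g0"]


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.integers(1, 500, 100)
        cm = _cm(np.column_stack([col] * 4))
        np.testing.assert_allclose(tmm_factors(cm), 1.0, atol=1e-6)

    def test_uniform_scaling_cancels(self, rng):
        a = rng.integers(10, 500, 200)
        b = rng.integers(10, 500, 200)
        cm = _cm(np.column_stack([a, b, 3 * b]))
        f = tmm_factors(cm)
        assert f[1] == pytest.approx(f[2], abs=1e-6)

    def test_composition_bias_recovered(self, rng):
        # 10% of genes 8-fold up in sample 1: unperturbed genes keep their
        # normalized expression iff factor_1/factor_0 = N_0/N_1'
        base = rng.integers(50, 1000, 1000).astype(float)
        spiked = base.copy()
        idx = rng.choice(1000, 100, replace=False)
        spiked[idx] *= 8
        cm = _cm(np.column_stack([base, spiked]).astype(int))
        f = tmm_factors(cm)
        truth = base.sum() / spiked.sum()  # library-size ratio of the spike
        assert (f[1] / f[0]) == pytest.approx(truth, rel=0.05)

    def test_geometric_mean_is_one(self, rng):
        for _ in range(5):
            counts = rng.integers(0, 300, size=(80, 6))
            counts[0] += 1  # avoid zero library
            f = tmm_factors(_cm(counts))
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_filtering_no_op_when_nothing_filtered(self, rng):
        counts = rng.integers(10, 400, size=(60, 5))
        cm = _cm(counts)
        np.testing.assert_allclose(tmm_factors(filter_genes(cm)), tmm_factors(cm))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_reference(self, rng, tmp_path):
        """Independent oracle: edgeR::calcNormFactors on the same matrix."""
        counts = rng.negative_binomial(5, 0.01, size=(300, 6))
        counts[rng.random(counts.shape) < 0.1] = 0
        counts[:, 0] += 1  # guard against empty libraries
        cm = _cm(counts)
        path = tmp_path / "counts.tsv"
        pd.DataFrame(counts).to_csv(path, sep="\t", index=False, header=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'x <- as.matrix(read.delim("{path}", header=FALSE));'
             'suppressMessages(library(edgeR));'
             'f <- calcNormFactors(x, method="TMM");'
             'cat(sprintf("%.10f", f), sep="\\n")'],
            capture_output=True, text=True, check=True,
        )
        ref = np.array([float(v) for v in r.stdout.strip().splitlines()])
        np.testing.assert_allclose(tmm_factors(cm), ref, rtol=1e-6)


class TestTissueMedians:
    def test_median_semantics_and_permutation_invariance(self, rng):
        counts = np.array([[1, 2, 100, 7], [10, 20, 30, 40]])
        tissues = ["t0", "t0", "t0", "t1"]
        cm = _cm(counts, tissues)
        f = np.ones(4)
        med = tissue_medians(cm, f)
        expr = cpm(cm, f)
        assert med.loc["g0", "t0"] == np.median(expr[0, :3])
        assert med.loc["g0", "t1"] == expr[0, 3]  # single-sample tissue
        perm = [2, 0, 1, 3]
        cm2 = CountMatrix(cm.genes, [cm.samples[i] for i in perm],
                          cm.tissue_of, counts[:, perm])
        med2 = tissue_medians(cm2, np.ones(4))
        pd.testing.assert_frame_equal(med, med2)


class TestEnrichmentZ:
    def test_constant_rows_all_excluded(self):
        med = pd.DataFrame(
            np.outer([1.0, 5.0, 9.0, 2.0], np.ones(4)),
            index=list("abcd"), columns=[f"t{j}" for j in range(4)],
        )
        enr = enrichment_z(med)
        assert set(enr.excluded_genes) == set("abcd")
        assert not enr.elevated.to_numpy().any()

    def test_planted_single_tissue_spike_detected(self, rng):
        for trial in range(5):
            base = rng.lognormal(3, 0.2, size=(50, 10))
            med = pd.DataFrame(base, index=[f"g{i}" for i in range(50)],
                               columns=[f"t{j}" for j in range(10)])
            med.iloc[7, 3] *= 10
            enr = enrichment_z(med)
            row = enr.z.loc["g7"]
            assert row["t3"] > 2
            assert row.idxmax() == "t3"
            # the spike dominates every other tissue of that gene by far
            assert row["t3"] > 5 * max(2.0, row.drop("t3").max())

    def test_stage1_affine_equivariance(self, rng):
        base = rng.lognormal(3, 0.5, size=(40, 6))
        med = pd.DataFrame(base, index=[f"g{i}" for i in range(40)],
                           columns=[f"t{j}" for j in range(6)])
        enr = enrichment_z(med)
        med2 = med.copy()
        med2["t2"] = 3.5 * med2["t2"] + 11.0
        enr2 = enrichment_z(med2)
        pd.testing.assert_series_equal(enr.stage1["t2"], enr2.stage1["t2"])

    def test_rows_standardized_to_median0_mad1(self, rng):
        med = pd.DataFrame(rng.lognormal(3, 0.5, size=(30, 8)))
        med.index = med.index.astype(str)
        med.columns = med.columns.astype(str)
        enr = enrichment_z(med)
        kept = [g for g in enr.genes if g not in enr.excluded_genes]
        z = enr.z.loc[kept].to_numpy()
        np.testing.assert_allclose(np.median(z, axis=1), 0.0, atol=1e-9)
        mad = np.median(np.abs(z - np.median(z, axis=1, keepdims=True)), axis=1)
        np.testing.assert_allclose(1.4826 * mad, 1.0, atol=1e-9)


class TestContrast:
    def _enr(self, elevated: np.ndarray):
        g, t = elevated.shape
        genes = [f"g{i}" for i in range(g)]
        tissues = [f"t{j}" for j in range(t)]
        zeros = pd.DataFrame(np.zeros((g, t)), index=genes, columns=tissues)
        from pqtlx.enrichment import EnrichmentMatrix

        return EnrichmentMatrix(genes, tissues, zeros, zeros, zeros,
                                pd.DataFrame(elevated, index=genes, columns=tissues))

    def test_hand_computed_chi2(self):
        # [[30, 70], [10, 90]]: hand Pearson formula gives exactly 12.5
        elevated = np.zeros((200, 1), dtype=bool)
        elevated[:30] = True       # coloc elevated
        elevated[100:110] = True   # noncoloc elevated
        groups = {f"g{i}": ("coloc" if i < 100 else "noncoloc") for i in range(200)}
        (c,) = contrast_by_group(self._enr(elevated), groups)
        assert (c.n_elevated_coloc, c.n_total_coloc) == (30, 100)
        assert (c.n_elevated_noncoloc, c.n_total_noncoloc) == (10, 100)
        assert c.chi2 == pytest.approx(pearson_chi2_2x2(30, 70, 10, 90), abs=1e-9)
        assert c.chi2 == pytest.approx(12.5, abs=1e-9)
        assert c.direction == "coloc"

    def test_equal_proportions_give_null(self):
        elevated = np.zeros((100, 1), dtype=bool)
        elevated[:20] = True
        elevated[50:70] = True
        groups = {f"g{i}": ("coloc" if i < 50 else "noncoloc") for i in range(100)}
        (c,) = contrast_by_group(self._enr(elevated), groups)
        assert c.chi2 == pytest.approx(0.0, abs=1e-12)
        assert c.p == pytest.approx(1.0)

    def test_group_label_swap_is_symmetric(self):
        elevated = np.zeros((60, 2), dtype=bool)
        elevated[:25, 0] = True
        elevated[10:20, 1] = True
        g1 = {f"g{i}": ("coloc" if i < 30 else "noncoloc") for i in range(60)}
        g2 = {k: ("noncoloc" if v == "coloc" else "coloc") for k, v in g1.items()}
        for c1, c2 in zip(contrast_by_group(self._enr(elevated), g1),
                          contrast_by_group(self._enr(elevated), g2)):
            assert c1.chi2 == pytest.approx(c2.chi2, abs=1e-12)
            assert c1.p == pytest.approx(c2.p, abs=1e-12)

    def test_zero_marginal_recorded_absent(self):
        elevated = np.zeros((40, 1), dtype=bool)  # nobody elevated anywhere
        groups = {f"g{i}": ("coloc" if i < 20 else "noncoloc") for i in range(40)}
        (c,) = contrast_by_group(self._enr(elevated), groups)
        assert c.chi2 is None and c.p is None
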