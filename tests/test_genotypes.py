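"""QC, imputation, glutenin recoding, kinship and diversity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatgs import (
    compute_grm, impute_missing, modified_rogers_distance, qc_markers,
    recode_glu, structure_pca,
)
from wheatgs.containers import GenotypeMatrix
from wheatgs.genotypes import glu_model_matrix
from wheatgs.synthetic import inject_marker_missingness, simulate_genotypes


def _toy_matrix(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        [f"L{i}" for i in range(n)], [f"M{j}" for j in range(m)],
        np.ones(m, dtype=int) if chrom is None else np.asarray(chrom),
        np.arange(m, dtype=float), dosages)


class TestQC:
    def test_maf_and_missingness_rules(self):
        n = 50
        rng = np.random.default_rng(0)
        good = rng.choice([-1.0, 1.0], size=(n, 1))
        rare = np.full((n, 1), -1.0)
        rare[:2] = 1.0                       # MAF 0.04 -> removed
        gappy = rng.choice([-1.0, 1.0], size=(n, 1))
        gappy[:6] = np.nan                   # 12% missing -> removed
        geno = _toy_matrix(np.hstack([good, rare, gappy]))
        kept, report = qc_markers(geno)
        assert kept.markers == ["M0"]
        assert report.removed_maf == ["M1"]
        assert report.removed_missing == ["M2"] or "M2" in report.removed_call_rate

    def test_clean_matrix_is_identity(self, small_pop):
        # once QC'd, a second pass changes nothing
        once, _ = qc_markers(small_pop["geno"])
        twice, report = qc_markers(once)
        assert report.n_kept == report.n_input
        np.testing.assert_array_equal(twice.dosages, once.dosages)

    def test_marker_order_invariance(self, small_pop):
        geno = inject_marker_missingness(small_pop["geno"], 0.05, 10, seed=5)
        kept_fwd, _ = qc_markers(geno)
        perm = np.random.default_rng(1).permutation(geno.n_markers)
        kept_perm, _ = qc_markers(geno.subset_markers(perm))
        assert sorted(kept_fwd.markers) == sorted(kept_perm.markers)


class TestImputation:
    def test_no_missing_is_identity(self, small_pop):
        out = impute_missing(small_pop["geno"], "column_mode", seed=0)
        np.testing.assert_array_equal(out.dosages, small_pop["geno"].dosages)

    def test_column_mode_rule(self):
        col = np.ones((10, 2))
        col[0, 0] = np.nan
        out = impute_missing(_toy_matrix(col), "column_mode", seed=0)
        assert out.dosages[0, 0] == 1.0

    def test_iterative_beats_or_matches_mode_on_masked_entries(self):
        geno, _ = simulate_genotypes(n_families=20, n_lines=60,
                                     n_chromosomes=2,
                                     markers_per_chromosome=60, seed=30)
        rng = np.random.default_rng(31)
        masked = geno.copy()
        mask = rng.random(masked.dosages.shape) < 0.05
        truth = masked.dosages[mask].copy()
        masked.dosages[mask] = np.nan
        err = {}
        for method in ("iterative_forest_like", "column_mode"):
            imp = impute_missing(masked, method, seed=32)
            err[method] = (imp.dosages[mask] != truth).mean()
        assert err["iterative_forest_like"] <= err["column_mode"]

    def test_fully_missing_marker_rejected(self):
        bad = np.ones((5, 2))
        bad[:, 1] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(_toy_matrix(bad), "column_mode", seed=0)


class TestGluRecoding:
    def test_glutenin_coding_table(self):
        calls = pd.DataFrame(
            {"Glu-A1": ["2*", "0", "1"], "Glu-B1": ["7+9", "6+8", "7+8"],
             "Glu-D1": ["5+10", "2+12", "2+12"]},
            index=["a", "b", "c"])
        coded = recode_glu(calls)
        np.testing.assert_array_equal(coded.loc["a"], [1.0, 1.0, -1.0])
        np.testing.assert_array_equal(coded.loc["b"], [-1.0, -1.0, 1.0])
        np.testing.assert_array_equal(coded.loc["c"], [1.0, 1.0, 1.0])

    def test_heterozygous_and_missing(self):
        calls = pd.DataFrame({"Glu-A1": ["0/1"], "Glu-B1": [np.nan],
                              "Glu-D1": ["5+10/2+12"]}, index=["a"])
        coded = recode_glu(calls)
        assert coded.loc["a", "Glu-A1"] == 0.0
        assert np.isnan(coded.loc["a", "Glu-B1"])
        assert coded.loc["a", "Glu-D1"] == 0.0
        assert set(glu_model_matrix(coded).loc["a"]) <= {-1.0, 0.0, 1.0}

    def test_unknown_allele_rejected(self):
        calls = pd.DataFrame({"Glu-A1": ["X"], "Glu-B1": ["7+8"],
                              "Glu-D1": ["2+12"]}, index=["a"])
        with pytest.raises(ValueError, match="unknown"):
            recode_glu(calls)

    def test_simulated_calls_recode_into_legal_set(self, small_pop):
        coded = glu_model_matrix(recode_glu(small_pop["glu"]))
        assert coded.isin([-1.0, 0.0, 1.0]).all().all()


class TestGRM:
    def _oracle(self, Z):
        """Loop-based Endelman-Jannink computation."""
        n, m = Z.shape
        p = np.array([(Z[:, k] + 1).sum() / (2 * n) for k in range(m)])
        W = np.array([[Z[i, k] + 1 - 2 * p[k] for k in range(m)]
                      for i in range(n)])
        denom = 2 * sum(p[k] * (1 - p[k]) for k in range(m))
        K = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                K[i, j] = sum(W[i, k] * W[j, k] for k in range(m)) / denom
        return K

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(40)
        Z = rng.choice([-1.0, 0.0, 1.0], size=(6, 8), p=[0.45, 0.1, 0.45])
        K = compute_grm(_toy_matrix(Z)).K
        np.testing.assert_allclose(K, self._oracle(Z), atol=1e-12)

    def test_identical_lines_share_diagonal_value(self):
        rng = np.random.default_rng(41)
        Z = rng.choice([-1.0, 1.0], size=(4, 20))
        Z[1] = Z[0]
        K = compute_grm(_toy_matrix(Z)).K
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_marker_duplication_invariance(self):
        rng = np.random.default_rng(42)
        Z = rng.choice([-1.0, 0.0, 1.0], size=(5, 10))
        K1 = compute_grm(_toy_matrix(Z)).K
        K2 = compute_grm(_toy_matrix(np.hstack([Z, Z]))).K
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(_toy_matrix(np.ones((4, 5))))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_psd_and_symmetric_for_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.choice([-1.0, 0.0, 1.0], size=(8, 15), p=[0.45, 0.1, 0.45])
        if np.all(Z == Z[0, :][None, :]) or np.ptp(Z) == 0:
            return
        try:
            K = compute_grm(_toy_matrix(Z)).K
        except ValueError:
            return
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-8


class TestRogersDistance:
    def test_identity_and_maximum(self):
        Z = np.array([[1.0] * 6, [1.0] * 6, [-1.0] * 6])
        D, _ = modified_rogers_distance(_toy_matrix(Z))
        assert D.iloc[0, 1] == 0.0
        assert D.iloc[0, 2] == pytest.approx(1.0)

    def test_matches_allele_frequency_oracle(self):
        rng = np.random.default_rng(50)
        Z = rng.choice([-1.0, 0.0, 1.0], size=(4, 6))
        D, _ = modified_rogers_distance(_toy_matrix(Z))
        m = Z.shape[1]
        for i in range(4):
            for j in range(4):
                # per-locus allele frequencies of the two alleles
                acc = 0.0
                for k in range(m):
                    pi = (Z[i, k] + 1) / 2
                    pj = (Z[j, k] + 1) / 2
                    acc += (pi - pj) ** 2 + ((1 - pi) - (1 - pj)) ** 2
                expected = np.sqrt(acc / (2 * m))
                assert D.iloc[i, j] == pytest.approx(expected, abs=1e-12)


class TestVcfImport:
    def test_gt_mapping_roundtrip(self, tmp_path):
        from wheatgs.genotypes import genotypes_from_vcf
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\tL3\n"
            "1\t100\tm1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tm2\tC\tT\t.\tPASS\t.\tGT\t1|1\t./.\t0/0\n")
        geno = genotypes_from_vcf(str(vcf))
        assert geno.lines == ["L1", "L2", "L3"]
        np.testing.assert_array_equal(geno.dosages[:, 0], [-1.0, 0.0, 1.0])
        assert geno.dosages[0, 1] == 1.0
        assert np.isnan(geno.dosages[1, 1])
        assert geno.dosages[2, 1] == -1.0


class TestStructurePCA:
    def test_eigenvalue_sum_is_trace_and_isotropic_case(self, small_pop):
        scores, explained = structure_pca(small_pop["kinship"])
        vals = np.linalg.eigvalsh(small_pop["kinship"].K)
        assert explained.sum() <= 1.0 + 1e-9
        assert scores.shape[0] == small_pop["kinship"].K.shape[0]
        # isotropic kinship: uniform explained variance
        from wheatgs.containers import Kinship
        eye = Kinship(["a", "b", "c"], np.eye(3))
        _, ev = structure_pca(eye, n_components=3)
        np.testing.assert_allclose(ev, [1 / 3] * 3, atol=1e-12)

    def test_divergent_families_separate_on_pc1(self):
        geno, fams = simulate_genotypes(n_families=2, lines_per_family=25,
                                        n_chromosomes=2,
                                        markers_per_chromosome=100, seed=60)
        scores, _ = structure_pca(compute_grm(geno))
        pc1 = scores["PC1"].to_numpy()
        fam = np.array(fams)
        gap = abs(pc1[fam == fam[0]].mean() - pc1[fam != fam[0]].mean())
        spread = pc1[fam == fam[0]].std() + pc1[fam != fam[0]].std()
        assert gap > 0.5 * spread
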