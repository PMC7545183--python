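import numpy as np
import pandas as pd
import pytest

from feralscan.gwas import (
    bonferroni_threshold,
    encode_sv_pseudo_variants,
    genotype_pca,
    kinship_matrix,
    local_structure_covariates,
    mlm_association,
    variance_explained,
)
from feralscan.variants import read_vcf, write_vcf
from tests.conftest import make_table
from tests.oracles import ols_marker_pvalue


def random_table_raw(rng, n=40, m=60, p=None):
    if p is None:
        p = rng.uniform(0.1, 0.9, size=m)
    dosage = 2 * (rng.random((n, m)) < p).astype(np.int8)
    return make_table(dosage)


class TestGenotypePca:
    def test_pc1_separates_two_clusters(self, rng):
        a = 2 * (rng.random((15, 50)) < 0.9).astype(np.int8)
        b = 2 * (rng.random((15, 50)) < 0.1).astype(np.int8)
        t = make_table(np.vstack([a, b]))
        pcs = genotype_pca(t, 2)
        assert (pcs[:15, 0].mean() - pcs[15:, 0].mean()) ** 2 > 4 * (
            pcs[:15, 0].var() + pcs[15:, 0].var()
        )

    def test_duplicated_sample_identical_coordinates(self, rng):
        t = random_table_raw(rng, n=20)
        dup = make_table(np.vstack([t.dosage, t.dosage[:1]]))
        pcs = genotype_pca(dup, 3)
        assert np.allclose(pcs[0], pcs[-1], atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        t = random_table_raw(rng, n=20, m=50)
        pcs = genotype_pca(t, 4)
        d = t.dosage.astype(float)
        d -= d.mean(axis=0)
        sd = d.std(axis=0)
        d = d[:, sd > 0] / sd[sd > 0]
        evals, evecs = np.linalg.eigh(d @ d.T)
        order = np.argsort(evals)[::-1][:4]
        for j, k in enumerate(order):
            score = evecs[:, k] * np.sqrt(evals[k])
            assert np.allclose(np.abs(pcs[:, j]), np.abs(score), atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            genotype_pca(random_table_raw(rng, n=5), 5)


class TestKinship:
    def test_symmetric_and_diagonal_dominant_in_expectation(self, rng):
        K = kinship_matrix(random_table_raw(rng))
        assert np.allclose(K, K.T)
        off = K[~np.eye(len(K), dtype=bool)]
        assert K.diagonal().mean() > off.mean()

    def test_identical_samples_equal_rows(self, rng):
        t = random_table_raw(rng, n=10)
        dup = make_table(np.vstack([t.dosage, t.dosage[:1]]))
        K = kinship_matrix(dup)
        assert np.allclose(K[0], K[-1])

    def test_matches_double_loop_oracle(self, rng):
        t = random_table_raw(rng, n=10, m=30)
        K = kinship_matrix(t)
        d = t.dosage.astype(float)
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        d, p = d[:, poly], p[poly]
        denom = (2 * p * (1 - p)).sum()
        for i in range(10):
            for j in range(10):
                kij = sum(
                    (d[i, s] - 2 * p[s]) * (d[j, s] - 2 * p[s]) for s in range(d.shape[1])
                ) / denom
                assert K[i, j] == pytest.approx(kij, abs=1e-10)


class TestMlmAssociation:
    def test_identity_kinship_reduces_to_ols(self, rng):
        t = random_table_raw(rng, n=50, m=40)
        y = rng.normal(size=50)
        assoc = mlm_association(t, y, None, np.eye(50))
        for j in range(40):
            p_ols = ols_marker_pvalue(t.dosage[:, j], y)
            assert abs(assoc["p"].iloc[j] - p_ols) < 1e-8

    def test_null_type_one_error_calibrated(self, rng):
        n, m = 80, 200
        t = random_table_raw(rng, n=n, m=m)
        y = rng.normal(size=n)  # phenotype independent of all markers
        K = kinship_matrix(t)
        assoc = mlm_association(t, y, None, K)
        rate = (assoc["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) <= 3 * se

    def test_perfect_marker_extreme_p(self, rng):
        t = random_table_raw(rng, n=100, m=5)
        y = t.dosage[:, 2].astype(float)
        assoc = mlm_association(t, y, None, np.eye(100))
        assert assoc["p"].iloc[2] < 1e-10

    def test_singular_covariates_rejected(self, rng):
        t = random_table_raw(rng, n=20, m=5)
        covs = np.ones((20, 2))  # duplicate of the intercept
        with pytest.raises(ValueError):
            mlm_association(t, np.zeros(20), covs, np.eye(20))


class TestBonferroni:
    def test_published_panel_size(self):
        thr = bonferroni_threshold(0.01, 35_045_206)
        assert thr == pytest.approx(2.85e-10, rel=5e-3)

    def test_simple_value_and_monotonicity(self):
        assert bonferroni_threshold(0.05, 10) == pytest.approx(5e-3)
        assert bonferroni_threshold(0.01, 100) > bonferroni_threshold(0.01, 1_000)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestEncodeSv:
    def sv_frame(self):
        return pd.DataFrame(
            {
                "id": ["del0"],
                "chrom": ["chr3D"],
                "pos": [55_500_001],
                "s0": ["present"],
                "s1": ["absent"],
                "s2": ["present"],
                "s3": ["unknown"],
                "s4": ["present"],
            }
        )

    def test_presence_encoding(self):
        t = encode_sv_pseudo_variants(self.sv_frame(), ["s0", "s1", "s2", "s3", "s4"])
        assert list(t.dosage[:, 0]) == [2, 0, 2, -1, 2]

    def test_round_trip_through_vcf(self, tmp_path):
        t = encode_sv_pseudo_variants(self.sv_frame(), ["s0", "s1", "s2", "s3", "s4"])
        path = tmp_path / "sv.vcf"
        write_vcf(t, path)
        back = read_vcf(path)
        assert (back.dosage == t.dosage).all()

    def test_bad_status_rejected(self):
        frame = self.sv_frame()
        frame.loc[0, "s1"] = "maybe"
        with pytest.raises(ValueError):
            encode_sv_pseudo_variants(frame, ["s0", "s1", "s2", "s3", "s4"])


class TestVarianceExplained:
    def test_orthogonal_marker_near_zero(self, rng):
        n = 200
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        ve = variance_explained(x, y, None, np.eye(n))
        assert ve < 0.05

    def test_marker_equal_to_phenotype_near_one(self, rng):
        n = 100
        x = rng.integers(0, 3, size=n).astype(float)
        ve = variance_explained(x, x.copy(), None, np.eye(n))
        assert ve > 0.99

    def test_planted_fraction_recovered_over_seeds(self):
        # SV generates the phenotype with 25% residual noise -> planted
        # variance fraction 0.75; mean recovery over 50 seeds within 5 pts
        planted = 0.75
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 102
            x = np.repeat([0.0, 2.0], n // 2)
            rng.shuffle(x)
            signal = x - x.mean()
            signal /= signal.std()
            noise = rng.normal(size=n)
            noise /= noise.std()
            y = np.sqrt(planted) * signal + np.sqrt(1 - planted) * noise
            estimates.append(variance_explained(x, y, None, np.eye(n)))
        assert abs(np.mean(estimates) - planted) < 0.05


class TestLocalStructureCovariates:
    def test_column_count_before_rank_filtering(self, rng):
        # two chromosomes with independent structure -> 10 columns survive
        a = np.hstack(
            [
                2 * (rng.random((30, 40)) < np.where(np.arange(30) < 15, 0.8, 0.2)[:, None]),
                2 * (rng.random((30, 40)) < rng.uniform(0.2, 0.8, (30, 40))),
            ]
        ).astype(np.int8)
        t = make_table(a, chrom=["chr3B"] * 40 + ["chr1A"] * 40)
        covs = local_structure_covariates(t, "chr3B", 5, 5)
        assert covs.shape == (30, 10)

    def test_identical_local_and_global_structure_filtered(self, rng):
        t = random_table_raw(rng, n=25, m=30)  # single chromosome
        with pytest.warns(UserWarning):
            covs = local_structure_covariates(t, "chr1A", 4, 4)
        assert covs.shape[1] < 8

    def test_too_few_target_sites_rejected(self, rng):
        t = random_table_raw(rng, n=20, m=10)
        with pytest.raises(ValueError):
            local_structure_covariates(t, "chr7D", 5, 5)
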