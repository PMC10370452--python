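"""Genotype coding, LD pruning, genotype PCA and the linear association model."""

import numpy as np
import pytest

from sweepscan import association as A


class TestEncodeGenotype:
    GENOS = [("A", "A"), ("A", "G"), ("G", "G")]

    def test_additive_counts_minor_copies(self):
        np.testing.assert_array_equal(
            A.encode_genotype(self.GENOS, "additive", minor="G"), [0, 1, 2]
        )

    def test_dominant_carrier_indicator(self):
        np.testing.assert_array_equal(
            A.encode_genotype(self.GENOS, "dominant", minor="G"), [0, 1, 1]
        )

    def test_minor_allele_determined_from_cohort(self):
        genos = [("A", "A")] * 5 + [("A", "G")]
        assert A.minor_allele(genos) == "G"

    def test_flipping_minor_maps_dosage_to_two_minus(self, rng):
        bases = np.array(["A", "G"])
        for _ in range(10):
            g = [tuple(bases[rng.integers(0, 2, 2)]) for _ in range(30)]
            if len({a for p in g for a in p}) < 2:
                continue
            d_g = A.encode_genotype(g, "additive", minor="G")
            d_a = A.encode_genotype(g, "additive", minor="A")
            np.testing.assert_array_equal(d_g, 2 - d_a)

    def test_missing_genotype_nan(self):
        out = A.encode_genotype(self.GENOS + [None], "additive", minor="G")
        assert np.isnan(out[3])

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            A.encode_genotype([("A", "A"), ("A", "A")], "additive")


class TestLdPrune:
    def test_perfectly_correlated_pair_drops_later_site(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        dosage = np.vstack([x, x, rng.integers(0, 3, 50).astype(float)])
        kept = A.ld_prune(dosage, r2_max=0.8, window=10, step=5)
        assert 0 in kept and 1 not in kept

    def test_orthogonal_sites_all_kept(self):
        dosage = np.eye(6) * 2  # mutually uncorrelated columns-ish
        kept = A.ld_prune(dosage, r2_max=0.8, window=6, step=3)
        assert len(kept) == 6

    def test_postcondition_no_high_r2_pair_in_window(self, rng):
        for _ in range(10):
            n_sites = int(rng.integers(5, 40))
            base = rng.integers(0, 3, (n_sites, 30)).astype(float)
            # plant some duplicated sites
            for _ in range(n_sites // 3):
                i, j = rng.integers(0, n_sites, 2)
                base[j] = base[i]
            window, step = 8, 3
            kept = A.ld_prune(base, r2_max=0.8, window=window, step=step)
            for start in range(0, max(n_sites - 1, 1), step):
                in_win = [i for i in kept if start <= i < start + window]
                for a in range(len(in_win)):
                    for b in range(a + 1, len(in_win)):
                        xi, xj = base[in_win[a]], base[in_win[b]]
                        if xi.std() == 0 or xj.std() == 0:
                            continue
                        r = np.corrcoef(xi, xj)[0, 1]
                        assert r * r <= 0.8 + 1e-12

    def test_window_too_small_raises(self, rng):
        with pytest.raises(ValueError):
            A.ld_prune(rng.integers(0, 3, (5, 10)).astype(float), window=1)


class TestComputePcs:
    def test_separates_two_diverged_populations(self, rng):
        # Balding-Nichols-style divergence: PC1 should split the groups
        p0 = rng.uniform(0.1, 0.9, 200)
        f = 0.2
        dosages = []
        labels = []
        for pop in range(2):
            p = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
            dosages.append(rng.binomial(2, p, size=(40, 200)).astype(float))
            labels += [pop] * 40
        x = np.vstack(dosages)
        pcs = A.compute_pcs(x, k=3)
        labels = np.array(labels)
        gap = abs(pcs[labels == 0, 0].mean() - pcs[labels == 1, 0].mean())
        spread = pcs[labels == 0, 0].std() + pcs[labels == 1, 0].std()
        assert gap > spread  # clear separation on PC1

    def test_components_orthogonal(self, rng):
        x = rng.binomial(2, 0.3, size=(50, 120)).astype(float)
        pcs = A.compute_pcs(x, k=4)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_constant_site_excluded(self, rng):
        x = rng.binomial(2, 0.4, size=(30, 50)).astype(float)
        x[:, 10] = 2.0
        pcs_with = A.compute_pcs(x, k=3)
        pcs_without = A.compute_pcs(np.delete(x, 10, axis=1), k=3)
        np.testing.assert_allclose(pcs_with, pcs_without, atol=1e-10)

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            A.compute_pcs(rng.binomial(2, 0.5, size=(5, 50)).astype(float), k=5)


class TestFitLinearModel:
    def test_phenotype_equals_dosage(self, rng):
        g = rng.integers(0, 3, 40).astype(float)
        res = A.fit_linear_model(g, g)
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_phenotype(self, rng):
        g = rng.integers(0, 3, 40).astype(float)
        res = A.fit_linear_model(np.full(40, 2.5), g)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == 0.0

    def test_matches_normal_equations(self, rng):
        for _ in range(10):
            n = 50
            g = rng.integers(0, 3, n).astype(float)
            cov = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            res = A.fit_linear_model(y, g, cov)
            x = np.column_stack([np.ones(n), g, cov])
            beta_hat = np.linalg.solve(x.T @ x, x.T @ y)
            assert res.beta == pytest.approx(beta_hat[1], abs=1e-10)

    def test_orthogonal_covariate_leaves_beta(self, rng):
        n = 80
        g = rng.integers(0, 3, n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        z = rng.normal(size=n)
        # orthogonalize z against intercept, dosage and phenotype
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), g, y]))
        z = z - q @ (q.T @ z)
        base = A.fit_linear_model(y, g)
        with_cov = A.fit_linear_model(y, g, z)
        assert with_cov.beta == pytest.approx(base.beta, abs=1e-10)

    def test_complete_case_drops_missing(self, rng):
        g = rng.integers(0, 3, 30).astype(float)
        y = 0.5 * g + rng.normal(size=30)
        g[3] = np.nan
        y[7] = np.nan
        res = A.fit_linear_model(y, g)
        assert res.n == 28

    def test_ci_uses_t_quantile(self, rng):
        from scipy import stats

        n = 25
        g = rng.integers(0, 3, n).astype(float)
        y = 0.4 * g + rng.normal(size=n)
        res = A.fit_linear_model(y, g)
        t = stats.t.ppf(0.975, n - 2)
        assert res.ci_low == pytest.approx(res.beta - t * res.se, abs=1e-10)
        assert res.ci_high == pytest.approx(res.beta + t * res.se, abs=1e-10)

    def test_collinear_design_raises_naming_columns(self, rng):
        g = rng.integers(0, 3, 30).astype(float)
        y = rng.normal(size=30)
        res = pytest.raises(ValueError, A.fit_linear_model, y, g, np.column_stack([g, g]))
        assert "collinear" in str(res.value)

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError, match="complete cases"):
            A.fit_linear_model(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestPhenotypeTable:
    def test_log_transform_requires_positive(self):
        with pytest.raises(ValueError):
            A.log_transform(np.array([1.0, 0.0]))
        np.testing.assert_allclose(A.log_transform(np.array([np.e])), [1.0])

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("sample_id\tsex\tphenotype\nA\t0\t12.0\nA\t1\t9.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            A.read_phenotype_table(str(p))

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("sample_id\tsex\nA\t0\n")
        with pytest.raises(ValueError, match="phenotype"):
            A.read_phenotype_table(str(p))
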