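"""nSL / XP-nSL shared-haplotype-length statistics against exhaustive oracles."""

import numpy as np
import pytest

import oracles
from conftest import make_matrix, random_matrix
from sweepscan import haplotype as H


class TestPairwiseSl:
    def test_identical_haplotypes_full_length(self, rng):
        hap = rng.integers(0, 2, 7).astype(np.int8)
        m = make_matrix(np.column_stack([hap, hap]))
        for focal in range(7):
            assert H.pairwise_sl(m, focal, np.array([0, 1])) == 7.0

    def test_hand_traced_run(self):
        # haplotypes 01100 and 01101 agree on sites 1-4 (1-based); at focal
        # site 3 the shared run has length 4
        m = make_matrix(np.column_stack([[0, 1, 1, 0, 0], [0, 1, 1, 0, 1]]))
        assert H.pairwise_sl(m, 2, np.array([0, 1])) == 4.0

    def test_single_haplotype_undefined(self, rng):
        m = random_matrix(rng, 5, 2)
        assert np.isnan(H.pairwise_sl(m, 0, np.array([0])))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            m = random_matrix(
                rng, int(rng.integers(3, 30)), int(rng.integers(2, 5)),
                missing_frac=float(rng.choice([0.0, 0.1])),
            )
            haps = np.arange(m.n_haplotypes)
            focal = int(rng.integers(m.n_sites))
            got = H.pairwise_sl(m, focal, haps)
            want = oracles.mean_sl_pairs(m.alleles, focal, haps)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)


class TestNsl:
    def test_mirror_symmetric_data_zero(self):
        # ancestral and derived carrier sets with identical internal structure
        block = np.array(
            [[0, 0, 1, 1],
             [0, 1, 0, 1],
             [1, 0, 1, 0],
             [0, 0, 1, 1]], dtype=np.int8
        )
        alleles = np.hstack([block, block])
        alleles[1] = [0, 0, 0, 0, 1, 1, 1, 1]  # focal: haps 4-7 derived
        m = make_matrix(alleles)
        df = H.nsl_scan(m, np.arange(8))
        assert df["raw"][1] == pytest.approx(0.0)

    def test_allele_relabel_flips_sign(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 20, 8)
            df = H.nsl_scan(m, np.arange(16))
            s = int(rng.integers(m.n_sites))
            flipped = m.alleles.copy()
            flipped[s] = 1 - flipped[s]
            m2 = make_matrix(flipped)
            df2 = H.nsl_scan(m2, np.arange(16))
            if np.isfinite(df["raw"][s]):
                assert df2["raw"][s] == pytest.approx(-df["raw"][s])

    def test_requires_polarized_matrix(self, rng):
        m = random_matrix(rng, 5, 3, polarized=False)
        with pytest.raises(ValueError, match="polarized"):
            H.nsl_scan(m, np.arange(6))

    def test_monomorphic_and_low_maf_undefined(self):
        alleles = np.zeros((4, 8), dtype=np.int8)
        alleles[1, 0] = 1  # singleton: MAF 1/8 > 0.05 but only 1 derived carrier
        m = make_matrix(alleles)
        df = H.nsl_scan(m, np.arange(8))
        assert np.isnan(df["raw"][0])  # monomorphic
        assert np.isnan(df["raw"][1])  # fewer than 2 derived carriers

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(40):
            m = random_matrix(
                rng, int(rng.integers(4, 40)), int(rng.integers(2, 7)),
                missing_frac=float(rng.choice([0.0, 0.05])),
            )
            haps = np.arange(m.n_haplotypes)
            df = H.nsl_scan(m, haps)
            for s in range(m.n_sites):
                want = oracles.nsl_site(m.alleles, s, haps)
                got = df["raw"][s]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestXpNsl:
    def test_identical_populations_zero(self, rng):
        m = random_matrix(rng, 15, 4)
        both = np.hstack([m.alleles, m.alleles])
        m2 = make_matrix(both)
        df = H.xpnsl_scan(m2, np.arange(8), np.arange(8, 16))
        finite = df["raw"].dropna()
        assert (finite.abs() < 1e-12).all()

    def test_swapping_populations_flips_sign(self, rng):
        m = random_matrix(rng, 20, 8)
        h1, h2 = np.arange(8), np.arange(8, 16)
        fwd = H.xpnsl_scan(m, h1, h2)["raw"]
        rev = H.xpnsl_scan(m, h2, h1)["raw"]
        mask = np.isfinite(fwd)
        np.testing.assert_allclose(fwd[mask], -rev[mask], atol=1e-12)

    def test_too_few_haplotypes_raises(self, rng):
        m = random_matrix(rng, 5, 3)
        with pytest.raises(ValueError, match="at least 2"):
            H.xpnsl_scan(m, np.array([0]), np.arange(2, 6))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            m = random_matrix(rng, int(rng.integers(4, 40)), int(rng.integers(2, 6)))
            k = m.n_haplotypes // 2
            h1, h2 = np.arange(k), np.arange(k, m.n_haplotypes)
            df = H.xpnsl_scan(m, h1, h2)
            for s in range(m.n_sites):
                want = oracles.xpnsl_site(m.alleles, s, h1, h2)
                got = df["raw"][s]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestNormalization:
    def test_two_scores_single_bin(self):
        out = H.normalize_scores(np.array([-1.0, 1.0]))
        np.testing.assert_allclose(out, [-1.0, 1.0])

    def test_bins_have_mean_zero_sd_one(self, rng):
        raw = rng.normal(size=300)
        bins = rng.integers(0, 5, 300)
        out = H.normalize_scores(raw, bins)
        for b in range(5):
            sel = bins == b
            assert abs(out[sel].mean()) < 1e-12
            assert out[sel].std() == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_bin_loop_oracle(self, rng):
        raw = rng.normal(size=200)
        raw[rng.random(200) < 0.1] = np.nan
        bins = rng.integers(-1, 4, 200)
        out = H.normalize_scores(raw, bins)
        for i in range(200):
            if bins[i] < 0 or np.isnan(raw[i]):
                assert np.isnan(out[i])
                continue
            sel = (bins == bins[i]) & np.isfinite(raw)
            vals = raw[sel]
            if sel.sum() < 2 or vals.std() == 0:
                assert np.isnan(out[i])
            else:
                assert out[i] == pytest.approx((raw[i] - vals.mean()) / vals.std())

    def test_small_or_constant_bins_undefined(self):
        out = H.normalize_scores(np.array([1.0, 2.0, 2.0, 5.0]),
                                 np.array([0, 1, 1, 2]))
        assert np.isnan(out[0])          # singleton bin
        assert np.isnan(out[1]) and np.isnan(out[2])  # zero variance
        assert np.isnan(out[3])

    def test_freq_bin_edges(self):
        bins = H.freq_bins(np.array([0.0, 0.019, 0.02, 0.5, 1.0]), width=0.02)
        assert bins.tolist() == [0, 0, 1, 25, 49]


class TestSlProperties:
    def test_sl_bounds_and_locality(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 20, 4)
            df = H.nsl_scan(m, np.arange(8))
            for col in ("sl_anc", "sl_der"):
                vals = df[col].dropna()
                assert ((vals >= 1) & (vals <= m.n_sites)).all()
        # appending sites beyond every pair's mismatch boundary changes nothing
        base = np.array([[0, 1], [1, 1], [0, 1], [1, 0]], dtype=np.int8)
        extra = np.vstack([base, rng.integers(0, 2, (5, 2)).astype(np.int8)])
        sl_base = H.pairwise_sl(make_matrix(base), 1, np.array([0, 1]))
        sl_ext = H.pairwise_sl(make_matrix(extra), 1, np.array([0, 1]))
        assert sl_base == sl_ext == 1.0
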