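"""Genotype-likelihood model, allele-frequency EM and site filters."""

import numpy as np
import pandas as pd
import pytest

from glpopgen.genolik import (GLMatrix, SiteFilterConfig, call_genotypes,
                              estimate_maf, freq_at_sites, genotype_prior,
                              gl_from_pileup, missingness_filter, prune_sites,
                              snp_test)

from conftest import make_model, simulate_gl_dataset


def counts_from_reads(reads):
    c = np.zeros(4)
    for r in reads:
        c["ACGT".index(r)] += 1
    return c


class TestGLFromPileup:
    def test_hand_computed_triple(self):
        """Two A reads, alleles (A, C), eps=0.01: likelihoods are the
        per-read products 0.99^2, 0.49667^2, (0.01/3)^2."""
        trip, missing = gl_from_pileup(counts_from_reads("AA"), ("A", "C"), 0.01)
        expected = np.array([0.9801, 0.496667**2, (0.01 / 3) ** 2])
        expected = np.log10(expected / expected.max())
        assert not missing
        np.testing.assert_allclose(trip, expected, atol=1e-4)

    def test_zero_reads_flat_missing(self):
        trip, missing = gl_from_pileup(np.zeros(4), ("A", "C"), 0.01)
        assert missing and np.allclose(trip, 0.0)

    def test_het_dominates_mixed_reads_at_small_eps(self):
        trip, _ = gl_from_pileup(counts_from_reads("AC"), ("A", "C"), 1e-6)
        assert trip[1] == 0.0  # max-normalized: het is the maximum
        assert trip[0] < -4 and trip[2] < -4

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            gl_from_pileup(counts_from_reads("AA"), ("A", "A"), 0.01)


def certain(g, n):
    """Linear GL triples asserting genotype g for n individuals."""
    out = np.full((1, n, 3), 1e-12)
    out[0, :, g] = 1.0
    return out


class TestMafEM:
    def test_all_hom_major(self):
        p = estimate_maf(certain(0, 6))
        assert p[0] < 1e-4

    def test_all_het_gives_half(self):
        p = estimate_maf(certain(1, 2))
        assert abs(p[0] - 0.5) < 1e-6

    def test_matches_grid_search(self):
        """EM frequency equals direct maximization over a fine grid."""
        rng = np.random.default_rng(42)
        truth_p = 0.3
        n = 10
        g = rng.binomial(2, truth_p, size=n)
        gl = np.full((1, n, 3), 0.05)
        gl[0, np.arange(n), g] = 1.0  # noisy but informative triples
        p_em = estimate_maf(gl)[0]
        grid = np.linspace(0, 1, 1001)
        ll = np.zeros_like(grid)
        for k, p in enumerate(grid):
            prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
            ll[k] = np.log((gl[0] * prior).sum(axis=1)).sum()
        assert abs(p_em - grid[ll.argmax()]) < 2e-3

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(1)
        gl = rng.random((1, 8, 3))
        from glpopgen.genolik import _site_loglik
        miss = np.zeros((1, 8), dtype=bool)
        lls = []
        for it in range(1, 30):
            p = estimate_maf(gl, miss, tol=0, max_iter=it)
            lls.append(_site_loglik(gl, miss, p)[0])
        assert np.all(np.diff(lls) > -1e-10)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            estimate_maf(np.ones((1, 3, 3)), np.ones((1, 3), dtype=bool))


class TestSnpTest:
    def test_monomorphic_not_a_snp(self):
        gl = certain(0, 8)
        miss = np.zeros((1, 8), dtype=bool)
        p = estimate_maf(gl, miss)
        pv = snp_test(gl, miss, p)
        assert pv[0] > 0.99

    def test_balanced_site_is_significant(self):
        gl = certain(1, 20)
        miss = np.zeros((1, 20), dtype=bool)
        p = estimate_maf(gl, miss)
        assert snp_test(gl, miss, p)[0] < 1e-6

    def test_marginal_site_matches_direct_lrt(self):
        from scipy.stats import chi2
        rng = np.random.default_rng(7)
        gl = np.clip(rng.random((1, 6, 3)), 0.2, None)
        miss = np.zeros((1, 6), dtype=bool)
        p = estimate_maf(gl, miss)
        pv = snp_test(gl, miss, p)[0]

        def ll(freq):
            prior = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
            return np.log((gl[0] * prior).sum(axis=1)).sum()

        grid = np.linspace(0, 1, 2001)
        lmax = max(ll(f) for f in grid)
        null = ll(0.0) if p[0] < 0.5 else ll(1.0)
        expect = chi2.sf(max(2 * (lmax - null), 0), 1)
        assert abs(pv - expect) < 1e-3


class TestCalling:
    def test_uncertain_site_left_missing(self):
        """GL (1, 0.25, 1e-5) with p=0.5, F=0: max posterior 2/3 < 0.95."""
        sites = pd.DataFrame({"contig": ["c"], "pos": [0], "major": ["A"],
                              "minor": ["C"], "ref": ["A"]})
        inds = pd.DataFrame({"id": ["x"], "location": ["l"], "region": ["r"]})
        gl = np.log10(np.array([[[1.0, 0.25, 1e-5]]]))
        glm = GLMatrix(sites=sites, individuals=inds, gl=gl,
                       depth=np.ones((1, 1), dtype=int))
        calls = call_genotypes(glm, np.array([0.5]), np.array([0.0]))
        assert calls[0, 0] == -1

    def test_certain_gl_called(self):
        sites = pd.DataFrame({"contig": ["c"], "pos": [0], "major": ["A"],
                              "minor": ["C"], "ref": ["A"]})
        inds = pd.DataFrame({"id": ["x"], "location": ["l"], "region": ["r"]})
        gl = np.log10(np.array([[[1.0, 1e-12, 1e-12]]]))
        glm = GLMatrix(sites=sites, individuals=inds, gl=gl,
                       depth=np.ones((1, 1), dtype=int))
        assert call_genotypes(glm, np.array([0.3]), np.array([0.0]))[0, 0] == 0

    def test_full_inbreeding_never_calls_het(self):
        prior = genotype_prior(np.array([0.5]), np.array([1.0]))
        assert prior[0, 1] == 0.0

    def test_calls_match_truth_on_deep_error_free_data(self):
        model = make_model()
        haps, _, glm = simulate_gl_dataset(
            model, {"Andes": 3, "Central": 3, "North": 3}, L=30_000,
            depth=40.0, eps=1e-4, seed=33, polarize="ancestral")
        truth = haps.diploid_genotypes()
        p = estimate_maf(glm.linear(), glm.missing)
        calls = call_genotypes(glm, np.clip(p, 1e-4, 1 - 1e-4),
                               np.zeros(glm.n_individuals))
        called = calls >= 0
        assert called.mean() > 0.95
        assert np.array_equal(calls[called], truth[called])


class TestFilters:
    def test_greedy_prune_walk(self):
        pos = np.array([100, 400, 700, 1300])
        keep = prune_sites(np.array(["c"] * 4), pos, 500)
        assert pos[keep].tolist() == [100, 700, 1300]

    def test_prune_restarts_per_contig(self):
        contigs = np.array(["c1", "c1", "c2"])
        pos = np.array([0, 100, 50])
        assert prune_sites(contigs, pos, 500).tolist() == [0, 2]

    def test_missing_fraction_rule(self):
        calls = np.zeros((1, 12), dtype=int)
        calls[0, :3] = -1  # 25% missing > 20%
        locs = np.array(["a"] * 6 + ["b"] * 6)
        assert not missingness_filter(calls, locs)[0]

    def test_whole_location_missing_rule(self):
        calls = np.zeros((1, 12), dtype=int)
        calls[0, :2] = -1  # only 17% missing overall...
        locs = np.array(["a"] * 2 + ["b"] * 10)
        assert not missingness_filter(calls, locs)[0]  # ...but all of 'a'
        assert missingness_filter(calls, locs,
                                  require_within_location=False)[0]

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            SiteFilterConfig(min_maf=0.7)


class TestFreqAtSites:
    def _glm(self, g_per_ind, ref="A"):
        n = len(g_per_ind)
        sites = pd.DataFrame({"contig": ["c"], "pos": [0], "major": ["A"],
                              "minor": ["C"], "ref": [ref]})
        inds = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                             "location": ["l"] * n, "region": ["r"] * n})
        gl = np.full((1, n, 3), -12.0)
        gl[0, np.arange(n), g_per_ind] = 0.0
        return GLMatrix(sites=sites, individuals=inds, gl=gl,
                        depth=np.ones((1, n), dtype=int))

    def test_all_hom_reference(self):
        df = freq_at_sites(self._glm([0, 0, 0, 0]), np.array([0]))
        assert df["alt_freq"].iloc[0] < 1e-4

    def test_all_hom_alternate(self):
        df = freq_at_sites(self._glm([2, 2, 2, 2]), np.array([0]))
        assert df["alt_freq"].iloc[0] > 1 - 1e-4

    def test_reference_forced_major_when_alt_common(self):
        """Even when ALT is the read-count major, the frequency reported is
        still that of the non-reference allele."""
        glm = self._glm([0, 0, 0, 1])  # mostly hom-major...
        glm.sites.loc[0, "major"] = "C"  # ...where the major is the ALT
        glm.sites.loc[0, "minor"] = "A"
        df = freq_at_sites(glm, np.array([0]))
        assert abs(df["alt_freq"].iloc[0] - 7 / 8) < 1e-3

    def test_absent_site_errors(self):
        with pytest.raises(KeyError):
            freq_at_sites(self._glm([0]), np.array([5]))

    def test_binomial_recovery(self):
        """Deep data at truth frequency 0.41 recovers it within 3 SE."""
        rng = np.random.default_rng(19)
        n = 200
        g = rng.binomial(2, 0.41, size=n)
        gl = np.full((1, n, 3), -12.0)
        gl[0, np.arange(n), g] = 0.0
        sites = pd.DataFrame({"contig": ["c"], "pos": [0], "major": ["A"],
                              "minor": ["C"], "ref": ["A"]})
        inds = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                             "location": ["l"] * n, "region": ["r"] * n})
        glm = GLMatrix(sites=sites, individuals=inds, gl=gl,
                       depth=np.ones((1, n), dtype=int))
        df = freq_at_sites(glm, np.array([0]))
        se = np.sqrt(0.41 * 0.59 / (2 * n))
        assert abs(df["alt_freq"].iloc[0] - 0.41) < 3 * se
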