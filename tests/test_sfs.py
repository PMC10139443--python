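"""SAF dynamic program, SFS EM against grid oracles, folding, masking."""

import itertools
from math import comb

import numpy as np
import pytest

from glpopgen.sfs import (em_sfs_1d, em_sfs_2d, fold_1d, fold_2d, mask_genic,
                          merge_intervals, project_saf, saf_matrix, saf_site)


def brute_force_saf(gl):
    """Exhaustive genotype-configuration enumeration oracle (n <= 4)."""
    n = gl.shape[0]
    out = np.zeros(2 * n + 1)
    for cfg in itertools.product(range(3), repeat=n):
        j = sum(cfg)
        out[j] += np.prod([gl[i, g] * comb(2, g) for i, g in enumerate(cfg)])
    out /= np.array([comb(2 * n, j) for j in range(2 * n + 1)])
    return out / out.max()


class TestSAF:
    def test_single_individual_is_own_triple(self):
        gl = np.array([[0.7, 0.2, 0.1]])
        saf = np.exp(saf_site(gl))
        np.testing.assert_allclose(saf, gl[0] / gl[0].max())

    def test_hom_plus_het_concentrates_at_one(self):
        gl = np.array([[1.0, 1e-300, 1e-300], [1e-300, 1.0, 1e-300]])
        saf = np.exp(saf_site(gl))
        assert saf.argmax() == 1
        assert saf[1] / saf.sum() > 1 - 1e-10

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_dp_equals_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        gl = rng.random((n, 3))
        np.testing.assert_allclose(np.exp(saf_site(gl)), brute_force_saf(gl),
                                   rtol=1e-10)

    def test_matrix_matches_per_site(self):
        rng = np.random.default_rng(5)
        gl = rng.random((20, 3, 3))
        mat = saf_matrix(gl)
        for s in range(20):
            np.testing.assert_allclose(mat[s], np.exp(saf_site(gl[s])),
                                       rtol=1e-10)

    def test_missing_individuals_projected_to_full_length(self):
        rng = np.random.default_rng(6)
        gl = rng.random((4, 3, 3))
        missing = np.zeros((4, 3), dtype=bool)
        missing[1, 0] = True
        mat = saf_matrix(gl, missing)
        assert mat.shape == (4, 7)
        assert np.isfinite(mat).all()

    def test_projection_preserves_certain_counts(self):
        """A certain j=2-of-4 site mixes to the hypergeometric over 8."""
        from scipy.stats import hypergeom
        saf = np.zeros(5)
        saf[2] = 1.0
        up = project_saf(saf, 8)
        expect = hypergeom.pmf(2, 8, np.arange(9), 4)
        np.testing.assert_allclose(up, expect, atol=1e-12)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            saf_site(np.empty((0, 3)))


def grid_simplex(K, step):
    """All probability vectors of length K on a lattice with given step."""
    ticks = int(round(1 / step))
    for cuts in itertools.combinations_with_replacement(range(ticks + 1), K - 1):
        v = np.diff([0, *cuts, ticks]) / ticks
        yield v


def refined_grid_search(ll, K, coarse=0.05, final=1e-4):
    """Simplex grid search with local zooming.

    The objective sum_s log(a_s . phi) is concave on the simplex, so a
    coarse global grid followed by shrinking local lattices around the
    incumbent converges to the maximizer.
    """
    best = max(grid_simplex(K, coarse), key=ll)
    step = coarse
    offsets = np.array(list(itertools.product(range(-2, 3), repeat=K)))
    while step > final:
        step /= 5.0
        improved = True
        while improved:
            cand = best[None, :] + offsets * step
            cand = cand[(cand >= 0).all(axis=1)]
            cand = cand / cand.sum(axis=1, keepdims=True)
            vals = [ll(c) for c in cand]
            k = int(np.argmax(vals))
            improved = vals[k] > ll(best) + 1e-14
            if improved:
                best = cand[k]
    return best


class TestEM1D:
    def test_two_certain_sites_split_evenly(self):
        saf = np.array([[1.0, 1e-12, 1e-12], [1e-12, 1e-12, 1.0]])
        res = em_sfs_1d(saf, max_iter=1000)
        np.testing.assert_allclose(res.proportions(), [0.5, 0.0, 0.5],
                                   atol=1e-6)

    def test_identical_sites_point_mass(self):
        saf = np.tile([[1e-12, 1.0, 1e-12]], (30, 1))
        res = em_sfs_1d(saf)
        assert res.proportions()[1] > 1 - 1e-6

    def test_matches_simplex_grid_search(self):
        """EM solution matches a refined lattice search within 1e-3 L1."""
        rng = np.random.default_rng(11)
        saf = rng.random((40, 3))
        res = em_sfs_1d(saf, max_iter=20000, tol=0)
        phi_em = res.proportions()

        def ll(phi):
            return np.log(saf @ phi + 1e-300).sum()

        best = refined_grid_search(ll, 3)
        assert ll(phi_em) >= ll(best) - 1e-9
        assert np.abs(phi_em - best).sum() < 1e-3

    def test_loglik_monotone(self):
        rng = np.random.default_rng(12)
        saf = rng.random((50, 5))
        res = em_sfs_1d(saf, tol=0, max_iter=200)
        assert np.all(np.diff(res.loglik_path) > -1e-8)

    def test_folding_conserves_total(self):
        rng = np.random.default_rng(13)
        saf = rng.random((30, 7))
        unf = em_sfs_1d(saf, folded=False)
        fol = em_sfs_1d(saf, folded=True)
        assert fol.counts.shape == (4,)
        assert abs(fol.counts.sum() - unf.counts.sum()) < 1e-6

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            em_sfs_1d(np.empty((0, 3)))


class TestEM2D:
    def test_certain_site_point_mass(self):
        a = np.array([[1e-12, 1.0, 1e-12]])
        b = np.array([[1.0, 1e-12, 1e-12]])
        res = em_sfs_2d(a, b)
        assert res.proportions()[1, 0] > 1 - 1e-6

    def test_marginals_match_1d_on_certain_sites(self):
        """With (near-)certain SAFs the 2D estimate is the empirical joint
        table, so its marginals equal the 1D estimates exactly."""
        rng = np.random.default_rng(21)
        ja = rng.integers(0, 3, size=80)
        jb = rng.integers(0, 3, size=80)
        a = np.full((80, 3), 1e-9)
        b = np.full((80, 3), 1e-9)
        a[np.arange(80), ja] = 1.0
        b[np.arange(80), jb] = 1.0
        res2 = em_sfs_2d(a, b, max_iter=3000, tol=1e-14)
        res1a = em_sfs_1d(a, max_iter=3000, tol=1e-14)
        res1b = em_sfs_1d(b, max_iter=3000, tol=1e-14)
        np.testing.assert_allclose(res2.proportions().sum(axis=1),
                                   res1a.proportions(), atol=1e-6)
        np.testing.assert_allclose(res2.proportions().sum(axis=0),
                                   res1b.proportions(), atol=1e-6)

    def test_matches_grid_oracle_tiny(self):
        """2x2-class EM agrees with a refined simplex grid search (1e-3 L1)."""
        rng = np.random.default_rng(22)
        a = rng.random((25, 2))  # haploid-like 2-class SAFs keep the grid tiny
        b = rng.random((25, 2))
        res = em_sfs_2d(a, b, max_iter=20000, tol=0)
        prods = np.einsum("si,sj->sij", a, b).reshape(25, 4)

        def ll(phi):
            return np.log(prods @ phi + 1e-300).sum()

        best = refined_grid_search(ll, 4)
        assert ll(res.proportions().ravel()) >= ll(best) - 1e-9
        assert np.abs(res.proportions().ravel() - best).sum() < 1e-3

    def test_chunked_equals_concatenated(self):
        rng = np.random.default_rng(23)
        a = rng.random((40, 3))
        b = rng.random((40, 3))
        whole = em_sfs_2d(a, b)
        chunked = em_sfs_2d([a[:15], a[15:]], [b[:15], b[15:]])
        np.testing.assert_allclose(whole.counts, chunked.counts, rtol=1e-8)


class TestFolding:
    def test_fold_1d_values(self):
        np.testing.assert_allclose(fold_1d(np.array([5.0, 3, 2, 1, 4])),
                                   [9, 4, 2])

    def test_fold_2d_pooled_conserves_total(self):
        rng = np.random.default_rng(31)
        m = rng.random((5, 7))
        f = fold_2d(m, "pooled")
        assert abs(f.sum() - m.sum()) < 1e-9
        # mirrored halves collapse: every kept cell has pooled count <= ntot/2
        na, nb = 4, 6
        for i in range(5):
            for j in range(7):
                if f[i, j] > 0:
                    assert 2 * (i + j) <= na + nb

    def test_fold_2d_per_population(self):
        m = np.zeros((3, 3))
        m[2, 1] = 1.0  # (2,1) of (2,2) folds to (0,1)
        f = fold_2d(m, "per-population")
        assert f[0, 1] == 1.0


class TestMasking:
    def test_flank_boundaries(self):
        keep = mask_genic(np.array([3999, 4100, 6999, 7000]),
                          np.array([[5000, 6000]]), flank=1000)
        assert keep.tolist() == [True, False, False, True]

    def test_no_genes_identity(self):
        keep = mask_genic(np.arange(10), np.empty((0, 2)))
        assert keep.all()

    def test_overlapping_expanded_intervals_merge(self):
        merged = merge_intervals(np.array([[0.0, 5.0], [4.0, 9.0], [20.0, 21.0]]))
        assert merged.tolist() == [[0.0, 9.0], [20.0, 21.0]]
        keep = mask_genic(np.array([7]), np.array([[0, 5], [6, 9]]), flank=1)
        assert not keep[0]


class TestNeutralShape:
    def test_constant_population_sfs_proportional_to_1_over_i(self):
        """Unfolded spectrum from unlinked neutral loci tracks 1/i."""
        from conftest import panmictic_model, simulate_unlinked_gl
        glm = simulate_unlinked_gl(
            panmictic_model(2000.0), {"Andes": 5}, n_loci=400, L=2000,
            mu=1e-7, depth=20.0, eps=1e-3, seed=77, polarize="ancestral")
        saf = saf_matrix(glm.linear(), glm.missing)
        res = em_sfs_1d(saf)
        prop = res.proportions()[1:-1]
        prop = prop / prop.sum()
        expect = 1.0 / np.arange(1, 10)
        expect /= expect.sum()
        assert np.max(np.abs(prop - expect)) < 0.04
        folded = fold_1d(res.counts)
        i = np.arange(1, 6)
        shape = 1.0 / i + np.where(i < 5, 1.0 / (10 - i), 0.0)
        np.testing.assert_allclose(folded[1:] / folded[1:].sum(),
                                   shape / shape.sum(), atol=0.05)
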