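"""Two-locus haplotype EM, pair collection and LD-decay fitting."""

import numpy as np
import pandas as pd
import pytest

from glpopgen.genolik import GLMatrix
from glpopgen.ldscan import (LDDecayFit, _decay_curve, collect_pairs,
                             fit_decay, model_fit_check, r2_em)


def certain_triples(dosages):
    gl = np.full((len(dosages), 3), 1e-12)
    gl[np.arange(len(dosages)), dosages] = 1.0
    return gl


def genotypes_from_haplotypes(h_counts, rng):
    """Random-mating diploids from haplotype counts (AB, Ab, aB, ab)."""
    hap_pool = np.repeat(np.arange(4), h_counts)
    rng.shuffle(hap_pool)
    pairs = hap_pool.reshape(-1, 2)
    a1 = np.array([0, 0, 1, 1])
    a2 = np.array([0, 1, 0, 1])
    g1 = a1[pairs].sum(axis=1)
    g2 = a2[pairs].sum(axis=1)
    return g1, g2


def _oracle_full(g1, g2, iters):
    """Classic phase-unknown two-locus EM on hard genotypes (independent
    re-implementation by explicit enumeration of ordered haplotype pairs)."""
    import itertools
    a1 = np.array([0, 0, 1, 1])
    a2 = np.array([0, 1, 0, 1])
    pairs = np.array(list(itertools.product(range(4), repeat=2)))
    pg1 = a1[pairs].sum(axis=1)
    pg2 = a2[pairs].sum(axis=1)
    h = np.full(4, 0.25)
    N = len(g1)
    for _ in range(iters):
        n = np.zeros(4)
        for x, y in zip(g1, g2):
            ok = (pg1 == x) & (pg2 == y)
            w = h[pairs[ok, 0]] * h[pairs[ok, 1]]
            w = w / w.sum()
            np.add.at(n, pairs[ok, 0], w)
            np.add.at(n, pairs[ok, 1], w)
        h = n / (2 * N)
    return h


class TestR2EM:
    def test_perfect_coupling_r2_one(self):
        """All haplotypes AB or ab at 50/50: r2 = 1."""
        rng = np.random.default_rng(0)
        g1, g2 = genotypes_from_haplotypes([30, 0, 0, 30], rng)
        r2, D, h, _ = r2_em(certain_triples(g1), certain_triples(g2))
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert abs(D) == pytest.approx(0.25, abs=1e-6)

    def test_known_haplotype_counts_closed_form(self):
        """Counts (40, 10, 10, 40): D = 0.15, r2 = 0.36."""
        rng = np.random.default_rng(1)
        g1, g2 = genotypes_from_haplotypes([40, 10, 10, 40], rng)
        r2, D, h, _ = r2_em(certain_triples(g1), certain_triples(g2),
                            tol=1e-13, max_iter=5000)
        # EM on certain genotypes recovers the realized haplotype counts
        oracle = _oracle_full(g1, g2, 2000)
        pA = oracle[2] + oracle[3]
        pB = oracle[1] + oracle[3]
        D_o = oracle[3] - pA * pB
        r2_o = D_o**2 / (pA * (1 - pA) * pB * (1 - pB))
        assert abs(D - D_o) < 1e-6
        assert abs(r2 - r2_o) < 1e-6
        assert abs(r2 - 0.36) < 0.1  # sampled pairing wiggles the exact value

    def test_matches_phase_unknown_oracle(self):
        rng = np.random.default_rng(2)
        g1, g2 = genotypes_from_haplotypes([25, 15, 10, 30], rng)
        _, _, h, _ = r2_em(certain_triples(g1), certain_triples(g2),
                           tol=1e-13, max_iter=3000)
        oracle = _oracle_full(g1, g2, 1000)
        np.testing.assert_allclose(np.sort(h), np.sort(oracle), atol=1e-4)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        g1, g2 = genotypes_from_haplotypes([25, 15, 10, 30], rng)
        r2a, *_ = r2_em(certain_triples(g1), certain_triples(g2))
        r2b, *_ = r2_em(certain_triples(2 - g1), certain_triples(g2))
        r2c, *_ = r2_em(certain_triples(g1), certain_triples(2 - g2))
        assert r2a == pytest.approx(r2b, abs=1e-8)
        assert r2a == pytest.approx(r2c, abs=1e-8)

    def test_monomorphic_rejected(self):
        g = certain_triples(np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="monomorphic"):
            r2_em(g, g)


def toy_glmatrix(positions, n_ind=8, seed=0):
    rng = np.random.default_rng(seed)
    S = len(positions)
    dos = rng.integers(0, 3, size=(S, n_ind))
    dos[:, 0] = 0
    dos[:, 1] = 1  # guarantee polymorphism
    gl = np.full((S, n_ind, 3), -12.0)
    for s in range(S):
        gl[s, np.arange(n_ind), dos[s]] = 0.0
    sites = pd.DataFrame({"contig": "c1", "pos": positions,
                          "major": "A", "minor": "C", "ref": "A"})
    inds = pd.DataFrame({"id": [f"i{k}" for k in range(n_ind)],
                         "location": "l", "region": "r"})
    return GLMatrix(sites=sites, individuals=inds, gl=gl,
                    depth=np.ones((S, n_ind), dtype=int))


class TestCollectPairs:
    def test_distance_boundary(self):
        glm = toy_glmatrix(np.array([0, 10_001]))
        assert len(collect_pairs(glm, max_dist=10_000, subsample=1.0)) == 0
        glm2 = toy_glmatrix(np.array([0, 10_000]))
        assert len(collect_pairs(glm2, max_dist=10_000, subsample=1.0)) == 1

    def test_full_enumeration_count(self):
        pos = np.array([0, 100, 250, 5_000, 30_000])
        glm = toy_glmatrix(pos)
        df = collect_pairs(glm, max_dist=10_000, subsample=1.0)
        # expected pairs within 10 kb on one contig
        expect = sum(1 for i in range(5) for j in range(i + 1, 5)
                     if pos[j] - pos[i] <= 10_000)
        assert len(df) == expect

    def test_seeded_subsample_reproducible(self):
        glm = toy_glmatrix(np.arange(0, 4000, 100))
        a = collect_pairs(glm, subsample=0.3, seed=5)
        b = collect_pairs(glm, subsample=0.3, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestDecayFit:
    def synthetic_pairs(self, lam, r2max, r2min, n=4000, noise=0.01, seed=4):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 10_000, n)
        r2 = np.clip(_decay_curve(d, lam, r2max, r2min)
                     + rng.normal(0, noise, n), 0, 1)
        return pd.DataFrame({"distance": d, "r2": r2})

    def test_flat_data_gives_zero_rate(self):
        rng = np.random.default_rng(5)
        pairs = pd.DataFrame({"distance": rng.uniform(0, 10_000, 2000),
                              "r2": np.clip(rng.normal(0.3, 0.02, 2000), 0, 1)})
        fit = fit_decay(pairs, n_boot=0)
        span = fit.curve(np.array([0.0, 10_000.0]))
        assert abs(span[0] - span[1]) < 0.02  # effectively flat

    def test_self_consistency_within_ten_percent(self):
        fit = fit_decay(self.synthetic_pairs(5e-4, 0.6, 0.1), n_boot=30)
        assert fit.decay_rate == pytest.approx(5e-4, rel=0.10)
        assert fit.r2_max == pytest.approx(0.6, rel=0.10)
        assert fit.r2_min == pytest.approx(0.1, rel=0.10)
        lo, hi = fit.ci["decay_rate"]
        assert lo <= fit.decay_rate <= hi

    def test_monotone_rate_recovery(self):
        rates = [fit_decay(self.synthetic_pairs(lam, 0.6, 0.1, seed=6),
                           n_boot=0).decay_rate
                 for lam in (2e-4, 5e-4, 1e-3)]
        assert rates[0] < rates[1] < rates[2]

    def test_failure_diagnostics(self):
        pairs = pd.DataFrame({"distance": [10.0, 20.0], "r2": [0.5, 0.4]})
        with pytest.raises(RuntimeError, match="bin size"):
            fit_decay(pairs, bin_size=100)


class TestModelFitCheck:
    def _obs(self):
        return LDDecayFit(decay_rate=5e-4, r2_max=0.6, r2_min=0.1,
                          ci={"decay_rate": (4e-4, 6e-4)}, bin_size=100,
                          n_pairs=100)

    def test_inside_and_boundary_consistent(self):
        df = model_fit_check(self._obs(), {
            "inside": np.array([4.5e-4, 5.5e-4]),
            "boundary": np.array([6e-4, 6e-4]),
            "outside": np.array([9e-4]),
        })
        v = df.set_index("model")
        assert v.loc["inside", "consistent"]
        assert v.loc["boundary", "consistent"]  # closed interval
        assert not v.loc["outside", "consistent"]
        assert v.loc["outside", "distance_to_ci"] == pytest.approx(3e-4)

    def test_ranking_by_closeness(self):
        df = model_fit_check(self._obs(), {
            "far": np.array([2e-3]), "near": np.array([5.2e-4]),
            "mid": np.array([8e-4])})
        assert df["model"].tolist() == ["near", "mid", "far"]


class TestSimulatedLD:
    def test_r2_declines_with_distance_and_recombination(self):
        """Simulated recombining data: binned r2 decays; higher recombination
        gives a faster fitted decay (monotone over a 3-point grid)."""
        from glpopgen.genolik import gl_matrix_from_pileup
        from glpopgen.syndata import SimConfig, simulate_genotypes, simulate_reads
        from conftest import individuals_for, panmictic_model

        lams = []
        for rec in (1e-8, 8e-8, 4e-7):
            cfg = SimConfig(samples={"Andes": 12}, L=30_000, mu=1.5e-7,
                            recomb=rec, seed=71, num_replicates=4)
            parts = []
            for k, haps in enumerate(simulate_genotypes(panmictic_model(4000.0), cfg)):
                pil = simulate_reads(haps, 25.0, 1e-3, seed=80 + k)
                parts.append(gl_matrix_from_pileup(pil, haps,
                                                   individuals_for(haps)))
            glm = GLMatrix.concat(parts)
            # keep common sites so r2 is informative
            lin = glm.linear()
            from glpopgen.genolik import estimate_maf
            maf = estimate_maf(lin, glm.missing)
            keep = np.minimum(maf, 1 - maf) > 0.1
            glm = glm.subset_sites(np.flatnonzero(keep))
            pairs = collect_pairs(glm, max_dist=10_000, subsample=0.12,
                                  seed=90)
            fit = fit_decay(pairs, bin_size=1000, n_boot=0)
            lams.append(fit.decay_rate)
        assert lams[0] < lams[1] < lams[2]
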