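"""Genotype likelihoods from read pileups, allele-frequency EM and site filters.

Likelihoods use the standard per-read error model: a read base matches a true
allele with probability 1 - eps and is any specific other base with
probability eps/3; heterozygotes average the two allele terms.  Triples are
stored log-scaled and max-normalized (max of each non-missing triple is 0),
ordered (hom-major, het, hom-minor).

The site filters mirror a conventional low-coverage SNP pipeline: a
likelihood-ratio SNP test, a minor-allele-frequency floor, distance pruning,
and missingness rules (global fraction and per-sampling-location presence).
Filter order is fixed: SNP test -> MAF -> prune -> missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .syndata import BASES, HaplotypeSet, ReadPileup

__all__ = [
    "GLMatrix",
    "SiteFilterConfig",
    "gl_from_pileup",
    "gl_matrix_from_pileup",
    "estimate_maf",
    "snp_test",
    "call_genotypes",
    "prune_sites",
    "missingness_filter",
    "prune_and_filter",
    "freq_at_sites",
    "genotype_prior",
]

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class GLMatrix:
    """Genotype likelihoods for every site x individual.

    Attributes
    ----------
    sites
        DataFrame with columns contig, pos (0-based), major, minor, ref.
    individuals
        DataFrame with columns id, location, region.
    gl
        (sites, individuals, 3) array of log10-scaled, max-normalized
        likelihoods ordered (hom-major, het, hom-minor).
    depth
        (sites, individuals) read depths; depth 0 marks a missing cell.
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame
    gl: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        S, N, three = self.gl.shape
        if three != 3 or self.depth.shape != (S, N):
            raise ValueError("gl must be (S, N, 3) with matching depth")
        if len(self.sites) != S or len(self.individuals) != N:
            raise ValueError("site/individual tables do not match gl shape")

    @property
    def missing(self) -> np.ndarray:
        return self.depth == 0

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def linear(self) -> np.ndarray:
        """Likelihood triples in linear scale (missing cells flat = 1)."""
        out = np.power(10.0, self.gl)
        out[self.missing] = 1.0
        return out

    def subset_sites(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(int)
        return GLMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            individuals=self.individuals,
            gl=self.gl[idx], depth=self.depth[idx],
        )

    def subset_individuals(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        return GLMatrix(
            sites=self.sites,
            individuals=self.individuals.iloc[idx].reset_index(drop=True),
            gl=self.gl[:, idx], depth=self.depth[:, idx],
        )

    def region_index(self, region: str) -> np.ndarray:
        return np.flatnonzero((self.individuals["region"] == region).to_numpy())

    @staticmethod
    def concat(parts: list["GLMatrix"]) -> "GLMatrix":
        """Stack site blocks (e.g. independent loci) over the same individuals."""
        if not parts:
            raise ValueError("nothing to concatenate")
        inds = parts[0].individuals
        for p in parts[1:]:
            if not p.individuals["id"].equals(inds["id"]):
                raise ValueError("parts must share the same individuals")
        return GLMatrix(
            sites=pd.concat([p.sites for p in parts], ignore_index=True),
            individuals=inds,
            gl=np.concatenate([p.gl for p in parts], axis=0),
            depth=np.concatenate([p.depth for p in parts], axis=0),
        )


@dataclass
class SiteFilterConfig:
    """Thresholds for the SNP / MAF / prune / missingness filter chain."""

    snp_p_threshold: float = 1e-6
    min_maf: float = 0.05
    prune_distance: int = 500
    max_missing_fraction: float = 0.20
    require_within_location: bool = True
    min_base_quality: int | None = 20  # real-data pass-through; unused on pileups

    def __post_init__(self) -> None:
        if not (0 < self.snp_p_threshold <= 1):
            raise ValueError("snp_p_threshold must be in (0, 1]")
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0 <= self.max_missing_fraction <= 1):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.prune_distance < 0:
            raise ValueError("prune_distance must be >= 0")


def gl_from_pileup(counts: np.ndarray, alleles: tuple[str, str],
                   epsilon: float) -> tuple[np.ndarray, bool]:
    """Log10 likelihood triple for one site/individual from base counts.

    Returns ``(triple, missing)``; the triple is max-normalized, ordered
    (hom-a1, het, hom-a2) for ``alleles = (a1, a2)``.  Zero reads yield a
    flat triple flagged missing.
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    a1, a2 = alleles
    if a1 == a2:
        raise ValueError("alleles must be distinct")
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return np.zeros(3), True
    i1, i2 = _BASE_IDX[a1], _BASE_IDX[a2]
    p_hom1 = np.full(4, epsilon / 3.0)
    p_hom1[i1] = 1.0 - epsilon
    p_hom2 = np.full(4, epsilon / 3.0)
    p_hom2[i2] = 1.0 - epsilon
    p_het = 0.5 * (p_hom1 + p_hom2)
    trip = np.array([
        float(counts @ np.log10(p_hom1)),
        float(counts @ np.log10(p_het)),
        float(counts @ np.log10(p_hom2)),
    ])
    return trip - trip.max(), False


def _gl_stack(counts: np.ndarray, a1_idx: np.ndarray, a2_idx: np.ndarray,
              epsilon: float) -> np.ndarray:
    """Vectorized log10 GL triples: counts (S, N, 4) -> (S, N, 3)."""
    S, N, _ = counts.shape
    eye = np.eye(4)
    p1 = np.where(eye[a1_idx][:, None, :] == 1, 1 - epsilon, epsilon / 3)  # (S,1,4)
    p2 = np.where(eye[a2_idx][:, None, :] == 1, 1 - epsilon, epsilon / 3)
    ph = 0.5 * (p1 + p2)
    gl = np.stack([
        (counts * np.log10(p1)).sum(axis=2),
        (counts * np.log10(ph)).sum(axis=2),
        (counts * np.log10(p2)).sum(axis=2),
    ], axis=2)
    gl -= gl.max(axis=2, keepdims=True)
    gl[counts.sum(axis=2) == 0] = 0.0
    return gl


def gl_matrix_from_pileup(
    pileup: ReadPileup,
    haps: HaplotypeSet,
    individuals: pd.DataFrame,
    epsilon: float | None = None,
    polarize: str = "major",
) -> GLMatrix:
    """Build a :class:`GLMatrix` from a simulated pileup.

    The ancestral base is recorded as the reference allele.  With
    ``polarize="major"`` the triple's first allele is the read-count major
    (ties broken toward the reference); ``polarize="ancestral"`` fixes the
    ordering (hom-ancestral, het, hom-derived) regardless of frequency,
    which unfolded (derived-allele) spectra require.
    """
    eps = pileup.epsilon if epsilon is None else epsilon
    eps = max(eps, 1e-6)  # GLs need a strictly positive error rate
    anc_i = np.array([_BASE_IDX[b] for b in pileup.anc_base])
    der_i = np.array([_BASE_IDX[b] for b in pileup.der_base])
    tot = pileup.counts.sum(axis=1)  # (S, 4)
    anc_tot = tot[np.arange(len(anc_i)), anc_i]
    der_tot = tot[np.arange(len(der_i)), der_i]
    if polarize == "ancestral":
        major_is_anc = np.ones(len(anc_i), dtype=bool)
    elif polarize == "major":
        major_is_anc = anc_tot >= der_tot
    else:
        raise ValueError(f"unknown polarization {polarize!r}")
    a1 = np.where(major_is_anc, anc_i, der_i)
    a2 = np.where(major_is_anc, der_i, anc_i)
    gl = _gl_stack(pileup.counts.astype(float), a1, a2, eps)
    base_arr = np.array(list(BASES))
    sites = pd.DataFrame({
        "contig": pileup.contig,
        "pos": pileup.positions,
        "major": base_arr[a1],
        "minor": base_arr[a2],
        "ref": pileup.anc_base,
    })
    return GLMatrix(sites=sites, individuals=individuals.reset_index(drop=True),
                    gl=gl, depth=pileup.depth)


# ---------------------------------------------------------------------------
# allele-frequency EM and the SNP likelihood-ratio test


def _hwe_prior(p: np.ndarray) -> np.ndarray:
    """HWE genotype probabilities for minor-allele frequency p: shape (..., 3)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=-1)


def estimate_maf(gl_linear: np.ndarray, missing: np.ndarray | None = None,
                 tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """EM estimate of the minor-allele frequency per site.

    ``gl_linear`` is (S, N, 3) linear-scale likelihood triples (hom-major,
    het, hom-minor).  Missing individuals (flat triples) contribute nothing.
    The EM update is the posterior-mean dosage under HWE; its log-likelihood
    is non-decreasing.
    """
    gl_linear = np.atleast_3d(gl_linear)
    S, N, _ = gl_linear.shape
    if missing is None:
        missing = np.zeros((S, N), dtype=bool)
    if np.all(missing.all(axis=1)):
        raise ValueError("every site is missing in all individuals")
    use = (~missing)[:, :, None]
    n_eff = (~missing).sum(axis=1)
    if np.any(n_eff == 0):
        raise ValueError("site with no non-missing individuals")
    p = np.full(S, 0.25)
    dosage = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        prior = _hwe_prior(p)[:, None, :]
        post = gl_linear * prior * use
        denom = post.sum(axis=2, keepdims=True)
        denom[denom == 0] = 1.0
        post = post / denom
        p_new = (post @ dosage).sum(axis=1) / (2.0 * n_eff)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return np.clip(p, 0.0, 1.0)


def _site_loglik(gl_linear: np.ndarray, missing: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood of frequency p under HWE."""
    prior = _hwe_prior(p)[:, None, :]
    lik = (gl_linear * prior).sum(axis=2)
    lik = np.where(missing, 1.0, lik)
    lik = np.clip(lik, 1e-300, None)
    return np.log(lik).sum(axis=1)


def snp_test(gl_linear: np.ndarray, missing: np.ndarray,
             p_hat: np.ndarray) -> np.ndarray:
    """Likelihood-ratio SNP test p-value per site.

    The null is the nearer monomorphic frequency (0 or 1); the statistic is
    referred to a chi-square with 1 df.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    ll_alt = _site_loglik(gl_linear, missing, p_hat)
    null_p = np.where(p_hat < 0.5, 0.0, 1.0)
    ll_null = _site_loglik(gl_linear, missing, null_p)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return chi2.sf(lrt, df=1)


def genotype_prior(p: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Inbreeding-adjusted genotype prior (hom-major, het, hom-minor).

    (q^2 + pqF, 2pq(1-F), p^2 + pqF) with negative entries clipped to 0 and
    the triple renormalized; ``p`` is the minor-allele frequency.
    """
    p = np.asarray(p, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any((F < -1) | (F > 1)):
        raise ValueError("inbreeding coefficient must lie in [-1, 1]")
    q = 1.0 - p
    pr = np.stack(np.broadcast_arrays(
        q * q + p * q * F, 2 * p * q * (1 - F), p * p + p * q * F
    ), axis=-1)
    pr = np.clip(pr, 0.0, None)
    tot = pr.sum(axis=-1, keepdims=True)
    tot[tot == 0] = 1.0
    return pr / tot


def call_genotypes(glm: GLMatrix, p_hat: np.ndarray, F: np.ndarray,
                   confidence: float = 0.95) -> np.ndarray:
    """Posterior genotype calls; cells below ``confidence`` are set missing.

    Returns an int matrix (sites, individuals) with values 0/1/2 counting
    minor alleles and -1 for missing (no data or unconfident).
    """
    p_hat = np.asarray(p_hat, dtype=float)
    if np.any((p_hat <= 0) | (p_hat >= 1)):
        raise ValueError("p_hat must lie strictly inside (0, 1) for calling")
    prior = genotype_prior(p_hat[:, None], np.asarray(F)[None, :])  # (S, N, 3)
    post = glm.linear() * prior
    post /= post.sum(axis=2, keepdims=True)
    best = post.argmax(axis=2)
    conf = post.max(axis=2)
    calls = np.where((conf >= confidence) & ~glm.missing, best, -1)
    return calls.astype(np.int8)


# ---------------------------------------------------------------------------
# filters


def prune_sites(contigs: np.ndarray, positions: np.ndarray,
                min_distance: int) -> np.ndarray:
    """Greedy left-to-right distance pruning; returns retained indices.

    The first site of each contig anchors the walk; a site is kept iff it is
    at least ``min_distance`` bp from the last kept site on that contig.
    """
    keep = []
    last: dict[str, int] = {}
    for i, (c, pos) in enumerate(zip(contigs, positions)):
        if c not in last or pos - last[c] >= min_distance:
            keep.append(i)
            last[c] = pos
    return np.asarray(keep, dtype=int)


def missingness_filter(calls: np.ndarray, locations: np.ndarray,
                       max_missing_fraction: float = 0.20,
                       require_within_location: bool = True) -> np.ndarray:
    """Boolean mask of sites passing the missing-data rules.

    Drops sites missing in more than ``max_missing_fraction`` of samples, and
    (optionally) sites missing in every individual of any sampling location.
    """
    miss = calls < 0
    ok = miss.mean(axis=1) <= max_missing_fraction
    if require_within_location:
        for loc in pd.unique(locations):
            cols = np.flatnonzero(locations == loc)
            ok &= ~miss[:, cols].all(axis=1)
    return ok


def prune_and_filter(glm: GLMatrix, calls: np.ndarray,
                     config: SiteFilterConfig) -> np.ndarray:
    """Apply distance pruning then missingness rules; returns retained indices."""
    kept = prune_sites(glm.sites["contig"].to_numpy(),
                       glm.sites["pos"].to_numpy(), config.prune_distance)
    locs = glm.individuals["location"].to_numpy()
    ok = missingness_filter(calls[kept], locs,
                            config.max_missing_fraction,
                            config.require_within_location)
    return kept[ok]


def snp_filter(glm: GLMatrix, config: SiteFilterConfig,
               p_hat: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """SNP-test + MAF stage of the filter chain.

    Returns ``(indices, p_hat_retained)`` of sites with SNP p-value below the
    threshold and minor-allele frequency at least ``min_maf``.
    """
    lin = glm.linear()
    if p_hat is None:
        p_hat = estimate_maf(lin, glm.missing)
    pvals = snp_test(lin, glm.missing, p_hat)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = np.flatnonzero((pvals < config.snp_p_threshold) & (maf >= config.min_maf))
    return keep, p_hat[keep]


def freq_at_sites(glm: GLMatrix, site_idx: np.ndarray,
                  by: str = "region") -> pd.DataFrame:
    """Per-group EM frequency of the non-reference allele at chosen sites.

    The reference allele is forced to be the "major" allele of the likelihood
    triple: triples whose major is the alternate allele are reversed before
    the EM, so the reported frequency is always that of the non-reference
    allele.  Raises ``KeyError`` for indices outside the site table.
    """
    site_idx = np.asarray(site_idx, dtype=int)
    if np.any((site_idx < 0) | (site_idx >= glm.n_sites)):
        bad = site_idx[(site_idx < 0) | (site_idx >= glm.n_sites)]
        raise KeyError(f"site indices not found: {bad.tolist()}")
    lin = glm.linear()[site_idx]
    flip = (glm.sites["major"].to_numpy() != glm.sites["ref"].to_numpy())[site_idx]
    lin[flip] = lin[flip, :, ::-1]
    rows = []
    groups = glm.individuals[by].to_numpy()
    for grp in pd.unique(groups):
        cols = np.flatnonzero(groups == grp)
        sub_missing = glm.missing[site_idx][:, cols]
        freqs = np.full(len(site_idx), np.nan)
        usable = ~sub_missing.all(axis=1)
        if usable.any():
            freqs[usable] = estimate_maf(lin[usable][:, cols], sub_missing[usable])
        for k, s in enumerate(site_idx):
            rows.append({
                by: grp,
                "contig": glm.sites["contig"].iloc[s],
                "pos": glm.sites["pos"].iloc[s],
                "alt_freq": freqs[k],
            })
    return pd.DataFrame(rows)
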