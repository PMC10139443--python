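"""Site-allele-frequency likelihoods and EM estimation of 1D/2D spectra.

A SAF record holds, for one site and one population of n diploids, the
likelihood of the read data given each possible derived-allele count
j = 0..2n.  With exchangeable alleles (no inbreeding) the exact vector is a
convolution over individuals of their multiplicity-weighted genotype
likelihood triples, divided by the hypergeometric configuration count
C(2n, j); this is checked against brute-force enumeration in the tests.

The genome-wide spectrum maximizes the composite likelihood
sum_s log sum_j phi_j * SAF_s(j) over the simplex by EM (non-decreasing
objective, capped iterations), optionally accumulated over genome chunks,
and folded only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "SAFRecord",
    "SFS1D",
    "SFS2D",
    "saf_site",
    "saf_matrix",
    "project_saf",
    "em_sfs_1d",
    "em_sfs_2d",
    "fold_1d",
    "fold_2d",
    "mask_genic",
    "merge_intervals",
]


@dataclass
class SAFRecord:
    """Per-site allele-frequency likelihood vector, log-scale max 0."""

    site_id: int
    population: str
    loglik: np.ndarray  # length 2n+1

    @property
    def n_alleles(self) -> int:
        return len(self.loglik) - 1


@dataclass
class SFS1D:
    population: str
    folded: bool
    counts: np.ndarray
    total_sites: float
    loglik_path: np.ndarray | None = None

    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class SFS2D:
    populations: tuple[str, str]
    folded: bool
    counts: np.ndarray
    total_sites: float
    loglik_path: np.ndarray | None = None

    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


# ---------------------------------------------------------------------------
# SAF construction


def saf_site(gl_linear: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
    """SAF vector for one site from (n, 3) linear GL triples.

    Triples must be ordered by derived (minor) allele dosage.  With ``F``
    omitted the computation is the exact exchangeable-allele dynamic program:
    convolve the multiplicity-weighted triples (GL0, 2*GL1, GL2) across
    individuals and divide entry j by C(2n, j).  With per-individual
    inbreeding coefficients the exchangeability breaks; the vector is then
    the product over individuals of sum_g GL_i(g) * prior(g | j/2n, F_i),
    an independent-draw approximation.  Returns log-scale, max-normalized.
    """
    gl_linear = np.atleast_2d(np.asarray(gl_linear, dtype=float))
    n = gl_linear.shape[0]
    if n == 0:
        raise ValueError("SAF requires at least one non-missing individual")
    if F is None:
        vec = np.array([1.0])
        w = np.array([1.0, 2.0, 1.0])
        for i in range(n):
            vec = np.convolve(vec, gl_linear[i] * w)
        denom = np.array([comb(2 * n, j) for j in range(2 * n + 1)], dtype=float)
        vec = vec / denom
    else:
        from .genolik import genotype_prior

        F = np.asarray(F, dtype=float)
        q = np.arange(2 * n + 1) / (2.0 * n)
        prior = genotype_prior(q[:, None], F[None, :])  # (2n+1, n, 3)
        vec = np.prod((prior * gl_linear[None, :, :]).sum(axis=2), axis=1)
    vec = np.clip(vec, 1e-300, None)
    out = np.log(vec)
    return out - out.max()


def saf_matrix(gl_linear: np.ndarray, missing: np.ndarray | None = None,
               F: np.ndarray | None = None,
               project_to_full: bool = True) -> np.ndarray:
    """SAF vectors for all sites of one population: (S, 2n+1) linear scale.

    Rows are normalized to max 1.  Sites with missing individuals are
    computed over the non-missing subset and mixed up to the full 2n via the
    hypergeometric missing-at-random identity (see :func:`project_saf`).
    Sites missing in all individuals get a flat (uninformative) row.
    """
    gl_linear = np.asarray(gl_linear, dtype=float)
    S, n, _ = gl_linear.shape
    K = 2 * n + 1
    out = np.empty((S, K))
    if missing is None:
        missing = np.zeros((S, n), dtype=bool)
    complete = ~missing.any(axis=1)
    if complete.any():
        # vectorized convolution across individuals for complete rows
        w = np.array([1.0, 2.0, 1.0])
        if F is None:
            sub = gl_linear[complete] * w  # (Sc, n, 3)
            acc = np.ones((sub.shape[0], 1))
            for i in range(n):
                K_i = acc.shape[1] + 2
                nxt = np.zeros((sub.shape[0], K_i))
                for g in range(3):
                    nxt[:, g:g + acc.shape[1]] += acc * sub[:, i, g][:, None]
                acc = nxt
            denom = np.array([comb(2 * n, j) for j in range(K)], dtype=float)
            acc = acc / denom
        else:
            from .genolik import genotype_prior

            q = np.arange(K) / (2.0 * n)
            prior = genotype_prior(q[:, None], np.asarray(F)[None, :])  # (K, n, 3)
            acc = np.prod(
                np.einsum("kng,sng->skn", prior, gl_linear[complete]), axis=2
            )
        acc = np.clip(acc, 1e-300, None)
        out[complete] = acc / acc.max(axis=1, keepdims=True)
    for s in np.flatnonzero(~complete):
        use = ~missing[s]
        if not use.any():
            out[s] = 1.0
            continue
        Fs = None if F is None else np.asarray(F)[use]
        vec = np.exp(saf_site(gl_linear[s, use], Fs))
        if project_to_full and use.sum() < n:
            vec = project_saf(vec, 2 * n)
        elif len(vec) != K:
            full = np.zeros(K)
            full[: len(vec)] = vec
            vec = full
        out[s] = vec / vec.max()
    return out


def project_saf(saf_linear: np.ndarray, n_target_alleles: int) -> np.ndarray:
    """Mix a SAF over 2m observed alleles up to a larger sample of alleles.

    Under missing-at-random sampling, P(D | J derived among N alleles) =
    sum_j HG(j; N, J, 2m) * P(D | j among 2m) exactly; this gives every site
    a common vector length regardless of which individuals were missing.
    """
    saf_linear = np.asarray(saf_linear, dtype=float)
    m2 = len(saf_linear) - 1
    if n_target_alleles < m2:
        raise ValueError("can only project toward a larger allele count")
    J = np.arange(n_target_alleles + 1)
    j = np.arange(m2 + 1)
    # weights[J, j] = P(j derived in 2m draws | J derived among N)
    weights = hypergeom.pmf(j[None, :], n_target_alleles, J[:, None], m2)
    return weights @ saf_linear


# ---------------------------------------------------------------------------
# EM spectra


def _em_generic(saf_list: list[np.ndarray], shape: tuple[int, ...],
                tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Shared EM driver over flattened frequency classes.

    ``saf_list`` holds per-chunk (S_c, K) linear SAF products already
    flattened to K = prod(shape) columns.
    """
    K = int(np.prod(shape))
    phi = np.full(K, 1.0 / K)
    total = sum(a.shape[0] for a in saf_list)
    if total == 0:
        raise ValueError("no sites supplied to the SFS EM")
    ll_path = []
    for _ in range(max_iter):
        acc = np.zeros(K)
        ll = 0.0
        for a in saf_list:
            denom = a @ phi
            denom = np.clip(denom, 1e-300, None)
            ll += float(np.log(denom).sum())
            acc += (a / denom[:, None]).sum(axis=0)
        phi_new = phi * acc / total
        phi_new /= phi_new.sum()
        ll_path.append(ll)
        if len(ll_path) > 1 and abs(ll_path[-1] - ll_path[-2]) <= tol * abs(ll_path[-2]):
            phi = phi_new
            break
        phi = phi_new
    return phi, np.asarray(ll_path)


def em_sfs_1d(saf: np.ndarray | list[np.ndarray], population: str = "pop",
              folded: bool = False, tol: float = 1e-8,
              max_iter: int = 400) -> SFS1D:
    """EM estimate of the 1D spectrum from linear SAF rows (S, 2n+1).

    Accepts a single array or a list of genome chunks (accumulated jointly).
    The EM runs on the unfolded grid; folding is applied at reporting.
    """
    chunks = [np.asarray(saf)] if isinstance(saf, np.ndarray) else [np.asarray(c) for c in saf]
    K = chunks[0].shape[1]
    if any(c.shape[1] != K for c in chunks):
        raise ValueError("all SAF chunks must share the same allele count")
    phi, ll = _em_generic(chunks, (K,), tol, max_iter)
    total = sum(c.shape[0] for c in chunks)
    counts = phi * total
    if folded:
        counts = fold_1d(counts)
    return SFS1D(population=population, folded=folded, counts=counts,
                 total_sites=total, loglik_path=ll)


def em_sfs_2d(saf_a: np.ndarray | list[np.ndarray],
              saf_b: np.ndarray | list[np.ndarray],
              populations: tuple[str, str] = ("A", "B"),
              folded: bool = False, tol: float = 1e-8, max_iter: int = 400,
              fold_convention: str = "pooled") -> SFS2D:
    """EM estimate of the joint 2D spectrum from per-population SAF rows.

    The per-site joint likelihood factorizes as SAF_A(j1) * SAF_B(j2); the
    EM therefore runs over the flattened (2n1+1) x (2n2+1) grid using a
    rank-1 Kronecker row per site, accumulated over chunks.
    """
    la = [saf_a] if isinstance(saf_a, np.ndarray) else list(saf_a)
    lb = [saf_b] if isinstance(saf_b, np.ndarray) else list(saf_b)
    if len(la) != len(lb):
        raise ValueError("population SAF chunk lists must align")
    Ka, Kb = la[0].shape[1], lb[0].shape[1]
    prods = []
    for a, b in zip(la, lb):
        if a.shape[0] != b.shape[0]:
            raise ValueError("chunks must cover the same sites in both populations")
        prods.append(np.einsum("si,sj->sij", a, b).reshape(a.shape[0], Ka * Kb))
    phi, ll = _em_generic(prods, (Ka, Kb), tol, max_iter)
    total = sum(a.shape[0] for a in la)
    counts = (phi * total).reshape(Ka, Kb)
    if folded:
        counts = fold_2d(counts, convention=fold_convention)
    return SFS2D(populations=populations, folded=folded, counts=counts,
                 total_sites=total, loglik_path=ll)


def fold_1d(counts: np.ndarray) -> np.ndarray:
    """Fold an unfolded 1D spectrum by the minor allele."""
    counts = np.asarray(counts, dtype=float)
    n2 = len(counts) - 1
    half = n2 // 2
    out = np.array([
        counts[j] + (counts[n2 - j] if j != n2 - j else 0.0)
        for j in range(half + 1)
    ])
    return out


def fold_2d(counts: np.ndarray, convention: str = "pooled") -> np.ndarray:
    """Fold a joint spectrum, keeping the full grid shape.

    ``"pooled"`` combines cell (i, j) with its mirror (2n1-i, 2n2-j) into the
    cell whose pooled derived count is smaller (lexicographic tie-break at
    the exact middle).  ``"per-population"`` folds each axis independently by
    its own minor allele, zeroing the mirrored half of each axis.
    """
    counts = np.asarray(counts, dtype=float)
    Ka, Kb = counts.shape
    na, nb = Ka - 1, Kb - 1
    out = np.zeros_like(counts)
    if convention == "pooled":
        ntot = na + nb
        for i in range(Ka):
            for j in range(Kb):
                mi, mj = na - i, nb - j
                pooled = i + j
                if pooled < ntot - pooled or (
                    pooled == ntot - pooled and (i, j) <= (mi, mj)
                ):
                    add = counts[i, j]
                    if (i, j) != (mi, mj):
                        add = add + counts[mi, mj]
                    out[i, j] = add
    elif convention == "per-population":
        for i in range(Ka):
            for j in range(Kb):
                ti = min(i, na - i)
                tj = min(j, nb - j)
                out[ti, tj] += counts[i, j]
    else:
        raise ValueError(f"unknown folding convention {convention!r}")
    return out


# ---------------------------------------------------------------------------
# genic masking


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals (start, end)."""
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def mask_genic(positions: np.ndarray, gene_intervals: np.ndarray,
               flank: int = 1000) -> np.ndarray:
    """Boolean mask of positions OUTSIDE all flank-expanded gene intervals.

    Intervals are 0-based half-open; each is expanded by ``flank`` bp on both
    sides (clipped at 0) and overlapping expansions merge.
    """
    positions = np.asarray(positions)
    iv = np.asarray(gene_intervals, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        return np.ones(len(positions), dtype=bool)
    iv = iv.copy()
    iv[:, 0] = np.maximum(iv[:, 0] - flank, 0)
    iv[:, 1] = iv[:, 1] + flank
    iv = merge_intervals(iv)
    keep = np.ones(len(positions), dtype=bool)
    for s, e in iv:
        keep &= ~((positions >= s) & (positions < e))
    return keep
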