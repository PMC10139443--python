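"""Population structure from genotype likelihoods.

Three estimators that never require hard genotype calls:

* per-individual inbreeding coefficients F (maximum likelihood under the
  inbreeding-adjusted HWE prior, F in [-1, 1]);
* PCA in the low-coverage style: iterated posterior-mean dosages with
  individual allele frequencies from a rank-K reconstruction, then the
  standardized covariance and its eigendecomposition;
* admixture proportions by EM on the binomial admixture likelihood
  (cluster frequencies F_k and individual proportions Q), with seeded
  restarts and a monotone objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .genolik import GLMatrix, estimate_maf, genotype_prior

__all__ = [
    "StructureResult",
    "inbreeding_ml",
    "pca_gl",
    "admixture_em",
]


@dataclass
class StructureResult:
    """Container for PCA / admixture / inbreeding outputs."""

    covariance: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    variance_fractions: np.ndarray | None = None
    coordinates: np.ndarray | None = None
    Q: np.ndarray | None = None
    Fk: np.ndarray | None = None
    inbreeding: np.ndarray | None = None
    loglik: float | None = None
    loglik_path: np.ndarray | None = None
    converged: bool = True
    restarts: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# inbreeding


def _inbreeding_loglik(F: float, gl_lin: np.ndarray, p: np.ndarray) -> float:
    prior = genotype_prior(p[:, None], np.array([[F]]))[:, 0, :]
    lik = (gl_lin * prior).sum(axis=1)
    return float(np.log(np.clip(lik, 1e-300, None)).sum())


def inbreeding_ml(glm: GLMatrix, freqs: np.ndarray | None = None,
                  tol: float = 1e-8) -> np.ndarray:
    """Per-individual ML inbreeding coefficient over F in [-1, 1].

    ``freqs`` are per-site minor-allele frequencies (estimated by EM when
    omitted).  The 1-D likelihood is maximized by bounded scalar
    optimization; sites where the individual is missing are ignored.
    """
    if glm.n_sites == 0:
        raise ValueError("no sites available for inbreeding estimation")
    lin = glm.linear()
    if freqs is None:
        freqs = estimate_maf(lin, glm.missing)
    freqs = np.clip(np.asarray(freqs, dtype=float), 1e-6, 1 - 1e-6)
    F_hat = np.zeros(glm.n_individuals)
    for i in range(glm.n_individuals):
        use = ~glm.missing[:, i]
        if not use.any():
            F_hat[i] = 0.0
            continue
        gl_i = lin[use, i, :]
        p_i = freqs[use]
        res = minimize_scalar(
            lambda F: -_inbreeding_loglik(F, gl_i, p_i),
            bounds=(-1.0, 1.0), method="bounded",
            options={"xatol": tol},
        )
        F_hat[i] = float(np.clip(res.x, -1.0, 1.0))
    return F_hat


# ---------------------------------------------------------------------------
# PCA


def pca_gl(glm: GLMatrix, n_axes: int = 2, tol: float = 1e-5,
           max_iter: int = 100) -> StructureResult:
    """Genotype-likelihood PCA with iterated individual allele frequencies.

    Algorithm: start from site frequencies p_s; compute posterior-mean
    dosages E[g_is]; refine per-individual frequencies pi_is from a rank-K
    reconstruction of the standardized dosage matrix; repeat until the
    covariance stabilizes.  The reported covariance is
    C_ij = (1/S) sum_s (E[g_is]-2p_s)(E[g_js]-2p_s) / (2p_s(1-p_s)).
    """
    if glm.n_individuals < 2 or glm.n_sites < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 sites")
    lin = glm.linear()
    p = np.clip(estimate_maf(lin, glm.missing), 1e-4, 1 - 1e-4)
    S, N, _ = lin.shape
    dos = np.array([0.0, 1.0, 2.0])
    pi = np.broadcast_to(p[:, None], (S, N)).copy()
    C_prev = None
    converged = False
    for it in range(max_iter):
        prior = genotype_prior(pi, np.zeros((S, N)))
        post = lin * prior
        post /= post.sum(axis=2, keepdims=True)
        E = post @ dos  # (S, N)
        norm = np.sqrt(2 * p * (1 - p))
        Z = (E - 2 * p[:, None]) / norm[:, None]
        C = (Z.T @ Z) / S
        if C_prev is not None and np.max(np.abs(C - C_prev)) < tol:
            converged = True
            C_prev = C
            break
        C_prev = C
        # rank-K reconstruction -> individual allele frequencies
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        K = min(n_axes, len(s))
        recon = (U[:, :K] * s[:K]) @ Vt[:K]
        pi = np.clip(p[:, None] + recon * norm[:, None] / 2.0, 1e-4, 1 - 1e-4)
    if not converged:
        import warnings

        warnings.warn("PCA iteration did not converge; returning last iterate")
    vals, vecs = np.linalg.eigh(C_prev)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    frac = vals / np.trace(C_prev)
    coords = vecs[:, :n_axes] * np.sqrt(np.clip(vals[:n_axes], 0, None))
    return StructureResult(covariance=C_prev, eigenvalues=vals,
                           variance_fractions=frac, coordinates=coords,
                           converged=converged)


# ---------------------------------------------------------------------------
# admixture


def _admix_loglik(lin: np.ndarray, q: np.ndarray) -> float:
    """log-likelihood given per-individual per-site allele frequencies q."""
    g1 = 2 * q * (1 - q)
    lik = lin[:, :, 0] * (1 - q) ** 2 + lin[:, :, 1] * g1 + lin[:, :, 2] * q**2
    return float(np.log(np.clip(lik, 1e-300, None)).sum())


def admixture_em(glm: GLMatrix, K: int, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 400, n_restarts: int = 5) -> StructureResult:
    """Admixture proportions Q and cluster frequencies Fk by EM.

    The model: individual i's minor-allele frequency at site s is
    q_is = sum_k Q_ik Fk_ks, and the genotype is Binomial(2, q_is) behind the
    likelihood triple.  EM follows the standard expected-allele-count
    updates; ``n_restarts`` seeded starts are run and the best likelihood
    kept.  Clusters are reported sorted by total mass (descending) so the
    output ordering is deterministic.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > glm.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    # sites x individuals -> EM operates on (S, N) broadcasting
    lin = glm.linear()  # (S, N, 3); missing cells flat (contribute nothing)
    S, N, _ = lin.shape
    rng_master = np.random.default_rng(seed)
    best = None
    restart_lls = []
    for _ in range(max(n_restarts, 1)):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        Q = rng.dirichlet(np.ones(K), size=N)  # (N, K)
        Fk = np.clip(rng.uniform(0.05, 0.95, size=(K, S)), 1e-4, 1 - 1e-4)
        ll_path = []
        for it in range(max_iter):
            q = (Q @ Fk).T  # (S, N)
            q = np.clip(q, 1e-6, 1 - 1e-6)
            prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=2)
            post = lin * prior
            post /= post.sum(axis=2, keepdims=True)
            Eg = post @ np.array([0.0, 1.0, 2.0])  # (S, N) expected minor dosage
            # attribute expected allele draws to clusters
            # a_isk = Eg * Q_ik Fk_ks / q_is ; b_isk = (2-Eg) * Q_ik (1-Fk_ks)/(1-q_is)
            w_min = Eg / q          # (S, N)
            w_maj = (2 - Eg) / (1 - q)
            a_k = Fk * (w_min @ Q).T           # (K, S): minor draws from cluster k
            b_k = (1 - Fk) * (w_maj @ Q).T
            a_i = Q * (Fk @ w_min).T           # (N, K): draws individual i took from k
            b_i = Q * ((1 - Fk) @ w_maj).T
            Fk = np.clip(a_k / np.clip(a_k + b_k, 1e-12, None), 1e-4, 1 - 1e-4)
            Q = (a_i + b_i) / (2.0 * S)
            Q = Q / Q.sum(axis=1, keepdims=True)
            ll = _admix_loglik(lin, np.clip((Q @ Fk).T, 1e-6, 1 - 1e-6))
            ll_path.append(ll)
            if len(ll_path) > 1 and abs(ll_path[-1] - ll_path[-2]) < tol * abs(ll_path[-2]):
                break
        restart_lls.append(ll_path[-1])
        if best is None or ll_path[-1] > best[0]:
            best = (ll_path[-1], Q, Fk, np.asarray(ll_path))
    ll, Q, Fk, path = best
    order = np.argsort(Q.sum(axis=0))[::-1]  # sort clusters by total mass
    return StructureResult(Q=Q[:, order], Fk=Fk[order], loglik=ll,
                           loglik_path=path, restarts=restart_lls)
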