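"""Windowed diversity, differentiation and the population branch statistic.

Per-site expectations are posterior means under the genome-wide SFS prior:
P(j | D) proportional to phi_j * SAF(j).  Window Fst is always the weighted
ratio-of-sums sum(alpha)/sum(beta) (mean-of-ratios is deliberately not
offered for windows); PBS transforms the three pairwise window Fst values
through T = -ln(1 - Fst) and isolates the branch specific to one population:
PBS_A = (T_AB + T_AC - T_BC) / 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "site_thetas",
    "tajima_constants",
    "tajimas_d",
    "fst_components",
    "weighted_fst",
    "windows_1d",
    "theta_windows",
    "pbs_scan",
]


def _posterior(saf_linear: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Per-site posterior over frequency classes, rows sum to 1."""
    saf_linear = np.atleast_2d(saf_linear)
    if saf_linear.shape[1] != len(prior):
        raise ValueError(
            f"SAF width {saf_linear.shape[1]} does not match prior length {len(prior)}"
        )
    post = saf_linear * prior[None, :]
    denom = post.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    return post / denom


def harmonic(m: int) -> float:
    """a_m = sum_{k=1}^{m-1} 1/k."""
    return float(np.sum(1.0 / np.arange(1, m)))


def site_thetas(saf_linear: np.ndarray, sfs_counts: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior per-site E[pi] and E[theta_W] under an SFS prior.

    ``sfs_counts`` is the unfolded genome-wide spectrum (any positive scale).
    E[pi] = sum_j P(j|D) j(2n-j)/C(2n,2); E[theta_W] = P(segregating)/a_2n.
    """
    prior = np.asarray(sfs_counts, dtype=float)
    post = _posterior(saf_linear, prior)
    K = post.shape[1]
    n2 = K - 1
    j = np.arange(K)
    pi_w = j * (n2 - j) / (n2 * (n2 - 1) / 2.0)
    e_pi = post @ pi_w
    p_seg = 1.0 - post[:, 0] - post[:, -1]
    e_tw = p_seg / harmonic(n2)
    return e_pi, e_tw


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sampled alleles."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sampled alleles")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: float, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating-site count, pairwise-diversity sum and n alleles.

    Returns NaN when S == 0 (the statistic is undefined).
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    return float((pi_sum - S / c["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Fst


def fst_components(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int,
                   estimator: str = "hudson") -> tuple[np.ndarray, np.ndarray]:
    """Per-site Fst numerator/denominator (alpha, beta) from sample frequencies.

    ``n1``/``n2`` are sampled allele counts.  The default Hudson/Bhatia form:
    alpha = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    beta = p1(1-p2) + p2(1-p1).  A Reynolds (1983) variant is selectable.
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("need more than one sampled allele in each population")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = p1 * (1 - p1)
    h2 = p2 * (1 - p2)
    if estimator == "hudson":
        alpha = (p1 - p2) ** 2 - h1 / (n1 - 1) - h2 / (n2 - 1)
        beta = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "reynolds":
        # Reynolds, Weir & Cockerham (1983) a-hat / (a+b)-hat, allele counts
        hu1 = h1 * n1 / (n1 - 1.0)
        hu2 = h2 * n2 / (n2 - 1.0)
        alpha = (p1 - p2) ** 2 - (hu1 / n1 + hu2 / n2)
        beta = (p1 - p2) ** 2 + (hu1 + hu2) / 2.0 - (hu1 / n1 + hu2 / n2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return alpha, beta


def posterior_freqs(saf_linear: np.ndarray, sfs_counts: np.ndarray) -> np.ndarray:
    """Posterior-mean sample allele frequency per site under an SFS prior."""
    prior = np.asarray(sfs_counts, dtype=float)
    post = _posterior(saf_linear, prior)
    K = post.shape[1]
    return post @ (np.arange(K) / (K - 1.0))


def joint_posterior_freqs(saf1: np.ndarray, saf2: np.ndarray,
                          sfs2d_counts: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean frequencies (p1, p2) per site under a joint 2D prior."""
    saf1 = np.atleast_2d(saf1)
    saf2 = np.atleast_2d(saf2)
    K1, K2 = saf1.shape[1], saf2.shape[1]
    prior = np.asarray(sfs2d_counts, dtype=float)
    if prior.shape != (K1, K2):
        raise ValueError("2D prior shape does not match the SAF widths")
    j1 = np.arange(K1) / (K1 - 1.0)
    j2 = np.arange(K2) / (K2 - 1.0)
    # per site: W = prior * outer(saf1_s, saf2_s)
    a1 = saf1 * 1.0
    a2 = saf2 * 1.0
    denom = np.einsum("si,ij,sj->s", a1, prior, a2)
    denom = np.clip(denom, 1e-300, None)
    num1 = np.einsum("si,i,ij,sj->s", a1, j1, prior, a2)
    num2 = np.einsum("si,ij,j,sj->s", a1, prior, j2, a2)
    return num1 / denom, num2 / denom


def weighted_fst(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Genome-wide weighted ("ratio of sums") Fst."""
    b = float(np.sum(beta))
    return float(np.sum(alpha) / b) if b > 0 else float("nan")


# ---------------------------------------------------------------------------
# windows


def windows_1d(positions: np.ndarray, contig_length: float,
               window: int, step: int) -> list[tuple[int, int, np.ndarray]]:
    """Sliding half-open windows [start, start+window) with their site indices."""
    positions = np.asarray(positions)
    out = []
    start = 0
    order = np.argsort(positions)
    pos_sorted = positions[order]
    while start < contig_length:
        end = start + window
        lo = np.searchsorted(pos_sorted, start, side="left")
        hi = np.searchsorted(pos_sorted, end, side="left")
        out.append((start, end, order[lo:hi]))
        start += step
    return out


def theta_windows(positions: np.ndarray, e_pi: np.ndarray, e_tw: np.ndarray,
                  n_alleles: int, contig_length: float, contig: str = "contig1",
                  window: int = 20_000, step: int = 20_000,
                  min_data: int = 0) -> pd.DataFrame:
    """Per-window summed pi, theta_W and Tajima's D.

    ``S`` for the D computation is the window's summed posterior probability
    of segregation (theta_W * a_n), the standard treatment for expected
    per-site thetas.
    """
    a1 = harmonic(n_alleles)
    rows = []
    for start, end, idx in windows_1d(positions, contig_length, window, step):
        n_sites = len(idx)
        if n_sites < min_data:
            continue
        pi = float(e_pi[idx].sum())
        tw = float(e_tw[idx].sum())
        S = tw * a1
        rows.append({
            "contig": contig, "start": start, "end": end, "n_sites": n_sites,
            "pi": pi, "theta_w": tw,
            "tajima_d": tajimas_d(S, pi, n_alleles) if S > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def _window_fst(alpha: np.ndarray, beta: np.ndarray, idx: np.ndarray) -> float:
    b = beta[idx].sum()
    if b <= 0:
        return float("nan")
    f = alpha[idx].sum() / b
    return float(min(max(f, 0.0), 1.0))  # clamp for the log transform


def pbs_scan(positions: np.ndarray,
             ab: tuple[np.ndarray, np.ndarray],
             ac: tuple[np.ndarray, np.ndarray],
             bc: tuple[np.ndarray, np.ndarray],
             contig_length: float,
             populations: tuple[str, str, str] = ("A", "B", "C"),
             contig: str = "contig1",
             window: int = 5_000, step: int = 500, min_data: int = 4_000,
             top_fraction: float = 0.001) -> pd.DataFrame:
    """PBS in sliding windows from three per-site (alpha, beta) streams.

    All three streams must cover the same ``positions``.  Windows with fewer
    than ``min_data`` sites carrying data are dropped; negative window Fst is
    clamped to 0 before T = -ln(1-Fst); windows where any Fst reaches 1 get
    infinite T and are excluded from top-fraction ranking.  The top
    ``top_fraction`` of retained finite windows is flagged per population.
    """
    pA, pB, pC = populations
    streams = {"ab": ab, "ac": ac, "bc": bc}
    for k, (al, be) in streams.items():
        if len(al) != len(positions) or len(be) != len(positions):
            raise ValueError(f"stream {k} does not cover the site list")
    rows = []
    for start, end, idx in windows_1d(positions, contig_length, window, step):
        if len(idx) < min_data:
            continue
        f_ab = _window_fst(*ab, idx)
        f_ac = _window_fst(*ac, idx)
        f_bc = _window_fst(*bc, idx)
        with np.errstate(divide="ignore"):
            t_ab = -np.log1p(-f_ab)
            t_ac = -np.log1p(-f_ac)
            t_bc = -np.log1p(-f_bc)
        rows.append({
            "contig": contig, "start": start, "end": end, "n_sites": len(idx),
            "fst_ab": f_ab, "fst_ac": f_ac, "fst_bc": f_bc,
            f"pbs_{pA}": (t_ab + t_ac - t_bc) / 2.0,
            f"pbs_{pB}": (t_ab + t_bc - t_ac) / 2.0,
            f"pbs_{pC}": (t_ac + t_bc - t_ab) / 2.0,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for pop in populations:
        col = df[f"pbs_{pop}"].to_numpy()
        finite = np.isfinite(col)
        flag = np.zeros(len(df), dtype=bool)
        n_top = int(np.ceil(top_fraction * finite.sum()))
        if n_top > 0 and finite.any():
            order = np.argsort(col[finite])[::-1][:n_top]
            flag[np.flatnonzero(finite)[order]] = True
        df[f"top_{pop}"] = flag
    return df
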