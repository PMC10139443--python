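"""Two-locus r-squared from genotype likelihoods and LD-decay fitting.

``r2_em`` runs the phase-unknown EM over the four two-locus haplotype
frequencies, with the genotype uncertainty of both sites integrated through
their likelihood triples (random mating pairs the two haplotypes of an
individual independently).  ``fit_decay`` bins pair r-squared by distance and
fits r2(d) = r2_min + (r2_max - r2_min) * exp(-lambda * d) by weighted
nonlinear least squares, with pair-bootstrap percentile intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genolik import GLMatrix

__all__ = [
    "LDPair",
    "LDDecayFit",
    "r2_em",
    "collect_pairs",
    "fit_decay",
    "model_fit_check",
]


@dataclass
class LDPair:
    site1: int
    site2: int
    distance: float
    r2: float
    D: float
    iterations: int


@dataclass
class LDDecayFit:
    decay_rate: float        # lambda, per bp
    r2_max: float
    r2_min: float
    ci: dict[str, tuple[float, float]]
    bin_size: int
    n_pairs: int

    def curve(self, d: np.ndarray) -> np.ndarray:
        return _decay_curve(np.asarray(d, dtype=float),
                            self.decay_rate, self.r2_max, self.r2_min)


# 16 ordered haplotype pairs -> genotype pair (g1, g2); haplotypes are
# indexed 0=AB, 1=Ab, 2=aB, 3=ab with "a"/"b" the minor alleles.
_HAP_ALLELE1 = np.array([0, 0, 1, 1])  # minor-allele dose at site 1 per haplotype
_HAP_ALLELE2 = np.array([0, 1, 0, 1])
_PAIRS = np.array(list(itertools.product(range(4), repeat=2)))
_G1 = _HAP_ALLELE1[_PAIRS[:, 0]] + _HAP_ALLELE1[_PAIRS[:, 1]]
_G2 = _HAP_ALLELE2[_PAIRS[:, 0]] + _HAP_ALLELE2[_PAIRS[:, 1]]
# haplotype-count design: _COUNT[p, k] = copies of haplotype k in pair p
_COUNT = np.zeros((16, 4))
for _p, (_h1, _h2) in enumerate(_PAIRS):
    _COUNT[_p, _h1] += 1
    _COUNT[_p, _h2] += 1


def r2_em(gl1: np.ndarray, gl2: np.ndarray, tol: float = 1e-8,
          max_iter: int = 500) -> tuple[float, float, np.ndarray, int]:
    """EM over two-locus haplotype frequencies from two GL triple sets.

    ``gl1``/``gl2`` are (N, 3) linear triples ordered by minor-allele dose.
    Returns ``(r2, D, h, iterations)`` with ``h`` the four haplotype
    frequencies (AB, Ab, aB, ab).  Raises ``ValueError`` when either site is
    effectively monomorphic (r2 undefined).
    """
    gl1 = np.atleast_2d(gl1)
    gl2 = np.atleast_2d(gl2)
    N = gl1.shape[0]
    if N < 2:
        raise ValueError("need at least two individuals")
    # per-individual likelihood of each ordered haplotype pair configuration
    lik_pair = gl1[:, _G1] * gl2[:, _G2]  # (N, 16)
    h = np.full(4, 0.25)
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        w = h[_PAIRS[:, 0]] * h[_PAIRS[:, 1]] * lik_pair  # (N, 16)
        denom = w.sum(axis=1, keepdims=True)
        if np.any(denom <= 0):
            raise ValueError("degenerate likelihood in haplotype EM")
        w = w / denom
        counts = w.sum(axis=0) @ _COUNT
        h_new = counts / (2.0 * N)
        ll = float(np.log(denom).sum())
        if abs(ll - ll_prev) < tol * max(abs(ll_prev), 1.0) and it > 1:
            h = h_new
            break
        h = h_new
        ll_prev = ll
    pA = h[2] + h[3]  # minor allele at site 1
    pB = h[1] + h[3]
    het1 = pA * (1 - pA)
    het2 = pB * (1 - pB)
    if het1 < 1e-8 or het2 < 1e-8:
        raise ValueError("monomorphic site: r2 undefined")
    D = h[3] - pA * pB
    r2 = D * D / (het1 * het2)
    return float(min(r2, 1.0)), float(D), h, it


def collect_pairs(glm: GLMatrix, max_dist: float = 10_000,
                  subsample: float = 0.10, seed: int = 0,
                  tol: float = 1e-8, max_iter: int = 500) -> pd.DataFrame:
    """r-squared for (a seeded subsample of) same-contig site pairs within range.

    Pairs at distance strictly greater than ``max_dist`` are excluded;
    monomorphic pairs are skipped.  Returns a tidy DataFrame (site1, site2,
    distance, r2, D, iterations).
    """
    if not (0 < subsample <= 1):
        raise ValueError("subsample must lie in (0, 1]")
    contigs = glm.sites["contig"].to_numpy()
    pos = glm.sites["pos"].to_numpy()
    order = np.lexsort((pos, contigs))
    cand = []
    for a_i in range(len(order)):
        i = order[a_i]
        for a_j in range(a_i + 1, len(order)):
            j = order[a_j]
            if contigs[j] != contigs[i]:
                break
            d = pos[j] - pos[i]
            if d > max_dist:
                break
            cand.append((i, j, float(d)))
    rng = np.random.default_rng(seed)
    if subsample < 1.0 and cand:
        keep = rng.random(len(cand)) < subsample
        cand = [c for c, k in zip(cand, keep) if k]
    lin = glm.linear()
    rows = []
    for i, j, d in cand:
        use = ~(glm.missing[i] | glm.missing[j])
        if use.sum() < 2:
            continue
        try:
            r2, D, _, it = r2_em(lin[i, use], lin[j, use], tol, max_iter)
        except ValueError:
            continue
        rows.append({"site1": i, "site2": j, "distance": d, "r2": r2,
                     "D": D, "iterations": it})
    return pd.DataFrame(rows, columns=["site1", "site2", "distance", "r2",
                                       "D", "iterations"])


def _decay_curve(d: np.ndarray, lam: float, r2_max: float, r2_min: float
                 ) -> np.ndarray:
    return r2_min + (r2_max - r2_min) * np.exp(-lam * d)


def _bin_pairs(pairs: pd.DataFrame, bin_size: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    b = (pairs["distance"].to_numpy() // bin_size).astype(int)
    centers, means, counts = [], [], []
    for k in np.unique(b):
        sel = b == k
        centers.append((k + 0.5) * bin_size)
        means.append(pairs.loc[sel, "r2"].mean())
        counts.append(sel.sum())
    return np.asarray(centers), np.asarray(means), np.asarray(counts)


def _fit_once(pairs: pd.DataFrame, bin_size: int) -> tuple[float, float, float]:
    d, y, n = _bin_pairs(pairs, bin_size)
    if len(d) < 2:
        raise ValueError("need at least two populated distance bins")
    span = max(d.max(), 1.0)
    p0 = (1.0 / span, float(np.clip(y[0], 1e-3, 1.0)),
          float(np.clip(y[-1], 0.0, 1.0)))
    popt, _ = curve_fit(
        _decay_curve, d, y, p0=p0, sigma=1.0 / np.sqrt(n),
        bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, 1.0]), maxfev=20_000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(pairs: pd.DataFrame, bin_size: int = 100, n_boot: int = 100,
              seed: int = 0) -> LDDecayFit:
    """Fit the three-parameter exponential decay to binned pair r-squared.

    Weighted NLS on bin means (weights = sqrt of pair counts); ``n_boot``
    pair-resampling bootstraps give 95% percentile intervals.  Raises with
    fit diagnostics when the optimizer cannot converge.
    """
    try:
        lam, r2max, r2min = _fit_once(pairs, bin_size)
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(
            f"LD decay fit failed on {len(pairs)} pairs with bin size "
            f"{bin_size}: {exc}"
        ) from exc
    rng = np.random.default_rng(seed)
    boots = {"decay_rate": [], "r2_max": [], "r2_min": []}
    for _ in range(n_boot):
        res = pairs.sample(n=len(pairs), replace=True,
                           random_state=int(rng.integers(2**31 - 1)))
        try:
            l_, ma, mi = _fit_once(res, bin_size)
        except (RuntimeError, ValueError):
            continue
        boots["decay_rate"].append(l_)
        boots["r2_max"].append(ma)
        boots["r2_min"].append(mi)
    ci = {}
    for k, v in boots.items():
        if v:
            ci[k] = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        else:
            ci[k] = (float("nan"), float("nan"))
    return LDDecayFit(decay_rate=lam, r2_max=r2max, r2_min=r2min, ci=ci,
                      bin_size=bin_size, n_pairs=len(pairs))


def model_fit_check(observed: LDDecayFit,
                    simulated_rates: dict[str, np.ndarray]) -> pd.DataFrame:
    """Compare per-model simulated decay rates against the observed 95% CI.

    A model is "consistent" when the median of its simulated decay rates
    falls inside the closed observed interval; otherwise the distance to the
    nearer CI edge is reported.  Models are ranked by |median - observed|.
    """
    lo, hi = observed.ci["decay_rate"]
    rows = []
    for name, rates in simulated_rates.items():
        rates = np.asarray(rates, dtype=float)
        if rates.size == 0:
            raise ValueError(f"no simulated replicates for model {name!r}")
        med = float(np.median(rates))
        inside = bool(lo <= med <= hi)
        dist = 0.0 if inside else float(min(abs(med - lo), abs(med - hi)))
        rows.append({
            "model": name, "median_rate": med, "consistent": inside,
            "distance_to_ci": dist,
            "abs_error": abs(med - observed.decay_rate),
        })
    df = pd.DataFrame(rows).sort_values("abs_error").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
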