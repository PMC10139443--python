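"""SFS composite-likelihood demographic inference for the three-population model.

The estimator treats the folded pairwise joint spectra among {Andes, Central,
North} as multinomial counts over polymorphic frequency classes.  Expected
class probabilities under a candidate parameter vector are obtained by
coalescent simulation: independent single-locus tree replicates whose
branch-length allele-frequency spectra are accumulated (the exact
infinite-sites expectation given the simulated trees, so no mutational
Monte-Carlo noise) under common random numbers, making the likelihood
surface deterministic for a fixed seed.  Maximization is derivative-free
(Nelder-Mead) on log-transformed parameters with seeded log-uniform
restarts; uncertainty comes from a parametric bootstrap (simulate at the
MLE, refit, percentile intervals).

Usage follows the model/results idiom::

    model = SFSDemography(observed, samples, variant="constant")
    res = model.fit(seed=1)
    res = res.parametric_bootstrap(reps=100, seed=2)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfs import fold_2d
from .syndata import DemographicModel, sim_tree_replicates

__all__ = [
    "PAIRS",
    "param_names",
    "default_bounds",
    "params_to_model",
    "expected_sfs",
    "sample_observed_sfs",
    "composite_ll",
    "SFSDemography",
    "SFSDemographyResults",
]

POPS = ("Andes", "Central", "North")
PAIRS = (("Andes", "Central"), ("Andes", "North"), ("Central", "North"))

_BASE = ["N_anc", "N_Andes", "N_Central", "N_North", "T_split_N", "T_split_C"]
_GROWTH = ["r_Andes", "r_Central", "r_North"]
_RESIZE = ["Ninit_Andes", "Ninit_Central", "Ninit_North",
           "Tresize_Andes", "Tresize_Central", "Tresize_North"]


def param_names(variant: str) -> list[str]:
    if variant == "constant":
        return list(_BASE)
    if variant == "growth":
        return _BASE + _GROWTH
    if variant == "resize":
        return _BASE + _RESIZE
    raise ValueError(f"unknown variant {variant!r}")


def default_bounds(variant: str) -> dict[str, tuple[float, float]]:
    """Desk-scale search bounds (diploid sizes, generations, per-gen rates)."""
    b: dict[str, tuple[float, float]] = {}
    for name in param_names(variant):
        if name.startswith(("N_", "Ninit")):
            b[name] = (1e2, 1e5)
        elif name.startswith(("T_", "Tresize")):
            b[name] = (1e2, 1e5)
        elif name.startswith("r_"):
            b[name] = (1e-5, 5e-2)
    return b


def params_to_model(variant: str, params: dict[str, float]) -> DemographicModel:
    """Build a validated :class:`DemographicModel` from a named parameter dict."""
    kw = dict(
        variant=variant,
        N_anc=params["N_anc"],
        T_split_N=params["T_split_N"],
        T_split_C=params["T_split_C"],
        N_final={p: params[f"N_{p}"] for p in POPS},
    )
    if variant == "growth":
        kw["r"] = {p: params[f"r_{p}"] for p in POPS}
    elif variant == "resize":
        kw["N_init"] = {p: params[f"Ninit_{p}"] for p in POPS}
        kw["T_resize"] = {p: params[f"Tresize_{p}"] for p in POPS}
    return DemographicModel(**kw)


# ---------------------------------------------------------------------------
# expected and observed spectra


def _fold_and_mask(arr: np.ndarray) -> np.ndarray:
    """Fold a pairwise spectrum and zero the monomorphic corners."""
    f = fold_2d(arr, convention="pooled")
    f[0, 0] = 0.0
    f[-1, -1] = 0.0
    return f


def expected_sfs(model: DemographicModel, samples: dict[str, int],
                 n_sims: int, seed: int, normalize: bool = False
                 ) -> dict[tuple[str, str], np.ndarray]:
    """Expected folded pairwise 2D-SFS by branch-length simulation.

    Simulates ``n_sims`` independent single-locus genealogies, accumulates
    the three-population branch allele-frequency spectrum, marginalizes it to
    the three pairs and folds (pooled-minor convention).  Entries are mean
    branch lengths (generations per bp-locus): multiplying by mu * L gives
    expected polymorphic-site counts, which is how the composite likelihood
    keeps the absolute time/size scale identifiable.  ``normalize=True``
    returns per-pair probabilities instead.  Deterministic given ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    reps = sim_tree_replicates(model, dict(samples), n_sims, seed)
    acc = None
    for ts in reps:
        sets = [ts.samples(population=i) for i in range(3)]
        a = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=False
        )
        acc = a if acc is None else acc + a
    out = {}
    idx = {p: i for i, p in enumerate(POPS)}
    for p1, p2 in PAIRS:
        other = ({0, 1, 2} - {idx[p1], idx[p2]}).pop()
        marg = acc.sum(axis=other)
        if idx[p1] > idx[p2]:
            marg = marg.T
        f = _fold_and_mask(marg) / n_sims
        if normalize:
            tot = f.sum()
            f = f / tot if tot > 0 else f
        out[(p1, p2)] = f
    return out


def sample_observed_sfs(model: DemographicModel, samples: dict[str, int],
                        theta_scale: float, seed: int,
                        n_sims: int = 3000) -> dict[tuple[str, str], np.ndarray]:
    """Draw Poisson pairwise spectra: parametric data at ``model``.

    ``theta_scale`` is mu * L_total, the genome-wide per-branch-generation
    mutational opportunity; cell counts are independent Poisson draws with
    intensity theta_scale * E[branch length], the infinite-sites analogue of
    unlinked-site simulation.  Used for bootstrap and calibration data.
    """
    intens = expected_sfs(model, samples, n_sims, seed + 104_729)
    rng = np.random.default_rng(seed)
    return {pair: rng.poisson(theta_scale * b).astype(float)
            for pair, b in intens.items()}


def composite_ll(observed: dict[tuple[str, str], np.ndarray],
                 expected: dict[tuple[str, str], np.ndarray],
                 theta_scale: float,
                 min_count: float = 10.0, floor: float = 0.5) -> float:
    """Poisson composite log-likelihood over retained spectrum entries.

    Cell counts are treated as independent Poisson with intensity
    lambda_e = theta_scale * branch_e; the contribution of a retained cell is
    m_e log(lambda_e) - lambda_e.  Cells whose observed count is below
    ``min_count`` are excluded.  Intensities are floored at ``floor`` (in
    count units, default half a count): a populated cell the candidate model
    predicts empty is penalized at the floor rate rather than diverging,
    which keeps a finitely-simulated expected spectrum from dominating the
    objective through single empty cells.
    """
    ll = 0.0
    used = 0
    for pair, obs in observed.items():
        if pair not in expected:
            raise KeyError(f"expected spectrum missing pair {pair}")
        exp = expected[pair]
        if exp.shape != obs.shape:
            raise ValueError(f"spectrum shape mismatch for pair {pair}")
        keep = obs >= min_count
        used += int(keep.sum())
        if keep.any():
            lam = np.maximum(theta_scale * exp[keep], floor)
            ll += float((obs[keep] * np.log(lam) - lam).sum())
    if used == 0:
        raise ValueError("all spectrum entries fell below the count threshold")
    return ll


# ---------------------------------------------------------------------------
# model / results


@dataclass
class FitSettings:
    """Optimizer and Monte-Carlo settings for the composite-likelihood fit.

    The search runs in two stages: a cheap global stage (``n_sims``
    genealogies per likelihood evaluation, ``maxiter`` Nelder-Mead
    iterations per restart) and a polish stage restarted from the incumbent
    on a lower-variance surface (``polish_n_sims``, ``polish_maxiter``).
    The polish suppresses the Monte-Carlo distortion of the argmax that a
    cheap common-random-numbers surface would otherwise allow the optimizer
    to exploit.
    """

    n_sims: int = 400
    n_restarts: int = 3
    maxiter: int = 150
    n_reruns: int = 2          # fresh-simplex restarts from the incumbent
    polish_n_sims: int = 4000
    polish_maxiter: int = 60
    data_n_sims: int = 30000   # fidelity when SIMULATING datasets (bootstrap)
    min_count: float = 10.0
    xatol: float = 0.02
    fatol: float = 0.5


class SFSDemography:
    """Composite-likelihood demographic model for observed pairwise spectra.

    Parameters
    ----------
    observed
        Dict keyed by population pair with folded 2D-SFS count matrices
        (shapes (2n1+1, 2n2+1) on the full grid, as produced by the sfs
        module or :func:`sample_observed_sfs`).
    samples
        Diploid sample sizes per population.
    theta_scale
        mu * L_total: expected mutations per branch-generation across the
        analyzed genome.  Ties the spectra to an absolute time scale.
    variant
        "constant", "growth" or "resize".
    bounds
        Optional per-parameter (low, high) search bounds; defaults are
        desk-scale.  Degenerate bounds (low == high) pin a parameter.
    """

    def __init__(self, observed, samples, theta_scale: float,
                 variant: str = "constant",
                 bounds: dict[str, tuple[float, float]] | None = None,
                 settings: FitSettings | None = None):
        self.observed = dict(observed)
        self.samples = dict(samples)
        if theta_scale <= 0:
            raise ValueError("theta_scale must be positive")
        self.theta_scale = float(theta_scale)
        self.variant = variant
        self.names = param_names(variant)
        self.bounds = default_bounds(variant)
        if bounds:
            self.bounds.update(bounds)
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi):
                raise ValueError(f"invalid bounds for {name}: {(lo, hi)}")
        self.settings = settings or FitSettings()

    # -- likelihood machinery ------------------------------------------
    def _neg_ll(self, x_log: np.ndarray, crn_seed: int,
                n_sims: int | None = None) -> float:
        params = dict(zip(self.names, np.exp(x_log)))
        try:
            model = params_to_model(self.variant, params)
        except Exception:
            return 1e18  # invalid topology/timing: soft rejection
        exp = expected_sfs(model, self.samples,
                           n_sims or self.settings.n_sims, crn_seed)
        try:
            return -composite_ll(self.observed, exp, self.theta_scale,
                                 self.settings.min_count)
        except ValueError:
            return 1e18

    def loglike(self, params: dict[str, float], seed: int = 12345) -> float:
        """Composite log-likelihood at a named parameter dict."""
        x = np.log([params[n] for n in self.names])
        return -self._neg_ll(x, seed)

    def _valid_start(self, x_log: np.ndarray) -> np.ndarray:
        """Project a start onto the model's ordering constraints.

        Ensures T_split_C < T_split_N and, for the resize variant, each
        T_resize strictly inside its population's branch, so the optimizer
        never begins inside the invalid-topology penalty region.
        """
        x = dict(zip(self.names, np.exp(x_log)))
        x["T_split_C"] = min(x["T_split_C"], 0.5 * x["T_split_N"])
        if self.variant == "resize":
            for pop in POPS:
                founding = x["T_split_N"] if pop == "North" else x["T_split_C"]
                x[f"Tresize_{pop}"] = min(x[f"Tresize_{pop}"], 0.5 * founding)
        return np.log([x[n] for n in self.names])

    def _draw_start(self, rng: np.random.Generator) -> np.ndarray:
        lo = np.log([self.bounds[n][0] for n in self.names])
        hi = np.log([self.bounds[n][1] for n in self.names])
        return self._valid_start(rng.uniform(lo, hi))

    def fit(self, seed: int = 1, n_restarts: int | None = None,
            start: dict[str, float] | None = None) -> "SFSDemographyResults":
        """Maximize the composite likelihood with seeded restarts."""
        from scipy.optimize import minimize

        st = self.settings
        R = st.n_restarts if n_restarts is None else n_restarts
        rng = np.random.default_rng(seed)
        crn_seed = int(rng.integers(1, 2**31 - 1))
        lo = np.log([self.bounds[n][0] for n in self.names])
        hi = np.log([self.bounds[n][1] for n in self.names])
        degenerate = np.isclose(lo, hi)
        restarts = []
        for r in range(max(R, 1)):
            if r == 0 and start is not None:
                x0 = np.log([start[n] for n in self.names])
            elif r == 0:
                x0 = self._valid_start((lo + hi) / 2.0)  # bounds center
            else:
                x0 = self._draw_start(rng)
            x0 = np.where(degenerate, lo, x0)
            if degenerate.all():
                ll = -self._neg_ll(lo, crn_seed)
                restarts.append({"x": np.exp(lo), "ll": ll, "success": True})
                continue
            try:
                res = minimize(
                    self._neg_ll, x0, args=(crn_seed,), method="Nelder-Mead",
                    options={"maxiter": st.maxiter, "xatol": st.xatol,
                             "fatol": st.fatol, "adaptive": True},
                )
                x = np.clip(res.x, lo, hi)
                ll_r = -float(res.fun)
                restarts.append({"x": np.exp(x), "ll": ll_r,
                                 "success": bool(np.isfinite(ll_r)
                                                 and ll_r > -1e17)})
            except Exception:
                restarts.append({"x": np.exp(x0), "ll": -np.inf, "success": False})
        ok = [r for r in restarts if r["success"] and np.isfinite(r["ll"])]
        if not ok:
            raise RuntimeError("every optimizer restart failed")
        best = max(ok, key=lambda r: r["ll"])
        x_best = np.log(best["x"])
        llf = best["ll"]
        # fresh-simplex reruns from the incumbent escape Nelder-Mead stalls
        # on the correlated time/size ridges of these models
        for _ in range(st.n_reruns if not degenerate.all() else 0):
            res = minimize(
                self._neg_ll, x_best, args=(crn_seed,), method="Nelder-Mead",
                options={"maxiter": st.maxiter, "xatol": st.xatol,
                         "fatol": st.fatol, "adaptive": True},
            )
            if np.isfinite(res.fun) and -float(res.fun) > llf:
                x_best = np.clip(res.x, lo, hi)
                llf = -float(res.fun)
        if st.polish_maxiter > 0 and st.polish_n_sims > st.n_sims \
                and not degenerate.all():
            polish_seed = int(rng.integers(1, 2**31 - 1))
            res = minimize(
                self._neg_ll, x_best, args=(polish_seed, st.polish_n_sims),
                method="Nelder-Mead",
                options={"maxiter": st.polish_maxiter, "xatol": st.xatol / 2,
                         "fatol": st.fatol, "adaptive": True},
            )
            if np.isfinite(res.fun) and -res.fun > -1e17:
                x_best = np.clip(res.x, lo, hi)
                llf = -float(res.fun)
                crn_seed = polish_seed
        params = dict(zip(self.names, np.exp(x_best)))
        return SFSDemographyResults(
            model=self, params=params, llf=llf, restarts=restarts,
            seed=seed, crn_seed=crn_seed,
        )


@dataclass
class SFSDemographyResults:
    """Fitted parameters, restart trajectories and bootstrap intervals."""

    model: SFSDemography
    params: dict[str, float]
    llf: float
    restarts: list[dict]
    seed: int
    crn_seed: int
    bootstrap: pd.DataFrame | None = None
    bootstrap_failures: int = 0

    @property
    def variant(self) -> str:
        return self.model.variant

    def fitted_model(self) -> DemographicModel:
        return params_to_model(self.variant, self.params)

    def conf_int(self, alpha: float = 0.05,
                 ci_type: str = "percentile") -> pd.DataFrame:
        """Bootstrap intervals; requires parametric_bootstrap().

        ``"percentile"`` brackets the refit distribution itself (always
        contains the bootstrap median).  ``"basic"`` reflects the quantiles
        around the point estimate (2*mle - q), which corrects first-order
        estimator bias and is the better choice when asking whether an
        interval covers the generating truth.
        """
        if self.bootstrap is None or self.bootstrap.empty:
            raise ValueError("run parametric_bootstrap() first")
        lo = self.bootstrap.quantile(alpha / 2)
        hi = self.bootstrap.quantile(1 - alpha / 2)
        if ci_type == "percentile":
            return pd.DataFrame({"lower": lo, "upper": hi})
        if ci_type == "basic":
            est = pd.Series(self.params)
            return pd.DataFrame({"lower": 2 * est - hi, "upper": 2 * est - lo})
        raise ValueError(f"unknown ci_type {ci_type!r}")

    def parametric_bootstrap(self, reps: int = 100, seed: int = 2,
                             n_restarts: int | None = None,
                             settings: FitSettings | None = None
                             ) -> "SFSDemographyResults":
        """Simulate at the MLE, refit each replicate, store the distributions.

        Refits use the ORIGINAL fit settings (and starting strategy) by
        default so the refit estimator is the estimator being calibrated —
        its numerical bias then cancels to first order in basic intervals.
        Pass ``settings`` to trade fidelity for speed.  ``reps=0`` is a
        no-op.  Refit failures are logged in ``bootstrap_failures`` and
        intervals are computed over the successes.
        """
        if reps == 0:
            return self
        mle = self.fitted_model()
        rng = np.random.default_rng(seed)
        rows, failures = [], 0
        st = self.model.settings
        sub_settings = settings or st
        for b in range(reps):
            rep_seed = int(rng.integers(1, 2**31 - 1))
            sim = sample_observed_sfs(
                mle, self.model.samples, self.model.theta_scale,
                seed=rep_seed, n_sims=st.data_n_sims,
            )
            sub = SFSDemography(sim, self.model.samples, self.model.theta_scale,
                                self.variant, bounds=self.model.bounds,
                                settings=sub_settings)
            try:
                r = sub.fit(seed=rep_seed, n_restarts=n_restarts)
                rows.append(r.params)
            except Exception:
                failures += 1
        self.bootstrap = pd.DataFrame(rows)
        self.bootstrap_failures = failures
        return self

    def summary(self) -> str:
        lines = [
            "SFS composite-likelihood demographic fit",
            "=" * 56,
            f"variant: {self.variant}    log-likelihood: {self.llf:.3f}",
            f"restarts: {len(self.restarts)} "
            f"(successful: {sum(r['success'] for r in self.restarts)})",
            "-" * 56,
            f"{'parameter':<18}{'estimate':>12}{'2.5%':>12}{'97.5%':>12}",
        ]
        ci = None
        if self.bootstrap is not None and not self.bootstrap.empty:
            ci = self.conf_int()
        for name in self.model.names:
            est = self.params[name]
            if ci is not None and name in ci.index:
                lines.append(f"{name:<18}{est:>12.4g}"
                             f"{ci.loc[name, 'lower']:>12.4g}"
                             f"{ci.loc[name, 'upper']:>12.4g}")
            else:
                lines.append(f"{name:<18}{est:>12.4g}{'--':>12}{'--':>12}")
        if self.bootstrap is not None:
            lines.append("-" * 56)
            lines.append(f"bootstrap replicates: {len(self.bootstrap)} "
                         f"(failures: {self.bootstrap_failures})")
        return "\n".join(lines)
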