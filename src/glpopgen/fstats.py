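"""Population allele-count tables and f2/f3 statistics with block jackknife.

f3(A; B, C) measures shared drift of A toward B and C: a significantly
negative value indicates A is admixed from sources related to B and C.
Per-site: (pA - pB)(pA - pC) minus the finite-sample heterozygosity
correction pA(1 - pA)/(nA - 1); the estimate is the mean over usable sites
and its standard error comes from a delete-one block jackknife over
consecutive SNP blocks (default 500 SNPs; a trailing partial block merges
into the last full block).  Significance convention: Z = f3/SE <= -3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "F3Result",
    "f2_hat",
    "f3_hat",
    "f3_all_triplets",
    "jackknife_se",
]

Z_SIGNIFICANCE = -3.0


@dataclass
class CountTable:
    """Per-site, per-group counts of two alleles from called genotypes.

    ``allele1``/``allele2`` have shape (sites, groups); their sum at a site
    is twice the number of individuals called there.
    """

    groups: list[str]
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.allele1 = np.asarray(self.allele1)
        self.allele2 = np.asarray(self.allele2)
        if self.allele1.shape != self.allele2.shape:
            raise ValueError("allele count matrices must share a shape")
        if self.allele1.shape[1] != len(self.groups):
            raise ValueError("group list does not match count columns")
        if (self.allele1 < 0).any() or (self.allele2 < 0).any():
            raise ValueError("negative allele counts")

    @property
    def n_sites(self) -> int:
        return self.allele1.shape[0]

    def totals(self, group: str) -> np.ndarray:
        g = self.groups.index(group)
        return self.allele1[:, g] + self.allele2[:, g]

    def freqs(self, group: str) -> np.ndarray:
        """Frequency of allele2; NaN where the group has no calls."""
        g = self.groups.index(group)
        tot = self.allele1[:, g] + self.allele2[:, g]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.allele2[:, g] / tot, np.nan)

    @classmethod
    def from_genotypes(cls, calls: np.ndarray, group_labels: np.ndarray
                       ) -> "CountTable":
        """Build from a (sites, individuals) call matrix (-1 = missing).

        ``allele2`` counts the minor/alternate allele (call value), and
        ``allele1`` the complementary allele.
        """
        calls = np.asarray(calls)
        groups = list(pd.unique(np.asarray(group_labels)))
        a1 = np.zeros((calls.shape[0], len(groups)), dtype=np.int64)
        a2 = np.zeros_like(a1)
        for g, name in enumerate(groups):
            cols = np.flatnonzero(np.asarray(group_labels) == name)
            sub = calls[:, cols]
            called = sub >= 0
            a2[:, g] = np.where(called, sub, 0).sum(axis=1)
            a1[:, g] = 2 * called.sum(axis=1) - a2[:, g]
        return cls(groups=groups, allele1=a1, allele2=a2)


@dataclass
class F3Result:
    triplet: tuple[str, str, str]
    f3: float
    se: float
    z: float
    block_size: int
    n_blocks: int
    n_sites: int

    @property
    def significant(self) -> bool:
        return self.z <= Z_SIGNIFICANCE

    def as_row(self) -> dict:
        a, b, c = self.triplet
        return {"Pop(A;B,C)": f"{a}; {b}, {c}", "F3": self.f3, "SE": self.se,
                "Z": self.z, "n_blocks": self.n_blocks, "n_sites": self.n_sites}


def _usable(table: CountTable, pops: list[str], min_alleles: int = 2) -> np.ndarray:
    ok = np.ones(table.n_sites, dtype=bool)
    for p in pops:
        ok &= table.totals(p) >= min_alleles
    return ok


def _het_correction(p: np.ndarray, n: np.ndarray, denom: str) -> np.ndarray:
    d = n - 1.0 if denom == "n-1" else n.astype(float)
    return p * (1 - p) / d


def f2_sites(table: CountTable, A: str, B: str, corrected: bool = True,
             denom: str = "n-1") -> tuple[np.ndarray, np.ndarray]:
    """Per-site f2 values and the mask of usable sites."""
    use = _usable(table, [A, B])
    pA, pB = table.freqs(A)[use], table.freqs(B)[use]
    vals = (pA - pB) ** 2
    if corrected:
        vals = vals - _het_correction(pA, table.totals(A)[use], denom) \
                    - _het_correction(pB, table.totals(B)[use], denom)
    return vals, use


def f2_hat(table: CountTable, A: str, B: str, corrected: bool = True,
           denom: str = "n-1") -> float:
    """Mean per-site f2 (squared drift distance) between two groups."""
    vals, _ = f2_sites(table, A, B, corrected, denom)
    if len(vals) == 0:
        raise ValueError("no usable sites for f2")
    return float(vals.mean())


def f3_sites(table: CountTable, A: str, B: str, C: str, corrected: bool = True,
             denom: str = "n-1") -> tuple[np.ndarray, np.ndarray]:
    """Per-site f3(A; B, C) values and the usable-site mask."""
    use = _usable(table, [A, B, C])
    pA, pB, pC = (table.freqs(p)[use] for p in (A, B, C))
    vals = (pA - pB) * (pA - pC)
    if corrected:
        vals = vals - _het_correction(pA, table.totals(A)[use], denom)
    return vals, use


def jackknife_se(values: np.ndarray, block_size: int) -> tuple[float, int]:
    """Delete-one block jackknife SE of the mean over consecutive blocks.

    Returns ``(se, n_blocks)``.  A trailing block shorter than ``block_size``
    merges into the last full block.
    """
    values = np.asarray(values, dtype=float)
    S = len(values)
    if block_size < 1:
        raise ValueError("block_size must be positive")
    edges = list(range(0, S, block_size))
    if len(edges) >= 2 and S - edges[-1] < block_size:
        edges.pop()  # merge the short tail into the previous block
    B = len(edges)
    if B < 2:
        raise ValueError("need at least two jackknife blocks")
    bounds = edges + [S]
    total = values.sum()
    est = []
    for b in range(B):
        lo, hi = bounds[b], bounds[b + 1]
        est.append((total - values[lo:hi].sum()) / (S - (hi - lo)))
    est = np.asarray(est)
    se = float(np.sqrt((B - 1) / B * np.sum((est - est.mean()) ** 2)))
    return se, B


def f3_hat(table: CountTable, A: str, B: str, C: str, block_size: int = 500,
           corrected: bool = True, denom: str = "n-1") -> F3Result:
    """f3(A; B, C) with block-jackknife SE and Z-score."""
    vals, use = f3_sites(table, A, B, C, corrected, denom)
    if len(vals) == 0:
        raise ValueError("no usable sites for f3")
    f3 = float(vals.mean())
    se, B = jackknife_se(vals, block_size)
    z = f3 / se if se > 0 else float("inf") * np.sign(f3 or 1)
    return F3Result(triplet=(A, B, C), f3=f3, se=se, z=float(z),
                    block_size=block_size, n_blocks=B, n_sites=len(vals))


def f3_all_triplets(table: CountTable, block_size: int = 500,
                    corrected: bool = True) -> pd.DataFrame:
    """f3 for every ordered triplet (A; B, C) with B < C, as a tidy table."""
    rows = []
    gs = table.groups
    for a in gs:
        others = [g for g in gs if g != a]
        for i, b in enumerate(others):
            for c in others[i + 1:]:
                try:
                    rows.append(f3_hat(table, a, b, c, block_size, corrected).as_row())
                except ValueError:
                    continue
    return pd.DataFrame(rows)
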