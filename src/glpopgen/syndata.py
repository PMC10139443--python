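"""Coalescent synthetic data: demographic models, haplotypes, and read pileups.

The generator emulates the shape of a low-coverage resequencing study of a
three-population system — a deep split of a "North" deme from the ancestor of
"Andes" and "Central", with per-population size histories that are constant,
exponentially growing, or instantaneously resized — plus optional migration
and an optional admixed deme.  Downstream modules (genotype likelihoods, SFS,
selection scans, F-statistics, demographic fitting, LD) all consume its
output, so every stage of the pipeline is testable without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np

__all__ = [
    "DemographicModel",
    "AdmixtureSpec",
    "SimConfig",
    "HaplotypeSet",
    "ReadPileup",
    "simulate_genotypes",
    "simulate_reads",
    "sim_tree_replicates",
]

POPULATIONS = ("Andes", "Central", "North")
BASES = "ACGT"


class ModelValidationError(ValueError):
    """A demographic model violated one of its structural invariants."""


@dataclass
class AdmixtureSpec:
    """An admixed deme formed at ``time`` as ``alpha:1-alpha`` from two sources.

    The target deme exists from the present back to ``time`` with diploid size
    ``size``; looking backward its lineages move to ``sources[0]`` with
    probability ``alpha`` and to ``sources[1]`` otherwise.
    """

    target: str
    sources: tuple[str, str]
    alpha: float
    time: float
    size: float = 1000.0


@dataclass
class DemographicModel:
    """Three-population split model ((Andes, Central), North).

    Parameters
    ----------
    variant
        ``"constant"`` (sizes fixed since founding), ``"growth"`` (each leaf
        population grows exponentially at rate ``r[pop]`` toward its
        present-day size), or ``"resize"`` (each leaf population changes
        instantaneously from ``N_init[pop]`` to ``N_final[pop]`` at
        ``T_resize[pop]`` generations ago).
    N_anc
        Diploid size of the root population, and by default also of the
        intermediate (Andes, Central) ancestor; pass ``N_intermediate`` to
        decouple them.
    T_split_N, T_split_C
        Generations ago at which North diverged from the (Andes, Central)
        ancestor, and at which Central diverged from Andes.  Requires
        ``T_split_N > T_split_C > 0``.
    migration
        Optional symmetric per-generation migration fractions, keyed by
        unordered population pair.
    """

    variant: str
    N_anc: float
    T_split_N: float
    T_split_C: float
    N_final: dict[str, float]
    r: dict[str, float] = field(default_factory=dict)
    N_init: dict[str, float] = field(default_factory=dict)
    T_resize: dict[str, float] = field(default_factory=dict)
    N_intermediate: float | None = None
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    admixture: AdmixtureSpec | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def founding_time(self, pop: str) -> float:
        return self.T_split_N if pop == "North" else self.T_split_C

    def validate(self) -> None:
        if self.variant not in ("constant", "growth", "resize"):
            raise ModelValidationError(f"unknown variant {self.variant!r}")
        if not (self.T_split_N > self.T_split_C > 0):
            raise ModelValidationError(
                "require T_split_N > T_split_C > 0; got "
                f"T_split_N={self.T_split_N}, T_split_C={self.T_split_C}"
            )
        sizes = [self.N_anc, *self.N_final.values(), *self.N_init.values()]
        if self.N_intermediate is not None:
            sizes.append(self.N_intermediate)
        if any(not np.isfinite(s) or s <= 0 for s in sizes):
            raise ModelValidationError("all population sizes must be positive")
        missing = [p for p in POPULATIONS if p not in self.N_final]
        if missing:
            raise ModelValidationError(f"N_final missing populations {missing}")
        if self.variant == "growth" and set(self.r) != set(POPULATIONS):
            raise ModelValidationError("growth variant needs r for every population")
        if self.variant == "resize":
            if set(self.N_init) != set(POPULATIONS) or set(self.T_resize) != set(POPULATIONS):
                raise ModelValidationError(
                    "resize variant needs N_init and T_resize for every population"
                )
            for pop in POPULATIONS:
                if not (0 < self.T_resize[pop] < self.founding_time(pop)):
                    raise ModelValidationError(
                        f"T_resize[{pop}]={self.T_resize[pop]} must lie strictly "
                        f"inside (0, founding time {self.founding_time(pop)})"
                    )
        if self.admixture is not None:
            a = self.admixture
            if not (0.0 <= a.alpha <= 1.0):
                raise ModelValidationError("admixture proportion must be in [0, 1]")
            if a.time <= 0 or a.time >= self.T_split_C:
                raise ModelValidationError(
                    "admixture time must fall after the most recent split"
                )
            if len(a.sources) != 2 or a.target in POPULATIONS:
                raise ModelValidationError("admixture needs a new target and 2 sources")
        for (p, q), m in self.migration.items():
            if m < 0:
                raise ModelValidationError(f"negative migration rate for {(p, q)}")

    # -- engine translation ----------------------------------------------
    def to_msprime(self) -> msprime.Demography:
        """Translate to an msprime ``Demography`` (backward-time events)."""
        dem = msprime.Demography()
        for pop in POPULATIONS:
            if self.variant == "growth":
                dem.add_population(
                    name=pop, initial_size=self.N_final[pop], growth_rate=self.r[pop]
                )
            else:
                dem.add_population(name=pop, initial_size=self.N_final[pop])
        n_mid = self.N_anc if self.N_intermediate is None else self.N_intermediate
        dem.add_population(name="AC", initial_size=n_mid)
        dem.add_population(name="ANC", initial_size=self.N_anc)
        if self.admixture is not None:
            a = self.admixture
            dem.add_population(name=a.target, initial_size=a.size)
        if self.variant == "resize":
            for pop in POPULATIONS:
                dem.add_population_parameters_change(
                    time=self.T_resize[pop], population=pop,
                    initial_size=self.N_init[pop],
                )
        if self.admixture is not None:
            a = self.admixture
            dem.add_admixture(
                time=a.time, derived=a.target, ancestral=list(a.sources),
                proportions=[a.alpha, 1.0 - a.alpha],
            )
        dem.add_population_split(
            time=self.T_split_C, derived=["Andes", "Central"], ancestral="AC"
        )
        dem.add_population_split(
            time=self.T_split_N, derived=["AC", "North"], ancestral="ANC"
        )
        for (p, q), m in self.migration.items():
            dem.set_symmetric_migration_rate([p, q], m)
        dem.sort_events()
        return dem

    def replace(self, **kw) -> "DemographicModel":
        return dataclasses.replace(self, **kw)


@dataclass
class SimConfig:
    """Sampling and genome settings for a simulation run.

    ``mu`` and ``recomb`` are per-bp per-generation rates.  The default
    recombination rate follows the 2.97 cM/Mb = 2.97e-8 crossovers/bp reading
    of moth linkage-map estimates; recombination defaults are only exercised
    by LD analyses, SFS-only runs may set it to 0.
    """

    samples: dict[str, int]
    L: float = 1_000_000
    mu: float = 2.9e-9
    recomb: float = 0.0
    seed: int = 1
    num_replicates: int = 1

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("sequence length must be >= 1 bp")
        if self.mu < 0 or self.recomb < 0:
            raise ValueError("rates must be non-negative")
        if not self.samples or any(n < 1 for n in self.samples.values()):
            raise ValueError("need >= 1 diploid sample in each sampled population")


@dataclass
class HaplotypeSet:
    """Biallelic segregating sites with their binary haplotypes.

    ``matrix`` is sites x haplotypes (two consecutive haplotypes per diploid,
    0 = ancestral, 1 = derived); ``positions`` are 0-based bp, strictly
    increasing; ``anc_base``/``der_base`` give the simulated nucleotides.
    """

    positions: np.ndarray
    matrix: np.ndarray
    pop_labels: np.ndarray  # one label per haplotype
    anc_base: np.ndarray
    der_base: np.ndarray
    contig: str = "contig1"
    L: float = 0.0

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_haplotypes(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_individuals(self) -> int:
        return self.n_haplotypes // 2

    def individual_pops(self) -> np.ndarray:
        return self.pop_labels[::2]

    def diploid_genotypes(self) -> np.ndarray:
        """Derived-allele dosage per site x individual (0/1/2)."""
        return self.matrix[:, ::2] + self.matrix[:, 1::2]


@dataclass
class ReadPileup:
    """Per-site, per-individual counts of the four bases.

    ``counts`` has shape (sites, individuals, 4) in A,C,G,T order.
    """

    counts: np.ndarray
    mean_depth: float
    epsilon: float
    positions: np.ndarray
    anc_base: np.ndarray
    der_base: np.ndarray
    contig: str = "contig1"

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)


def _samples_of(model: DemographicModel, config: SimConfig) -> dict[str, int]:
    known = set(POPULATIONS) | ({model.admixture.target} if model.admixture else set())
    unknown = set(config.samples) - known
    if unknown:
        raise ModelValidationError(f"samples requested from unknown demes {unknown}")
    return dict(config.samples)


def _extract_haplotypes(ts, pop_order: list[str], rng: np.random.Generator,
                        contig: str, L: float) -> HaplotypeSet:
    pop_name = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
    node_pop = np.array([ts.node(u).population for u in ts.samples()])
    labels = np.array([pop_name[p] for p in node_pop])
    keep, positions, genos = [], [], []
    for var in ts.variants():
        g = var.genotypes
        if len(var.alleles) != 2:
            continue  # recurrent mutation made the site multi-allelic
        if not (0 < g.sum() < len(g)):
            continue
        positions.append(int(var.site.position))
        genos.append(g.astype(np.int8))
    if positions:
        pos = np.asarray(positions)
        mat = np.asarray(genos)
        # discrete genome: collapse ties so positions are strictly increasing
        uniq, first = np.unique(pos, return_index=True)
        pos, mat = pos[np.sort(first)], mat[np.sort(first)]
    else:
        pos = np.empty(0, dtype=int)
        mat = np.empty((0, len(labels)), dtype=np.int8)
    anc = rng.integers(0, 4, size=len(pos))
    der = (anc + rng.integers(1, 4, size=len(pos))) % 4
    return HaplotypeSet(
        positions=pos, matrix=mat, pop_labels=labels,
        anc_base=np.array(list(BASES))[anc], der_base=np.array(list(BASES))[der],
        contig=contig, L=L,
    )


def simulate_genotypes(
    model: DemographicModel, config: SimConfig
) -> HaplotypeSet | list[HaplotypeSet]:
    """Draw haplotypes from the coalescent under ``model``.

    Returns one :class:`HaplotypeSet` (or a list when
    ``config.num_replicates > 1``).  Deterministic given
    ``(model, config, config.seed)``.
    """
    model.validate()
    samples = _samples_of(model, config)
    dem = model.to_msprime()
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=config.L,
        recombination_rate=config.recomb, random_seed=config.seed,
        num_replicates=config.num_replicates,
    )
    out = []
    pop_order = list(samples)
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=config.mu, random_seed=config.seed + 7_654_321 + i,
            model=msprime.BinaryMutationModel(),
        )
        rng = np.random.default_rng(config.seed + 31 * i + 5)
        out.append(_extract_haplotypes(mts, pop_order, rng, f"contig{i + 1}", config.L))
    return out[0] if config.num_replicates == 1 else out


def sim_tree_replicates(model: DemographicModel, samples: dict[str, int],
                        n_reps: int, seed: int):
    """Yield independent single-locus tree sequences (no mutations).

    Used for branch-length-based expected SFS computations; common random
    numbers are realized by deriving the replicate seed stream from ``seed``.
    """
    model.validate()
    dem = model.to_msprime()
    return msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=1,
        random_seed=seed, num_replicates=n_reps,
    )


def simulate_reads(
    haps: HaplotypeSet, mean_depth: float, epsilon: float, seed: int
) -> ReadPileup:
    """Simulate a Poisson-depth pileup with uniform base-error ``epsilon``.

    Per site and individual the read depth is Poisson(``mean_depth``); each
    read picks one of the individual's two alleles uniformly and is miscalled
    to one of the other three bases with probability ``epsilon``.
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must lie in [0, 1)")
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    rng = np.random.default_rng(seed)
    S, H = haps.matrix.shape
    N = H // 2
    base_idx = {b: i for i, b in enumerate(BASES)}
    anc_i = np.array([base_idx[b] for b in haps.anc_base], dtype=np.int64)
    der_i = np.array([base_idx[b] for b in haps.der_base], dtype=np.int64)

    depth = rng.poisson(mean_depth, size=(S, N))
    # reads drawn from haplotype 1 vs haplotype 2 of each individual
    from_h1 = rng.binomial(depth, 0.5)
    from_h2 = depth - from_h1
    counts = np.zeros((S, N, 4), dtype=np.int32)
    alle = np.stack([haps.matrix[:, ::2], haps.matrix[:, 1::2]])  # (2, S, N)
    for h, nreads in ((0, from_h1), (1, from_h2)):
        true_base = np.where(alle[h] == 1, der_i[:, None], anc_i[:, None])  # (S, N)
        correct = rng.binomial(nreads, 1.0 - epsilon)
        wrong = nreads - correct
        np.add.at(
            counts.reshape(-1, 4),
            (np.arange(S * N), true_base.ravel()),
            correct.ravel(),
        )
        if epsilon > 0:
            err = rng.multinomial(wrong.ravel(), [1 / 3] * 3)  # (S*N, 3)
            other = (true_base.ravel()[:, None] + np.array([1, 2, 3])) % 4
            np.add.at(
                counts.reshape(-1, 4),
                (np.repeat(np.arange(S * N), 3), other.ravel()),
                err.ravel(),
            )
    return ReadPileup(
        counts=counts, mean_depth=mean_depth, epsilon=epsilon,
        positions=haps.positions, anc_base=haps.anc_base, der_base=haps.der_base,
        contig=haps.contig,
    )
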