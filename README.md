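# glpopgen

Population genomics from genotype likelihoods, for low-coverage
whole-genome resequencing studies — with a built-in coalescent data
generator so every stage can be exercised and tested without any external
data.

Low-coverage designs (1–17x per individual) make hard genotype calls
unreliable; the estimators here therefore work directly on per-site
genotype-likelihood triples P(reads | g), g ∈ {0, 1, 2} copies of an
allele, and propagate that uncertainty through every downstream statistic.
The package covers the full analysis arc of a three-population divergence
and selection study:

* **syndata** — coalescent simulation (msprime underneath) of the
  three-deme topology ((Andes, Central), North) with constant /
  exponential-growth / instantaneous-resize size histories, optional
  migration and an admixed deme; Poisson-depth read pileups with a uniform
  base-error rate.
* **genolik** — genotype likelihoods from pileups; minor-allele-frequency
  EM; likelihood-ratio SNP test; inbreeding-aware genotype calling at a
  posterior confidence cutoff; distance pruning and missingness filters.
* **sfs** — site-allele-frequency (SAF) likelihood vectors P(D | j derived
  of 2n) by exact dynamic programming, and EM estimation of folded or
  unfolded 1D and joint 2D site-frequency spectra.
* **popstats** — posterior per-site pi and Watterson's theta under an SFS
  prior, Tajima's D, Hudson/Bhatia Fst as weighted ratio-of-sums
  `sum(alpha)/sum(beta)`, and the population branch statistic
  `PBS_A = (T_AB + T_AC - T_BC)/2`, `T = -ln(1 - Fst)`, in sliding windows
  with genome-wide top-fraction flagging.
* **structure** — per-individual inbreeding coefficients, PCA on posterior
  dosages with iterated individual allele frequencies, and admixture
  proportions (Q, cluster frequencies) by EM with seeded restarts.
* **fstats** — allele-count tables from called genotypes, f2/f3 drift
  statistics with delete-one block-jackknife standard errors; a
  significantly negative f3(A; B, C) (Z ≤ −3) flags A as admixed.
* **demography** — composite-likelihood fitting of the three-population
  models to folded pairwise 2D spectra, with expected spectra obtained from
  branch-length simulation under common random numbers, seeded restarts,
  and a parametric bootstrap (`SFSDemography(...).fit()` returns a results
  object with `summary()` and `conf_int()`).
* **ldscan** — two-locus r² from genotype likelihoods by haplotype-frequency
  EM, and LD-decay fitting `r²(d) = r²_min + (r²_max − r²_min)·exp(−λd)`
  with pair-bootstrap intervals, plus the decay-rate model-fit check.
* **pipeline / cli** — a configurable end-to-end runner
  (`glpopgen run-all --seed 5 --out run/`) producing plain-text artifacts
  (BEAGLE-GL, VCF, SFS tables, window TSVs, allele-count tables) and a
  checksummed manifest.

## Worked example: detecting admixture with f3

Simulate three diverged demes plus a deme formed 50 generations ago as a
50/50 mixture of "Central" and "North", call genotypes from truth, build an
allele-count table, and test the mixed deme:

```python
import numpy as np
from glpopgen.syndata import (AdmixtureSpec, DemographicModel, SimConfig,
                              simulate_genotypes)
from glpopgen.fstats import CountTable, f3_hat

model = DemographicModel(
    variant="constant", N_anc=5000, T_split_N=6000, T_split_C=1500,
    N_final={"Andes": 3000, "Central": 3000, "North": 3000},
    admixture=AdmixtureSpec(target="Mix", sources=("Central", "North"),
                            alpha=0.5, time=50, size=3000),
)
cfg = SimConfig(samples={"Andes": 6, "Central": 6, "North": 6, "Mix": 6},
                L=20_000, mu=1e-7, seed=11, num_replicates=60)
tables = [CountTable.from_genotypes(h.diploid_genotypes(), h.individual_pops())
          for h in simulate_genotypes(model, cfg) if h.n_sites]
table = CountTable(groups=tables[0].groups,
                   allele1=np.concatenate([t.allele1 for t in tables]),
                   allele2=np.concatenate([t.allele2 for t in tables]))
res = f3_hat(table, "Mix", "Central", "North", block_size=200)
print(f"sites used: {res.n_sites}  blocks: {res.n_blocks}")
print(f"f3(Mix; Central, North) = {res.f3:.5f}  SE = {res.se:.5f}  Z = {res.z:.2f}")
print("admixture detected:", res.significant)
```

Output:

```
sites used: 14738  blocks: 73
f3(Mix; Central, North) = -0.02689  SE = 0.00203  Z = -13.27
admixture detected: True
```

The f3 statistic measures the covariance of the target's allele-frequency
offsets from the two sources; drift on the target's own branch pushes it
positive, admixture pulls it negative. Here the estimate is negative at 13
jackknife standard errors — unambiguous admixture, as simulated.

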