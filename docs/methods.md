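# Methods

This note records the models, estimators and numerical choices behind
glpopgen, and what the synthetic-data tests do and do not establish.

## The data model

The unit of input is the genotype-likelihood triple: for each site and
diploid individual, P(reads | g) for g ∈ {0, 1, 2} copies of one of the two
alleles, stored log10-scaled and max-normalized. Triples come from the
package's own read model — depth per site/individual is
Poisson(mean_depth); each read copies one of the individual's two alleles
uniformly and is miscalled to a specific other base with probability ε/3 —
so P(base | allele a) = 1−ε if base = a, ε/3 otherwise, and heterozygotes
average the two allele terms. Cells with zero reads are flat triples
flagged missing. Real-data mode reads the same triples from BEAGLE-GL
files; map/base-quality filtering has no synthetic analogue and is a
pass-through setting only.

## Synthetic data generator

`syndata` wraps msprime's backward-time coalescent. The demographic object
is the three-deme topology ((Andes, Central), North) with three size
histories: constant, exponential growth per leaf deme, or a single
instantaneous resize per leaf deme; optional symmetric migration and an
optional admixed deme (α : 1−α pulse at a set time). Natural parameter
counts are 6 / 9 / 12 (ancestral size, two split times, three final sizes,
plus growth rates or resize size/time pairs); the intermediate
(Andes, Central) ancestor defaults to the root size and can be decoupled.
Mutations use a binary model on a discrete genome; only biallelic
segregating sites are emitted, polarized ancestral/derived with random base
labels. Recombination defaults to 0 (SFS statistics do not need linkage)
and is switched on for LD analyses; the moth-scale default rate is
2.97e-8 crossovers/bp/generation (2.97 cM/Mb — the printed unit elsewhere
is self-inconsistent, and this reading is used throughout).

Desk-scale defaults emulate the shape, not the size, of a real study:
three diverged demes (ancestral size 5,000; splits 6,000 and 1,500
generations ago; final sizes 10,000 / 2,000 / 2,000), 4–8 diploids per
deme, mean depth ~8x, ε ≈ 0.005, and an inflated per-bp mutation rate
(1e-7) so that kilobase-scale simulations carry realistic site counts.
What passing tests show is that the estimators recover the generating
process under the stated noise model; what they cannot show is robustness
to alignment artifacts, mapping bias, indels, base-quality structure or
reference bias, none of which the generator produces.

## SAF and SFS estimation

The site-allele-frequency vector is P(D | j derived among 2n). With
exchangeable alleles (no inbreeding) it is computed exactly: convolve the
multiplicity-weighted triples (GL0, 2·GL1, GL2) across individuals and
divide entry j by C(2n, j); the tests verify this against exhaustive
enumeration of genotype configurations. With inbreeding coefficients
supplied, exchangeability fails and the vector is the product over
individuals of Σ_g GL_i(g)·P(g | j/2n, F_i) — an independent-draw
approximation using the clipped prior
(q²+pqF, 2pq(1−F), p²+pqF). Sites with missing individuals are computed
over the observed subset and mixed up to the common 2n through the
missing-at-random identity P(D | J of 2n) = Σ_j HG(j; 2n, J, 2m)·P(D | j of
2m); this replaces down-projection, which is not well-defined for
likelihood vectors without a prior.

Spectra maximize Σ_s log Σ_j φ_j SAF_s(j) over the simplex by EM
(non-decreasing objective, relative tolerance 1e-8, 400-iteration cap;
chunked accumulation for genome pieces). Folding happens only at
reporting: 1D by the minor allele; 2D by default by the pooled minor
(cell (i, j) merged with (2n1−i, 2n2−j), lexicographic tie-break at the
exact middle), with a per-population-minor convention behind a switch.

## Diversity, differentiation, selection

Per-site E[pi] and E[theta_W] are posterior means under the genome-wide SFS
prior. Tajima's D uses the classical constants; D is undefined (NaN) at
S = 0. Fst uses the Hudson/Bhatia per-site components
α = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1), β = p1(1−p2) + p2(1−p1)
with posterior-mean sample frequencies under the joint 2D prior (Reynolds
1983 behind a switch). Windows always use the weighted ratio-of-sums; a
negative window Fst is clamped to 0 before T = −ln(1−Fst) and Fst = 1
yields +inf T, excluded from ranking. PBS windows default to 5 kb / 500 bp
step; the data threshold counts sites carrying SAF data (switchable to
variable-only), and the top 0.1% is flagged per population over retained
finite windows. The identity PBS_A + PBS_B = T_AB holds to machine
precision and is asserted.

## Structure

Inbreeding F is estimated per individual by bounded 1-D likelihood
maximization over [−1, 1] (Brent); a mixture EM is only natural on [0, 1],
and the direct maximizer is verified against a grid oracle. PCA iterates
posterior-mean dosages, a rank-K SVD reconstruction of the standardized
matrix giving per-individual allele frequencies, and the covariance
C_ij = (1/S) Σ_s (E[g_is]−2p_s)(E[g_js]−2p_s)/(2p_s(1−p_s)); on certain
genotypes one pass reproduces the closed-form genotype covariance.
Admixture uses the standard expected-allele-count EM on
q_is = Σ_k Q_ik F_ks (monotone likelihood, Q rows renormalized each step),
five seeded restarts by default, clusters reported sorted by total mass.

## f-statistics

Sample frequencies come from called genotypes (mirroring a
genotype-call + allele-count pathway); per-site
f3(A; B, C) = (pA−pB)(pA−pC) − pA(1−pA)/(nA−1), averaged over usable
sites, with the heterozygosity-correction denominator (n vs n−1)
switchable. Standard errors are delete-one block jackknife over
consecutive 500-SNP blocks; a trailing partial block merges into the last
full block. Significance is Z ≤ −3. The identity
f3 = [f2(A,B)+f2(A,C)−f2(B,C)]/2 holds exactly with corrections disabled.

## Demographic inference

The estimator is a composite likelihood on the three folded pairwise 2D
spectra among the demes. Expected spectra are computed by simulating
independent single-locus genealogies and accumulating *branch-length*
allele-frequency spectra (the exact infinite-sites conditional expectation
given the trees — no mutational Monte-Carlo noise), under common random
numbers so the surface is deterministic per seed. Cells are treated as
independent Poisson counts with intensity θ_scale · E[branch length],
θ_scale = μ·L of the analyzed genome; this ties the spectra to an absolute
time scale (per-pair normalized multinomial likelihoods leave the overall
time/size scale unidentified — only branch drift ratios T/2N would be
pinned). Cells with observed count below 10 are excluded; intensities are
floored at half a count so that a finitely-simulated expected spectrum
cannot dominate the objective through single empty cells.

Maximization is Nelder-Mead on log parameters: a cheap global stage from a
validity-projected bounds-center start plus log-uniform restarts, fresh
simplex reruns from the incumbent (ridge escapes), then a polish stage on
a lower-variance surface. Invalid topologies (split order, resize times
outside their branch) score a large penalty, and restarts stuck entirely in
the penalty region are marked failed. The parametric bootstrap simulates
datasets at the MLE from a high-fidelity expected spectrum and refits with
the original settings; `conf_int` offers percentile intervals (the refit
distribution itself) and basic/pivotal intervals (2·MLE − quantiles),
which correct first-order estimator bias and are the right choice for
truth-coverage questions.

Desk-scale fitting conditions used by the tests and the acceptance script:
8 diploids per deme, θ_scale = 0.29 (100 Mb of sequence at
2.9e-9 /bp/generation), 300 genealogies per global-stage evaluation, 2,000
in the polish, 20,000 when simulating bootstrap data. Known limitation,
measured and deliberate: at these Monte-Carlo budgets the likelihood is
only resolved to a few hundred log-units, so near-optimum ridge points
(deep split time against outer-deme sizes) are not fully distinguished; the
optimizer's deterministic path then imparts a small common bias (point
estimates typically within ±8% of truth) that bootstrap refits share, and
the resulting 95% intervals — tight around a slightly displaced point —
undercover the generating truth for a subset of parameters. Split-time
*ordering* is robustly recovered. The same qualitative behavior (point
estimates outside parametric-bootstrap intervals for ancestral/final sizes)
is a recognized feature of SFS composite-likelihood fitting at full scale
as well.

## LD

Two-locus r² comes from the phase-unknown EM over four haplotype
frequencies with genotype uncertainty integrated through the likelihood
triples (random mating; 16 ordered haplotype-pair states); monomorphic
sites are skipped. Decay fitting bins pair r² by distance (default 100 bp
bins), fits r²(d) = r²_min + (r²_max − r²_min)e^{−λd} by least squares
weighted by √(pairs per bin), and bootstraps pairs for 95% percentile
intervals. The model-fit check compares each candidate model's median
simulated decay rate with the observed CI (closed interval), reporting the
distance otherwise and ranking models by |median − observed λ|. The
three-parameter exponential is this package's explicit, documented choice
of decay curve; a drift-expectation form is intentionally out of scope.

## Determinism and degenerate inputs

Every stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from one master seed and reruns are byte-identical. Degenerate
cases have defined behavior: zero reads → missing flat triple; S = 0 →
Tajima's D missing; monomorphic pair → r² undefined, pair skipped;
degenerate (lower = upper) fit bounds → the pinned point with its
likelihood; bootstrap reps = 0 → no-op.
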