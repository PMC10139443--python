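import pandas as pd
import pytest

from glpopgen.genolik import gl_matrix_from_pileup
from glpopgen.syndata import DemographicModel, SimConfig, simulate_genotypes, simulate_reads


def make_model(**kw):
    """Diverged three-population constant-size model at desk scale."""
    defaults = dict(
        variant="constant", N_anc=5000.0, T_split_N=6000.0, T_split_C=1500.0,
        N_final={"Andes": 10_000.0, "Central": 2_000.0, "North": 2_000.0},
    )
    defaults.update(kw)
    return DemographicModel(**defaults)


def panmictic_model(N=1000.0):
    """Splits collapsed to ~0 so all demes behave as one population of size N."""
    return DemographicModel(
        variant="constant", N_anc=N, T_split_N=2.0, T_split_C=1.0,
        N_final={"Andes": N, "Central": N, "North": N},
    )


def individuals_for(haps):
    pops = haps.individual_pops()
    return pd.DataFrame({
        "id": [f"{p}_{i}" for i, p in enumerate(pops)],
        "location": [f"{p}_loc" for p in pops],
        "region": pops,
    })


def simulate_gl_dataset(model, samples, L=100_000, mu=1e-7, depth=8.0,
                        eps=0.005, seed=11, polarize="major"):
    cfg = SimConfig(samples=samples, L=L, mu=mu, seed=seed)
    haps = simulate_genotypes(model, cfg)
    pileup = simulate_reads(haps, depth, eps, seed=seed + 1)
    glm = gl_matrix_from_pileup(pileup, haps, individuals_for(haps),
                                polarize=polarize)
    return haps, pileup, glm


def simulate_unlinked_gl(model, samples, n_loci, L=2000, mu=1e-7, depth=20.0,
                         eps=1e-3, seed=11, polarize="ancestral"):
    """Concatenated GL matrix over independent loci (one genealogy each)."""
    from glpopgen.genolik import GLMatrix

    cfg = SimConfig(samples=samples, L=L, mu=mu, seed=seed,
                    num_replicates=n_loci)
    reps = simulate_genotypes(model, cfg)
    inds = None
    parts = []
    for k, haps in enumerate(reps):
        if haps.n_sites == 0:
            continue
        if inds is None:
            inds = individuals_for(haps)
        pileup = simulate_reads(haps, depth, eps, seed=seed + 1000 + k)
        parts.append(gl_matrix_from_pileup(pileup, haps, inds,
                                           polarize=polarize))
    return GLMatrix.concat(parts)


@pytest.fixture(scope="session")
def three_pop_dataset():
    """Shared diverged dataset: 3 demes x 4 diploids, 100 kb at 8x."""
    model = make_model()
    haps, pileup, glm = simulate_gl_dataset(
        model, {"Andes": 4, "Central": 4, "North": 4}, seed=11)
    return {"model": model, "haps": haps, "pileup": pileup, "glm": glm}
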