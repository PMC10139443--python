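"""End-to-end orchestration: config validation, stage graph, manifest.

A run is fully reproducible from its config: every stage seed is derived
from the single top-level seed, outputs are plain text (TSV / VCF / BEAGLE /
SFS tables), and a manifest records each file with its producing stage,
sha256 checksum and the hash of the resolved config.  The stage graph is
syndata -> genolik -> {sfs -> popstats, structure, fstats, demography,
ldscan}; requesting a stage without its dependency is an error naming the
missing stage, and partially written outputs are removed on failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography as dem_mod
from . import fstats as fstats_mod
from . import io as io_mod
from . import ldscan as ld_mod
from . import popstats as ps_mod
from . import sfs as sfs_mod
from . import structure as st_mod
from .genolik import (SiteFilterConfig, call_genotypes,
                      gl_matrix_from_pileup, prune_and_filter, snp_filter)
from .syndata import (AdmixtureSpec, DemographicModel, SimConfig,
                      simulate_genotypes, simulate_reads)

__all__ = ["RunConfig", "run_pipeline", "STAGES", "STAGE_DEPS"]

log = logging.getLogger("glpopgen")

STAGES = ("syndata", "genolik", "sfs", "popstats", "structure", "fstats",
          "demography", "ldscan")
STAGE_DEPS = {
    "syndata": (),
    "genolik": ("syndata",),
    "sfs": ("genolik",),
    "popstats": ("sfs",),
    "structure": ("genolik",),
    "fstats": ("genolik",),
    "demography": ("sfs",),
    "ldscan": ("genolik",),
}

_KNOWN_KEYS = {
    "stages", "seed", "out_dir", "model", "sim", "reads", "filters",
    "windows", "pbs", "demography", "ld", "structure", "fstats",
}
_MODEL_KEYS = {"variant", "N_anc", "T_split_N", "T_split_C", "N_final", "r",
               "N_init", "T_resize", "N_intermediate", "migration", "admixture"}
_SIM_KEYS = {"samples", "L", "mu", "recomb", "num_replicates"}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: list[str]
    seed: int
    out_dir: str
    model: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    reads: dict = field(default_factory=lambda: {"mean_depth": 8.0, "epsilon": 0.005})
    filters: dict = field(default_factory=dict)
    windows: dict = field(default_factory=lambda: {"window": 20_000, "step": 20_000})
    pbs: dict = field(default_factory=lambda: {"window": 5_000, "step": 500,
                                               "min_data": 40, "top_fraction": 0.001})
    demography: dict = field(default_factory=lambda: {"variant": "constant",
                                                      "n_sims": 1000,
                                                      "n_restarts": 2,
                                                      "maxiter": 60,
                                                      "n_reruns": 0,
                                                      "polish_n_sims": 2000,
                                                      "polish_maxiter": 15})
    ld: dict = field(default_factory=lambda: {"max_dist": 10_000,
                                              "subsample": 0.10,
                                              "bin_size": 100, "n_boot": 20})
    structure: dict = field(default_factory=lambda: {"n_axes": 2, "K": 3})
    fstats: dict = field(default_factory=lambda: {"block_size": 500})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in (("model", _MODEL_KEYS), ("sim", _SIM_KEYS)):
            extra = set(raw.get(key, {})) - allowed
            if extra:
                raise ValueError(f"unknown {key} keys: {sorted(extra)}")
        cfg = cls(
            stages=list(raw.get("stages", list(STAGES))),
            seed=int(raw.get("seed", 1)),
            out_dir=str(raw.get("out_dir", "glpopgen_run")),
        )
        for key in ("model", "sim", "reads", "filters", "windows", "pbs",
                    "demography", "ld", "structure", "fstats"):
            if key in raw:
                getattr(cfg, key).update(raw[key])
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        for s in cfg.stages:
            missing = [d for d in STAGE_DEPS[s] if d not in cfg.stages]
            if missing:
                raise ValueError(
                    f"stage '{s}' requires stage '{missing[0]}' to be enabled"
                )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        return {
            "stages": self.stages, "seed": self.seed, "out_dir": self.out_dir,
            "model": self.model, "sim": self.sim, "reads": self.reads,
            "filters": self.filters, "windows": self.windows, "pbs": self.pbs,
            "demography": self.demography, "ld": self.ld,
            "structure": self.structure, "fstats": self.fstats,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _default_model(cfg: RunConfig) -> DemographicModel:
    m = dict(cfg.model)
    adm = m.pop("admixture", None)
    if adm is not None:
        adm = AdmixtureSpec(target=adm["target"],
                            sources=tuple(adm["sources"]),
                            alpha=float(adm["alpha"]), time=float(adm["time"]),
                            size=float(adm.get("size", 1000.0)))
    defaults = dict(variant="constant", N_anc=5000.0, T_split_N=6000.0,
                    T_split_C=1500.0,
                    N_final={"Andes": 10_000.0, "Central": 2_000.0,
                             "North": 2_000.0})
    defaults.update(m)
    return DemographicModel(admixture=adm, **defaults)


def _default_sim(cfg: RunConfig) -> SimConfig:
    s = dict(cfg.sim)
    s.setdefault("samples", {"Andes": 6, "Central": 6, "North": 6})
    s.setdefault("L", 200_000)
    s.setdefault("mu", 1e-7)
    s.setdefault("recomb", 0.0)
    return SimConfig(seed=cfg.seed, **s)


def _individuals_table(samples: dict[str, int]) -> pd.DataFrame:
    rows = []
    for pop, n in samples.items():
        for i in range(n):
            rows.append({"id": f"{pop}_{i}", "location": f"{pop}_loc",
                         "region": pop})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Writes a ``manifest.json`` listing every output with its stage and
    checksum plus the resolved config.  On failure, files created by this
    run are removed before the exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.resolved(), "config_hash": cfg.config_hash(),
                      "files": [], "stage_seconds": {}, "attrition": {}}
    created: list[Path] = []
    ctx: dict = {}

    def emit(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        created.append(path)
        manifest["files"].append({"file": name, "stage": stage,
                                  "sha256": _sha256(path)})

    try:
        for stage in [s for s in STAGES if s in cfg.stages]:
            t0 = time.time()
            _run_stage(stage, cfg, ctx, emit)
            manifest["stage_seconds"][stage] = round(time.time() - t0, 3)
            log.info("stage %s done in %.2fs", stage,
                     manifest["stage_seconds"][stage])
        manifest["attrition"] = ctx.get("attrition", {})
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n")
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
    return out


def _run_stage(stage: str, cfg: RunConfig, ctx: dict, emit) -> None:
    if stage == "syndata":
        model = _default_model(cfg)
        sim = _default_sim(cfg)
        haps = simulate_genotypes(model, sim)
        if isinstance(haps, list):
            haps = haps[0]
        pileup = simulate_reads(haps, float(cfg.reads.get("mean_depth", 8.0)),
                                float(cfg.reads.get("epsilon", 0.005)),
                                seed=cfg.seed + 11)
        ctx.update(model=model, sim=sim, haps=haps, pileup=pileup)
        truth = haps.diploid_genotypes()
        sites = pd.DataFrame({
            "contig": haps.contig, "pos": haps.positions,
            "major": haps.anc_base, "minor": haps.der_base, "ref": haps.anc_base,
        })
        ids = _individuals_table(sim.samples)["id"].tolist()
        emit(stage, "truth.vcf", lambda p: io_mod.write_vcf(
            p, sites, truth, ids, {haps.contig: int(haps.L)}))
        emit(stage, "haplotypes.tsv", lambda p: pd.DataFrame(
            haps.matrix, index=haps.positions).to_csv(p, sep="\t"))
    elif stage == "genolik":
        sim = ctx["sim"]
        inds = _individuals_table(sim.samples)
        glm = gl_matrix_from_pileup(ctx["pileup"], ctx["haps"], inds)
        fcfg = SiteFilterConfig(**cfg.filters)
        keep, p_hat = snp_filter(glm, fcfg)
        ctx["attrition"] = {"sites_in": glm.n_sites, "snp_maf_pass": len(keep)}
        glm_snp = glm.subset_sites(keep)
        F = st_mod.inbreeding_ml(glm_snp, p_hat)
        calls = call_genotypes(glm_snp, np.clip(p_hat, 1e-4, 1 - 1e-4), F)
        kept2 = prune_and_filter(glm_snp, calls, fcfg)
        ctx["attrition"]["prune_missing_pass"] = len(kept2)
        ctx.update(glm=glm, glm_snp=glm_snp, p_hat=p_hat, F=F, calls=calls,
                   kept=kept2, inds=inds)
        emit(stage, "genolik.beagle", lambda p: io_mod.write_beagle(glm_snp, p))
        emit(stage, "calls.vcf", lambda p: io_mod.write_vcf(
            p, glm_snp.sites, calls, inds["id"].tolist()))
        emit(stage, "inbreeding.tsv", lambda p: pd.DataFrame(
            {"id": inds["id"], "F": F}).to_csv(p, sep="\t", index=False))
    elif stage == "sfs":
        glm = ctx["glm"]  # SFS uses all sites, no SNP/MAF filtering
        lin = glm.linear()
        regions = list(dict.fromkeys(glm.individuals["region"]))
        safs, sfs1 = {}, {}
        for reg in regions:
            cols = glm.region_index(reg)
            saf = sfs_mod.saf_matrix(lin[:, cols], glm.missing[:, cols])
            safs[reg] = saf
            sfs1[reg] = sfs_mod.em_sfs_1d(saf, population=reg)
            emit(stage, f"sfs1d_{reg}.txt",
                 lambda p, r=reg: io_mod.write_sfs1d(sfs1[r], p))
        sfs2 = {}
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                sfs2[(r1, r2)] = sfs_mod.em_sfs_2d(
                    safs[r1], safs[r2], populations=(r1, r2))
                emit(stage, f"sfs2d_{r1}_{r2}.txt",
                     lambda p, k=(r1, r2): io_mod.write_sfs2d(sfs2[k], p))
        ctx.update(safs=safs, sfs1=sfs1, sfs2=sfs2, regions=regions)
    elif stage == "popstats":
        glm, haps = ctx["glm"], ctx["haps"]
        regions = ctx["regions"]
        pos = glm.sites["pos"].to_numpy()
        wcfg = cfg.windows
        theta_all = []
        for reg in regions:
            n_alleles = ctx["safs"][reg].shape[1] - 1
            e_pi, e_tw = ps_mod.site_thetas(ctx["safs"][reg],
                                            ctx["sfs1"][reg].counts)
            theta_all.append(ps_mod.theta_windows(
                pos, e_pi, e_tw, n_alleles, haps.L, contig=haps.contig,
                window=int(wcfg.get("window", 20_000)),
                step=int(wcfg.get("step", 20_000))).assign(region=reg))
        emit(stage, "theta_windows.tsv", lambda p: io_mod.write_windows(
            pd.concat(theta_all, ignore_index=True), p))
        # pairwise weighted Fst + PBS over the first three regions
        comps = {}
        for (r1, r2), s2 in ctx["sfs2"].items():
            p1, p2 = ps_mod.joint_posterior_freqs(
                ctx["safs"][r1], ctx["safs"][r2], s2.counts)
            n1 = ctx["safs"][r1].shape[1] - 1
            n2 = ctx["safs"][r2].shape[1] - 1
            comps[(r1, r2)] = ps_mod.fst_components(p1, p2, n1, n2)
        fst_rows = [{"pair": f"{r1}-{r2}",
                     "weighted_fst": ps_mod.weighted_fst(*ab)}
                    for (r1, r2), ab in comps.items()]
        emit(stage, "fst_global.tsv", lambda p: pd.DataFrame(fst_rows).to_csv(
            p, sep="\t", index=False))
        if len(regions) >= 3:
            A, B, C = regions[:3]
            pcfg = cfg.pbs
            scan = ps_mod.pbs_scan(
                pos, comps[(A, B)], comps[(A, C)], comps[(B, C)], haps.L,
                populations=(A, B, C), contig=haps.contig,
                window=int(pcfg.get("window", 5000)),
                step=int(pcfg.get("step", 500)),
                min_data=int(pcfg.get("min_data", 40)),
                top_fraction=float(pcfg.get("top_fraction", 0.001)))
            emit(stage, "pbs_windows.tsv",
                 lambda p: io_mod.write_windows(scan, p))
            ctx["pbs"] = scan
    elif stage == "structure":
        glm_snp = ctx["glm_snp"]
        inds = ctx["inds"]
        pca = st_mod.pca_gl(glm_snp, n_axes=int(cfg.structure.get("n_axes", 2)))
        adm = st_mod.admixture_em(glm_snp, K=int(cfg.structure.get("K", 3)),
                                  seed=cfg.seed + 17)
        coords = pd.DataFrame(pca.coordinates,
                              columns=[f"PC{i+1}" for i in
                                       range(pca.coordinates.shape[1])])
        coords.insert(0, "id", inds["id"])
        emit(stage, "pca_coords.tsv",
             lambda p: coords.to_csv(p, sep="\t", index=False))
        emit(stage, "pca_covariance.tsv", lambda p: pd.DataFrame(
            pca.covariance, index=inds["id"], columns=inds["id"]).to_csv(
                p, sep="\t"))
        qdf = pd.DataFrame(adm.Q, columns=[f"Q{k+1}" for k in
                                           range(adm.Q.shape[1])])
        qdf.insert(0, "id", inds["id"])
        emit(stage, "admixture_Q.tsv",
             lambda p: qdf.to_csv(p, sep="\t", index=False))
        ctx.update(pca=pca, admix=adm)
    elif stage == "fstats":
        glm_snp, calls, kept = ctx["glm_snp"], ctx["calls"], ctx["kept"]
        locs = ctx["inds"]["location"].to_numpy()
        table = fstats_mod.CountTable.from_genotypes(calls[kept], locs)
        emit(stage, "counts.treemix", lambda p: io_mod.write_counts(table, p))
        f3 = fstats_mod.f3_all_triplets(
            table, block_size=int(cfg.fstats.get("block_size", 500)))
        emit(stage, "f3.tsv", lambda p: f3.to_csv(p, sep="\t", index=False))
        ctx["f3"] = f3
    elif stage == "demography":
        dcfg = cfg.demography
        samples = {p: int(n) for p, n in ctx["sim"].samples.items()
                   if p in dem_mod.POPS}
        observed = {}
        for (r1, r2), s2 in ctx["sfs2"].items():
            if r1 in dem_mod.POPS and r2 in dem_mod.POPS:
                observed[(r1, r2)] = dem_mod._fold_and_mask(s2.counts)
        settings = dem_mod.FitSettings(
            n_sims=int(dcfg.get("n_sims", 1000)),
            n_restarts=int(dcfg.get("n_restarts", 2)),
            maxiter=int(dcfg.get("maxiter", 60)),
            n_reruns=int(dcfg.get("n_reruns", 0)),
            polish_n_sims=int(dcfg.get("polish_n_sims", 2000)),
            polish_maxiter=int(dcfg.get("polish_maxiter", 15)),
            min_count=float(dcfg.get("min_count", 10)))
        theta_scale = float(ctx["sim"].mu) * float(ctx["sim"].L)
        model = dem_mod.SFSDemography(observed, samples, theta_scale,
                                      variant=dcfg.get("variant", "constant"),
                                      settings=settings)
        res = model.fit(seed=cfg.seed + 23)
        reps = int(dcfg.get("bootstrap_reps", 0))
        if reps:
            res.parametric_bootstrap(reps=reps, seed=cfg.seed + 29)
        emit(stage, "demography_fit.txt",
             lambda p: Path(p).write_text(res.summary() + "\n"))
        emit(stage, "demography_params.tsv", lambda p: pd.Series(
            res.params).rename("estimate").to_csv(p, sep="\t"))
        ctx["demography"] = res
    elif stage == "ldscan":
        glm_snp = ctx["glm_snp"]
        lcfg = cfg.ld
        pairs = ld_mod.collect_pairs(
            glm_snp, max_dist=float(lcfg.get("max_dist", 10_000)),
            subsample=float(lcfg.get("subsample", 0.10)), seed=cfg.seed + 37)
        emit(stage, "ld_pairs.tsv",
             lambda p: pairs.to_csv(p, sep="\t", index=False))
        if len(pairs) >= 10:
            fit = ld_mod.fit_decay(pairs,
                                   bin_size=int(lcfg.get("bin_size", 100)),
                                   n_boot=int(lcfg.get("n_boot", 20)),
                                   seed=cfg.seed + 41)
            emit(stage, "ld_decay.tsv", lambda p: pd.DataFrame([{
                "decay_rate": fit.decay_rate, "r2_max": fit.r2_max,
                "r2_min": fit.r2_min,
                "decay_rate_lo": fit.ci["decay_rate"][0],
                "decay_rate_hi": fit.ci["decay_rate"][1],
                "n_pairs": fit.n_pairs}]).to_csv(p, sep="\t", index=False))
            ctx["ld_fit"] = fit
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
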