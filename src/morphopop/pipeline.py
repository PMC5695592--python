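"""End-to-end orchestration: simulate/load data, run the morphometric and
genetic stages, and write a reproducible report bundle.

Stage order mirrors the analysis flow the package implements:
standardize -> categorize -> MDI/PDI -> rank ANOVA / DFA -> trait tree,
then diversity -> F-statistics -> distances -> trees -> admixture
clustering / Evanno -> AMOVA -> demographic conversions.  One master seed
is configured; per-stage seeds are derived deterministically by hashing
the stage name, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

from . import __version__, cluster, io, morpho, popgen
from .simulate import SimDesign, default_design, simulate_genotypes, simulate_traits, write_provenance

log = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32(stage) mixed with the master seed."""
    return (zlib.crc32(stage.encode()) ^ (master * 2_654_435_761)) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "out"
    design: SimDesign | None = None           # None -> bundled default design
    genotypes_path: str | None = None         # GenAlEx CSV; overrides simulation
    traits_path: str | None = None            # trait TSV; overrides simulation
    characters: list[str] | None = None       # categorical-matrix character list
    run_morpho: bool = True
    run_genetics: bool = True
    run_clustering: bool = True
    run_amova: bool = True
    fst_boot: int = 1000
    tree_boot: int = 200
    amova_perm: int = 200
    k_min: int = 1
    k_max: int = 4
    mcmc_runs: int = 3
    mcmc_burn_in: int = 500
    mcmc_iter: int = 2000
    mu: float = 5e-4

    def validate(self) -> None:
        for p in (self.genotypes_path, self.traits_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest (also written
    to ``<outdir>/manifest.json``).  Any stage failure aborts with the stage
    name; outputs of completed stages are retained."""
    cfg.validate()
    out = Path(cfg.outdir)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    results: dict = {}

    def run_stage(name: str, fn):
        t0 = time.time()
        subdir = out / name
        subdir.mkdir(parents=True, exist_ok=True)
        try:
            outputs = fn(subdir) or []
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "elapsed_s": round(time.time() - t0, 3),
            "seed": stage_seed(cfg.seed, name),
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
            },
        }
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    # ---- data -------------------------------------------------------------
    def data_stage(subdir: Path):
        files = []
        if cfg.genotypes_path:
            results["genotypes"] = io.read_genalex(cfg.genotypes_path)
        if cfg.traits_path:
            results["traits"] = io.read_traits(cfg.traits_path)
        if "genotypes" not in results or "traits" not in results:
            design = cfg.design or default_design(seed=stage_seed(cfg.seed, "data"))
            design.seed = stage_seed(cfg.seed, "data")
            if "genotypes" not in results:
                results["genotypes"] = simulate_genotypes(design)
                io.write_genalex(results["genotypes"], subdir / "genotypes.csv")
                files.append(subdir / "genotypes.csv")
            if "traits" not in results:
                results["traits"] = simulate_traits(design, results["genotypes"])
                io.write_traits(results["traits"], subdir / "traits.tsv")
                files.append(subdir / "traits.tsv")
            write_provenance(design, subdir / "provenance.json")
            files.append(subdir / "provenance.json")
        io.write_structure(results["genotypes"], subdir / "genotypes.str")
        files.append(subdir / "genotypes.str")
        return files

    run_stage("data", data_stage)

    # ---- morphometrics ----------------------------------------------------
    if cfg.run_morpho:
        def morpho_stage(subdir: Path):
            t = results["traits"]
            std, params = morpho.standardize(t)
            results["traits_std"] = std
            cat = morpho.categorize(std, characters=cfg.characters)
            results["categorical"] = cat
            io.write_categorical(cat, subdir / "categorical.tsv")
            mdi_pop = morpho.mdi(cat, "population")
            mdi_pop.per_group.to_csv(subdir / "mdi_populations.tsv", sep="\t")
            mdi_mgmt = morpho.mdi(cat, t.management_labels())
            mdi_mgmt.per_group.to_csv(subdir / "mdi_management.tsv", sep="\t")
            pdi_m = morpho.pdi(cat, "population")
            io.write_phylip_dist(pdi_m, subdir / "pdi.dist")
            anova = morpho.kruskal_wallis(t, t.management_labels())
            anova.table.to_csv(subdir / "rank_anova.tsv", sep="\t")
            lda_res = morpho.lda(std, t.management_labels())
            lda_res.confusion.to_csv(subdir / "lda_confusion.tsv", sep="\t")
            lda_res.percent_correct.to_csv(subdir / "lda_percent_correct.tsv", sep="\t")
            tree = morpho.trait_cluster(std, "population")
            io.write_newick(tree, subdir / "trait_upgma.nwk")
            results["lda"] = lda_res
            results["mdi"] = mdi_pop
            return [
                subdir / n
                for n in (
                    "categorical.tsv", "mdi_populations.tsv", "mdi_management.tsv",
                    "pdi.dist", "rank_anova.tsv", "lda_confusion.tsv",
                    "lda_percent_correct.tsv", "trait_upgma.nwk",
                )
            ]

        run_stage("morpho", morpho_stage)

    # ---- population genetics ----------------------------------------------
    if cfg.run_genetics:
        def popgen_stage(subdir: Path):
            g = results["genotypes"]
            div = popgen.diversity(g)
            div.to_csv(subdir / "diversity.tsv", sep="\t")
            results["diversity"] = div
            seed = stage_seed(cfg.seed, "popgen")
            fst_plain = popgen.fst(g, correction="none", n_boot=cfg.fst_boot, seed=seed)
            fst_ena = popgen.fst(g, correction="ena", n_boot=cfg.fst_boot, seed=seed)
            results["fst"] = {"none": fst_plain, "ena": fst_ena}
            with open(subdir / "fst.json", "w") as fh:
                json.dump(
                    {
                        "uncorrected": {"theta": fst_plain.theta, "ci": fst_plain.ci},
                        "ena": {"theta": fst_ena.theta, "ci": fst_ena.ci},
                    },
                    fh, indent=1,
                )
            fis_s = popgen.fis(g)
            fis_s.to_csv(subdir / "fis.tsv", sep="\t")
            freqs = popgen.allele_frequencies(g, estimate_nulls=True)
            results["freqs"] = freqs
            nei = popgen.nei_distance(freqs)
            io.write_phylip_dist(nei, subdir / "nei_d.dist")
            dc = popgen.chord_distance(freqs, correction="ina")
            io.write_phylip_dist(dc, subdir / "chord_dc_ina.dist")
            results["nei"] = nei
            # demographic conversions from the SMM moment estimate of theta
            theta = {
                pop: popgen.theta_from_he_smm(div.loc[pop, "He"]) for pop in div.index
            }
            ne = {pop: popgen.ne_from_theta(t_, cfg.mu) for pop, t_ in theta.items()}
            with open(subdir / "demography.tsv", "w") as fh:
                fh.write("population\ttheta_smm\tNe\n")
                for pop in div.index:
                    fh.write(f"{pop}\t{theta[pop]:.6g}\t{ne[pop]:.6g}\n")
            return [
                subdir / n
                for n in ("diversity.tsv", "fst.json", "fis.tsv", "nei_d.dist",
                          "chord_dc_ina.dist", "demography.tsv")
            ]

        run_stage("popgen", popgen_stage)

    # ---- clustering -------------------------------------------------------
    if cfg.run_clustering and cfg.run_genetics:
        def cluster_stage(subdir: Path):
            g = results["genotypes"]
            seed = stage_seed(cfg.seed, "cluster")
            tree = cluster.bootstrap_tree(
                g,
                lambda gg: popgen.nei_distance(popgen.allele_frequencies(gg)),
                n_boot=cfg.tree_boot,
                seed=seed,
            )
            io.write_newick(tree, subdir / "nei_upgma_boot.nwk")
            runs = []
            for k in range(cfg.k_min, cfg.k_max + 1):
                for rep in range(cfg.mcmc_runs):
                    runs.append(
                        cluster.admixture_mcmc(
                            g, K=k, burn_in=cfg.mcmc_burn_in, n_iter=cfg.mcmc_iter,
                            seed=seed + 1000 * k + rep, freq_model="correlated",
                        )
                    )
            results["admixture_runs"] = runs
            files = [subdir / "nei_upgma_boot.nwk"]
            try:
                ev = cluster.evanno(runs)
                ev.to_csv(subdir / "evanno.tsv", sep="\t")
                results["evanno"] = ev
                files.append(subdir / "evanno.tsv")
                best_k = ev.attrs["best_k_delta"] or ev.attrs["best_k_lnp"]
            except ValueError:
                best_k = cfg.k_max
            best_runs = [r for r in runs if r.K == best_k]
            aligned, _ = cluster.align_labels(best_runs)
            q_mean = sum(a.values for a in aligned) / len(aligned)
            qdf = aligned[0].copy()
            qdf.loc[:, :] = q_mean
            qdf.to_csv(subdir / f"q_matrix_K{best_k}.tsv", sep="\t")
            files.append(subdir / f"q_matrix_K{best_k}.tsv")
            return files

        run_stage("cluster", cluster_stage)

    # ---- AMOVA ------------------------------------------------------------
    if cfg.run_amova and cfg.run_genetics:
        def amova_stage(subdir: Path):
            g = results["genotypes"]
            seed = stage_seed(cfg.seed, "amova")
            res2 = cluster.amova(g, groups=None, n_perm=cfg.amova_perm, seed=seed)
            res2.table.to_csv(subdir / "amova_all_populations.tsv", sep="\t")
            files = [subdir / "amova_all_populations.tsv"]
            design = cfg.design or default_design()
            species = {p.name: p.species for p in design.populations}
            if all(pop in species for pop in g.populations):
                res3 = cluster.amova(
                    g, groups={p: species[p] for p in g.populations},
                    n_perm=cfg.amova_perm, seed=seed,
                )
                res3.table.to_csv(subdir / "amova_species.tsv", sep="\t")
                results["amova_species"] = res3
                files.append(subdir / "amova_species.tsv")
            results["amova"] = res2
            return files

        run_stage("amova", amova_stage)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["results"] = results
    return manifest
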