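"""End-to-end pipeline: simulate -> associate -> coexpress -> hotclust -> subtype.

All numeric thresholds live in :class:`PipelineConfig` (the literature
defaults are defaults, not constants), every stage derives its random
stream from the global seed via a fixed per-stage counter, and each stage
writes its outputs (with a done-marker carrying the config hash) before the
next starts, so a run can resume from any completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, coexpression, hotclusters, io, subtyping
from ._utils import stage_seed
from .simulate import (
    EffectSpec,
    ModuleSpec,
    SimulationConfig,
    SubgroupSpec,
    gene_names,
    simulate_all,
)


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The default synthetic study: 145 subjects, 24^3 grid, 200 genes x 5 SNPs.

    Four causal genes each drive one GMV sphere (beta = 1 per allele); the
    causal genes sit inside a 20-gene co-expression module planted in the
    (FC, stage 2) stratum; and the 72 cases split into three planted
    subgroups whose GMV-shift profiles over the four spheres point 120
    degrees apart (so correlation-distance clustering can both separate
    them and, when under-clustered, is forced to split one group), with
    positive-scale and negative-scale PANSS shifts for groups 1 and 2.
    """
    genes = gene_names(200)
    causal = [genes[10], genes[50], genes[120], genes[180]]
    centers = [(7, 7, 7), (7, 16, 16), (16, 7, 16), (16, 16, 7)]
    effects = [
        EffectSpec(gene=g, snp_index=0, center=c, radius=3.5, beta=1.0)
        for g, c in zip(causal, centers)
    ]
    module_genes = tuple(causal + [genes[i] for i in range(150, 166)])
    # three group-shift profiles at 120 degrees in a zero-sum 2-D subspace
    e1 = np.array([0.5, -0.5, 0.5, -0.5])
    e2 = np.array([0.5, 0.5, -0.5, -0.5])
    s = 1.2
    profiles = [
        s * (np.cos(th) * e1 + np.sin(th) * e2)
        for th in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
    ]
    subgroups = [
        SubgroupSpec(size=24, gmv_shifts=tuple(profiles[0]), panss_shifts={"P": 2}),
        SubgroupSpec(size=24, gmv_shifts=tuple(profiles[1]), panss_shifts={"N": 2}),
        SubgroupSpec(size=24, gmv_shifts=tuple(profiles[2]), panss_shifts={}),
    ]
    return SimulationConfig(
        n_cases=72,
        n_controls=73,
        n_genes=200,
        snps_per_gene=5,
        maf_range=(0.1, 0.4),
        ld_block_rho=0.3,
        grid_shape=(24, 24, 24),
        voxel_size_mm=1.5,
        effect_plan=effects,
        noise_sd=0.2,
        expr_module_plan=[ModuleSpec(genes=module_genes, region="FC", stage=2, rho=0.95)],
        subgroup_plan=subgroups,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """All pipeline knobs with their literature defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig = None  # default_study_config(seed) when None
    subject_min_call_rate: float = 0.97
    marker_max_missing: float = 0.05
    marker_min_maf: float = 0.05
    marker_hwe_alpha: float = 1e-6
    p_threshold: float = 1e-6
    record_p_max: float = 1e-4
    pcc_threshold: float = 0.8
    n_resamples: int = 10_000
    fwhm_mm: float = 8.0
    cluster_threshold: float = 0.2304
    connectivity: int = 18
    k_min: int = 2
    k_max: int = 10
    kmeans_replicates: int = 1000
    n_permutations: int = 10_000
    bonferroni_alpha: float = 0.05

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = default_study_config(self.seed)
        positive = [
            "p_threshold", "record_p_max", "pcc_threshold", "n_resamples", "fwhm_mm",
            "cluster_threshold", "kmeans_replicates", "n_permutations", "bonferroni_alpha",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pcc_threshold < 1:
            raise ValueError("pcc_threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        sim["effect_plan"] = [dataclasses.asdict(e) for e in self.simulation.effect_plan]
        sim["expr_module_plan"] = [dataclasses.asdict(m) for m in self.simulation.expr_module_plan]
        sim["subgroup_plan"] = [dataclasses.asdict(g) for g in self.simulation.subgroup_plan]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            sim["effect_plan"] = [
                EffectSpec(**{**e, "center": tuple(e["center"])}) for e in sim.get("effect_plan", [])
            ]
            sim["expr_module_plan"] = [
                ModuleSpec(**{**m, "genes": tuple(m["genes"])}) for m in sim.get("expr_module_plan", [])
            ]
            sim["subgroup_plan"] = [
                SubgroupSpec(
                    **{
                        **g,
                        "gmv_shifts": tuple(g["gmv_shifts"])
                        if not np.isscalar(g["gmv_shifts"])
                        else g["gmv_shifts"],
                    }
                )
                for g in sim.get("subgroup_plan", [])
            ]
            for key in ("maf_range", "grid_shape", "covariate_effects"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stage-by-stage executor with done-markers for resumability."""

    STAGES = ("simulate", "associate", "coexpress", "hotclust", "subtype")

    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.config = config
        self.resume = resume
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.timings: dict[str, float] = {}

    def _marker(self, stage: str) -> Path:
        return self.out / f".{stage}.done.json"

    def _stage_complete(self, stage: str) -> bool:
        marker = self._marker(stage)
        if not marker.exists():
            return False
        info = json.loads(marker.read_text())
        if info.get("config_hash") != self.config.config_hash():
            return False
        return all((self.out / f).exists() for f in info.get("outputs", []))

    def _finish(self, stage: str, outputs: list[Path]) -> None:
        rel = [str(p.relative_to(self.out)) for p in outputs]
        self._marker(stage).write_text(
            json.dumps({"config_hash": self.config.config_hash(), "outputs": rel}, indent=2)
        )

    # -- stages --------------------------------------------------------
    def run(self) -> dict:
        for stage in self.STAGES:
            t0 = time.perf_counter()
            fresh = not (self.resume and self._stage_complete(stage))
            getattr(self, f"_{stage}")(fresh)
            self.timings[stage] = time.perf_counter() - t0
        return self._write_manifest()

    def _simulate(self, fresh: bool) -> None:
        cfg = self.config
        out = self.out / "inputs"
        if fresh:
            study = simulate_all(cfg.simulation)
            out.mkdir(exist_ok=True)
            io.write_raw(study.genotypes, out / "genotypes.raw.tsv", out / "genotypes.annot.tsv")
            io.write_table(study.covariates, out / "covariates.tsv")
            io.write_gmv(study.gmv, out / "gmv")
            io.write_expression(study.expression, out / "expression.tsv", out / "expression_meta.tsv")
            io.write_table(study.panss, out / "panss.tsv")
            io.write_truth(study.truth, out / "truth", cfg.simulation.voxel_size_mm)
            io.write_mask_nifti(study.atlas, out / "atlas.nii", cfg.simulation.voxel_size_mm)
            pd.Series(study.atlas_names).rename("region").to_csv(out / "atlas_labels.tsv", sep="\t")
            self.state.update(
                genotypes=study.genotypes,
                covariates=study.covariates,
                gmv=study.gmv,
                truth=study.truth,
                expression=study.expression,
                panss=study.panss,
                atlas=study.atlas,
                atlas_names=study.atlas_names,
            )
            self._finish(
                "simulate",
                [out / "genotypes.raw.tsv", out / "covariates.tsv", out / "gmv" / "gmv_manifest.tsv",
                 out / "expression.tsv", out / "panss.tsv", out / "truth" / "ground_truth.json",
                 out / "atlas.nii"],
            )
        else:
            self.state.update(
                genotypes=io.read_raw(out / "genotypes.raw.tsv", out / "genotypes.annot.tsv"),
                covariates=io.read_table(out / "covariates.tsv"),
                gmv=io.read_gmv(out / "gmv" / "gmv_manifest.tsv"),
                truth=io.read_truth(out / "truth" / "ground_truth.json"),
                expression=io.read_expression(out / "expression.tsv", out / "expression_meta.tsv"),
                panss=io.read_table(out / "panss.tsv"),
                atlas=io.read_nifti(out / "atlas.nii"),
                atlas_names=io.read_table(out / "atlas_labels.tsv")["region"].to_dict(),
            )

    def _associate(self, fresh: bool) -> None:
        from .genotypes import qc_markers, qc_subjects

        cfg = self.config
        out = self.out / "assoc"
        g = qc_subjects(self.state["genotypes"], cfg.subject_min_call_rate)
        g = qc_markers(
            g, cfg.marker_max_missing, cfg.marker_min_maf, cfg.marker_hwe_alpha
        )
        self.state["genotypes_qc"] = g
        if fresh:
            gmv = self.state["gmv"]
            cov = self.state["covariates"].loc[g.subject_ids]
            gmv_sub = association.GMVImageSet(
                volumes=gmv.volumes[[gmv.subject_ids.index(s) for s in g.subject_ids]],
                subject_ids=list(g.subject_ids),
                voxel_size_mm=gmv.voxel_size_mm,
                affine=gmv.affine,
            )
            res = association.snp_voxel_regression(
                g, gmv_sub, cov, keep_dense=False, record_p_max=cfg.record_p_max
            )
            res = association.select_candidates(res, cfg.p_threshold)
            out.mkdir(exist_ok=True)
            io.write_table(res.gene_table(), out / "gene_table.tsv")
            io.write_table(res.significant_pairs, out / "significant_pairs.tsv", index=False)
            pd.Series(sorted(res.candidate_genes), name="gene").to_csv(
                out / "candidate_genes.tsv", sep="\t", index=False
            )
            self.state["assoc"] = res
            self.state["significant_pairs"] = res.significant_pairs
            self.state["candidate_genes"] = set(res.candidate_genes)
            self._finish("associate", [out / "gene_table.tsv", out / "significant_pairs.tsv",
                                       out / "candidate_genes.tsv"])
        else:
            pairs = pd.read_csv(out / "significant_pairs.tsv", sep="\t")
            cands = pd.read_csv(out / "candidate_genes.tsv", sep="\t")["gene"]
            self.state["significant_pairs"] = pairs
            self.state["candidate_genes"] = set(cands)

    def _coexpress(self, fresh: bool) -> None:
        cfg = self.config
        out = self.out / "coexpress"
        if not fresh:
            self.state["coexpress_table"] = pd.read_csv(out / "interconnectedness.tsv", sep="\t")
            return
        expr = self.state["expression"]
        pool = list(expr.genes)
        candidates = sorted(self.state["candidate_genes"])
        rng_seed = stage_seed(cfg.seed, "coexpress")
        if len(candidates) < 2:
            table = pd.DataFrame(columns=["stratum", "threshold", "weighted", "observed", "p"])
        else:
            table = coexpression.stability_suite(
                expr,
                candidates,
                pool,
                thresholds=(cfg.pcc_threshold,),
                n_resamples=cfg.n_resamples,
                seed=np.random.default_rng(rng_seed),
                modes=(True,),
            )
        out.mkdir(exist_ok=True)
        io.write_table(table, out / "interconnectedness.tsv", index=False)
        self.state["coexpress_table"] = table
        self._finish("coexpress", [out / "interconnectedness.tsv"])

    def _hotclust(self, fresh: bool) -> None:
        cfg = self.config
        out = self.out / "hotclust"
        pairs = self.state["significant_pairs"]
        g = self.state["genotypes_qc"]
        grid = self.state["gmv"].grid_shape
        wmap = hotclusters.raw_weights(pairs, grid, cfg.simulation.voxel_size_mm)
        wmap = hotclusters.ld_correct(wmap, pairs, g)
        wmap = hotclusters.smooth(wmap, cfg.fwhm_mm)
        clusters = hotclusters.extract_clusters(wmap, cfg.cluster_threshold, cfg.connectivity)
        clusters = hotclusters.annotate_clusters(
            clusters, pairs, g.snp_meta, self.state["atlas"], self.state["atlas_names"]
        )
        self.state["wmap"] = wmap
        self.state["clusters"] = clusters
        if fresh:
            out.mkdir(exist_ok=True)
            vx = cfg.simulation.voxel_size_mm
            io.write_map_nifti(wmap.raw, out / "weights_raw.nii", vx)
            io.write_map_nifti(wmap.corrected, out / "weights_corrected.nii", vx)
            io.write_map_nifti(wmap.smoothed, out / "weights_smoothed.nii", vx)
            label_map = np.zeros(grid, dtype=np.int16)
            for cl in clusters:
                label_map[tuple(cl.voxels.T)] = cl.rank
            io.write_mask_nifti(label_map, out / "cluster_labels.nii", vx)
            io.write_table(hotclusters.cluster_report(clusters), out / "cluster_report.tsv", index=False)
            self._finish("hotclust", [out / "cluster_report.tsv", out / "cluster_labels.nii"])

    def _subtype(self, fresh: bool) -> None:
        cfg = self.config
        out = self.out / "subtype"
        clusters = self.state["clusters"]
        if not clusters:
            out.mkdir(exist_ok=True)
            io.write_table(pd.DataFrame(), out / "labels.tsv")
            self._finish("subtype", [out / "labels.tsv"])
            return
        gmv = self.state["gmv"]
        panss = self.state["panss"]
        feat_all = subtyping.extract_hc_features(gmv, clusters)
        patients = [s for s in feat_all.index if s in set(panss.index)]
        feat = feat_all.loc[patients]
        sub_seed = stage_seed(cfg.seed, "subtype")
        child_kmeans, child_perm = sub_seed.spawn(2)
        result = subtyping.choose_k(
            feat,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_replicates=cfg.kmeans_replicates,
            seed=child_kmeans,
        )
        panss_full = subtyping.panss_subscales(panss.loc[patients])
        perm = subtyping.permutation_test_subscales(
            panss_full, result.labels, n_perm=cfg.n_permutations,
            seed=np.random.default_rng(child_perm),
        )
        gmv_tests = subtyping.hc_group_gmv_test(feat, result.labels, alpha=cfg.bonferroni_alpha)
        self.state["subtype"] = result
        self.state["perm"] = perm
        self.state["gmv_tests"] = gmv_tests
        if fresh:
            out.mkdir(exist_ok=True)
            io.write_table(result.labels.to_frame(), out / "labels.tsv")
            io.write_table(
                pd.Series(result.igp_by_k, name="mean_igp").rename_axis("K").to_frame(),
                out / "igp_by_k.tsv",
            )
            io.write_table(perm.group_means, out / "subscale_group_means.tsv")
            io.write_table(perm.group_p, out / "subscale_group_p.tsv")
            io.write_table(perm.pairwise, out / "subscale_pairwise.tsv", index=False)
            io.write_table(gmv_tests, out / "hc_group_tests.tsv", index=False)
            self._finish(
                "subtype",
                [out / "labels.tsv", out / "igp_by_k.tsv", out / "subscale_group_means.tsv",
                 out / "subscale_pairwise.tsv", out / "hc_group_tests.tsv"],
            )

    def _write_manifest(self) -> dict:
        files = sorted(
            p for p in self.out.rglob("*") if p.is_file() and not p.name.startswith(".")
            and p.name != "run_manifest.json"
        )
        manifest = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "outputs": {str(p.relative_to(self.out)): _sha256(p) for p in files},
        }
        (self.out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages in order and return the run manifest."""
    return PipelineRun(config, resume=resume).run()
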