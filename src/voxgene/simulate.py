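"""Synthetic study generator with planted, recoverable ground truth.

Emulates the inputs of a multi-scale imaging-genetics study of first-episode
schizophrenia: LD-blocked additive genotypes, per-subject grey-matter-volume
(GMV) images carrying planted SNP effects inside voxel spheres, brain
developmental expression with planted co-expressed modules in specific
(region, stage) strata, and 30-item PANSS symptom records with planted
subgroup shifts.  Every stage downstream of the generator can therefore be
tested against known truth without any external data.

Genotypes use a latent-Gaussian threshold copula: one latent factor per gene
block induces exchangeable correlation ``ld_block_rho`` between the block's
SNPs, and per-haplotype thresholding at each SNP's drawn minor-allele
frequency yields Hardy-Weinberg genotype frequencies marginally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("FC", "SC", "SM", "TP")
STAGES = (1, 2, 3)

PANSS_ITEMS = (
    [f"P{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"G{i}" for i in range(1, 17)]
)

ATLAS_REGION_NAMES = {
    1: "Frontal_L",
    2: "Frontal_R",
    3: "Parietal_L",
    4: "Parietal_R",
    5: "Temporal_L",
    6: "Temporal_R",
    7: "Occipital_L",
    8: "Occipital_R",
}


def gene_names(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


@dataclass(frozen=True)
class EffectSpec:
    """One planted SNP -> GMV effect inside a voxel sphere.

    ``center`` is in voxel indices, ``radius`` in voxels (radius 0 plants a
    single voxel), ``beta`` is the GMV change per minor allele.
    """

    gene: str
    snp_index: int
    center: tuple[int, int, int]
    radius: float
    beta: float


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expressed gene module confined to one (region, stage) stratum."""

    genes: tuple[str, ...]
    region: str
    stage: int
    rho: float

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage}; expected one of {STAGES}")
        if not 0 <= self.rho < 1:
            raise ValueError(f"within-module correlation must be in [0, 1), got {self.rho}")


@dataclass(frozen=True)
class SubgroupSpec:
    """One planted patient subgroup: its size, GMV shifts and symptom shifts.

    ``gmv_shifts`` is either a scalar applied inside every planted effect
    sphere or a sequence aligned with the effect plan.  ``panss_shifts`` maps
    an item block ("P", "N", "G") to an integer per-item shift.
    """

    size: int
    gmv_shifts: float | tuple[float, ...] = 0.0
    panss_shifts: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated study design: 72 cases + 73 controls, 1.5 mm
    voxels, and a desk-scale 24x24x24 grid with 200 genes x 5 SNPs in place
    of the full genome-wide panel and whole-brain grid.
    """

    n_cases: int = 72
    n_controls: int = 73
    n_genes: int = 200
    snps_per_gene: int = 5
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_block_rho: float = 0.3
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.5
    effect_plan: list[EffectSpec] = field(default_factory=list)
    covariate_effects: tuple[float, float, float] = (-0.003, 0.05, 0.0)  # age, sex, edu
    noise_sd: float = 0.2
    gmv_baseline: float = 1.0
    expr_module_plan: list[ModuleSpec] = field(default_factory=list)
    expr_samples_per_stratum: int = 30
    panss_item_sd: float = 2.0
    subgroup_plan: list[SubgroupSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_genes", "snps_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not abs(self.ld_block_rho) < 1:
            raise ValueError("|ld_block_rho| must be < 1")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        names = set(gene_names(self.n_genes))
        for eff in self.effect_plan:
            if eff.gene not in names:
                raise ValueError(f"effect gene {eff.gene!r} not in the gene universe")
            if not 0 <= eff.snp_index < self.snps_per_gene:
                raise ValueError(f"snp_index {eff.snp_index} outside 0..{self.snps_per_gene - 1}")
            for c, dim in zip(eff.center, self.grid_shape):
                if not (eff.radius <= c <= dim - 1 - eff.radius):
                    raise ValueError(
                        f"effect sphere at {eff.center} radius {eff.radius} "
                        f"does not fit inside grid {self.grid_shape}"
                    )
        for mod in self.expr_module_plan:
            missing = set(mod.genes) - names
            if missing:
                raise ValueError(f"module genes not in gene universe: {sorted(missing)}")
        if self.subgroup_plan:
            total = sum(g.size for g in self.subgroup_plan)
            if total != self.n_cases:
                raise ValueError(
                    f"subgroup sizes sum to {total}, expected n_cases={self.n_cases}"
                )
            for g in self.subgroup_plan:
                if not np.isscalar(g.gmv_shifts) and len(g.gmv_shifts) != len(self.effect_plan):
                    raise ValueError("per-sphere gmv_shifts must align with effect_plan")

    @property
    def case_ids(self) -> list[str]:
        return [f"case{i:03d}" for i in range(self.n_cases)]

    @property
    def control_ids(self) -> list[str]:
        return [f"ctrl{i:03d}" for i in range(self.n_controls)]

    @property
    def subject_ids(self) -> list[str]:
        return self.case_ids + self.control_ids


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    causal_snp_ids: set[str]
    causal_gene_ids: set[str]
    true_cluster_masks: list[np.ndarray]
    true_group_labels: pd.Series  # per-case group index, 1-based
    planted_modules: list[ModuleSpec]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # streams: 0 genotypes, 1 covariates, 2 gmv, 3 expression, 4 panss
    return np.random.default_rng(np.random.SeedSequence([config.seed, 0, stream]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig):
    """Draw subjects x SNPs additive genotype calls with per-gene LD blocks.

    Within a gene block the two haplotypes of every subject share a latent
    Gaussian factor with loading sqrt(ld_block_rho); thresholding each SNP's
    latent value at Phi^-1(MAF) yields Bernoulli(MAF) alleles, hence
    Hardy-Weinberg genotype frequencies at the drawn MAF, correlated within
    the block and independent across genes.
    """
    from .genotypes import GenotypeMatrix

    rng = _rng(config, 0)
    n = config.n_cases + config.n_controls
    m = config.snps_per_gene
    rho = config.ld_block_rho
    lo, hi = config.maf_range

    genes = gene_names(config.n_genes)
    calls = np.empty((n, config.n_genes * m), dtype=np.int8)
    meta_rows = []
    chrom_pos = {}
    for gi, gene in enumerate(genes):
        mafs = rng.uniform(lo, hi, size=m)
        thresh = stats.norm.ppf(mafs)
        alleles = np.zeros((n, m), dtype=np.int8)
        for _hap in range(2):
            u = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, m))
            z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps
            alleles += (z < thresh[None, :]).astype(np.int8)
        calls[:, gi * m : (gi + 1) * m] = alleles
        chrom = (gi % 22) + 1
        for k in range(m):
            pos = chrom_pos.get(chrom, 0) + 10_000
            chrom_pos[chrom] = pos
            meta_rows.append(
                {"snp": f"snp{gi * m + k:05d}", "gene": gene, "chrom": chrom, "pos": pos}
            )
    snp_meta = pd.DataFrame(meta_rows).set_index("snp")
    return GenotypeMatrix(calls=calls, snp_meta=snp_meta, subject_ids=list(config.subject_ids))


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age/sex/education covariates, identically distributed in cases and controls."""
    rng = _rng(config, 1)
    n = config.n_cases + config.n_controls
    df = pd.DataFrame(
        {
            "age": rng.uniform(16.0, 45.0, size=n),
            "sex": rng.integers(0, 2, size=n),
            "education": rng.uniform(6.0, 18.0, size=n),
            "is_case": [1] * config.n_cases + [0] * config.n_controls,
        },
        index=pd.Index(config.subject_ids, name="subject"),
    )
    return df


# ---------------------------------------------------------------------------
# grey matter volumes
# ---------------------------------------------------------------------------

def sphere_mask(grid_shape, center, radius) -> np.ndarray:
    """Boolean mask of voxels within Euclidean distance ``radius`` of center."""
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _snp_id_for(config: SimulationConfig, gene: str, snp_index: int) -> str:
    gi = gene_names(config.n_genes).index(gene)
    return f"snp{gi * config.snps_per_gene + snp_index:05d}"


def _group_labels(config: SimulationConfig) -> pd.Series:
    labels = np.ones(config.n_cases, dtype=int)
    if config.subgroup_plan:
        start = 0
        for gi, grp in enumerate(config.subgroup_plan, start=1):
            labels[start : start + grp.size] = gi
            start += grp.size
    return pd.Series(labels, index=pd.Index(config.case_ids, name="subject"), name="group")


def simulate_gmv(config: SimulationConfig, genotypes, covariates: pd.DataFrame):
    """Per-subject GMV volumes with planted additive SNP effects.

    GMV(subject, voxel) = baseline + sum of planted effects hitting the voxel
    (beta x minor-allele count) + covariate terms + subgroup shifts inside
    effect spheres (cases only) + N(0, noise_sd^2), floored at zero.
    Returns (GMVImageSet, GroundTruth); effect spheres must be disjoint so
    the truth masks partition cleanly.
    """
    from .association import GMVImageSet

    if list(genotypes.subject_ids) != list(covariates.index):
        raise ValueError("genotypes and covariates must cover the same subjects in order")
    rng = _rng(config, 2)
    n = len(genotypes.subject_ids)
    shape = tuple(config.grid_shape)

    masks = [sphere_mask(shape, e.center, e.radius) for e in config.effect_plan]
    occupancy = np.zeros(shape, dtype=int)
    for msk in masks:
        occupancy += msk
    if np.any(occupancy > 1):
        overlapping = [e.gene for e, msk in zip(config.effect_plan, masks) if msk[occupancy > 1].any()]
        raise ValueError(f"overlapping effect spheres (genes {sorted(set(overlapping))}); truth masks must be disjoint")

    vols = np.full((n,) + shape, config.gmv_baseline, dtype=float)
    a_age, a_sex, a_edu = config.covariate_effects
    cov_term = (
        a_age * covariates["age"].to_numpy()
        + a_sex * covariates["sex"].to_numpy()
        + a_edu * covariates["education"].to_numpy()
    )
    vols += cov_term[:, None, None, None]

    for eff, msk in zip(config.effect_plan, masks):
        snp_id = _snp_id_for(config, eff.gene, eff.snp_index)
        counts = genotypes.calls[:, genotypes.snp_meta.index.get_loc(snp_id)].astype(float)
        vols[:, msk] += eff.beta * counts[:, None]

    labels = _group_labels(config)
    if config.subgroup_plan and config.effect_plan:
        case_pos = {s: i for i, s in enumerate(genotypes.subject_ids)}
        for gi, grp in enumerate(config.subgroup_plan, start=1):
            shifts = (
                [float(grp.gmv_shifts)] * len(masks)
                if np.isscalar(grp.gmv_shifts)
                else [float(s) for s in grp.gmv_shifts]
            )
            rows = [case_pos[s] for s in labels.index[labels == gi]]
            for shift, msk in zip(shifts, masks):
                if shift:
                    for r in rows:
                        vols[r][msk] += shift

    if config.noise_sd > 0:
        vols += rng.normal(0.0, config.noise_sd, size=vols.shape)
    np.maximum(vols, 0.0, out=vols)

    truth = GroundTruth(
        causal_snp_ids={_snp_id_for(config, e.gene, e.snp_index) for e in config.effect_plan},
        causal_gene_ids={e.gene for e in config.effect_plan},
        true_cluster_masks=masks,
        true_group_labels=labels,
        planted_modules=list(config.expr_module_plan),
    )
    gmv = GMVImageSet(
        volumes=vols,
        subject_ids=list(genotypes.subject_ids),
        voxel_size_mm=config.voxel_size_mm,
    )
    return gmv, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig):
    """Gene x sample expression with planted modules in single strata.

    Samples are tagged with (region, stage) over the 4 x 3 developmental
    strata.  Inside its stratum a planted module's genes load on a shared
    factor with loading sqrt(rho) (pairwise correlation rho); everywhere else
    all genes are independent standard normals.
    """
    from .coexpression import ExpressionSet

    rng = _rng(config, 3)
    genes = gene_names(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    cols, meta_rows = [], []
    blocks = []
    for region in REGIONS:
        for stage in STAGES:
            k = config.expr_samples_per_stratum
            X = rng.standard_normal((config.n_genes, k))
            for mod in config.expr_module_plan:
                if mod.region == region and mod.stage == stage:
                    f = rng.standard_normal(k)
                    idx = [gene_pos[g] for g in mod.genes]
                    X[idx] = np.sqrt(mod.rho) * f[None, :] + np.sqrt(1 - mod.rho) * rng.standard_normal((len(idx), k))
            blocks.append(X)
            for i in range(k):
                sid = f"{region}_s{stage}_{i:02d}"
                cols.append(sid)
                meta_rows.append({"sample": sid, "region": region, "stage": stage})
    matrix = pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene"), columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionSet(matrix=matrix, sample_meta=meta)


# ---------------------------------------------------------------------------
# PANSS
# ---------------------------------------------------------------------------

_BLOCK_SLICES = {"P": slice(0, 7), "N": slice(7, 14), "G": slice(14, 30)}


def simulate_panss(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """30 integer PANSS items per case, clipped to the instrument's 1-7 range.

    Each item is 1 + round(|N(0, panss_item_sd)|) plus the planted per-item
    shift of the case's subgroup on the P/N/G block, then clipped.
    """
    rng = _rng(config, 4)
    labels = truth.true_group_labels
    n = len(labels)
    items = 1 + np.round(np.abs(rng.normal(0.0, config.panss_item_sd, size=(n, 30))))
    for gi, grp in enumerate(config.subgroup_plan, start=1):
        rows = np.flatnonzero(labels.to_numpy() == gi)
        for block, shift in grp.panss_shifts.items():
            if block not in _BLOCK_SLICES:
                raise ValueError(f"unknown PANSS block {block!r}; expected P, N or G")
            if 1 + shift >= 7:
                warnings.warn(
                    f"PANSS shift {shift} on block {block} forces all items to ceiling",
                    stacklevel=2,
                )
            items[np.ix_(rows, range(30)[_BLOCK_SLICES[block]])] += shift
    items = np.clip(items, 1, 7).astype(int)
    return pd.DataFrame(items, index=labels.index.copy(), columns=PANSS_ITEMS)


# ---------------------------------------------------------------------------
# atlas & bundle
# ---------------------------------------------------------------------------

def make_atlas(grid_shape) -> tuple[np.ndarray, dict[int, str]]:
    """Octant parcellation of the grid into 8 labelled regions (synthetic atlas)."""
    shape = tuple(grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    half = [s // 2 for s in shape]
    grids = np.indices(shape)
    octant = (
        (grids[0] >= half[0]).astype(int) * 4
        + (grids[1] >= half[1]).astype(int) * 2
        + (grids[2] >= half[2]).astype(int)
    )
    labels = (octant + 1).astype(np.int16)
    return labels, dict(ATLAS_REGION_NAMES)


@dataclass
class SimulatedStudy:
    """Bundle of all generated inputs plus the planted truth."""

    config: SimulationConfig
    genotypes: object
    covariates: pd.DataFrame
    gmv: object
    truth: GroundTruth
    expression: object
    panss: pd.DataFrame
    atlas: np.ndarray
    atlas_names: dict[int, str]


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator under the config's seed and bundle the outputs."""
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    gmv, truth = simulate_gmv(config, genotypes, covariates)
    expression = simulate_expression(config)
    panss = simulate_panss(config, truth)
    atlas, names = make_atlas(config.grid_shape)
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        covariates=covariates,
        gmv=gmv,
        truth=truth,
        expression=expression,
        panss=panss,
        atlas=atlas,
        atlas_names=names,
    )
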