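"""Hot-cluster (HC) extraction from significant SNP x voxel associations.

Each voxel is first weighted by the number of distinct SNPs significantly
associated with its GMV.  The raw count is then corrected for linkage
disequilibrium: within each chromosome the voxel's significant SNPs
contribute the Li-Ji effective number of independent tests computed from
the eigenvalues of their genotype correlation matrix (perfectly correlated
SNPs collapse to 1; independent SNPs count fully), and chromosomes add
independently.  The corrected map is smoothed with an isotropic Gaussian
kernel (FWHM 8 mm by default) and supra-threshold voxels are merged into
connected components ("voxels sharing at least one edge or side", i.e.
18-connectivity by default).  Clusters are ranked by their maximum voxel
weight and annotated with the genes of the SNPs driving them and the modal
atlas region they occupy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import fwhm_to_sigma
from .genotypes import MISSING, GenotypeMatrix

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class VoxelWeightMap:
    """Raw, LD-corrected and smoothed per-voxel SNP-count weights."""

    raw: np.ndarray
    voxel_size_mm: float = 1.5
    corrected: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    fwhm_mm: float | None = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 3:
            raise ValueError("weight maps are 3-D")
        if np.any(self.raw < 0) or not np.allclose(self.raw, np.round(self.raw)):
            raise ValueError("raw weights must be non-negative integer counts")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def final(self) -> np.ndarray:
        for m in (self.smoothed, self.corrected, self.raw):
            if m is not None:
                return m
        raise AssertionError("unreachable")


@dataclass
class HotCluster:
    """One connected supra-threshold component of the voxel weight map."""

    voxels: np.ndarray  # (size, 3) voxel indices
    max_weight: float
    rank: int
    associated_genes: set[str] = field(default_factory=set)
    atlas_label: str | None = None
    atlas_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    @property
    def name(self) -> str:
        return f"HC{self.rank}"

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def _pairs_table(sig_pairs) -> pd.DataFrame:
    """Normalize (SNP, voxel) pairs into a deduplicated DataFrame."""
    if isinstance(sig_pairs, pd.DataFrame):
        df = sig_pairs[["snp", "i", "j", "k"]].copy()
    else:
        df = pd.DataFrame(list(sig_pairs), columns=["snp", "i", "j", "k"])
    return df.drop_duplicates(["snp", "i", "j", "k"]).reset_index(drop=True)


def raw_weights(sig_pairs, grid_shape, voxel_size_mm: float = 1.5) -> VoxelWeightMap:
    """Count distinct significantly associated SNPs per voxel (set semantics)."""
    shape = tuple(grid_shape)
    raw = np.zeros(shape, dtype=float)
    df = _pairs_table(sig_pairs)
    if len(df):
        coords = df[["i", "j", "k"]].to_numpy(int)
        if coords.min() < 0 or np.any(coords >= np.array(shape)[None, :]):
            raise ValueError("voxel index outside the grid")
        counts = df.groupby(["i", "j", "k"])["snp"].nunique()
        idx = np.array(list(counts.index))
        raw[idx[:, 0], idx[:, 1], idx[:, 2]] = counts.to_numpy(float)
    return VoxelWeightMap(raw=raw, voxel_size_mm=voxel_size_mm)


def li_ji_meff(corr: np.ndarray) -> float:
    """Li-Ji effective number of independent tests from a correlation matrix.

    m_eff = sum over eigenvalues of [1(lambda >= 1) + (lambda - floor(lambda))];
    equals m for identity correlation and 1 for a perfectly correlated block.
    """
    lam = np.linalg.eigvalsh(np.asarray(corr, dtype=float))
    lam = np.clip(lam, 0.0, None)
    # snap to integers before flooring: f is discontinuous at integer
    # eigenvalues and rank-deficient blocks land epsilon below them
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) < 1e-9, near, lam)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def _genotype_corr(genotypes: GenotypeMatrix, snp_ids: tuple[str, ...]) -> np.ndarray | None:
    cols = genotypes.snp_meta.index.get_indexer(list(snp_ids))
    calls = genotypes.calls[:, cols].astype(float)
    complete = (calls != MISSING).all(axis=1)
    if complete.sum() < 2:
        return None
    X = calls[complete]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        # constant SNPs carry no LD information; treat as uncorrelated with the rest
        corr = np.eye(len(snp_ids))
        ok = sd > 0
        if ok.sum() >= 2:
            sub = np.corrcoef(X[:, ok].T)
            corr[np.ix_(ok, ok)] = sub
        return corr
    return np.corrcoef(X.T)


def ld_correct(wmap: VoxelWeightMap, sig_pairs, genotypes: GenotypeMatrix) -> VoxelWeightMap:
    """Replace each voxel's SNP count by the per-chromosome effective count.

    The voxel's significant SNPs are grouped by chromosome; each group
    contributes its Li-Ji effective number, and groups add.  SNPs on
    different chromosomes are never corrected against each other.  With
    fewer than 2 complete-call subjects the correction is skipped with a
    warning (corrected = raw).
    """
    df = _pairs_table(sig_pairs)
    corrected = np.zeros_like(wmap.raw)
    if not len(df):
        return replace(wmap, corrected=corrected)
    chrom = genotypes.snp_meta["chrom"]
    missing_snps = set(df["snp"]) - set(genotypes.snp_meta.index)
    if missing_snps:
        raise KeyError(f"SNPs absent from genotypes: {sorted(missing_snps)}")
    df = df.assign(chrom=df["snp"].map(chrom))
    cache: dict[tuple[str, ...], float] = {}
    skipped = False
    for (i, j, k), vox in df.groupby(["i", "j", "k"]):
        total = 0.0
        for _c, grp in vox.groupby("chrom"):
            snps = tuple(sorted(grp["snp"].unique()))
            if snps not in cache:
                if len(snps) == 1:
                    cache[snps] = 1.0
                else:
                    corr = _genotype_corr(genotypes, snps)
                    if corr is None:
                        skipped = True
                        cache[snps] = float(len(snps))
                    else:
                        cache[snps] = li_ji_meff(corr)
            total += cache[snps]
        corrected[i, j, k] = total
    if skipped:
        warnings.warn("fewer than 2 complete-call subjects for some SNP groups; LD correction skipped there", stacklevel=2)
    corrected = np.minimum(corrected, wmap.raw)
    return replace(wmap, corrected=corrected)


def smooth(wmap: VoxelWeightMap, fwhm_mm: float = 8.0) -> VoxelWeightMap:
    """Convolve the corrected map with an isotropic unit-sum Gaussian kernel.

    sigma (voxels) = FWHM / (2 sqrt(2 ln 2)) / voxel size; zero-padded
    boundaries, kernel truncated at 4 sigma.
    """
    sigma = fwhm_to_sigma(fwhm_mm, wmap.voxel_size_mm)
    src = wmap.corrected if wmap.corrected is not None else wmap.raw
    sm = ndimage.gaussian_filter(src, sigma=sigma, mode="constant", cval=0.0, truncate=4.0)
    return replace(wmap, smoothed=sm, fwhm_mm=fwhm_mm)


def extract_clusters(
    wmap: VoxelWeightMap,
    threshold: float = 0.2304,
    connectivity: int = 18,
) -> list[HotCluster]:
    """Partition strictly supra-threshold voxels into connected components.

    Components are ranked (HC1, HC2, ...) by decreasing maximum voxel
    weight.  ``threshold=None`` with ``percentile`` is handled by
    :func:`percentile_threshold`.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    m = wmap.final
    supra = m > threshold
    labels, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        clusters.append((float(m[labels == lab].max()), vox))
    clusters.sort(key=lambda c: (-c[0], c[1][0].tolist()))
    return [
        HotCluster(voxels=vox, max_weight=mw, rank=r)
        for r, (mw, vox) in enumerate(clusters, start=1)
    ]


def percentile_threshold(wmap: VoxelWeightMap, percentile: float = 99.5) -> float:
    """Data-driven alternative to the fixed cluster-forming threshold."""
    return float(np.percentile(wmap.final, percentile))


def annotate_clusters(
    clusters: list[HotCluster],
    sig_pairs,
    snp_meta: pd.DataFrame,
    atlas: np.ndarray,
    atlas_names: dict[int, str] | None = None,
) -> list[HotCluster]:
    """Attach gene sets and modal atlas region labels to each cluster.

    A gene is associated with a cluster when one of its SNPs has a
    significant voxel inside the cluster.  The atlas label is the modal
    region over the cluster's voxels, with the full label-fraction
    breakdown retained.
    """
    df = _pairs_table(sig_pairs).assign(gene=lambda d: d["snp"].map(snp_meta["gene"]))
    atlas = np.asarray(atlas)
    out = []
    for cl in clusters:
        if np.any(cl.voxels >= np.array(atlas.shape)[None, :]):
            raise ValueError("atlas grid does not cover the cluster voxels")
        vox_set = set(map(tuple, cl.voxels))
        in_cluster = [tuple(r) in vox_set for r in df[["i", "j", "k"]].to_numpy(int)]
        genes = set(df.loc[in_cluster, "gene"])
        labels = atlas[tuple(cl.voxels.T)]
        vals, counts = np.unique(labels, return_counts=True)
        fracs = {int(v): c / counts.sum() for v, c in zip(vals, counts)}
        if atlas_names:
            named = {atlas_names.get(v, str(v)): f for v, f in fracs.items()}
        else:
            named = {str(v): f for v, f in fracs.items()}
        modal = max(named.items(), key=lambda kv: (kv[1], kv[0]))[0]
        out.append(
            replace(cl, associated_genes=genes, atlas_label=modal, atlas_fractions=named)
        )
    return out


def cluster_report(clusters: list[HotCluster]) -> pd.DataFrame:
    """Tidy per-HC table: id, size, max weight, atlas region, associated genes."""
    return pd.DataFrame(
        [
            {
                "hc": cl.name,
                "size": cl.size,
                "max_weight": cl.max_weight,
                "atlas_region": cl.atlas_label,
                "genes": ";".join(sorted(cl.associated_genes)),
            }
            for cl in clusters
        ]
    )
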