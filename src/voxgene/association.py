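"""Mass-univariate SNP x voxel association screen on grey-matter volume.

For each SNP s and in-mask voxel v the model

    GMV_v = b0 + b1 * g_s + b2 * age + b3 * sex + b4 * education + e

is fit by ordinary least squares over the subjects with a non-missing call
at s, and b1's two-sided t-test P-value (df = n_used - 5) is recorded.  The
fit is computed exactly via Frisch-Waugh residualization: GMV and genotype
are both residualized on the covariate block, so the slope, its standard
error and the t statistic equal the full OLS ones while vectorizing over
all voxels (and over all complete-call SNPs) at once.

A gene becomes a candidate when at least one of its SNP x voxel tests falls
strictly below the screening threshold (1e-6 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

_SNP_CHUNK = 256


@dataclass
class GMVImageSet:
    """Per-subject 3-D grey-matter-volume maps on one shared grid."""

    volumes: np.ndarray  # (n_subjects, nx, ny, nz)
    subject_ids: list[str]
    voxel_size_mm: float = 1.5
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be (subjects, x, y, z)")
        if self.volumes.shape[0] != len(self.subject_ids):
            raise ValueError("one volume per subject required")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]


@dataclass
class AssociationResult:
    """Outputs of the SNP x voxel screen.

    ``recorded_pairs`` holds every test with P <= ``record_p_max`` so that
    candidate selection can be re-run at any threshold up to that cap even
    when the dense per-test arrays were not kept.
    """

    snp_ids: pd.Index
    snp_gene: pd.Series  # SNP id -> gene symbol
    voxel_coords: np.ndarray  # (V, 3) in-mask voxel indices
    grid_shape: tuple[int, int, int]
    min_p_per_snp: pd.Series
    recorded_pairs: pd.DataFrame  # snp, i, j, k, beta, t, p
    record_p_max: float
    n_tests: int
    dense: dict[str, np.ndarray] | None = None  # beta, t, p as (S, V)
    p_threshold: float | None = None
    significant_pairs: pd.DataFrame | None = None
    candidate_genes: set[str] = field(default_factory=set)

    @property
    def min_p_per_gene(self) -> pd.Series:
        return self.min_p_per_snp.groupby(self.snp_gene).min()

    def gene_table(self) -> pd.DataFrame:
        """Per-gene summary: best SNP, min P, and (if selected) significant voxel count."""
        best = self.min_p_per_snp.groupby(self.snp_gene).idxmin()
        out = pd.DataFrame({"best_snp": best, "min_p": self.min_p_per_gene})
        if self.significant_pairs is not None and len(self.significant_pairs):
            nv = (
                self.significant_pairs.assign(gene=lambda d: d["snp"].map(self.snp_gene))
                .groupby("gene")
                .apply(lambda d: d[["i", "j", "k"]].drop_duplicates().shape[0], include_groups=False)
            )
            out["n_sig_voxels"] = nv.reindex(out.index).fillna(0).astype(int)
        else:
            out["n_sig_voxels"] = 0
        out.index.name = "gene"
        return out


def _fwl_stats(g_resid, y_resid, yss, df):
    """Slope, t and two-sided p for residualized genotypes vs residualized GMV.

    g_resid: (S, n); y_resid unused beyond yss (V,) and the cross-product.
    Returns (S, V) arrays; SNPs with (numerically) zero genotype variance or
    non-positive df yield NaN.
    """
    gss = np.einsum("sn,sn->s", g_resid, g_resid)
    ok = gss > 1e-10 * g_resid.shape[1]
    safe_gss = np.where(ok, gss, np.nan)
    slope = (g_resid @ y_resid) / safe_gss[:, None]
    sse = np.maximum(yss[None, :] - slope**2 * safe_gss[:, None], 0.0)
    if df <= 0:
        nan = np.full_like(slope, np.nan)
        return slope, nan, nan
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / safe_gss[:, None])
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # exact fits: se == 0 -> |t| = inf -> p = 0
    p = np.where(np.isinf(t), 0.0, p)
    return slope, t, p


def _residualizer(C: np.ndarray):
    """Return a function projecting columns onto the orthocomplement of span(C)."""
    Q, _ = np.linalg.qr(C)

    def resid(M: np.ndarray) -> np.ndarray:
        return M - Q @ (Q.T @ M)

    return resid


def snp_voxel_regression(
    g: GenotypeMatrix,
    gmv: GMVImageSet,
    cov: pd.DataFrame,
    voxel_mask: np.ndarray | None = None,
    keep_dense: bool | None = None,
    record_p_max: float = 1e-4,
) -> AssociationResult:
    """Run the OLS screen for every SNP against every in-mask voxel.

    Subjects must be identically ordered across genotypes, volumes and
    covariates.  Subjects with a missing call at a SNP are dropped for that
    SNP's tests (per-test complete cases).  ``keep_dense=None`` keeps the
    full (S, V) beta/t/p arrays only when S*V <= 2e6.
    """
    if list(g.subject_ids) != list(gmv.subject_ids) or list(g.subject_ids) != list(cov.index):
        raise ValueError("subjects must align (same ids, same order) across genotypes, GMV and covariates")
    n = g.n_subjects
    shape = gmv.grid_shape
    if voxel_mask is None:
        voxel_mask = np.ones(shape, dtype=bool)
    voxel_mask = np.asarray(voxel_mask, dtype=bool)
    if voxel_mask.shape != shape:
        raise ValueError("voxel mask shape must match the GMV grid")
    coords = np.argwhere(voxel_mask)
    Y = gmv.volumes[:, voxel_mask]  # (n, V)
    V = Y.shape[1]
    S = g.n_snps
    if keep_dense is None:
        keep_dense = S * V <= 2_000_000

    C = np.column_stack(
        [np.ones(n), cov["age"].to_numpy(float), cov["sex"].to_numpy(float), cov["education"].to_numpy(float)]
    )
    calls = g.calls
    has_missing = (calls == MISSING).any(axis=0)
    df_full = n - 5

    resid_full = _residualizer(C)
    Yr = resid_full(Y)
    yss = np.einsum("nv,nv->v", Yr, Yr)  # (V,)

    min_p = np.full(S, np.nan)
    pair_frames: list[pd.DataFrame] = []
    dense = {"beta": np.empty((S, V)), "t": np.empty((S, V)), "p": np.empty((S, V))} if keep_dense else None

    def collect(rows, slope, t, p):
        rows = np.asarray(rows)
        finite = np.isfinite(p)
        masked = np.where(finite, p, np.inf)
        row_min = masked.min(axis=1)
        min_p[rows] = np.where(finite.any(axis=1), row_min, np.nan)
        hit_s, hit_v = np.where(p <= record_p_max)
        if hit_s.size:
            pair_frames.append(
                pd.DataFrame(
                    {
                        "snp": g.snp_ids[np.asarray(rows)[hit_s]],
                        "i": coords[hit_v, 0],
                        "j": coords[hit_v, 1],
                        "k": coords[hit_v, 2],
                        "beta": slope[hit_s, hit_v],
                        "t": t[hit_s, hit_v],
                        "p": p[hit_s, hit_v],
                    }
                )
            )
        if dense is not None:
            dense["beta"][rows], dense["t"][rows], dense["p"][rows] = slope, t, p

    complete = np.flatnonzero(~has_missing)
    for start in range(0, complete.size, _SNP_CHUNK):
        rows = complete[start : start + _SNP_CHUNK]
        G = calls[:, rows].T.astype(float)  # (chunk, n)
        Gr = resid_full(G.T).T
        slope, t, p = _fwl_stats(Gr, Yr, yss, df_full)
        collect(rows, slope, t, p)

    for s_idx in np.flatnonzero(has_missing):
        use = calls[:, s_idx] != MISSING
        n_used = int(use.sum())
        df = n_used - 5
        Cm = C[use]
        resid = _residualizer(Cm)
        Ym = resid(Y[use])
        yss_m = np.einsum("nv,nv->v", Ym, Ym)
        Gm = resid(calls[use, s_idx].astype(float)[:, None]).T
        slope, t, p = _fwl_stats(Gm, Ym, yss_m, df)
        collect([s_idx], slope, t, p)

    pairs = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["snp", "i", "j", "k", "beta", "t", "p"])
    )
    return AssociationResult(
        snp_ids=g.snp_ids,
        snp_gene=g.snp_meta["gene"],
        voxel_coords=coords,
        grid_shape=shape,
        min_p_per_snp=pd.Series(min_p, index=g.snp_ids, name="min_p"),
        recorded_pairs=pairs.sort_values(["snp", "i", "j", "k"]).reset_index(drop=True),
        record_p_max=record_p_max,
        n_tests=S * V,
        dense=dense,
    )


def select_candidates(res: AssociationResult, p_threshold: float = 1e-6) -> AssociationResult:
    """Populate candidate genes and significant pairs at a strict P threshold.

    A gene is a candidate iff its minimum SNP x voxel P is strictly below
    ``p_threshold``; the significant pairs are every test strictly below it.
    """
    if res.dense is None and p_threshold > res.record_p_max:
        raise ValueError(
            f"threshold {p_threshold} exceeds the recorded cap {res.record_p_max} "
            "and dense results were not kept; re-run the screen with a larger record_p_max"
        )
    sig = res.recorded_pairs[res.recorded_pairs["p"] < p_threshold].reset_index(drop=True)
    gene_min = res.min_p_per_gene
    candidates = set(gene_min.index[gene_min < p_threshold])
    return replace(
        res,
        p_threshold=p_threshold,
        significant_pairs=sig,
        candidate_genes=candidates,
    )
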