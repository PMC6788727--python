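"""Voxel weighting, LD correction, smoothing and connected components."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from voxgene._utils import fwhm_to_sigma
from voxgene.hotclusters import (
    VoxelWeightMap,
    annotate_clusters,
    extract_clusters,
    ld_correct,
    li_ji_meff,
    percentile_threshold,
    raw_weights,
    smooth,
)

from conftest import make_genotypes


def pairs_df(pairs):
    return pd.DataFrame(pairs, columns=["snp", "i", "j", "k"])


def flood_fill_components(mask, connectivity):
    """Brute-force BFS component labeling oracle over a boolean 3-D mask."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            cur = q.popleft()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestRawWeights:
    def test_counts_distinct_snps(self):
        w = raw_weights(pairs_df([("s1", 2, 2, 2), ("s2", 2, 2, 2), ("s1", 1, 1, 1)]), (4, 4, 4))
        assert w.raw[2, 2, 2] == 2
        assert w.raw[1, 1, 1] == 1
        assert w.raw.sum() == 3

    def test_duplicates_counted_once(self):
        w = raw_weights(pairs_df([("s1", 0, 0, 0), ("s1", 0, 0, 0)]), (2, 2, 2))
        assert w.raw[0, 0, 0] == 1

    def test_empty_pairs_all_zero(self):
        w = raw_weights(pairs_df([]), (3, 3, 3))
        assert w.raw.sum() == 0

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            raw_weights(pairs_df([("s1", 5, 0, 0)]), (4, 4, 4))


class TestLDCorrection:
    def test_perfectly_correlated_pair_counts_once(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 40)
        g = make_genotypes(np.column_stack([col, col]), genes=["GA", "GA"], chroms=[1, 1])
        pairs = pairs_df([("s0", 1, 1, 1), ("s1", 1, 1, 1)])
        w = ld_correct(raw_weights(pairs, (3, 3, 3)), pairs, g)
        assert w.raw[1, 1, 1] == 2
        assert w.corrected[1, 1, 1] == pytest.approx(1.0)

    def test_different_chromosomes_not_corrected(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 40)
        g = make_genotypes(np.column_stack([col, col]), genes=["GA", "GB"], chroms=[1, 2])
        pairs = pairs_df([("s0", 1, 1, 1), ("s1", 1, 1, 1)])
        w = ld_correct(raw_weights(pairs, (3, 3, 3)), pairs, g)
        assert w.corrected[1, 1, 1] == pytest.approx(2.0)

    def test_independent_snps_count_fully(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(4000, 3))
        g = make_genotypes(calls, chroms=[1, 1, 1])
        pairs = pairs_df([("s0", 0, 0, 0), ("s1", 0, 0, 0), ("s2", 0, 0, 0)])
        w = ld_correct(raw_weights(pairs, (2, 2, 2)), pairs, g)
        assert w.corrected[0, 0, 0] == pytest.approx(3.0, abs=0.15)

    def test_exchangeable_block_matches_eigen_oracle(self):
        # 5 SNPs with exchangeable correlation ~0.5 via a shared latent factor
        rng = np.random.default_rng(2)
        n = 2000
        latent = rng.normal(size=n)
        cols = []
        for _ in range(5):
            z = np.sqrt(0.5) * latent + np.sqrt(0.5) * rng.normal(size=n)
            cols.append(np.digitize(z, [-0.6, 0.6]))
        calls = np.column_stack(cols)
        g = make_genotypes(calls, chroms=[7] * 5)
        pairs = pairs_df([(f"s{i}", 0, 0, 0) for i in range(5)])
        w = ld_correct(raw_weights(pairs, (1, 1, 1)), pairs, g)
        corr = np.corrcoef(calls.T.astype(float))
        lam = np.linalg.eigvalsh(corr)
        oracle = sum((l >= 1) + (l - np.floor(l)) for l in np.clip(lam, 0, None))
        assert w.corrected[0, 0, 0] == pytest.approx(oracle, rel=1e-9)
        assert 1.0 < w.corrected[0, 0, 0] < 5.0

    def test_li_ji_boundary_behaviours(self):
        assert li_ji_meff(np.eye(4)) == pytest.approx(4.0)
        assert li_ji_meff(np.ones((4, 4))) == pytest.approx(1.0)

    def test_too_few_subjects_warns_and_skips(self):
        g = make_genotypes(np.array([[0, 1]]), chroms=[1, 1])
        pairs = pairs_df([("s0", 0, 0, 0), ("s1", 0, 0, 0)])
        with pytest.warns(UserWarning, match="complete-call"):
            w = ld_correct(raw_weights(pairs, (1, 1, 1)), pairs, g)
        assert w.corrected[0, 0, 0] == w.raw[0, 0, 0]


class TestSmoothing:
    def test_sigma_conversion_closed_form(self):
        assert fwhm_to_sigma(8.0, 1.5) == pytest.approx(8.0 / 2.3548200450309493 / 1.5, rel=1e-9)
        assert fwhm_to_sigma(8.0, 1.5) == pytest.approx(2.265, abs=1e-3)

    def test_impulse_response_unit_mass_and_symmetric(self):
        raw = np.zeros((21, 21, 21))
        raw[10, 10, 10] = 1.0
        w = smooth(VoxelWeightMap(raw=raw, voxel_size_mm=1.5, corrected=raw), fwhm_mm=8.0)
        assert w.smoothed.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(w.smoothed, w.smoothed[::-1, :, :], atol=1e-12)
        np.testing.assert_allclose(w.smoothed, w.smoothed[:, :, ::-1], atol=1e-12)

    def test_constant_interior_unchanged(self):
        raw = np.ones((40, 40, 40))
        w = smooth(VoxelWeightMap(raw=raw, voxel_size_mm=1.5, corrected=raw), fwhm_mm=8.0)
        assert w.smoothed[20, 20, 20] == pytest.approx(1.0, abs=1e-6)

    def test_mass_never_increases(self):
        rng = np.random.default_rng(4)
        raw = rng.integers(0, 4, size=(12, 12, 12)).astype(float)
        w = smooth(VoxelWeightMap(raw=raw, corrected=raw), fwhm_mm=6.0)
        assert w.smoothed.sum() <= raw.sum() + 1e-9

    def test_nonpositive_fwhm_rejected(self):
        raw = np.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="FWHM"):
            smooth(VoxelWeightMap(raw=raw), fwhm_mm=0.0)


class TestClusterExtraction:
    def _wmap(self, arr):
        arr = np.asarray(arr, dtype=float)
        return VoxelWeightMap(raw=np.zeros_like(arr), smoothed=arr)

    def test_two_blobs_match_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        m = rng.random((24, 24, 24))
        m[:, 11:13, :] = 0.0  # sub-threshold separating plane
        wmap = self._wmap(m)
        for conn in (6, 18, 26):
            clusters = extract_clusters(wmap, threshold=0.7, connectivity=conn)
            got = {frozenset(map(tuple, c.voxels)) for c in clusters}
            assert got == flood_fill_components(m > 0.7, conn)

    def test_all_below_threshold_empty(self):
        assert extract_clusters(self._wmap(np.full((5, 5, 5), 0.1)), threshold=0.2304) == []

    def test_threshold_is_strict(self):
        m = np.zeros((3, 3, 3))
        m[1, 1, 1] = 0.2304
        assert extract_clusters(self._wmap(m), threshold=0.2304) == []
        m[1, 1, 1] = 0.23041
        assert len(extract_clusters(self._wmap(m), threshold=0.2304)) == 1

    def test_corner_contact_depends_on_connectivity(self):
        m = np.zeros((4, 4, 4))
        m[0, 0, 0] = m[1, 1, 1] = 1.0  # share only a corner
        assert len(extract_clusters(self._wmap(m), 0.5, connectivity=18)) == 2
        assert len(extract_clusters(self._wmap(m), 0.5, connectivity=26)) == 1
        m2 = np.zeros((4, 4, 4))
        m2[0, 0, 0] = m2[0, 1, 1] = 1.0  # share an edge
        assert len(extract_clusters(self._wmap(m2), 0.5, connectivity=18)) == 1
        assert len(extract_clusters(self._wmap(m2), 0.5, connectivity=6)) == 2

    def test_rank_ordering_by_max_weight(self):
        m = np.zeros((8, 8, 8))
        m[1, 1, 1] = 0.5
        m[5, 5, 5] = 0.9
        clusters = extract_clusters(self._wmap(m), 0.3)
        assert clusters[0].max_weight == pytest.approx(0.9)
        assert clusters[0].name == "HC1"
        assert clusters[1].max_weight == pytest.approx(0.5)

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        m = rng.random((10, 10, 10))
        clusters = extract_clusters(self._wmap(m), threshold=0.8)
        all_vox = [tuple(v) for c in clusters for v in c.voxels]
        assert len(all_vox) == len(set(all_vox))  # disjoint
        assert len(all_vox) == int((m > 0.8).sum())  # exhaustive

    def test_percentile_threshold_alternative(self):
        m = np.zeros((10, 10, 10))
        m[5, 5, 5] = 1.0
        thr = percentile_threshold(self._wmap(m), 99.9)
        assert 0.0 <= thr < 1.0


class TestAnnotation:
    def _cluster_inputs(self):
        m = np.zeros((6, 6, 6))
        m[1:3, 1:3, 1:3] = 1.0
        wmap = VoxelWeightMap(raw=np.zeros_like(m), smoothed=m)
        clusters = extract_clusters(wmap, 0.5)
        pairs = pairs_df([("s0", 1, 1, 1), ("s1", 2, 2, 2), ("s2", 5, 5, 5)])
        g = make_genotypes(
            np.random.default_rng(0).integers(0, 3, (5, 3)),
            genes=["GA", "GB", "GC"], chroms=[1, 2, 3],
        )
        return clusters, pairs, g

    def test_genes_from_intersecting_significant_voxels(self):
        clusters, pairs, g = self._cluster_inputs()
        atlas = np.ones((6, 6, 6), dtype=int)
        out = annotate_clusters(clusters, pairs, g.snp_meta, atlas, {1: "RegionA"})
        assert out[0].associated_genes == {"GA", "GB"}  # GC's voxel lies outside
        assert out[0].atlas_label == "RegionA"

    def test_modal_atlas_label_with_fractions(self):
        clusters, pairs, g = self._cluster_inputs()
        atlas = np.ones((6, 6, 6), dtype=int)
        atlas[1, :, :] = 2  # 4 of 8 cluster voxels -> tie broken lexicographically
        atlas[1, 1, 1] = 1  # now 5/8 labelled 1
        out = annotate_clusters(clusters, pairs, g.snp_meta, atlas, {1: "A", 2: "B"})
        assert out[0].atlas_label == "A"
        assert out[0].atlas_fractions["A"] == pytest.approx(5 / 8)
        assert out[0].atlas_fractions["B"] == pytest.approx(3 / 8)

    def test_atlas_grid_mismatch_rejected(self):
        clusters, pairs, g = self._cluster_inputs()
        with pytest.raises(ValueError, match="atlas"):
            annotate_clusters(clusters, pairs, g.snp_meta, np.ones((2, 2, 2), dtype=int))
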