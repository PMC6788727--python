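"""Correlation K-means, IGP model selection, PANSS subscales and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxgene.association import GMVImageSet
from voxgene.hotclusters import VoxelWeightMap, extract_clusters
from voxgene.simulate import PANSS_ITEMS
from voxgene.subtyping import (
    CorrelationKMeans,
    choose_k,
    correlation_kmeans,
    extract_hc_features,
    hc_group_gmv_test,
    igp,
    panss_subscales,
    permutation_test_subscales,
)


def make_panss(items_by_patient):
    return pd.DataFrame(
        items_by_patient, columns=PANSS_ITEMS,
        index=pd.Index([f"pt{i}" for i in range(len(items_by_patient))], name="subject"),
    )


def two_group_features(n_per=10, seed=0, spread=0.05):
    """Rows correlated with one of two orthogonal profile templates."""
    rng = np.random.default_rng(seed)
    t1 = np.array([1.0, -1.0, 1.0, -1.0])
    t2 = np.array([1.0, 1.0, -1.0, -1.0])
    rows, truth = [], []
    for g, t in ((1, t1), (2, t2)):
        for _ in range(n_per):
            rows.append(5.0 + t + rng.normal(0, spread, 4))
            truth.append(g)
    feat = pd.DataFrame(rows, index=pd.Index([f"pt{i}" for i in range(2 * n_per)], name="subject"))
    return feat, np.array(truth)


class TestFeatureExtraction:
    def test_mean_over_cluster_voxels(self):
        vols = np.zeros((1, 4, 4, 4))
        vols[0, 0, 0, 0] = 0.4
        vols[0, 0, 0, 1] = 0.6
        gmv = GMVImageSet(volumes=vols, subject_ids=["a"])
        m = np.zeros((4, 4, 4))
        m[0, 0, 0] = m[0, 0, 1] = 1.0
        clusters = extract_clusters(VoxelWeightMap(raw=np.zeros_like(m), smoothed=m), 0.5)
        feat = extract_hc_features(gmv, clusters)
        assert feat.loc["a", "HC1"] == pytest.approx(0.5)

    def test_constant_image_gives_constant_features(self):
        vols = np.full((3, 4, 4, 4), 0.7)
        gmv = GMVImageSet(volumes=vols, subject_ids=["a", "b", "c"])
        m = np.zeros((4, 4, 4))
        m[1:3, 1:3, 1] = 1.0
        clusters = extract_clusters(VoxelWeightMap(raw=np.zeros_like(m), smoothed=m), 0.5)
        feat = extract_hc_features(gmv, clusters)
        assert np.allclose(feat.to_numpy(), 0.7)


class TestCorrelationKMeans:
    def test_scale_invariant_recovery_of_rescaled_templates(self):
        # exact positive rescalings of two orthogonal profiles: d = 0 within groups
        t1 = np.array([1.0, -1.0, 1.0, -1.0])
        t2 = np.array([1.0, 1.0, -1.0, -1.0])
        rows = [a * t1 + b for a, b in [(1, 0), (2.5, 1), (0.3, -2)]]
        rows += [a * t2 + b for a, b in [(1, 0), (4, 2), (0.5, 5)]]
        feat = pd.DataFrame(rows)
        labels, cost = correlation_kmeans(feat, 2, n_replicates=20, seed=0)
        assert cost == pytest.approx(0.0, abs=1e-12)
        assert len(set(labels.iloc[:3])) == 1 and len(set(labels.iloc[3:])) == 1
        assert set(labels) == {1, 2}

    def test_k1_groups_everyone(self):
        feat, _ = two_group_features()
        labels, cost = correlation_kmeans(feat, 1, n_replicates=5, seed=1)
        assert set(labels) == {1}
        assert cost > 0

    def test_recovery_over_replicate_datasets(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(20):
            feat, truth = two_group_features(n_per=12, seed=seed, spread=0.3)
            labels, _ = correlation_kmeans(feat, 2, n_replicates=50, seed=seed)
            if adjusted_rand_score(truth, labels) >= 0.9:
                hits += 1
        assert hits >= 18

    def test_constant_row_rejected_with_patient_name(self):
        feat, _ = two_group_features()
        feat.loc["pt3"] = 2.0
        with pytest.raises(ValueError, match="pt3"):
            correlation_kmeans(feat, 2, n_replicates=2, seed=0)

    def test_sklearn_estimator_interface(self):
        feat, _ = two_group_features()
        est = CorrelationKMeans(n_clusters=2, n_replicates=10, random_state=0)
        assert est.get_params()["n_clusters"] == 2
        est.fit(feat)
        assert est.labels_.shape == (len(feat),)
        assert est.cluster_centers_.shape[0] == 2
        assert est.inertia_ >= 0
        pred = est.predict(feat)
        np.testing.assert_array_equal(pred, est.labels_)

    def test_deterministic_under_seed(self):
        feat, _ = two_group_features(spread=0.4)
        l1, c1 = correlation_kmeans(feat, 3, n_replicates=30, seed=42)
        l2, c2 = correlation_kmeans(feat, 3, n_replicates=30, seed=42)
        assert c1 == c2
        pd.testing.assert_series_equal(l1, l2)


class TestIGP:
    def test_separated_groups_score_one(self):
        feat, truth = two_group_features()
        per_group, mean = igp(feat, truth)
        assert per_group == {1: 1.0, 2: 1.0}
        assert mean == 1.0

    def test_singleton_group_scores_zero(self):
        feat, truth = two_group_features(n_per=5)
        labels = truth.copy()
        labels[0] = 3  # singleton: its nearest neighbour is necessarily elsewhere
        per_group, _ = igp(feat, labels)
        assert per_group[3] == 0.0

    def test_random_labels_on_structureless_data_near_half(self):
        rng = np.random.default_rng(0)
        means = []
        for rep in range(30):
            feat = pd.DataFrame(rng.normal(size=(40, 6)))
            labels = np.array([1] * 20 + [2] * 20)
            means.append(igp(feat, labels)[1])
        assert np.mean(means) == pytest.approx(0.5, abs=0.07)

    def test_nearest_neighbour_tie_broken_to_lowest_index(self):
        # three identical rows: everyone's NN is the lowest-index other row
        feat = pd.DataFrame([[1.0, 2.0, 3.0]] * 3 + [[3.0, 1.0, 2.0]])
        per_group, _ = igp(feat, [1, 1, 2, 2])
        assert per_group[1] == 1.0  # rows 0,1 pick each other
        assert per_group[2] == 0.0  # row 2's NN is row 0 (lowest index among ties)


class TestChooseK:
    def test_ties_resolve_to_smallest_k(self):
        feat, _ = two_group_features(n_per=8, spread=0.01)
        res = choose_k(feat, k_range=(2, 3), n_replicates=30, seed=0)
        # both K give IGP 1.0 on cleanly separated data; the documented rule
        # keeps the most parsimonious grouping
        assert res.igp_by_k[2] == res.igp_by_k[3] == 1.0
        assert res.K == 2

    def test_k_equal_to_n_patients_all_singletons(self):
        feat, _ = two_group_features(n_per=3)
        res = choose_k(feat, k_range=(2, len(feat)), n_replicates=10, seed=1)
        assert res.igp_by_k[len(feat)] == 0.0

    def test_k_above_n_rejected(self):
        feat, _ = two_group_features(n_per=2)
        with pytest.raises(ValueError, match="exceed"):
            choose_k(feat, k_range=(2, 10), n_replicates=5, seed=0)


class TestPANSSSubscales:
    def test_minimum_scores(self):
        df = panss_subscales(make_panss([[1] * 30]))
        row = df.iloc[0]
        assert (row["P"], row["N"], row["G"], row["TT"], row["PN"]) == (7, 7, 16, 30, 0)

    def test_extreme_positive_profile(self):
        items = [7] * 7 + [1] * 7 + [1] * 16
        row = panss_subscales(make_panss([items])).iloc[0]
        assert (row["P"], row["N"], row["PN"], row["TT"]) == (49, 7, 42, 72)

    def test_item_out_of_range_rejected(self):
        bad = [[1] * 29 + [8]]
        with pytest.raises(ValueError, match="outside 1-7"):
            panss_subscales(make_panss(bad))

    def test_inconsistent_recorded_subscale_rejected(self):
        df = make_panss([[2] * 30])
        df["P"] = 99
        with pytest.raises(ValueError, match="disagrees"):
            panss_subscales(df)


class TestPermutationTests:
    def test_identical_scores_give_p_one_and_zero_diffs(self):
        panss = make_panss([[3] * 30] * 12)
        labels = [1] * 6 + [2] * 6
        res = permutation_test_subscales(panss, labels, n_perm=200, seed=0)
        assert (res.pairwise["observed_diff"] == 0).all()
        assert (res.pairwise["p"] == 1.0).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        base = 1 + np.round(np.abs(rng.normal(0, 1.5, size=(30, 30)))).clip(0, 6)
        items = base.copy()
        items[:10, :7] = np.clip(items[:10, :7] + 3, 1, 7)  # strong P shift, group 1
        panss = make_panss(items.astype(int))
        labels = [1] * 10 + [2] * 20
        res = permutation_test_subscales(panss, labels, n_perm=2000, seed=1)
        p_pair = res.pairwise.query("subscale == 'P'")["p"].iloc[0]
        assert p_pair < 0.05

    def test_null_p_uniform_over_replicates(self):
        # the one-tailed percentile p is exactly uniform under the null;
        # the default doubled two-tailed p must remain valid (conservative)
        rng = np.random.default_rng(9)
        p_one, p_two = [], []
        for rep in range(300):
            items = 1 + np.round(np.abs(rng.normal(0, 2.0, size=(24, 30)))).clip(0, 6)
            panss = make_panss(items.astype(int))
            labels = [1] * 12 + [2] * 12
            res1 = permutation_test_subscales(
                panss, labels, n_perm=250, seed=rng, subscales=("PN",), tails="one"
            )
            res2 = permutation_test_subscales(
                panss, labels, n_perm=250, seed=rng, subscales=("PN",)
            )
            p_one.append(res1.pairwise["p"].iloc[0])
            p_two.append(res2.pairwise["p"].iloc[0])
        assert stats.kstest(p_one, "uniform").pvalue > 0.01
        for alpha in (0.05, 0.1):
            se = np.sqrt(alpha * (1 - alpha) / 300)
            assert np.mean(np.array(p_two) <= alpha) <= alpha + 3 * se

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        items = 1 + np.round(np.abs(rng.normal(0, 2.0, size=(16, 30)))).clip(0, 6)
        panss = make_panss(items.astype(int))
        labels = pd.Series([1] * 8 + [2] * 8, index=panss.index)
        res1 = permutation_test_subscales(panss, labels, n_perm=500, seed=3)
        order = rng.permutation(len(panss))
        res2 = permutation_test_subscales(panss.iloc[order], labels.iloc[order], n_perm=500, seed=3)
        pd.testing.assert_frame_equal(res1.group_means, res2.group_means)


def exact_ranksum_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    null = np.array(
        [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    )
    return min(1.0, 2 * min((null >= obs).mean(), (null <= obs).mean()))


class TestRankSumTests:
    exact_ranksum_oracle = staticmethod(exact_ranksum_oracle)

    def test_matches_exact_enumeration_for_small_groups(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            x = rng.normal(size=6)
            y = rng.normal(loc=0.8, size=7)
            feat = pd.DataFrame({"HC1": np.concatenate([x, y])})
            labels = [1] * 6 + [2] * 7
            table = hc_group_gmv_test(feat, labels, alpha=0.05)
            p_pkg = table.query("group == 1")["p"].iloc[0]
            p_oracle = self.exact_ranksum_oracle(x, y)
            assert p_pkg == pytest.approx(p_oracle, abs=1e-9)

    def test_bonferroni_threshold_over_16_hcs(self):
        rng = np.random.default_rng(1)
        feat = pd.DataFrame(rng.normal(size=(20, 16)), columns=[f"HC{i+1}" for i in range(16)])
        table = hc_group_gmv_test(feat, [1] * 10 + [2] * 10, alpha=0.05)
        assert (table["bonferroni_threshold"] == 0.05 / 16).all()
        assert table["bonferroni_threshold"].iloc[0] == 0.003125

    def test_shifted_group_flagged_only_on_its_hc(self):
        rng = np.random.default_rng(3)
        feat = pd.DataFrame(rng.normal(size=(30, 4)), columns=["HC1", "HC2", "HC3", "HC4"])
        feat.loc[feat.index[:10], "HC2"] += 3.0  # +3 SD shift for group 1
        table = hc_group_gmv_test(feat, [1] * 10 + [2] * 20, alpha=0.05)
        g1 = table.query("group == 1").set_index("hc")["significant"]
        assert bool(g1["HC2"])
        assert not g1[["HC1", "HC3", "HC4"]].any()

    def test_small_group_skipped_with_warning(self):
        feat = pd.DataFrame({"HC1": np.arange(6.0)})
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = hc_group_gmv_test(feat, [1, 2, 2, 2, 2, 2])
        assert set(table["group"]) == {2}
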