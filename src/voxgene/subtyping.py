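"""Patient subtyping by hot-cluster GMV profiles and PANSS characterization.

Patients are represented by their mean GMV over each hot cluster and
clustered by K-means under the correlation distance d(x, y) = 1 - PCC(x, y).
The number of groups is chosen (over K = 2..10) by maximizing the mean
in-group proportion (IGP): the fraction of each group's members whose
nearest neighbour under d shares their label.  Group differences are then
characterized on the PANSS subscales (P, N, G, total TT, composite
PN = P - N) by a label-permutation test, and per-hot-cluster GMV
differences (each group vs the rest) by two-sided Wilcoxon rank-sum tests
with Bonferroni correction over the hot clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from ._utils import as_rng, correlation_distance_matrix, standardize_rows
from .simulate import PANSS_ITEMS

SUBSCALES = ("P", "N", "G", "TT", "PN")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_hc_features(gmv, clusters) -> pd.DataFrame:
    """Patients x HCs matrix of mean GMV over each cluster's voxels."""
    rows = {}
    for cl in clusters:
        if cl.size == 0:
            raise ValueError(f"cluster {cl.name} is empty")
        if np.any(cl.voxels >= np.array(gmv.grid_shape)[None, :]):
            raise ValueError(f"cluster {cl.name} lies outside the GMV grid")
        vox = tuple(cl.voxels.T)
        rows[cl.name] = gmv.volumes[(slice(None),) + vox].mean(axis=1)
    return pd.DataFrame(rows, index=pd.Index(gmv.subject_ids, name="subject"))


# ---------------------------------------------------------------------------
# correlation-distance K-means
# ---------------------------------------------------------------------------

class CorrelationKMeans(BaseEstimator, ClusterMixin):
    """K-means under d(x, y) = 1 - Pearson correlation of feature rows.

    Rows are standardized to zero mean and unit norm, which makes d half the
    squared Euclidean distance, so Lloyd iterations with mean centroids
    minimize the within-group correlation-distance cost.  The best of
    ``n_replicates`` random initializations (by within-group cost) is kept.
    Labels are 1-based (1..K).  An empty cluster during iteration is
    re-seeded from the point farthest from its centroid.

    Parameters
    ----------
    n_clusters : number of groups K.
    n_replicates : random restarts; the minimum-cost solution wins.
    max_iter, tol : Lloyd iteration caps.
    random_state : seed for centroid initialization.

    Attributes (after fit)
    ----------------------
    labels_ : (n,) int array of group labels in 1..K.
    cluster_centers_ : (K, p) centroids in the row-standardized space.
    inertia_ : sum over patients of d(x, centroid of its group).
    n_iter_ : iterations used by the winning replicate.
    """

    def __init__(self, n_clusters=3, n_replicates=1000, max_iter=100, tol=1e-10, random_state=None):
        self.n_clusters = n_clusters
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _dist_to_centers(Z: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """d(x, c) = 1 - corr(x, c) with rows of Z already standardized."""
        cc = centers - centers.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(cc, axis=1)
        norms[norms == 0] = 1.0  # degenerate centroid: maximal distance below
        corr = Z @ (cc / norms[:, None]).T
        return 1.0 - corr

    def _lloyd(self, Z: np.ndarray, rng: np.random.Generator):
        n, _ = Z.shape
        K = self.n_clusters
        centers = Z[rng.choice(n, size=K, replace=False)]
        labels = np.full(n, -1)
        cost = np.inf
        for it in range(1, self.max_iter + 1):
            D = self._dist_to_centers(Z, centers)
            labels = D.argmin(axis=1)
            # re-seed empty clusters from the farthest point
            for k in range(K):
                if not np.any(labels == k):
                    far = D[np.arange(n), labels].argmax()
                    centers[k] = Z[far]
                    labels[far] = k
            new_centers = np.vstack([Z[labels == k].mean(axis=0) for k in range(K)])
            new_cost = float(self._dist_to_centers(Z, new_centers)[np.arange(n), labels].sum())
            converged = np.array_equal(new_centers, centers) or cost - new_cost <= self.tol
            centers, cost = new_centers, new_cost
            if converged:
                break
        return labels, centers, cost, it

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < self.n_clusters:
            raise ValueError(f"need at least K={self.n_clusters} patients, got {len(X)}")
        values = X.to_numpy(float)
        const = values.std(axis=1) == 0
        if const.any():
            bad = list(X.index[const])
            raise ValueError(f"constant feature rows (correlation undefined) for patients {bad}")
        Z = standardize_rows(values)
        rng = as_rng(self.random_state)
        best = None
        for _ in range(self.n_replicates):
            labels, centers, cost, it = self._lloyd(Z, rng)
            if best is None or cost < best[2]:
                best = (labels, centers, cost, it)
        labels, centers, cost, it = best
        self.labels_ = labels + 1
        self.cluster_centers_ = centers
        self.inertia_ = cost
        self.n_iter_ = it
        self.feature_names_in_ = np.asarray(X.columns)
        self._train_index = X.index
        return self

    def predict(self, X):
        Z = standardize_rows(pd.DataFrame(X).to_numpy(float))
        return self._dist_to_centers(Z, self.cluster_centers_).argmin(axis=1) + 1

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def correlation_kmeans(feat: pd.DataFrame, K: int, n_replicates: int = 1000, seed=None):
    """Functional wrapper: returns (labels Series 1..K, within-group cost)."""
    est = CorrelationKMeans(n_clusters=K, n_replicates=n_replicates, random_state=seed).fit(feat)
    return pd.Series(est.labels_, index=feat.index, name="group"), est.inertia_


# ---------------------------------------------------------------------------
# IGP and model selection
# ---------------------------------------------------------------------------

def igp(feat: pd.DataFrame, labels) -> tuple[dict[int, float], float]:
    """In-group proportion per group and its unweighted mean over groups.

    Each patient's nearest *other* patient under the correlation distance is
    found (ties broken toward the lowest patient index); a group's IGP is
    the fraction of members whose nearest neighbour shares their label.
    Singleton groups necessarily score 0.
    """
    lab = np.asarray(pd.Series(labels).reindex(feat.index) if isinstance(labels, pd.Series) else labels)
    if len(lab) != len(feat):
        raise ValueError("one label per patient required")
    if len(feat) < 2:
        raise ValueError("IGP needs at least 2 patients")
    D = correlation_distance_matrix(feat.to_numpy(float))
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(axis=1)  # argmin takes the lowest index on ties
    match = lab[nn] == lab
    per_group = {int(gr): float(match[lab == gr].mean()) for gr in np.unique(lab)}
    return per_group, float(np.mean(list(per_group.values())))


@dataclass
class SubtypeResult:
    """Chosen grouping with its IGP-by-K diagnostics."""

    labels: pd.Series
    K: int
    igp_by_k: dict[int, float]
    within_group_cost: float
    n_replicates: int
    seed: int | None


def choose_k(
    feat: pd.DataFrame,
    k_range=range(2, 11),
    n_replicates: int = 1000,
    seed=None,
) -> SubtypeResult:
    """Cluster at every K in ``k_range`` and keep the K maximizing mean IGP.

    Ties in mean IGP resolve to the smallest K (deterministic).
    """
    k_range = [int(k) for k in k_range]
    if max(k_range) > len(feat):
        raise ValueError("K cannot exceed the number of patients")
    rng = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = rng.spawn(len(k_range))
    igp_by_k: dict[int, float] = {}
    fits = {}
    for k, child in zip(k_range, children):
        labels, cost = correlation_kmeans(feat, k, n_replicates=n_replicates, seed=child)
        _, mean_igp = igp(feat, labels)
        igp_by_k[k] = mean_igp
        fits[k] = (labels, cost)
    best_k = max(sorted(igp_by_k), key=lambda k: (igp_by_k[k], -k))
    labels, cost = fits[best_k]
    return SubtypeResult(
        labels=labels,
        K=best_k,
        igp_by_k=igp_by_k,
        within_group_cost=cost,
        n_replicates=n_replicates,
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )


# ---------------------------------------------------------------------------
# PANSS subscales and group tests
# ---------------------------------------------------------------------------

def panss_subscales(items: pd.DataFrame) -> pd.DataFrame:
    """Derive P, N, G, TT and PN = P - N from the 30 PANSS items.

    Validates the 1-7 item range; if subscale columns are already present
    they must agree with the item sums (consistency check).
    """
    missing = [c for c in PANSS_ITEMS if c not in items.columns]
    if missing:
        raise ValueError(f"missing PANSS items: {missing}")
    vals = items[PANSS_ITEMS]
    if (vals < 1).any().any() or (vals > 7).any().any():
        bad = vals.index[((vals < 1) | (vals > 7)).any(axis=1)].tolist()
        raise ValueError(f"PANSS items outside 1-7 for patients {bad}")
    out = items.copy()
    derived = {
        "P": vals[[f"P{i}" for i in range(1, 8)]].sum(axis=1),
        "N": vals[[f"N{i}" for i in range(1, 8)]].sum(axis=1),
        "G": vals[[f"G{i}" for i in range(1, 17)]].sum(axis=1),
    }
    derived["TT"] = derived["P"] + derived["N"] + derived["G"]
    derived["PN"] = derived["P"] - derived["N"]
    for name, series in derived.items():
        if name in items.columns and not np.array_equal(items[name].to_numpy(), series.to_numpy()):
            bad = items.index[items[name] != series].tolist()
            raise ValueError(f"recorded subscale {name} disagrees with item sums for patients {bad}")
        out[name] = series
    return out


@dataclass
class PermutationTestResult:
    """Group-mean and pairwise-difference permutation tests for one subscale set."""

    group_means: pd.DataFrame  # subscale x group observed means
    group_p: pd.DataFrame  # subscale x group two-tailed p for each group's mean
    pairwise: pd.DataFrame  # subscale, group_a, group_b, observed diff, p
    omnibus_p: pd.Series  # subscale -> p for max |pairwise difference|
    null_group_means: dict[str, np.ndarray]  # subscale -> (n_perm, n_groups)
    n_perm: int


def _perm_p(null: np.ndarray, observed: float, tails: str = "two", add_one: bool = True) -> float:
    """Empirical permutation p-value.

    ``tails="two"``: doubled smaller tail, capped at 1 (conservative on
    discrete statistics).  ``tails="one"``: upper-tail percentile of the
    observed value in the null, which is exactly uniform under the null.
    Both use the add-one correction so p is never 0.
    """
    n = len(null)
    a = 1 if add_one else 0
    hi = (null >= observed).sum()
    if tails == "one":
        return float((hi + a) / (n + a))
    lo = (null <= observed).sum()
    p = 2.0 * (min(hi, lo) + a) / (n + a)
    return float(min(1.0, p))


def permutation_test_subscales(
    panss: pd.DataFrame,
    labels,
    n_perm: int = 10_000,
    seed=None,
    subscales=SUBSCALES,
    tails: str = "two",
) -> PermutationTestResult:
    """Permutation tests of subscale means across patient groups.

    The null permutes group labels over patients (group sizes fixed).  Per
    subscale it reports each group's mean with an empirical p, every
    pairwise difference of group means with its p, and an omnibus p on the
    maximum absolute pairwise difference.  ``tails`` selects the doubled
    two-tailed p (default) or the one-tailed upper percentile.
    """
    panss = panss_subscales(panss) if not set(subscales) <= set(panss.columns) else panss
    lab = pd.Series(labels).reindex(panss.index) if isinstance(labels, pd.Series) else pd.Series(np.asarray(labels), index=panss.index)
    if lab.isna().any():
        raise ValueError("every patient needs a group label")
    lab_arr = lab.to_numpy()
    groups = np.unique(lab_arr)
    rng = as_rng(seed)
    perms = np.vstack([rng.permutation(len(lab_arr)) for _ in range(n_perm)])
    perm_labels = lab_arr[perms]  # (n_perm, n): labels reassigned, sizes fixed

    means, group_p, pair_rows, omnibus, null_store = {}, {}, [], {}, {}
    for sub in subscales:
        x = panss[sub].to_numpy(float)
        obs = np.array([x[lab_arr == g].mean() for g in groups])
        null = np.empty((n_perm, len(groups)))
        for gi, g in enumerate(groups):
            mask = perm_labels == g
            null[:, gi] = (np.where(mask, x[None, :], 0.0).sum(axis=1)) / mask.sum(axis=1)
        means[sub] = obs
        group_p[sub] = [_perm_p(null[:, gi], obs[gi], tails) for gi in range(len(groups))]
        null_store[sub] = null
        obs_diffs, null_diffs = [], []
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                d_obs = obs[a] - obs[b]
                d_null = null[:, a] - null[:, b]
                pair_rows.append(
                    {
                        "subscale": sub,
                        "group_a": int(groups[a]),
                        "group_b": int(groups[b]),
                        "observed_diff": d_obs,
                        "p": _perm_p(d_null, d_obs, tails),
                    }
                )
                obs_diffs.append(abs(d_obs))
                null_diffs.append(np.abs(d_null))
        max_null = np.max(np.vstack(null_diffs), axis=0)
        omnibus[sub] = float((1 + (max_null >= max(obs_diffs)).sum()) / (n_perm + 1))

    idx = pd.Index([int(g) for g in groups], name="group")
    return PermutationTestResult(
        group_means=pd.DataFrame(means, index=idx).T,
        group_p=pd.DataFrame(group_p, index=idx).T,
        pairwise=pd.DataFrame(pair_rows),
        omnibus_p=pd.Series(omnibus, name="omnibus_p"),
        null_group_means=null_store,
        n_perm=n_perm,
    )


def hc_group_gmv_test(feat: pd.DataFrame, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of each group vs the rest on every HC feature.

    Two-sided Mann-Whitney (exact for small groups without ties); per group
    the p-values are Bonferroni-flagged at alpha / (number of HCs).
    """
    lab = pd.Series(labels).reindex(feat.index) if isinstance(labels, pd.Series) else pd.Series(np.asarray(labels), index=feat.index)
    groups = np.unique(lab.to_numpy())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_hc = feat.shape[1]
    bonf = alpha / n_hc
    rows = []
    for g in groups:
        members = feat[lab == g]
        others = feat[lab != g]
        if len(members) < 2:
            warnings.warn(f"group {g} has fewer than 2 members; tests skipped", stacklevel=2)
            continue
        for hc in feat.columns:
            stat, p = stats.mannwhitneyu(
                members[hc], others[hc], alternative="two-sided", method="auto"
            )
            rows.append(
                {
                    "group": int(g),
                    "hc": hc,
                    "statistic": float(stat),
                    "p": float(p),
                    "bonferroni_threshold": bonf,
                    "significant": bool(p < bonf),
                }
            )
    return pd.DataFrame(rows)
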