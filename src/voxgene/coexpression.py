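"""Spatio-temporal co-expression networks and interconnectedness testing.

Brain developmental expression samples are stratified into 4 anatomical
regions (FC, SC, SM, TP) x 3 developmental stages.  Within a stratum the
network's edge weight between two genes is the absolute Pearson correlation
of their expression, kept only when strictly above a threshold (0.8 by
default).  A gene set's *interconnectedness* is the sum of the surviving
edge weights among its members; its significance is assessed against the
empirical distribution of equally sized gene sets resampled uniformly from
the risk-gene pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng
from .simulate import REGIONS, STAGES

MERGED = "merged"


@dataclass
class ExpressionSet:
    """Genes x samples expression with (region, stage) sample labels."""

    matrix: pd.DataFrame  # index genes, columns sample ids
    sample_meta: pd.DataFrame  # index sample ids, columns region, stage

    def __post_init__(self):
        if not self.matrix.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.matrix.columns.equals(self.sample_meta.index):
            raise ValueError("sample metadata must cover exactly the expression samples, in order")
        bad_region = set(self.sample_meta["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown regions {sorted(bad_region)}")
        bad_stage = set(self.sample_meta["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages {sorted(bad_stage)}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def strata(self) -> list[tuple[str, int]]:
        return [(r, s) for r in REGIONS for s in STAGES]

    def stratum_samples(self, stratum) -> pd.Index:
        if stratum == MERGED:
            return self.matrix.columns
        region, stage = stratum
        meta = self.sample_meta
        return meta.index[(meta["region"] == region) & (meta["stage"] == stage)]


@dataclass
class CoexpressionNetwork:
    """Thresholded |PCC| adjacency over a gene universe for one stratum."""

    gene_universe: pd.Index
    weights: np.ndarray
    threshold: float
    weighted: bool
    stratum: tuple[str, int] | str

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.gene_universe),) * 2:
            raise ValueError("weights must be square over the gene universe")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight diagonal must be zero")
        self.weights = W

    def edge_density(self) -> float:
        n = len(self.gene_universe)
        if n < 2:
            return 0.0
        return float((self.weights > 0).sum() / (n * (n - 1)))


def threshold_weights(corr: np.ndarray, threshold: float, weighted: bool = True) -> np.ndarray:
    """Zero out |correlations| <= threshold (strictly greater survives); binarize if unweighted."""
    W = np.abs(np.asarray(corr, dtype=float)).copy()
    np.fill_diagonal(W, 0.0)
    W[W <= threshold] = 0.0
    if not weighted:
        W = (W > 0).astype(float)
    return W


def build_network(
    expr: ExpressionSet,
    stratum: tuple[str, int] | str,
    threshold: float = 0.8,
    weighted: bool = True,
) -> CoexpressionNetwork:
    """Build the thresholded co-expression network for one stratum (or 'merged').

    Zero-variance genes keep their node but get no edges (warned); fewer
    than 3 samples in the stratum is an error (PCC too unstable to define).
    """
    samples = expr.stratum_samples(stratum)
    if len(samples) < 3:
        raise ValueError(f"stratum {stratum!r} has {len(samples)} samples; need at least 3")
    X = expr.matrix[samples].to_numpy(float)
    sd = X.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance genes in stratum {stratum!r}; their edges set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    W = threshold_weights(corr, threshold, weighted)
    W[zero_var, :] = 0.0
    W[:, zero_var] = 0.0
    return CoexpressionNetwork(
        gene_universe=expr.genes, weights=W, threshold=threshold, weighted=weighted, stratum=stratum
    )


def _gene_indices(net: CoexpressionNetwork, genes) -> np.ndarray:
    idx = net.gene_universe.get_indexer(list(genes))
    if (idx < 0).any():
        unknown = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes not in network universe: {sorted(unknown)}")
    return idx


def interconnectedness(net: CoexpressionNetwork, genes) -> float:
    """Sum of edge weights over unordered gene pairs within ``genes``."""
    idx = _gene_indices(net, genes)
    if idx.size < 2:
        return 0.0
    sub = net.weights[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0)


@dataclass
class InterconnectednessResult:
    """Observed statistic vs a resampling null for one network."""

    observed: float
    null_samples: np.ndarray
    p_value: float
    n_resamples: int
    stratum: tuple[str, int] | str
    threshold: float
    weighted: bool

    def __post_init__(self):
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            # p may be exactly 0 only in strict mode without the add-one correction
            if not 0 <= self.p_value <= 1:
                raise ValueError("p_value outside [0, 1]")
        if len(self.null_samples) != self.n_resamples:
            raise ValueError("null sample count must equal n_resamples")

    @property
    def significant_001(self) -> bool:
        return self.p_value < 0.01

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.1


def resampling_test(
    net: CoexpressionNetwork,
    candidates,
    pool,
    n_resamples: int = 10_000,
    seed=None,
    add_one: bool = True,
    strict_greater: bool = False,
) -> InterconnectednessResult:
    """Compare the candidates' interconnectedness with random same-size gene sets.

    Each of ``n_resamples`` draws samples |candidates| genes uniformly
    without replacement from ``pool``.  By default p counts null values >=
    observed with the add-one correction (p can never be exactly zero);
    ``strict_greater`` reproduces the plain fraction of strictly larger
    nulls.
    """
    cand = list(dict.fromkeys(candidates))
    pool = list(dict.fromkeys(pool))
    if not set(cand) <= set(pool):
        raise ValueError("candidates must be a subset of the pool")
    pool_idx = _gene_indices(net, pool)
    k = len(cand)
    if k > len(pool):
        raise ValueError("candidate set larger than pool")
    observed = interconnectedness(net, cand)

    rng = as_rng(seed)
    # vectorized subset draws: rank random keys, take the k smallest per draw
    keys = rng.random((n_resamples, len(pool)))
    take = np.argpartition(keys, k - 1, axis=1)[:, :k] if k > 0 else np.empty((n_resamples, 0), int)
    subsets = pool_idx[take]  # (n_resamples, k)
    indicator = np.zeros((n_resamples, len(net.gene_universe)))
    np.put_along_axis(indicator, subsets, 1.0, axis=1)
    null = np.einsum("rg,rg->r", indicator @ net.weights, indicator) / 2.0

    if strict_greater:
        p = float((null > observed).sum()) / n_resamples
    else:
        p = (float((null >= observed).sum()) + (1.0 if add_one else 0.0)) / (
            n_resamples + (1 if add_one else 0)
        )
    return InterconnectednessResult(
        observed=observed,
        null_samples=null,
        p_value=p,
        n_resamples=n_resamples,
        stratum=net.stratum,
        threshold=net.threshold,
        weighted=net.weighted,
    )


def stability_suite(
    expr: ExpressionSet,
    candidates,
    pool,
    thresholds=(0.8,),
    n_resamples: int = 10_000,
    seed=None,
    include_merged: bool = True,
    modes=(True, False),
) -> pd.DataFrame:
    """Resampling test over every stratum (+ merged) x weighting mode x threshold.

    Returns a tidy table with one row per combination, analogous to the
    stability columns of a supplementary results sheet (e.g. 'p-0.8w').
    """
    rng = as_rng(seed)
    strata: list = list(expr.strata())
    if include_merged:
        strata.append(MERGED)
    rows = []
    for stratum in strata:
        for threshold in thresholds:
            for weighted in modes:
                net = build_network(expr, stratum, threshold=threshold, weighted=weighted)
                res = resampling_test(net, candidates, pool, n_resamples=n_resamples, seed=rng)
                rows.append(
                    {
                        "stratum": stratum if isinstance(stratum, str) else f"{stratum[0]}_{stratum[1]}",
                        "threshold": threshold,
                        "weighted": weighted,
                        "observed": res.observed,
                        "p": res.p_value,
                    }
                )
    return pd.DataFrame(rows)
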