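"""Shared numerical helpers: seed derivation, FWHM conversion, distances."""

from __future__ import annotations

import numpy as np

# FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian kernel
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: fixed stage order for counter-based sub-seed derivation; re-running one
#: stage never shifts another stage's random stream.
STAGE_INDEX = {
    "simulate": 0,
    "associate": 1,
    "coexpress": 2,
    "hotclust": 3,
    "subtype": 4,
}


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert a smoothing kernel's FWHM in mm to sigma in voxel units."""
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm}")
    if voxel_size_mm <= 0:
        raise ValueError(f"voxel size must be positive, got {voxel_size_mm}")
    return fwhm_mm / FWHM_PER_SIGMA / voxel_size_mm


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Counter-based per-stage seed: SeedSequence([global_seed, stage_index])."""
    return np.random.SeedSequence([int(global_seed), STAGE_INDEX[stage]])


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


def as_rng(seed) -> np.random.Generator:
    """Accept an int, SeedSequence, Generator or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row to mean zero and scale to unit L2 norm.

    After this transform, 1 - PCC(x, y) = ||x' - y'||^2 / 2, which makes the
    correlation distance a monotone function of Euclidean distance.
    Constant rows raise ValueError (correlation undefined).
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"constant rows (correlation undefined) at indices {bad.tolist()}")
    return Xc / norms[:, None]


def correlation_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson correlation between rows of X; values in [0, 2]."""
    Z = standardize_rows(X)
    d = 1.0 - Z @ Z.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)
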