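"""Cross-validated Mahalanobis (crossnobis) RDM estimation.

The crossnobis distance whitens per-run condition betas by a shrinkage
estimate of the voxel noise covariance (from GLM residuals) and takes the
inner product of condition-difference patterns from *independent* runs.
Averaging over run pairs makes the estimator unbiased: with no true pattern
difference its expectation is zero, so entries may be negative.

Also provides the robustness procedures used alongside ROI results: the
mean-positivity check, permutation-based reliability voxel selection, and
across-participant noise ceilings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .inference import spearman_tc
from .rdm import RDM, from_upper_triangle

__all__ = [
    "NoiseCov",
    "shrinkage_covariance",
    "crossnobis_rdm",
    "crossnobis_from_whitened",
    "mean_rdm_positivity",
    "reliability_voxel_mask",
    "noise_ceilings",
]


@dataclass(frozen=True)
class NoiseCov:
    """Voxel noise covariance with diagonal-target shrinkage."""

    matrix: np.ndarray
    gamma: float
    dof: int

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def whitener(self) -> np.ndarray:
        """Symmetric inverse square root of the covariance."""
        vals, vecs = np.linalg.eigh(self.matrix)
        if vals.min() <= 0:
            raise np.linalg.LinAlgError("covariance not positive-definite")
        return (vecs / np.sqrt(vals)) @ vecs.T


def shrinkage_covariance(residuals: np.ndarray, gamma: float | str = "auto") -> NoiseCov:
    """Diagonal-target shrinkage covariance from GLM residuals.

    Sigma = (1 - gamma) * S + gamma * diag(S), with S the sample covariance
    of the time-by-voxel residuals.  ``gamma='auto'`` uses the analytic
    optimal weight (Schafer-Strimmer): the summed sampling variance of the
    off-diagonal covariances divided by their summed squares, clipped to
    [0, 1].  Zero-variance voxels trigger a warning and a small ridge.
    """
    r = np.asarray(residuals, dtype=float)
    t, p = r.shape
    if t < 2:
        raise ValueError("need more than one timepoint")
    xc = r - r.mean(axis=0)
    s = xc.T @ xc / (t - 1)

    if isinstance(gamma, str):
        if gamma != "auto":
            raise ValueError(f"unknown gamma {gamma!r}")
        # var of each covariance entry from the centered cross-products
        w = xc[:, :, None] * xc[:, None, :]          # t x p x p
        var_s = t / (t - 1) ** 3 * ((w - w.mean(axis=0)) ** 2).sum(axis=0)
        off = ~np.eye(p, dtype=bool)
        denom = (s[off] ** 2).sum()
        gamma_val = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0, 1))
    else:
        gamma_val = float(gamma)
        if not 0 <= gamma_val <= 1:
            raise ValueError("gamma must lie in [0, 1]")

    sigma = (1 - gamma_val) * s + gamma_val * np.diag(np.diag(s))
    zero_var = np.diag(s) <= 0
    if zero_var.any():
        warnings.warn(
            f"{zero_var.sum()} zero-variance voxel(s); adding ridge",
            RuntimeWarning,
        )
        sigma = sigma + np.eye(p) * max(1e-12, 1e-6 * np.diag(s).max())
    # guard: shrinkage target can still be near-singular for tiny t
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = sigma + np.eye(p) * 1e-8 * max(np.diag(sigma).max(), 1.0)
    return NoiseCov(matrix=sigma, gamma=gamma_val, dof=t - 1)


def crossnobis_rdm(betas: np.ndarray, cov: NoiseCov | list[NoiseCov] | None) -> RDM:
    """Cross-validated Mahalanobis RDM from per-run condition betas.

    Parameters
    ----------
    betas:
        Array of shape (runs, conditions, voxels).
    cov:
        A pooled :class:`NoiseCov`, one per run, or None for identity
        whitening (cross-validated squared Euclidean distance).

    The entry for conditions (i, j) is the mean over unordered run pairs
    (m, n) of ``(b_i^m - b_j^m)' W'W (b_i^n - b_j^n) / P`` where W is the
    whitener and P the voxel count; division by P makes values comparable
    across ROI sizes.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim != 3:
        raise ValueError("betas must be (runs, conditions, voxels)")
    n_runs, n_cond, n_vox = b.shape
    if n_runs < 2:
        raise ValueError("crossnobis needs at least 2 runs for cross-validation")
    if cov is None:
        white = b
    elif isinstance(cov, NoiseCov):
        white = b @ cov.whitener()
    else:
        if len(cov) != n_runs:
            raise ValueError("need one NoiseCov per run")
        white = np.stack([b[m] @ c.whitener() for m, c in zip(range(n_runs), cov)])
    return crossnobis_from_whitened(white, meta={"n_runs": n_runs, "n_voxels": n_vox})


def crossnobis_from_whitened(white: np.ndarray, meta: dict | None = None) -> RDM:
    """Crossnobis on already-whitened per-run patterns (runs x cond x vox)."""
    n_runs, n_cond, n_vox = white.shape
    vals = np.zeros((n_cond, n_cond))
    pairs = list(combinations(range(n_runs), 2))
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            d = white[:, i, :] - white[:, j, :]     # runs x vox
            cross = d @ d.T                          # runs x runs
            vals[i, j] = vals[j, i] = np.mean(
                [cross[m, n] for m, n in pairs]
            ) / n_vox
    meta = dict(meta or {})
    meta.setdefault("normalization", "per-voxel")
    return RDM(values=vals, meta=meta)


def mean_rdm_positivity(rdm: RDM) -> dict:
    """Mean of the six cross-validated distances and whether it is positive.

    Consistent condition patterns across runs push cross-validated distances
    positive; a non-positive mean flags an RDM dominated by noise.
    """
    m = float(rdm.vector.mean())
    return {"mean": m, "positive": m > 0}


def reliability_voxel_mask(
    betas: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permutation-based reliability voxel selection.

    A voxel's reliability is the Pearson correlation of its condition-
    response profile between the odd-run and even-run averages.  The null
    distribution per voxel comes from shuffling condition labels
    independently within each run; voxels whose observed reliability exceeds
    the (1 - alpha) null quantile are retained.
    """
    b = np.asarray(betas, dtype=float)
    n_runs, n_cond, n_vox = b.shape
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    if n_cond < 2:
        raise ValueError("reliability undefined with fewer than 2 conditions")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def split_half_r(x: np.ndarray) -> np.ndarray:
        odd = x[::2].mean(axis=0)    # cond x vox
        even = x[1::2].mean(axis=0)
        oc = odd - odd.mean(axis=0)
        ec = even - even.mean(axis=0)
        denom = np.sqrt((oc**2).sum(axis=0) * (ec**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (oc * ec).sum(axis=0) / denom
        return np.where(denom > 0, r, 0.0)

    observed = split_half_r(b)
    null = np.empty((n_perm, n_vox))
    for k in range(n_perm):
        shuffled = np.stack([b[r][rng.permutation(n_cond)] for r in range(n_runs)])
        null[k] = split_half_r(shuffled)
    thresh = np.quantile(null, 1 - alpha, axis=0)
    return observed > thresh


def noise_ceilings(subject_rdms: list[RDM]) -> dict:
    """Across-participant noise ceiling on the Spearman scale.

    Upper bound: mean over subjects of the tie-corrected Spearman between
    each subject's RDM vector and the group-mean vector (subject included).
    Lower bound: the same with the subject left out of the mean.
    """
    vectors = np.stack([r.vector for r in subject_rdms])
    n = len(vectors)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = vectors.mean(axis=0)
    upper = np.mean([spearman_tc(v, grand) for v in vectors])
    loo = (grand * n - vectors) / (n - 1)
    lower = np.mean([spearman_tc(v, m) for v, m in zip(vectors, loo)])
    return {"lower": float(lower), "upper": float(upper)}
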