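"""Model-neural RDM comparison and group-level inference.

Subject-level statistics are tie-corrected Spearman correlations between the
canonical 6-entry RDM vectors, optionally partialling out competing model
RDMs via the recursive partial-correlation formula applied to midrank
correlations.  Group-level inference Fisher z-transforms the per-subject
coefficients and applies a one-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "spearman_tc",
    "partial_spearman",
    "group_model_test",
    "bonferroni_alpha",
    "RsaResult",
    "rsa_subject",
]


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: a constant input."""


class DegenerateCovariateError(ValueError):
    """A covariate is perfectly rank-correlated with x or y."""


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.asarray(x, dtype=float), method="average")


def spearman_tc(x, y) -> float:
    """Tie-corrected Spearman rank correlation.

    Pearson correlation of midranks; ties receive average ranks, which is
    the standard tie correction (and what ``scipy.stats.spearmanr``
    computes).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length 1-D with n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise UndefinedCorrelationError("constant input")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def partial_spearman(x, y, covariates=(), rtol: float = 1e-8) -> float:
    """Rank partial correlation of x and y given covariate vectors.

    Applies the first-order recursion
    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``
    covariate by covariate on tie-corrected Spearman correlations.  The
    result is invariant to covariate order; this is asserted at runtime for
    multi-covariate calls (order sensitivity beyond round-off indicates a
    degenerate covariate set).
    """
    covariates = [np.asarray(c, float) for c in covariates]
    r = _partial_recursive(x, y, covariates)
    if len(covariates) > 1:
        r_rev = _partial_recursive(x, y, covariates[::-1])
        if not np.isclose(r, r_rev, atol=1e-6):
            raise DegenerateCovariateError(
                f"covariate order changes partial r ({r} vs {r_rev}); "
                "covariates are near-collinear in rank space"
            )
    return r


def _partial_recursive(x, y, covariates) -> float:
    if not covariates:
        return spearman_tc(x, y)
    z, rest = covariates[0], covariates[1:]
    r_xy = _partial_recursive(x, y, rest)
    r_xz = _partial_recursive(x, z, rest)
    r_yz = _partial_recursive(y, z, rest)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise DegenerateCovariateError(
            "covariate perfectly rank-correlated with an input"
        )
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def group_model_test(subject_r, side: str = "greater") -> dict:
    """One-sample t test on Fisher z-transformed subject correlations.

    Returns ``{"t", "p", "df", "mean_z"}``; ``side`` is ``'greater'`` (the
    directional hypothesis that the model is positively expressed) or
    ``'two-sided'``.
    """
    r = np.asarray(subject_r, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| = 1 gives infinite Fisher z")
    z = np.arctanh(r)
    alternative = {"greater": "greater", "two-sided": "two-sided"}[side]
    res = stats.ttest_1samp(z, popmean=0.0, alternative=alternative)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": len(r) - 1,
        "mean_z": float(z.mean()),
    }


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance level alpha / m."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class RsaResult:
    """Group RSA outcome for one model (optionally with covariates)."""

    model: str
    covariates: tuple[str, ...]
    subject_r: np.ndarray
    t: float
    p: float
    df: int
    side: str
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "covariates": list(self.covariates),
            "t": self.t,
            "p": self.p,
            "df": self.df,
            "side": self.side,
            "alpha": self.alpha,
            "mean_r": float(np.mean(self.subject_r)),
        }


def rsa_subject(neural_vector, model_vector, covariate_vectors=None) -> float:
    """Subject-level (partial) tie-corrected Spearman between a neural RDM
    vector and a model RDM vector."""
    covs = covariate_vectors or []
    return partial_spearman(model_vector, neural_vector, covs)


def rsa_group(
    neural_vectors,
    model_vector,
    covariate_vectors=None,
    model_name: str = "model",
    covariate_names: tuple[str, ...] = (),
    side: str = "greater",
    alpha: float = 0.05,
) -> RsaResult:
    """Run the subject-level (partial) correlation for every subject and the
    group-level one-sample t test on Fisher z scores.

    ``covariate_vectors`` may be shared 6-vectors or a per-subject list of
    lists (for subject-specific covariates such as reaction-time RDMs).
    """
    rs = []
    for i, nv in enumerate(neural_vectors):
        if covariate_vectors is None:
            covs = []
        elif covariate_vectors and np.ndim(covariate_vectors[0]) == 2:
            covs = list(covariate_vectors[i])  # per-subject covariates
        else:
            covs = list(covariate_vectors)
        rs.append(rsa_subject(nv, model_vector, covs))
    rs = np.asarray(rs)
    test = group_model_test(rs, side=side)
    return RsaResult(
        model=model_name,
        covariates=tuple(covariate_names),
        subject_r=rs,
        t=test["t"],
        p=test["p"],
        df=test["df"],
        side=side,
        alpha=alpha,
    )
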