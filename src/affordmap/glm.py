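"""First-level GLM: HRF, design matrices from events, and OLS beta/residual
extraction for the RSA stage.

Condition events are modeled as stick (zero-duration) regressors, one per
state, convolved with a canonical double-gamma hemodynamic response; visual
and motor nuisance events get their own regressors.  The fit is plain
ordinary least squares per voxel; residuals feed the noise-covariance
estimate used by the cross-validated Mahalanobis distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["hrf", "build_design_matrix", "fit_glm", "DesignMatrix", "GlmFit",
           "DesignSingularError"]


class DesignSingularError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix rank-deficient; offending columns: {self.columns}")


DEFAULT_HRF_PARAMS = {
    "peak_delay": 6.0,      # shape of the response gamma (unit scale)
    "undershoot_delay": 16.0,
    "undershoot_ratio": 1.0 / 6.0,
    "dispersion": 1.0,
}


def hrf(t, params: dict | None = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic response at times ``t`` (seconds).

    Difference of two gamma densities: a response peaking near 5 s and an
    undershoot scaled by ``undershoot_ratio``.  hrf(0) = 0 and the response
    has decayed to a fraction of a percent of its peak by ~32 s.
    """
    p = {**DEFAULT_HRF_PARAMS, **(params or {})}
    t = np.asarray(t, dtype=float)
    d = p["dispersion"]

    def gamma_pdf(x, shape):
        x = np.maximum(x, 0.0) / d
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp(
            (shape - 1) * np.log(x[pos]) - x[pos] - special.gammaln(shape)
        ) / d
        return out

    return gamma_pdf(t, p["peak_delay"]) - p["undershoot_ratio"] * gamma_pdf(
        t, p["undershoot_delay"]
    )


@dataclass
class DesignMatrix:
    """time x regressor design with labeled columns."""

    frame: pd.DataFrame
    tr: float
    condition_columns: list[str]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _convolved_regressor(
    onsets: np.ndarray,
    tr: float,
    n_vols: int,
    hrf_params: dict | None,
    dt: float = 0.1,
    hrf_length: float = 32.0,
) -> np.ndarray:
    """Stick events convolved with the HRF, sampled on the TR grid."""
    n_hi = int(np.ceil(n_vols * tr / dt)) + 1
    sticks = np.zeros(n_hi)
    idx = np.round(np.asarray(onsets) / dt).astype(int)
    np.add.at(sticks, idx, 1.0)
    kernel = hrf(np.arange(0, hrf_length, dt), hrf_params)
    conv = np.convolve(sticks, kernel)[:n_hi]
    sample_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return conv[sample_idx]


def build_design_matrix(
    events: pd.DataFrame,
    tr: float,
    n_vols: int,
    hrf_params: dict | None = None,
    extra_regressors: pd.DataFrame | None = None,
    n_drift_cosines: int = 0,
    dt: float = 0.1,
) -> DesignMatrix:
    """Design matrix from a BIDS-style events table.

    One stick regressor per ``trial_type`` (state conditions and nuisance
    event types alike), HRF-convolved and sampled at the TR grid, plus
    optional continuous regressors (e.g., motion), optional low-frequency
    cosine drift columns, and an intercept.

    Raises :class:`DesignSingularError` when the result is rank-deficient,
    naming the offending (all-zero or collinear) columns.
    """
    onset_arr = events["onset"].to_numpy(dtype=float)
    if (onset_arr >= n_vols * tr).any():
        raise ValueError("event onsets beyond the acquired run")
    types = events["trial_type"].to_numpy()
    cols = {}
    for tt in pd.unique(types):
        cols[str(tt)] = _convolved_regressor(
            onset_arr[types == tt], tr, n_vols, hrf_params, dt=dt
        )
    frame = pd.DataFrame(cols)
    if extra_regressors is not None:
        if len(extra_regressors) != n_vols:
            raise ValueError("extra regressors must have n_vols rows")
        frame = pd.concat([frame, extra_regressors.reset_index(drop=True)], axis=1)
    grid = np.arange(n_vols)
    for k in range(1, n_drift_cosines + 1):
        frame[f"drift_cos{k}"] = np.cos(np.pi * k * (grid + 0.5) / n_vols)
    frame["intercept"] = 1.0
    x = frame.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = [c for c in frame.columns if np.allclose(frame[c], 0)]
        if not bad:  # collinear but no all-zero column: name near-dependent ones
            _, r = np.linalg.qr(x)
            bad = [frame.columns[i] for i in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
        raise DesignSingularError(bad)
    condition_cols = [c for c in frame.columns if c.startswith("state")]
    return DesignMatrix(frame=frame, tr=tr, condition_columns=condition_cols)


@dataclass
class GlmFit:
    """OLS fit: condition betas, nuisance betas, residuals, and dof."""

    betas: pd.DataFrame          # condition x voxel
    nuisance_betas: pd.DataFrame
    residuals: np.ndarray        # time x voxel
    dof: int

    @property
    def condition_betas(self) -> np.ndarray:
        return self.betas.to_numpy()


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary-least-squares fit of ``bold`` (time x voxel) on the design.

    Per-voxel fits are independent; residuals are orthogonal to every design
    column up to numerical precision.
    """
    x = design.matrix
    bold = np.asarray(bold, dtype=float)
    if bold.shape[0] != x.shape[0]:
        raise ValueError(
            f"time dimension mismatch: bold {bold.shape[0]} vs design {x.shape[0]}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise DesignSingularError(design.columns)
    coef, *_ = np.linalg.lstsq(x, bold, rcond=None)
    resid = bold - x @ coef
    all_betas = pd.DataFrame(coef, index=design.columns)
    cond = design.condition_columns
    nuis = [c for c in design.columns if c not in cond]
    return GlmFit(
        betas=all_betas.loc[cond],
        nuisance_betas=all_betas.loc[nuis],
        residuals=resid,
        dof=bold.shape[0] - rank,
    )
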