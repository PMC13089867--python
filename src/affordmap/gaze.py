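"""Eyetracking analysis: blink scrubbing, epoching, condition timecourses,
lateralization, cluster-based permutation inference, and the statistics
linking gaze to behavior and to neural RDMs.

The pipeline follows the standard fixation-timecourse recipe: blinks are
masked with a 100 ms buffer on each side, the two eyes are averaged into a
cyclopean signal, trials are cut into [-500, 2500] ms epochs around
stimulus onset, per-condition median timecourses are lightly smoothed with
a truncated Gaussian kernel, and the state-2 minus state-3 difference in x
is tested across subjects with a one-sample-t cluster permutation test
using sign flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rdm import RDM

__all__ = [
    "CleanGaze",
    "GazeEpochs",
    "Cluster",
    "ClusterResult",
    "preprocess_gaze",
    "epoch_gaze",
    "condition_timecourses",
    "lateralization_timecourse",
    "cluster_permutation_test",
    "cluster_median_shift",
    "window_median_lateralization",
    "paired_lateralization_test",
    "brain_gaze_link",
    "performance_correlation",
    "plot_lateralization",
    "EPOCH_WINDOW_MS",
]

EPOCH_WINDOW_MS = (-500.0, 2500.0)


class NoValidSamplesError(ValueError):
    """Every sample in the stream is blink-masked."""


@dataclass
class CleanGaze:
    """Cyclopean gaze after blink scrubbing (NaN where masked)."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    hz: float


def preprocess_gaze(stream, blink_buffer_ms: float = 100.0) -> CleanGaze:
    """Scrub blinks (with a buffer on both sides, boundary-inclusive) and
    average the two eyes into a single (x, y) per sample."""
    t = np.asarray(stream.t_ms, dtype=float)
    blink = np.asarray(stream.blink, dtype=bool)
    missing = blink.copy()
    if blink.any():
        n_buf = int(round(blink_buffer_ms * stream.hz / 1000.0))
        if n_buf > 0:
            # dilate the blink mask by n_buf samples on each side
            kernel = np.ones(2 * n_buf + 1, dtype=bool)
            missing = np.convolve(blink, kernel, mode="same") > 0
    if missing.all():
        raise NoValidSamplesError("no valid samples after blink scrubbing")
    x = (np.asarray(stream.xl, float) + np.asarray(stream.xr, float)) / 2.0
    y = (np.asarray(stream.yl, float) + np.asarray(stream.yr, float)) / 2.0
    x = np.where(missing, np.nan, x)
    y = np.where(missing, np.nan, y)
    return CleanGaze(t_ms=t, x=x, y=y, missing=missing, hz=stream.hz)


@dataclass
class GazeEpochs:
    """Per-trial epochs on a fixed grid around stimulus onset.

    ``data`` has shape (trials, samples, 2) for (x, y); ``mask`` is True
    where a sample was blink-scrubbed or outside the recording.
    """

    data: np.ndarray
    mask: np.ndarray
    conditions: np.ndarray
    times_ms: np.ndarray
    hz: float


def epoch_gaze(
    clean: CleanGaze,
    onsets_s: np.ndarray,
    conditions: np.ndarray,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
) -> GazeEpochs:
    """Cut the cleaned stream into trials.

    Alignment is exact: a sample recorded k ms after onset lands at the
    epoch index for +k ms.  Samples outside the recording are masked.
    """
    dt_ms = 1000.0 / clean.hz
    rel = np.arange(window_ms[0], window_ms[1] + dt_ms / 2, dt_ms)
    n_t = len(rel)
    n_trials = len(onsets_s)
    data = np.full((n_trials, n_t, 2), np.nan)
    mask = np.ones((n_trials, n_t), dtype=bool)
    n = len(clean.t_ms)
    t0 = clean.t_ms[0]
    for i, onset in enumerate(np.asarray(onsets_s, float)):
        onset_idx = int(round((onset * 1000.0 - t0) / dt_ms))
        lo = onset_idx + int(round(window_ms[0] / dt_ms))
        idx = lo + np.arange(n_t)
        valid = (idx >= 0) & (idx < n)
        data[i, valid, 0] = clean.x[idx[valid]]
        data[i, valid, 1] = clean.y[idx[valid]]
        mask[i, valid] = np.isnan(clean.x[idx[valid]])
    return GazeEpochs(
        data=data,
        mask=mask,
        conditions=np.asarray(conditions),
        times_ms=rel,
        hz=clean.hz,
    )


def _truncated_gaussian_kernel(sigma_ms: float, max_window_ms: float, dt_ms: float):
    half = int(np.floor((max_window_ms / 2.0) / dt_ms))
    t = np.arange(-half, half + 1) * dt_ms
    k = np.exp(-0.5 * (t / sigma_ms) ** 2)
    return k / k.sum()


def _smooth_nan(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve ignoring NaNs; output NaN where the local kernel mass is 0."""
    valid = ~np.isnan(x)
    filled = np.where(valid, x, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    return out


def condition_timecourses(
    epochs: GazeEpochs,
    sigma_ms: float = 4.25,
    max_window_ms: float = 20.0,
) -> dict[int, np.ndarray]:
    """Median-across-trials timecourse per condition, lightly smoothed.

    Per timepoint the median is over that condition's unmasked samples (no
    interpolation); the temporal smoothing kernel is a Gaussian of
    sigma = 4.25 ms truncated to a 20 ms total support and renormalized.
    Returns condition -> (samples, 2) array for (x, y).
    """
    dt_ms = 1000.0 / epochs.hz
    kernel = _truncated_gaussian_kernel(sigma_ms, max_window_ms, dt_ms)
    out = {}
    for cond in np.unique(epochs.conditions):
        sel = epochs.conditions == cond
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(epochs.data[sel], axis=0)  # samples x 2
        smoothed = np.column_stack(
            [_smooth_nan(med[:, 0], kernel), _smooth_nan(med[:, 1], kernel)]
        )
        out[int(cond)] = smoothed
    return out


def lateralization_timecourse(tc_pos: np.ndarray, tc_neg: np.ndarray) -> np.ndarray:
    """x difference (positive-affording minus negative-affording state).

    Positive values mean a rightward skew for the state affording positive
    actions.
    """
    tc_pos, tc_neg = np.asarray(tc_pos, float), np.asarray(tc_neg, float)
    if tc_pos.shape != tc_neg.shape:
        raise ValueError("time grids do not match")
    return tc_pos - tc_neg


# ---------------------------------------------------------------------------
# Cluster permutation


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p: float
    indices: np.ndarray = field(repr=False, default=None)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    tail: str
    threshold: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < 0.05]


def _t_timecourse(data: np.ndarray) -> np.ndarray:
    """Per-timepoint one-sample t across subjects (rows)."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _clusters_above(t: np.ndarray, threshold: float) -> list[np.ndarray]:
    above = t > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(t))
    return [np.arange(s, e) for s, e in zip(starts, ends)]


def _max_cluster_masses(t_rows: np.ndarray, threshold: float) -> np.ndarray:
    """Maximum supra-threshold cluster mass per row, vectorized over rows."""
    above = t_rows > threshold
    vals = np.where(above, t_rows, 0.0)
    cs = np.cumsum(vals, axis=1)
    padded = np.pad(above, ((0, 0), (1, 1)))
    start_mask = padded[:, 1:-1] & ~padded[:, :-2]
    end_mask = padded[:, 1:-1] & ~padded[:, 2:]
    r_s, c_s = np.where(start_mask)
    r_e, c_e = np.where(end_mask)   # aligned with starts in row-major order
    masses = cs[r_e, c_e] - cs[r_s, c_s] + vals[r_s, c_s]
    out = np.zeros(t_rows.shape[0])
    np.maximum.at(out, r_s, masses)
    return out


def cluster_permutation_test(
    subject_diffs: np.ndarray,
    times_ms: np.ndarray | None = None,
    n_perm: int = 10_000,
    tail: str = "greater",
    cluster_threshold: float | None = None,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """One-sample cluster permutation test on subject timecourses.

    Per-timepoint one-sample t values above the cluster-forming threshold
    (default: the one-tailed p = 0.05 critical t at df = n-1) are grouped
    into contiguous clusters scored by summed t.  The null distribution of
    the maximum cluster mass comes from random per-subject sign flips;
    p = (1 + #{null >= observed}) / (1 + n_perm), so p is never exactly 0.
    """
    data = np.asarray(subject_diffs, dtype=float)
    if data.ndim != 2:
        raise ValueError("subject_diffs must be subjects x time")
    n_sub, n_time = data.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail != "greater":
        raise NotImplementedError("only the one-tailed 'greater' test is provided")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if times_ms is None:
        times_ms = np.arange(n_time, dtype=float)
    times_ms = np.asarray(times_ms, float)
    if cluster_threshold is None:
        cluster_threshold = float(stats.t.ppf(0.95, df=n_sub - 1))

    t_obs = _t_timecourse(data)
    cluster_idx = _clusters_above(t_obs, cluster_threshold)
    masses = np.array([t_obs[c].sum() for c in cluster_idx])

    # Sign-flip null: under flips the per-timepoint mean square is fixed,
    # so t can be recomputed from flipped means alone.
    msq = (data**2).mean(axis=0)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_max = np.zeros(n_perm)
    chunk = max(1, int(2e7 // max(n_time, 1)))
    for s in range(0, n_perm, chunk):
        f = flips[s : s + chunk]
        means = f @ data / n_sub                      # perms x time
        var = (msq - means**2) * n_sub / (n_sub - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_null = means / np.sqrt(var / n_sub)
        t_null = np.nan_to_num(t_null)
        null_max[s : s + len(f)] = _max_cluster_masses(t_null, cluster_threshold)

    clusters = []
    for c, mass in zip(cluster_idx, masses):
        p = (1 + np.sum(null_max >= mass)) / (1 + n_perm)
        clusters.append(
            Cluster(
                start_ms=float(times_ms[c[0]]),
                end_ms=float(times_ms[c[-1]]),
                mass=float(mass),
                p=float(p),
                indices=c,
            )
        )
    clusters.sort(key=lambda c: c.start_ms)
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_perm,
        tail=tail,
        threshold=float(cluster_threshold),
    )


def cluster_median_shift(
    subject_diff: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
) -> float:
    """Median lateralization over the cluster window: the per-subject effect
    size."""
    times_ms = np.asarray(times_ms, float)
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("empty cluster window")
    return float(np.nanmedian(np.asarray(subject_diff, float)[sel]))


def window_median_lateralization(
    trial_x: list[np.ndarray] | np.ndarray,
    conditions: np.ndarray,
    times_ms: np.ndarray,
    window_center_ms: float,
    window_s: float = 1.0,
    pair: tuple[int, int] = (2, 3),
) -> dict:
    """Trial-median gaze lateralization in a fixed window (the procedure used
    on low-rate gaze estimates such as decoded fMRI gaze).

    Per trial: median x inside a ``window_s``-long window centered on the
    cluster; per condition: median across trials.  Returns the per-condition
    medians per subject-call plus the difference for the requested pair.
    """
    x = np.asarray(trial_x, float)
    conditions = np.asarray(conditions)
    times_ms = np.asarray(times_ms, float)
    half = window_s * 1000.0 / 2.0
    sel = (times_ms >= window_center_ms - half) & (times_ms <= window_center_ms + half)
    if not sel.any():
        raise ValueError("window outside the epoch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        trial_medians = np.nanmedian(x[:, sel], axis=1)
    out = {}
    for cond in pair:
        vals = trial_medians[conditions == cond]
        if len(vals) == 0:
            raise ValueError(f"no trials for condition {cond}")
        out[cond] = float(np.nanmedian(vals))
    out["difference"] = out[pair[0]] - out[pair[1]]
    return out


def paired_lateralization_test(per_subject: list[dict], pair=(2, 3)) -> dict:
    """One-sided paired t test that condition ``pair[0]`` medians are further
    right than ``pair[1]`` across subjects."""
    a = np.array([d[pair[0]] for d in per_subject])
    b = np.array([d[pair[1]] for d in per_subject])
    if len(a) < 2:
        raise ValueError("need at least 2 subjects")
    res = stats.ttest_rel(a, b, alternative="greater")
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": len(a) - 1}


def brain_gaze_link(
    subject_rdms: list[RDM],
    gaze_shifts,
    pair: tuple[int, int] = (2, 3),
    normalization: str = "rms",
) -> dict:
    """Correlate normalized neural distance for a condition pair with the
    per-subject gaze lateralization.

    Each subject's RDM vector is normalized (default: divided by its root
    mean square, making the extracted entry invariant to overall RDM scale)
    before the (pair) entry is correlated with the gaze shifts (Pearson,
    two-sided).
    """
    shifts = np.asarray(gaze_shifts, float)
    if len(subject_rdms) != len(shifts):
        raise ValueError("subject lists do not match")
    if len(shifts) < 3:
        raise ValueError("need at least 3 subjects")
    dist = np.array(
        [r.normalized(normalization).entry(*pair) for r in subject_rdms]
    )
    if np.std(dist) == 0 or np.std(shifts) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(dist, shifts)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


def performance_correlation(shifts, probe_accuracy) -> dict:
    """Pearson correlation between gaze lateralization strength and probe
    performance (two-sided)."""
    shifts = np.asarray(shifts, float)
    acc = np.asarray(probe_accuracy, float)
    if shifts.shape != acc.shape or len(shifts) < 3:
        raise ValueError("need matched lists with n >= 3")
    if np.std(shifts) == 0 or np.std(acc) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(shifts, acc)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


def plot_lateralization(
    times_ms: np.ndarray,
    subject_diffs: np.ndarray,
    result: ClusterResult | None = None,
    path=None,
):
    """Group lateralization timecourse with significant clusters shaded.

    Returns the matplotlib figure; writes SVG/PNG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.asarray(subject_diffs, float)
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.axhline(0, color="0.6", lw=0.8)
    ax.fill_between(times_ms, mean - sem, mean + sem, alpha=0.3, lw=0)
    ax.plot(times_ms, mean, lw=1.2)
    if result is not None:
        for c in result.significant:
            ax.axvspan(c.start_ms, c.end_ms, color="tab:orange", alpha=0.2)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("x difference: positive − negative\naffording state (px)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
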