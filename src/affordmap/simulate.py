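"""Synthetic participants: multivoxel BOLD runs, gaze streams, and probe
behavior with known ground truth.

The generator mirrors the study conditions: 8 fMRI runs (4 eyetracker runs)
of 80 trials with 16 probes each, four states whose pattern geometry is a
weighted mixture of the model RDMs, gaze that lateralizes for the
positive- versus negative-affording states inside a fixed post-onset
window, and probe reaction times that depend on state.  Every dataset
carries the parameters that generated it so downstream estimates can be
checked against truth rather than against other estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from . import rdm as rdm_mod
from .glm import DesignMatrix, build_design_matrix
from .graph import StateActionGraph, TrialSequence, generate_run_sequence

__all__ = [
    "GenerativeConfig",
    "SubjectDataset",
    "GazeStream",
    "embed_geometry",
    "NotEuclideanEmbeddableError",
    "simulate_subject_fmri",
    "simulate_subject_gaze",
    "simulate_behavior",
    "simulate_subject",
    "mixture_distance_matrix",
    "write_subject_data",
    "load_bold_runs",
]


class NotEuclideanEmbeddableError(ValueError):
    """The requested RDM mixture is not a valid squared-distance matrix."""


@dataclass(frozen=True)
class GenerativeConfig:
    """Ground-truth parameters for one synthetic cohort.

    Defaults follow the study conditions: 8 fMRI runs of 80 trials (16
    probes) at TR = 1 s, ~140 voxels (a right entorhinal ROI), four
    eyetracker runs at 1,000 Hz with the lateralization window at
    899-1,757 ms after onset, and probe response windows of 1.4 s (fMRI) /
    1.2 s (eyetracker).
    """

    n_subjects: int = 57
    n_runs: int = 8
    n_trials: int = 80
    n_probe: int = 16
    n_voxels: int = 140
    tr: float = 1.0
    geometry_weights: dict = field(
        default_factory=lambda: {"affordance": 1.0, "linkdist": 0.0, "magnitude": 0.0}
    )
    signal_scale: float = 0.7
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    spatial_lengthscale: float = 2.0   # voxels; 0 -> diagonal noise
    run_jitter_sd: float = 0.0
    nuisance_amplitude: float = 1.0
    # gaze branch
    gaze_runs: int = 4
    gaze_hz: float = 1000.0
    gaze_shift: float = 15.0                 # pixels, per state (state2 +, state3 -)
    gaze_window_ms: tuple[float, float] = (899.0, 1757.0)
    gaze_ramp_ms: float = 100.0
    gaze_noise_sd: float = 25.0              # pixels, slow fixational drift
    gaze_measurement_sd: float = 3.0         # pixels, white per-eye jitter
    blink_rate_hz: float = 0.25
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    screen_center: tuple[float, float] = (960.0, 540.0)
    # behavior
    rt_means: dict = field(
        default_factory=lambda: {1: 0.60, 2: 0.66, 3: 0.66, 4: 0.60}
    )
    rt_sd: float = 0.12
    probe_accuracy: float = 0.85

    def validate(self) -> list[str]:
        problems = []
        if not all(np.isfinite(list(self.geometry_weights.values()))):
            problems.append("geometry weights must be finite")
        lo, hi = self.gaze_window_ms
        if not (-500 <= lo < hi <= 2500):
            problems.append("gaze window must lie within the [-500, 2500] ms epoch")
        if not 0 <= self.probe_accuracy <= 1:
            problems.append("probe accuracy must be a probability")
        if not -1 < self.ar_coef < 1:
            problems.append("AR(1) coefficient must lie in (-1, 1)")
        return problems

    def with_(self, **kwargs) -> "GenerativeConfig":
        return replace(self, **kwargs)


@dataclass
class GazeStream:
    """Binocular gaze samples with blink flags (times in ms)."""

    t_ms: np.ndarray
    xl: np.ndarray
    yl: np.ndarray
    xr: np.ndarray
    yr: np.ndarray
    blink: np.ndarray
    hz: float
    screen_center: tuple[float, float] = (960.0, 540.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.t_ms,
                "xl": self.xl,
                "yl": self.yl,
                "xr": self.xr,
                "yr": self.yr,
                "blink": self.blink.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.3f")

    @classmethod
    def from_tsv(cls, path, hz: float = 1000.0) -> "GazeStream":
        df = pd.read_csv(path, sep="\t")
        return cls(
            t_ms=df["time_ms"].to_numpy(float),
            xl=df["xl"].to_numpy(float),
            yl=df["yl"].to_numpy(float),
            xr=df["xr"].to_numpy(float),
            yr=df["yr"].to_numpy(float),
            blink=df["blink"].to_numpy(bool),
            hz=hz,
        )


@dataclass
class SubjectDataset:
    """One simulated participant with retained ground truth."""

    subject_id: int
    graph: StateActionGraph
    config: GenerativeConfig
    sequences: list[TrialSequence] = field(default_factory=list)
    bold_runs: list[np.ndarray] = field(default_factory=list)
    designs: list[DesignMatrix] = field(default_factory=list)
    gaze_sequences: list[TrialSequence] = field(default_factory=list)
    gaze_streams: list[GazeStream] = field(default_factory=list)
    behavior: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pattern geometry


def mixture_distance_matrix(graph: StateActionGraph, weights: dict) -> np.ndarray:
    """Weighted sum of the model RDMs, interpreted as squared distances."""
    builders = {
        "affordance": rdm_mod.affordance_rdm,
        "linkdist": rdm_mod.linkdist_rdm,
        "magnitude": rdm_mod.magnitude_rdm,
    }
    total = np.zeros((4, 4))
    for name, w in weights.items():
        if name not in builders:
            raise KeyError(f"unknown geometry component {name!r}")
        if w:
            total = total + w * builders[name](graph).values
    return total


def embed_geometry(
    target: np.ndarray,
    n_voxels: int,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Condition patterns (4 x n_voxels) whose pairwise squared Euclidean
    distances equal ``scale * target``.

    Classical multidimensional scaling: double-center the squared-distance
    matrix, eigendecompose, and embed the (at most 3) positive dimensions
    into voxel space through a seeded random orthonormal basis, so the
    geometry spreads over all voxels while patterns stay centered across
    conditions.  A negative eigenvalue beyond tolerance means the mixture is
    not realizable as a Euclidean configuration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = scale * np.asarray(target, dtype=float)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(gram)
    if vals.min() < -tol * max(vals.max(), 1.0):
        raise NotEuclideanEmbeddableError(
            f"mixture has negative Gram eigenvalue {vals.min():.3e}"
        )
    keep = vals > tol * max(vals.max(), 1.0)
    coords = vecs[:, keep] * np.sqrt(np.clip(vals[keep], 0, None))
    k = coords.shape[1]
    if k > n_voxels:
        raise ValueError(f"need at least {k} voxels to embed the geometry")
    if k == 0:
        return np.zeros((n, n_voxels))
    q, _ = np.linalg.qr(rng.standard_normal((n_voxels, k)))
    return coords @ q.T


# ---------------------------------------------------------------------------
# BOLD


def _spatial_cholesky(config: GenerativeConfig) -> np.ndarray | None:
    if config.spatial_lengthscale <= 0:
        return None
    idx = np.arange(config.n_voxels)
    k = np.exp(-np.abs(idx[:, None] - idx[None, :]) / config.spatial_lengthscale)
    try:
        return np.linalg.cholesky(k)
    except np.linalg.LinAlgError as err:
        raise ValueError("voxel covariance not positive-definite") from err


def _ar1_noise(
    n_t: int, n_v: int, config: GenerativeConfig, chol: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    z = rng.standard_normal((n_t + 50, n_v))
    if chol is not None:
        z = z @ chol.T
    a = config.ar_coef
    e = sp_signal.lfilter([np.sqrt(1 - a**2)], [1.0, -a], z, axis=0)
    return config.noise_sd * e[50:]


def simulate_subject_fmri(
    graph: StateActionGraph,
    config: GenerativeConfig,
    seed: int | np.random.Generator = 0,
    subject_id: int = 0,
) -> SubjectDataset:
    """Simulate the fMRI branch of one participant.

    Per run: a counterbalanced trial sequence, a design matrix with state
    stick regressors plus a probe nuisance regressor, BOLD = design x
    (ground-truth patterns + run-wise jitter) + AR(1) noise with optionally
    spatially correlated voxels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = mixture_distance_matrix(graph, config.geometry_weights)
    patterns = embed_geometry(target, config.n_voxels, config.signal_scale, seed=rng)
    chol = _spatial_cholesky(config)

    ds = SubjectDataset(subject_id=subject_id, graph=graph, config=config)
    ds.truth = {
        "patterns": patterns,
        "geometry_weights": dict(config.geometry_weights),
        "signal_scale": config.signal_scale,
    }
    for run in range(config.n_runs):
        seq = generate_run_sequence(
            graph,
            session="fmri",
            n_trials=config.n_trials,
            n_probe=config.n_probe,
            seed=rng,
            run_id=run,
        )
        events = seq.trials
        n_vols = int(np.ceil((events["onset"].max() + 16.0) / config.tr))
        design = build_design_matrix(events, tr=config.tr, n_vols=n_vols)
        run_patterns = patterns + config.run_jitter_sd * rng.standard_normal(
            patterns.shape
        )
        # amplitude matrix aligned with design columns: condition patterns,
        # random nuisance amplitudes, zero intercept
        columns = design.columns
        cond_order = {c: i for i, c in enumerate(sorted(design.condition_columns))}
        amps = np.zeros((len(columns), config.n_voxels))
        for k, col in enumerate(columns):
            if col in cond_order:
                amps[k] = run_patterns[cond_order[col]]
            elif col != "intercept":
                amps[k] = config.nuisance_amplitude * rng.standard_normal(
                    config.n_voxels
                )
        bold = design.matrix @ amps
        bold += _ar1_noise(n_vols, config.n_voxels, config, chol, rng)
        ds.sequences.append(seq)
        ds.designs.append(design)
        ds.bold_runs.append(bold)
    return ds


# ---------------------------------------------------------------------------
# Gaze


def _ramped_window(
    t_ms: np.ndarray, onset_ms: float, window: tuple[float, float], ramp: float
) -> np.ndarray:
    """Trapezoidal profile: 0 outside [w0, w1], linear 100-ms ramps inside
    the window edges, 1 in the flat middle."""
    lo, hi = onset_ms + window[0], onset_ms + window[1]
    up = np.clip((t_ms - lo) / ramp, 0.0, 1.0)
    down = np.clip((hi - t_ms) / ramp, 0.0, 1.0)
    return np.minimum(up, down) * ((t_ms >= lo) & (t_ms <= hi))


def simulate_subject_gaze(
    sequence: TrialSequence,
    config: GenerativeConfig,
    seed: int | np.random.Generator = 0,
    shift: float | None = None,
) -> GazeStream:
    """Simulate one run's binocular gaze stream.

    The common (cyclopean) signal is slow fixational drift around screen
    center; state-2 stimulus trials add +shift and state-3 trials -shift on
    x inside the configured post-onset window with linear ramps.  Each eye
    sees the common signal plus independent white jitter; blinks are
    Poisson-placed flagged gaps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = config.gaze_shift if shift is None else shift
    fs = config.gaze_hz
    dt_ms = 1000.0 / fs
    events = sequence.stimulus_trials
    dur_ms = (events["onset"].max() + 4.0) * 1000.0
    n = int(np.ceil(dur_ms / dt_ms))
    t_ms = np.arange(n) * dt_ms

    def drift() -> np.ndarray:
        # white noise smoothed to ~50 ms scale, rescaled to the target sd
        w = rng.standard_normal(n)
        s = gaussian_filter1d(w, sigma=max(0.050 * fs, 1.0))
        sd = s.std()
        return config.gaze_noise_sd * s / sd if sd > 0 else s

    x = drift() + config.screen_center[0]
    y = drift() + config.screen_center[1]
    for _, tr_row in events.iterrows():
        state = int(tr_row["state"])
        if state not in (2, 3):
            continue
        sign = 1.0 if state == 2 else -1.0
        x += (
            sign
            * shift
            * _ramped_window(
                t_ms, tr_row["onset"] * 1000.0, config.gaze_window_ms,
                config.gaze_ramp_ms,
            )
        )

    jit = config.gaze_measurement_sd
    xl = x + jit * rng.standard_normal(n)
    xr = x + jit * rng.standard_normal(n)
    yl = y + jit * rng.standard_normal(n)
    yr = y + jit * rng.standard_normal(n)

    blink = np.zeros(n, dtype=bool)
    if config.blink_rate_hz > 0:
        n_blinks = rng.poisson(config.blink_rate_hz * dur_ms / 1000.0)
        starts = rng.uniform(0, dur_ms, size=n_blinks)
        durs = rng.uniform(*config.blink_duration_ms, size=n_blinks)
        for s, d in zip(starts, durs):
            i0, i1 = int(s / dt_ms), int((s + d) / dt_ms)
            blink[i0 : min(i1 + 1, n)] = True

    return GazeStream(
        t_ms=t_ms, xl=xl, yl=yl, xr=xr, yr=yr, blink=blink, hz=fs,
        screen_center=config.screen_center,
    )


# ---------------------------------------------------------------------------
# Behavior


def simulate_behavior(
    config: GenerativeConfig,
    sequences: list[TrialSequence],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Probe-trial responses: Bernoulli accuracy and state-dependent RTs.

    RTs are Gaussian around the per-state mean; draws beyond the response
    window count as missed responses (flagged, RT set to NaN), so recorded
    RTs never exceed the window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for seq in sequences:
        probes = seq.probe_trials
        if probes.empty:
            raise ValueError(f"run {seq.run_id} has no probe trials")
        for _, p in probes.iterrows():
            state = int(p["state"])
            rt = config.rt_means[state] + config.rt_sd * rng.standard_normal()
            rt = max(rt, 0.05)
            window = float(p["response_window"])
            missed = rt > window
            correct = bool(rng.random() < config.probe_accuracy) and not missed
            rows.append(
                dict(
                    run=seq.run_id,
                    trial=int(p["index"]),
                    state=state,
                    number=int(p["number"]),
                    probe_correct_pair=bool(p["probe_correct"]),
                    response_correct=correct,
                    rt=np.nan if missed else rt,
                    missed=missed,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole subject


def simulate_subject(
    graph: StateActionGraph,
    config: GenerativeConfig,
    seed: int | np.random.Generator = 0,
    subject_id: int = 0,
    fmri: bool = True,
    gaze: bool = True,
) -> SubjectDataset:
    """Simulate a full participant: fMRI runs, eyetracker runs, behavior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fmri:
        ds = simulate_subject_fmri(graph, config, seed=rng, subject_id=subject_id)
    else:
        ds = SubjectDataset(subject_id=subject_id, graph=graph, config=config)
        ds.truth = {
            "geometry_weights": dict(config.geometry_weights),
            "signal_scale": config.signal_scale,
        }
    if gaze:
        per_subject_shift = config.gaze_shift
        ds.truth["gaze_shift"] = per_subject_shift
        for run in range(config.gaze_runs):
            seq = generate_run_sequence(
                graph,
                session="eyetracker",
                n_trials=config.n_trials,
                n_probe=config.n_probe,
                seed=rng,
                run_id=run,
            )
            ds.gaze_sequences.append(seq)
            ds.gaze_streams.append(
                simulate_subject_gaze(seq, config, seed=rng, shift=per_subject_shift)
            )
    all_seqs = ds.sequences + ds.gaze_sequences
    if all_seqs:
        ds.behavior = simulate_behavior(config, all_seqs, seed=rng)
    return ds


# ---------------------------------------------------------------------------
# Persistence


def write_subject_data(ds: SubjectDataset, out_dir, bold_format: str = "npz") -> None:
    """Write one subject's data as plain files.

    Per fMRI run: ``sub-XX_run-YY_events.tsv`` and BOLD as NPZ
    (``bold`` array, time x voxel) or a 4D NIfTI (voxels unfolded on the
    first axis).  Per eyetracker run: gaze TSV.  Behavior as CSV; the task
    graph as JSON.
    """
    from pathlib import Path

    from .graph import write_events_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = f"sub-{ds.subject_id:02d}"
    (out / f"{sid}_graph.json").write_text(ds.graph.to_json())
    for seq, bold in zip(ds.sequences, ds.bold_runs):
        stem = f"{sid}_task-recall_run-{seq.run_id:02d}"
        write_events_tsv(seq, out / f"{stem}_events.tsv")
        if bold_format == "npz":
            np.savez(out / f"{stem}_bold.npz", bold=bold)
        elif bold_format == "nifti":
            import nibabel as nib

            img = nib.Nifti1Image(
                bold.T[:, None, None, :].astype(np.float32), affine=np.eye(4)
            )
            nib.save(img, out / f"{stem}_bold.nii")
        else:
            raise ValueError(f"unknown bold format {bold_format!r}")
    for seq, stream in zip(ds.gaze_sequences, ds.gaze_streams):
        stem = f"{sid}_task-recall_run-{seq.run_id:02d}"
        write_events_tsv(seq, out / f"{stem}_eyetrack_events.tsv")
        stream.to_tsv(out / f"{stem}_gaze.tsv")
    if ds.behavior is not None:
        ds.behavior.to_csv(out / f"{sid}_behavior.csv", index=False)


def load_bold_runs(out_dir, subject_id: int) -> list[np.ndarray]:
    """Load the NPZ BOLD runs written by :func:`write_subject_data`."""
    from pathlib import Path

    sid = f"sub-{subject_id:02d}"
    paths = sorted(Path(out_dir).glob(f"{sid}_task-recall_run-*_bold.npz"))
    return [np.load(p)["bold"] for p in paths]
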