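"""End-to-end orchestration: simulate a cohort, run the fMRI and gaze
branches, and assemble a report.

The stage order mirrors the experimental analysis: trial design -> GLM ->
crossnobis RDM -> model comparison with partial correlations -> group test;
and for gaze: scrub -> epoch -> condition medians -> lateralization ->
cluster permutation -> per-subject effect sizes -> correlations with
behavior and with the neural RDMs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gaze as gz
from . import inference, rdm as rdm_mod
from .crossnobis import crossnobis_rdm, mean_rdm_positivity, noise_ceilings, shrinkage_covariance
from .glm import fit_glm
from .graph import StateActionGraph, build_graph
from .rdm import RDM
from .simulate import GenerativeConfig, SubjectDataset, simulate_subject

__all__ = [
    "PipelineConfig",
    "Report",
    "run_pipeline",
    "validate_config",
    "analyze_subject_fmri",
    "analyze_subject_gaze",
    "analyze_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one synthetic-cohort analysis."""

    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    seed: int = 0
    graph_offset: int = 21
    graph_modules: int = 36
    n_perm: int = 10_000
    alpha: float = 0.05
    n_hemispheres: int = 2          # Bonferroni family for the main model
    covariates: tuple[str, ...] = ("linkdist", "magnitude")
    run_fmri: bool = True
    run_gaze: bool = True
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generative", {})
        if isinstance(gen, dict):
            for key in ("geometry_weights", "rt_means"):
                if key in gen and isinstance(gen[key], dict):
                    gen[key] = {int(k) if str(k).isdigit() else k: v
                                for k, v in gen[key].items()}
            for key in ("gaze_window_ms", "blink_duration_ms", "screen_center"):
                if key in gen and isinstance(gen[key], list):
                    gen[key] = tuple(gen[key])
            gen = GenerativeConfig(**gen)
        if "covariates" in d and isinstance(d["covariates"], list):
            d["covariates"] = tuple(d["covariates"])
        return cls(generative=gen, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema and cross-field checks; returns a list of diagnostics (empty
    when the configuration is valid)."""
    diags = list(config.generative.validate())
    if config.seed is None:
        diags.append("seed must be set explicitly")
    if config.n_perm < 1:
        diags.append("n_perm must be >= 1")
    if not (0 < config.alpha < 1):
        diags.append("alpha must be in (0, 1)")
    if config.generative.n_probe > config.generative.n_trials:
        diags.append("probe count exceeds trial count")
    unknown = set(config.covariates) - {"linkdist", "magnitude", "rt", "gaze"}
    if unknown:
        diags.append(f"unknown covariates {sorted(unknown)}")
    return diags


@dataclass
class Report:
    """All group statistics plus per-subject tables and provenance."""

    config_hash: str
    seed: int
    subject_rdms: list[RDM] = field(default_factory=list)
    subject_r: dict = field(default_factory=dict)
    group_tests: dict = field(default_factory=dict)
    rdm_positivity: dict | None = None
    noise_ceiling: dict | None = None
    cluster: dict | None = None
    gaze_shifts: list[float] = field(default_factory=list)
    probe_accuracy: list[float] = field(default_factory=list)
    performance_corr: dict | None = None
    brain_gaze: dict | None = None
    recovery: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o

        return clean(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "subject_rdm_vectors": [r.vector for r in self.subject_rdms],
                "subject_r": self.subject_r,
                "group_tests": self.group_tests,
                "rdm_positivity": self.rdm_positivity,
                "noise_ceiling": self.noise_ceiling,
                "cluster": self.cluster,
                "gaze_shifts": self.gaze_shifts,
                "probe_accuracy": self.probe_accuracy,
                "performance_corr": self.performance_corr,
                "brain_gaze": self.brain_gaze,
                "recovery": self.recovery,
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Subject-level analyses


def analyze_subject_fmri(ds: SubjectDataset, per_run_cov: bool = True) -> dict:
    """GLM betas -> shrinkage noise covariance -> crossnobis RDM, plus the
    subject's reaction-time RDM from fMRI-session probe behavior."""
    betas, covs = [], []
    for bold, design in zip(ds.bold_runs, ds.designs):
        fit = fit_glm(bold, design)
        b = fit.betas.loc[sorted(design.condition_columns)].to_numpy()
        betas.append(b)
        covs.append(shrinkage_covariance(fit.residuals))
    betas = np.stack(betas)
    cov = covs if per_run_cov else covs[0]
    neural = crossnobis_rdm(betas, cov)

    rt_rdm = None
    if ds.behavior is not None:
        fmri_runs = {s.run_id for s in ds.sequences}
        beh = ds.behavior[
            ds.behavior["run"].isin(fmri_runs) & ~ds.behavior["missed"]
        ]
        means = beh.groupby("state")["rt"].mean().to_dict()
        if len(means) == 4:
            rt_rdm = rdm_mod.behavior_rdm(means, metric="absdiff")
    return {"neural_rdm": neural, "rt_rdm": rt_rdm, "betas": betas}


def analyze_subject_gaze(ds: SubjectDataset) -> dict:
    """Scrub, epoch, and reduce one subject's eyetracker runs to condition
    timecourses and the state-2 minus state-3 x lateralization."""
    all_data, all_mask, all_cond = [], [], []
    times = None
    hz = None
    for seq, stream in zip(ds.gaze_sequences, ds.gaze_streams):
        clean = gz.preprocess_gaze(stream)
        stim = seq.stimulus_trials
        epochs = gz.epoch_gaze(
            clean, stim["onset"].to_numpy(), stim["state"].to_numpy()
        )
        all_data.append(epochs.data)
        all_mask.append(epochs.mask)
        all_cond.append(epochs.conditions)
        times, hz = epochs.times_ms, epochs.hz
    merged = gz.GazeEpochs(
        data=np.concatenate(all_data),
        mask=np.concatenate(all_mask),
        conditions=np.concatenate(all_cond),
        times_ms=times,
        hz=hz,
    )
    tcs = gz.condition_timecourses(merged)
    diff = gz.lateralization_timecourse(tcs[2][:, 0], tcs[3][:, 0])
    return {"epochs": merged, "timecourses": tcs, "diff": diff, "times_ms": times}


def _probe_accuracy(ds: SubjectDataset, runs: set[int]) -> float:
    beh = ds.behavior[ds.behavior["run"].isin(runs)]
    return float(beh["response_correct"].mean())


# ---------------------------------------------------------------------------
# Cohort


def analyze_cohort(
    datasets: list[SubjectDataset],
    config: PipelineConfig,
    seed: int | None = None,
) -> Report:
    """Run every enabled analysis stage on an already-simulated cohort."""
    seed = config.seed if seed is None else seed
    report = Report(config_hash=config_hash(config), seed=seed)
    graph = datasets[0].graph

    if config.run_fmri and datasets[0].bold_runs:
        model_vecs = {
            "affordance": rdm_mod.affordance_rdm(graph).vector,
            "linkdist": rdm_mod.linkdist_rdm(graph).vector,
            "magnitude": rdm_mod.magnitude_rdm(graph).vector,
        }
        neural_vecs, rt_vecs = [], []
        for ds in datasets:
            sub = analyze_subject_fmri(ds)
            report.subject_rdms.append(sub["neural_rdm"])
            neural_vecs.append(sub["neural_rdm"].vector)
            rt_vecs.append(None if sub["rt_rdm"] is None else sub["rt_rdm"].vector)

        shared_covs = [model_vecs[c] for c in config.covariates if c in model_vecs]
        subject_r = []
        for i, nv in enumerate(neural_vecs):
            covs = list(shared_covs)
            if "rt" in config.covariates and rt_vecs[i] is not None:
                covs.append(rt_vecs[i])
            subject_r.append(inference.partial_spearman(model_vecs["affordance"], nv, covs))
        report.subject_r["affordance"] = subject_r
        test = inference.group_model_test(subject_r, side="greater")
        test["alpha"] = inference.bonferroni_alpha(config.alpha, config.n_hemispheres)
        test["significant"] = test["p"] < test["alpha"]
        report.group_tests["affordance_partial"] = test

        pos = [mean_rdm_positivity(r) for r in report.subject_rdms]
        report.rdm_positivity = {
            "fraction_positive": float(np.mean([p["positive"] for p in pos])),
            "mean_of_means": float(np.mean([p["mean"] for p in pos])),
        }
        if len(report.subject_rdms) >= 3:
            try:
                report.noise_ceiling = noise_ceilings(report.subject_rdms)
            except Exception:
                report.noise_ceiling = None

        truth_w = datasets[0].truth.get("geometry_weights", {})
        if truth_w.get("affordance", 0) > 0 and datasets[0].config.signal_scale > 0:
            report.recovery["mean_affordance_r"] = float(np.mean(subject_r))

    if config.run_gaze and datasets[0].gaze_streams:
        diffs, times = [], None
        for ds in datasets:
            sub = analyze_subject_gaze(ds)
            diffs.append(sub["diff"])
            times = sub["times_ms"]
        diffs = np.stack(diffs)
        cluster = gz.cluster_permutation_test(
            np.nan_to_num(diffs),
            times_ms=times,
            n_perm=config.n_perm,
            seed=seed + 1,
        )
        sig = cluster.significant
        report.cluster = {
            "threshold": cluster.threshold,
            "n_permutations": cluster.n_permutations,
            "clusters": [
                {"start_ms": c.start_ms, "end_ms": c.end_ms, "mass": c.mass, "p": c.p}
                for c in cluster.clusters
            ],
        }
        if sig:
            window = (sig[0].start_ms, sig[0].end_ms)
            report.cluster["window_ms"] = list(window)
            shifts = [
                gz.cluster_median_shift(d, times, window) for d in diffs
            ]
            report.gaze_shifts = [float(s) for s in shifts]
            gaze_runs = {s.run_id for s in datasets[0].gaze_sequences}
            acc = [_probe_accuracy(ds, gaze_runs) for ds in datasets]
            report.probe_accuracy = acc
            try:
                report.performance_corr = gz.performance_correlation(shifts, acc)
            except ValueError:
                report.performance_corr = None
            if report.subject_rdms:
                try:
                    report.brain_gaze = gz.brain_gaze_link(
                        report.subject_rdms, shifts
                    )
                except ValueError:
                    report.brain_gaze = None
    return report


def run_pipeline(config: PipelineConfig) -> Report:
    """Simulate a cohort under ``config`` and run every enabled stage.

    Fully deterministic in the seed: the report hash is a pure function of
    the configuration.
    """
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid configuration: " + "; ".join(diags))
    gen = config.generative
    graph = build_graph(config.graph_offset, config.graph_modules)
    datasets = []
    root = np.random.SeedSequence(config.seed)
    for sid, child in enumerate(root.spawn(gen.n_subjects)):
        datasets.append(
            simulate_subject(
                graph,
                gen,
                seed=np.random.default_rng(child),
                subject_id=sid,
                fmri=config.run_fmri,
                gaze=config.run_gaze,
            )
        )
    report = analyze_cohort(datasets, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        config.to_yaml(out / "config.yaml")
    return report


def config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
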