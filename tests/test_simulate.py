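"""Synthetic-data generator: geometry embedding, BOLD, gaze, behavior."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform, pdist

from affordmap import simulate as sim
from affordmap.glm import fit_glm
from affordmap.rdm import affordance_rdm, behavior_rdm
from affordmap.simulate import GenerativeConfig


class TestEmbedGeometry:
    def test_affordance_distances_recovered(self, graph):
        target = affordance_rdm(graph).values
        pats = sim.embed_geometry(target, n_voxels=30, scale=1.0, seed=0)
        d2 = squareform(pdist(pats)) ** 2
        np.testing.assert_allclose(d2, target, atol=1e-9)

    def test_scale_multiplies_squared_distances(self, graph):
        target = affordance_rdm(graph).values
        pats = sim.embed_geometry(target, n_voxels=12, scale=2.5, seed=1)
        d2 = squareform(pdist(pats)) ** 2
        np.testing.assert_allclose(d2, 2.5 * target, atol=1e-9)

    def test_zero_scale_collapses_patterns(self, graph):
        pats = sim.embed_geometry(affordance_rdm(graph).values, 10, scale=0.0)
        assert np.allclose(pats, pats[0])

    def test_patterns_centered(self, graph):
        pats = sim.embed_geometry(affordance_rdm(graph).values, 20, seed=3)
        assert np.allclose(pats.mean(axis=0), 0, atol=1e-12)

    def test_non_embeddable_mixture_rejected(self):
        bad = np.array(
            [[0, 1, 4, 1], [1, 0, 1, 4], [4, 1, 0, 1], [1, 4, 1, 0]], dtype=float
        )
        # square with both diagonals short: violates the triangle structure
        with pytest.raises(sim.NotEuclideanEmbeddableError):
            sim.embed_geometry(bad, 10)


class TestSimulateFmri:
    def test_noiseless_beta_recovery(self, graph):
        cfg = GenerativeConfig(
            n_runs=2, n_trials=20, n_probe=4, n_voxels=10,
            signal_scale=1.0, noise_sd=0.0, nuisance_amplitude=0.0,
            run_jitter_sd=0.0, spatial_lengthscale=0.0,
        )
        ds = sim.simulate_subject_fmri(graph, cfg, seed=4)
        fit = fit_glm(ds.bold_runs[0], ds.designs[0])
        recovered = fit.betas.loc[sorted(ds.designs[0].condition_columns)].to_numpy()
        np.testing.assert_allclose(recovered, ds.truth["patterns"], atol=1e-6)

    def test_seed_determinism(self, graph, small_fmri_config):
        a = sim.simulate_subject_fmri(graph, small_fmri_config, seed=9)
        b = sim.simulate_subject_fmri(graph, small_fmri_config, seed=9)
        for ra, rb in zip(a.bold_runs, b.bold_runs):
            np.testing.assert_array_equal(ra, rb)

    def test_truth_retained(self, graph, small_fmri_config):
        ds = sim.simulate_subject_fmri(graph, small_fmri_config, seed=2)
        assert ds.truth["signal_scale"] == small_fmri_config.signal_scale
        assert ds.truth["patterns"].shape == (4, small_fmri_config.n_voxels)

    def test_events_align_with_bold(self, graph, small_fmri_config):
        ds = sim.simulate_subject_fmri(graph, small_fmri_config, seed=2)
        for seq, bold in zip(ds.sequences, ds.bold_runs):
            assert seq.trials["onset"].max() < bold.shape[0] * small_fmri_config.tr


class TestSimulateGaze:
    @pytest.fixture()
    def sequence(self, graph):
        from affordmap.graph import generate_run_sequence

        return generate_run_sequence(
            graph, "eyetracker", n_trials=20, n_probe=4, seed=0
        )

    def test_shift_applied_in_window(self, graph, sequence):
        cfg = GenerativeConfig(
            gaze_hz=500.0, gaze_shift=40.0, gaze_noise_sd=0.0,
            gaze_measurement_sd=0.0, blink_rate_hz=0.0,
        )
        stream = sim.simulate_subject_gaze(sequence, cfg, seed=1)
        stim = sequence.stimulus_trials
        t2 = stim[stim["state"] == 2].iloc[0]["onset"] * 1000
        t3 = stim[stim["state"] == 3].iloc[0]["onset"] * 1000
        mid = lambda t0: np.argmin(np.abs(stream.t_ms - (t0 + 1300)))
        x = (stream.xl + stream.xr) / 2
        assert x[mid(t2)] - cfg.screen_center[0] == pytest.approx(40.0, abs=1e-6)
        assert x[mid(t3)] - cfg.screen_center[0] == pytest.approx(-40.0, abs=1e-6)
        before = np.argmin(np.abs(stream.t_ms - (t2 + 200)))  # before the window
        assert x[before] - cfg.screen_center[0] == pytest.approx(0.0, abs=1e-6)

    def test_zero_blink_rate_no_gaps(self, sequence):
        cfg = GenerativeConfig(gaze_hz=500.0, blink_rate_hz=0.0)
        stream = sim.simulate_subject_gaze(sequence, cfg, seed=2)
        assert not stream.blink.any()

    def test_blinks_flagged(self, sequence):
        cfg = GenerativeConfig(gaze_hz=500.0, blink_rate_hz=1.0)
        stream = sim.simulate_subject_gaze(sequence, cfg, seed=3)
        assert stream.blink.any()

    def test_tsv_roundtrip(self, sequence, tmp_path):
        cfg = GenerativeConfig(gaze_hz=500.0)
        stream = sim.simulate_subject_gaze(sequence, cfg, seed=4)
        stream.to_tsv(tmp_path / "gaze.tsv")
        back = sim.GazeStream.from_tsv(tmp_path / "gaze.tsv", hz=500.0)
        np.testing.assert_allclose(back.xl, stream.xl, atol=1e-3)
        np.testing.assert_array_equal(back.blink, stream.blink)


class TestSimulateBehavior:
    @pytest.fixture()
    def sequences(self, graph):
        from affordmap.graph import generate_run_sequence

        return [
            generate_run_sequence(graph, "fmri", n_trials=40, n_probe=8, seed=s)
            for s in range(3)
        ]

    def test_perfect_accuracy(self, sequences):
        cfg = GenerativeConfig(probe_accuracy=1.0, rt_sd=0.0)
        beh = sim.simulate_behavior(cfg, sequences, seed=0)
        assert beh[~beh["missed"]]["response_correct"].all()

    def test_rts_within_response_window(self, sequences):
        cfg = GenerativeConfig(rt_sd=0.5)
        beh = sim.simulate_behavior(cfg, sequences, seed=1)
        recorded = beh[~beh["missed"]]
        assert (recorded["rt"] <= 1.4 + 1e-9).all()
        assert beh["missed"].any()  # wide RT spread produces some misses

    def test_rt_rdm_recovers_state_structure(self, graph):
        from affordmap.graph import generate_run_sequence

        seqs = [
            generate_run_sequence(graph, "fmri", n_trials=80, n_probe=16, seed=s)
            for s in range(40)
        ]
        cfg = GenerativeConfig(
            rt_means={1: 0.5, 2: 0.7, 3: 0.7, 4: 0.5}, rt_sd=0.02
        )
        beh = sim.simulate_behavior(cfg, seqs, seed=2)
        means = beh[~beh["missed"]].groupby("state")["rt"].mean().to_dict()
        rdm = behavior_rdm(means, metric="absdiff")
        expected = np.array([0.2, 0.2, 0.0, 0.0, 0.2, 0.2])
        np.testing.assert_allclose(rdm.vector, expected, atol=0.02)


class TestConfigValidation:
    def test_default_config_valid(self):
        assert GenerativeConfig().validate() == []

    def test_bad_window_flagged(self):
        cfg = GenerativeConfig(gaze_window_ms=(100.0, 3000.0))
        assert any("window" in p for p in cfg.validate())


class TestPersistence:
    def test_subject_data_roundtrip(self, graph, small_fmri_config, tmp_path):
        ds = sim.simulate_subject(graph, small_fmri_config, seed=11, subject_id=3)
        sim.write_subject_data(ds, tmp_path)
        assert (tmp_path / "sub-03_graph.json").exists()
        back = sim.load_bold_runs(tmp_path, subject_id=3)
        assert len(back) == small_fmri_config.n_runs
        for a, b in zip(back, ds.bold_runs):
            np.testing.assert_array_equal(a, b)

    def test_nifti_export(self, graph, tmp_path):
        import nibabel as nib

        cfg = GenerativeConfig(
            n_runs=2, n_trials=12, n_probe=4, n_voxels=8, gaze_runs=0
        )
        ds = sim.simulate_subject(graph, cfg, seed=1, gaze=False)
        sim.write_subject_data(ds, tmp_path, bold_format="nifti")
        img = nib.load(tmp_path / "sub-00_task-recall_run-00_bold.nii")
        assert img.shape[0] == 8  # voxels unfolded on the first axis
        assert img.shape[-1] == ds.bold_runs[0].shape[0]
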