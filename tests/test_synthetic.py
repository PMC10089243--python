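"""Synthetic-experiment generator: structure, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

import serialdep as sd
from serialdep.circstats import rayleigh_uniform_test
from serialdep.simulate import envelope, read_trial_table, write_trial_table


class TestTrialTable:
    def test_structure_and_block_layout(self):
        t = sd.generate_trial_table(400, 50, seed=1)
        assert len(t) == 400
        assert t["block_index"].nunique() == 8
        assert t["prev_target_ori"].isna().sum() == 8  # one per block start
        # orientation domain and cue/target consistency
        for col in ("ori1", "ori2", "target_ori"):
            vals = t[col].dropna()
            assert ((vals >= 0) & (vals < 180)).all()
        rf = t["cue"] == "report_first"
        assert np.allclose(t.loc[rf, "target_ori"], t.loc[rf, "ori1"])
        assert np.allclose(t.loc[~rf, "target_ori"], t.loc[~rf, "ori2"])
        one = t["n_items"] == 1
        assert (t.loc[one, ["ori1", "ori2"]].isna().sum(axis=1) == 1).all()
        assert t.loc[~one, ["ori1", "ori2"]].notna().all().all()

    def test_condition_mix_degenerate(self):
        t = sd.generate_trial_table(100, 50, (1, 0, 0, 0), seed=0)
        assert (t["cue"] == "report_first").all() and (t["n_items"] == 2).all()

    def test_determinism(self):
        a = sd.generate_trial_table(100, 50, seed=7)
        b = sd.generate_trial_table(100, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = sd.generate_trial_table(100, 50, seed=8)
        assert not np.allclose(a["ori1"], c["ori1"])

    def test_orientations_uniform(self):
        t = sd.generate_trial_table(2500, 50, (1, 0, 0, 0), seed=3)
        for col in ("ori1", "ori2"):
            _, p = sd.kuiper_uniform_test(t[col].to_numpy())
            assert p > 0.01

    @pytest.mark.parametrize(
        "kwargs", [dict(n_trials=0), dict(n_trials=10, condition_mix=(0.5, 0.5, 0.5, 0.5))]
    )
    def test_rejects_bad_arguments(self, kwargs):
        with pytest.raises(ValueError):
            sd.generate_trial_table(**{"block_size": 50, **kwargs})

    def test_csv_roundtrip(self, tmp_path):
        t = sd.generate_trial_table(60, 20, seed=2)
        t = sd.generate_behavior(t, sd.BehaviorParams(), seed=2)
        write_trial_table(t, tmp_path / "trials.csv")
        back = read_trial_table(tmp_path / "trials.csv")
        pd.testing.assert_frame_equal(t[back.columns], back, check_dtype=False)


class TestBehaviorGeneration:
    def test_noiseless_unbiased_reproduces_target(self):
        t = sd.generate_trial_table(50, 50, seed=0)
        p = sd.BehaviorParams(kappa=np.inf, p_target=1, p_guess=0, p_swap=0,
                              attract_amp=0, repulse_amp=0)
        out = sd.generate_behavior(t, p, seed=0)
        assert np.allclose(out["response"], out["target_ori"])

    def test_dog_peak_bias_exact(self):
        # a single between-trial inducer at delta=+25 with amp 3, width 25
        t = sd.generate_trial_table(4, 4, (0, 0, 1, 0), seed=0)
        t.loc[1, "prev_target_ori"] = (t.loc[1, "target_ori"] + 25) % 180
        p = sd.BehaviorParams(kappa=np.inf, p_target=1, p_guess=0, p_swap=0,
                              attract_amp=3, attract_width=25, repulse_amp=0)
        out = sd.generate_behavior(t, p, seed=0)
        err = sd.circular_error(out.loc[1, "response"], out.loc[1, "target_ori"])
        assert err == pytest.approx(3.0, abs=1e-9)

    def test_pure_guessing_is_uniform(self):
        t = sd.generate_trial_table(2000, 2000, seed=1)
        p = sd.BehaviorParams(kappa=8, p_target=0, p_guess=1, p_swap=0)
        out = sd.generate_behavior(t, p, seed=1)
        _, pval = rayleigh_uniform_test(out["response"].to_numpy())
        assert pval > 0.01

    def test_missing_target_rejected(self):
        t = sd.generate_trial_table(20, 20, seed=0)
        t.loc[3, "target_ori"] = np.nan
        with pytest.raises(ValueError):
            sd.generate_behavior(t, sd.BehaviorParams(), seed=0)


class TestEpochs:
    def test_envelope_shape(self):
        p = sd.NeuralParams(signal_onset=0.05, signal_peak=0.15, signal_offset=0.7)
        t = np.array([-0.1, 0.05, 0.10, 0.15, 0.425, 0.7, 0.75])
        h = envelope(t, p)
        assert h == pytest.approx([0, 0, 0.5, 1.0, 0.5, 0.0, 0.0])

    def test_invalid_envelope_rejected(self):
        with pytest.raises(ValueError):
            sd.NeuralParams(signal_onset=0.3, signal_peak=0.2, signal_offset=0.7)

    def test_deterministic_and_noise_only_when_absent(self):
        t = sd.generate_trial_table(20, 20, (0, 0, 1, 0), seed=4)  # grating2 absent
        p = sd.NeuralParams(n_channels=8, sfreq=50.0, t_start=-0.1, t_end=0.75, seed=4)
        a = sd.generate_epochs(t, p, "grating2")
        b = sd.generate_epochs(t, p, "grating2")
        assert np.array_equal(a.data, b.data)
        # grating 2 never shown: epochs carry no envelope-locked pattern
        u, v = sd.generate_patterns(p)
        proj = np.einsum("tcs,c->ts", a.data, u)
        h = envelope(a.times, p)
        corr = np.corrcoef(np.abs(proj).mean(axis=0), h)[0, 1]
        assert abs(corr) < 0.5

    def test_encoding_shift_rule(self):
        # inducer 30 deg clockwise, shift 10 in range (10,50] -> encoded theta-10
        t = sd.generate_trial_table(6, 6, (0, 0, 1, 0), seed=0)
        t["prev_target_ori"] = (t["ori1"] + 30) % 180
        p = sd.NeuralParams(n_channels=8, sfreq=50.0, t_start=-0.1, t_end=0.75,
                            noise_sd=0.0, snr=1.0, repulse_shift=10.0,
                            shift_range=(10.0, 50.0), shift_inducer="prev_target", seed=0)
        ep = sd.generate_epochs(t, p, "grating1")
        u, v = sd.generate_patterns(p)
        peak = np.argmin(np.abs(ep.times - p.signal_peak))
        enc = np.degrees(np.arctan2(ep.data[:, :, peak] @ v, ep.data[:, :, peak] @ u)) / 2
        expected = sd.signed_diff(t["ori1"] - 10.0, 0.0)
        assert np.allclose(sd.signed_diff(enc, expected), 0.0, atol=1e-8)

        # shift of zero leaves the encoded orientation untouched
        p0 = sd.NeuralParams(n_channels=8, sfreq=50.0, t_start=-0.1, t_end=0.75,
                             noise_sd=0.0, snr=1.0, repulse_shift=0.0, seed=0)
        ep0 = sd.generate_epochs(t, p0, "grating1")
        enc0 = np.degrees(np.arctan2(ep0.data[:, :, peak] @ v, ep0.data[:, :, peak] @ u)) / 2
        assert np.allclose(sd.signed_diff(enc0, t["ori1"]), 0.0, atol=1e-8)

    def test_container_roundtrip(self, tmp_path):
        t = sd.generate_trial_table(10, 10, seed=0)
        p = sd.NeuralParams(n_channels=8, sfreq=50.0, t_start=-0.1, t_end=0.75, seed=0)
        ep = sd.generate_epochs(t, p, "grating2")
        path = ep.save(tmp_path / "ep")
        back = sd.EpochsData.load(path)
        assert np.array_equal(ep.data, back.data)
        assert back.channel_types == ep.channel_types
        assert back.info["which_event"] == "grating2"

    def test_from_mne_adapter(self):
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(0)
        info = mne.create_info(["A1", "A2", "A3"], sfreq=100.0, ch_types="eeg")
        arr = mne.EpochsArray(rng.normal(size=(4, 3, 20)), info, tmin=-0.05, verbose=False)
        ep = sd.EpochsData.from_mne(arr)
        assert ep.n_trials == 4 and ep.n_channels == 3
        assert ep.channel_types == ["generic"] * 3
        assert ep.sfreq == 100.0
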