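import numpy as np
import pytest

import serialdep as sd


@pytest.fixture(scope="session")
def small_neural_params():
    """Desk-scale epoch generator settings shared across decoding tests."""
    return dict(
        n_channels=16,
        sfreq=100.0,
        t_start=-0.1,
        t_end=0.75,
        snr=1.0,
        noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def tuned_run(small_neural_params):
    """One simulated session with a repulsive encoding shift, decoded once.

    Shared by decoding and neural-bias tests: 240 one-item report-first
    trials (grating 1 only), 16 channels, encoding shifted 10 degrees away
    from the previous trial's target.
    """
    tab = sd.generate_trial_table(240, 60, (0, 0, 1, 0), seed=5)
    npar = sd.NeuralParams(
        repulse_shift=10.0,
        shift_range=(0.0, 60.0),
        shift_inducer="prev_target",
        seed=5,
        **small_neural_params,
    )
    epochs = sd.generate_epochs(tab, npar, "grating1")
    feats = sd.build_features(epochs, window_len=10).crop(0.25, 0.60, decim=3)
    labels = tab["ori1"].to_numpy(dtype=float)
    ev = sd.decode_cv(feats, labels, sd.ClassBins(10), seed=1)
    rel = sd.align_evidence(ev, labels)
    return {"table": tab, "params": npar, "epochs": epochs, "labels": labels,
            "evidence": ev, "rel": rel}
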