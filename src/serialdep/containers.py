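"""In-memory and on-disk containers for epoched multichannel recordings.

``EpochsData`` is a lightweight trials x channels x time container with the
metadata the decoding pipeline needs (sampling rate, time axis, channel types
and 3-D positions).  It is serialized as an ``.npz`` archive plus a JSON
sidecar holding free-form provenance (e.g. generator parameters), and can be
imported from MNE-Python epochs when that package is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHANNEL_TYPES = ("gradiometer", "magnetometer", "generic")


@dataclass
class EpochsData:
    """Epoched multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Signal values (field units; channel-type scaling is applied later,
        at feature construction).
    times : ndarray
        Time axis in seconds, strictly increasing, uniformly spaced at
        ``1/sfreq``.
    sfreq : float
        Sampling frequency in Hz.
    channel_names, channel_types : list of str
        Per-channel labels; types are drawn from
        ``{"gradiometer", "magnetometer", "generic"}``.
    channel_positions : ndarray, shape (n_channels, 3)
        Sensor positions (arbitrary units) used by searchlight analyses.
    info : dict
        Free-form provenance (generation parameters, event name, ...).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_names: list
    channel_types: list
    channel_positions: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if self.times.shape != (n_t,):
            raise ValueError("times length does not match data")
        if len(self.channel_names) != n_ch or len(self.channel_types) != n_ch:
            raise ValueError("channel metadata length does not match data")
        if self.channel_positions.shape != (n_ch, 3):
            raise ValueError("channel_positions must be (n_channels, 3)")
        for t in self.channel_types:
            if t not in CHANNEL_TYPES:
                raise ValueError(f"unknown channel type {t!r}")
        if n_t > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sfreq, atol=1e-6):
                raise ValueError("times must be uniform at 1/sfreq and increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def n_times(self):
        return self.data.shape[2]

    def save(self, path):
        """Write to ``<path>.npz`` plus ``<path>.json`` sidecar."""
        path = Path(path)
        if path.suffix == ".npz":
            path = path.with_suffix("")
        np.savez(
            path.with_suffix(".npz"),
            data=self.data,
            times=self.times,
            sfreq=np.asarray(self.sfreq),
            channel_names=np.asarray(self.channel_names),
            channel_types=np.asarray(self.channel_types),
            channel_positions=self.channel_positions,
        )
        path.with_suffix(".json").write_text(json.dumps(self.info, indent=2, default=str))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path):
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        with np.load(path, allow_pickle=False) as f:
            data = f["data"]
            times = f["times"]
            sfreq = float(f["sfreq"])
            names = [str(x) for x in f["channel_names"]]
            types = [str(x) for x in f["channel_types"]]
            pos = f["channel_positions"]
        sidecar = path.with_suffix(".json")
        info = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data, times, sfreq, names, types, pos, info)

    @classmethod
    def from_mne(cls, epochs):
        """Adapt an MNE ``Epochs``/``EpochsArray`` object.

        MNE channel types ``grad``/``mag`` map to gradiometer/magnetometer;
        anything else becomes ``generic``.  Requires ``mne`` to be installed.
        """
        import mne  # local import: optional dependency

        type_map = {"grad": "gradiometer", "mag": "magnetometer"}
        data = epochs.get_data(copy=True)
        ch_types = [type_map.get(t, "generic") for t in epochs.get_channel_types()]
        pos = np.array([ch["loc"][:3] for ch in epochs.info["chs"]], dtype=float)
        return cls(
            data=data,
            times=epochs.times.copy(),
            sfreq=float(epochs.info["sfreq"]),
            channel_names=list(epochs.ch_names),
            channel_types=ch_types,
            channel_positions=pos,
            info={"source": "mne", "mne_version": mne.__version__},
        )
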