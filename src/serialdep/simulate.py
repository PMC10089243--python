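"""Synthetic experiments: trial tables, biased responses, orientation-tuned epochs.

Emulates a two-grating continuous-report working-memory study: on each trial
up to two gratings with independent uniform orientations in [0, 180) are
shown, a cue selects which one to reproduce, and trials run in blocks.  The
generator plants *known* biases so every downstream analysis has a
parameter-recovery surface:

* behavioral responses follow a target/swap/guess von Mises mixture with an
  attractive difference-of-Gaussians (DoG) pull toward the previous trial's
  target and a repulsive DoG push away from the same-trial nontarget;
* multichannel epochs carry an orientation-tuned two-dimensional sensor
  pattern (cos/sin of the doubled angle) under a piecewise-linear
  stimulus-locked envelope, with an optional repulsive *encoding* shift away
  from an inducer orientation and an optional (typically sign-reversed)
  lingering trace of the previous target.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .circstats import dog, signed_diff, vonmises_ori_noise, wrap_ori
from .containers import EpochsData

#: Condition order used by ``condition_mix``:
#: (cue, number of items).  One-item report-first trials show only grating 1;
#: one-item report-second trials show only grating 2 (the cue is always valid).
CONDITIONS = (
    ("report_first", 2),
    ("report_second", 2),
    ("report_first", 1),
    ("report_second", 1),
)

TRIAL_COLUMNS = [
    "trial_index",
    "block_index",
    "ori1",
    "ori2",
    "cue",
    "n_items",
    "target_ori",
    "nontarget_ori",
    "response",
    "prev_target_ori",
    "prev_nontarget_ori",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Response-model parameters.

    ``kappa`` is the von Mises concentration on the doubled-angle circle
    (``np.inf`` = noiseless).  ``p_target/p_guess/p_swap`` are the mixture
    weights (must sum to 1); swaps center on the same-trial nontarget only.
    DoG amplitudes are in degrees of peak bias, widths in degrees; the
    attractive term pulls toward the previous trial's target, the repulsive
    term pushes away from the same-trial nontarget.
    """

    kappa: float = 8.0
    p_target: float = 0.9
    p_guess: float = 0.067
    p_swap: float = 0.033
    attract_amp: float = 1.5
    attract_width: float = 30.0
    repulse_amp: float = 1.0
    repulse_width: float = 25.0

    def __post_init__(self):
        probs = (self.p_target, self.p_guess, self.p_swap)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("mixture probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("p_target + p_guess + p_swap must sum to 1")
        if self.attract_width <= 0 or self.repulse_width <= 0:
            raise ValueError("DoG widths must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class NeuralParams:
    """Epoch-generator parameters.

    The tuned pattern has amplitude ``snr`` against i.i.d. Gaussian sensor
    noise of SD ``noise_sd`` per sample, under a piecewise-linear envelope
    rising from ``signal_onset`` to 1 at ``signal_peak`` and back to 0 at
    ``signal_offset`` (seconds).  ``repulse_shift`` (degrees) displaces the
    *encoded* orientation away from the inducer when the absolute
    inducer-stimulus distance falls in ``shift_range``; ``shift_inducer``
    selects the inducer ("prev_target" or "same_trial").  ``linger_amp`` adds
    a pattern at the previous target's orientation (negative = sign-reversed
    trace).  ``n_pattern_channels`` optionally confines the tuned pattern to
    the first k channels (searchlight localization tests).
    """

    n_channels: int = 32
    sfreq: float = 100.0
    t_start: float = -0.2
    t_end: float = 0.8
    signal_onset: float = 0.05
    signal_peak: float = 0.15
    signal_offset: float = 0.7
    snr: float = 1.0
    repulse_shift: float = 0.0
    shift_range: tuple = (0.0, 60.0)
    shift_inducer: str = "prev_target"
    linger_amp: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    n_pattern_channels: Optional[int] = None

    def __post_init__(self):
        if self.n_channels < 8:
            raise ValueError("n_channels must be >= 8")
        if not (self.t_start < self.signal_onset < self.signal_peak < self.signal_offset <= self.t_end):
            raise ValueError(
                "envelope must satisfy t_start < signal_onset < signal_peak "
                "< signal_offset <= t_end"
            )
        if self.snr < 0 or self.noise_sd < 0:
            raise ValueError("snr and noise_sd must be >= 0")
        lo, hi = self.shift_range
        if not (0.0 <= lo < hi <= 90.0):
            raise ValueError("shift_range must satisfy 0 <= lo < hi <= 90")
        if self.shift_inducer not in ("prev_target", "same_trial"):
            raise ValueError("shift_inducer must be 'prev_target' or 'same_trial'")


def generate_trial_table(n_trials, block_size=50, condition_mix=(0.25, 0.25, 0.25, 0.25), seed=0):
    """Random trial table with uniform orientations and block structure.

    Orientations are i.i.d. uniform on [0, 180), independent between gratings
    and trials.  Conditions are drawn per trial from ``condition_mix`` (order
    as in :data:`CONDITIONS`).  ``prev_target_ori``/``prev_nontarget_ori``
    carry over from the preceding trial within a block and are NaN on the
    first trial of each block.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    if block_size <= 0:
        raise ValueError("block_size must be > 0")
    mix = np.asarray(condition_mix, dtype=float)
    if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("condition_mix must be 4 non-negative probabilities summing to 1")

    rng = np.random.default_rng(seed)
    cond = rng.choice(4, size=n_trials, p=mix)
    ori1 = rng.uniform(0.0, 180.0, n_trials)
    ori2 = rng.uniform(0.0, 180.0, n_trials)

    cue = np.array([CONDITIONS[c][0] for c in cond])
    n_items = np.array([CONDITIONS[c][1] for c in cond])
    # one-item trials show only the cued grating
    ori1 = np.where((n_items == 1) & (cue == "report_second"), np.nan, ori1)
    ori2 = np.where((n_items == 1) & (cue == "report_first"), np.nan, ori2)

    target = np.where(cue == "report_first", ori1, ori2)
    nontarget = np.where(cue == "report_first", ori2, ori1)

    trial_index = np.arange(n_trials)
    block_index = trial_index // block_size
    first_of_block = trial_index % block_size == 0

    prev_target = np.roll(target, 1)
    prev_nontarget = np.roll(nontarget, 1)
    prev_target[first_of_block] = np.nan
    prev_nontarget[first_of_block] = np.nan

    return pd.DataFrame(
        {
            "trial_index": trial_index,
            "block_index": block_index,
            "ori1": ori1,
            "ori2": ori2,
            "cue": cue,
            "n_items": n_items,
            "target_ori": target,
            "nontarget_ori": nontarget,
            "response": np.full(n_trials, np.nan),
            "prev_target_ori": prev_target,
            "prev_nontarget_ori": prev_nontarget,
        }
    )


def generate_behavior(table, params: BehaviorParams, seed=0):
    """Fill the ``response`` column with mixture + bias + noise draws.

    Each response is a mixture draw — target-centered, swap (nontarget-
    centered) or uniform guess — plus, on target-component trials, the
    systematic bias ``+DoG(Δ_between) − DoG(Δ_within)`` and von Mises noise,
    folded into [0, 180).  Deltas are signed circular differences
    (inducer − target) in (−90, 90]; absent inducers contribute zero bias.
    On one-item trials the swap mass is reallocated to the target component
    (there is no item to swap to).
    """
    if table["target_ori"].isna().any():
        raise ValueError("all trials must have target_ori to generate responses")
    rng = np.random.default_rng(seed)
    n = len(table)

    target = table["target_ori"].to_numpy(dtype=float)
    nontarget = table["nontarget_ori"].to_numpy(dtype=float)
    prev_target = table["prev_target_ori"].to_numpy(dtype=float)
    has_nt = np.isfinite(nontarget)
    has_prev = np.isfinite(prev_target)

    u = rng.random(n)
    p_t_eff = np.where(has_nt, params.p_target, params.p_target + params.p_swap)
    comp = np.full(n, 2)  # guess
    comp[u < p_t_eff + np.where(has_nt, params.p_swap, 0.0)] = 1  # swap
    comp[u < p_t_eff] = 0  # target

    d_between = np.where(has_prev, signed_diff(np.where(has_prev, prev_target, 0.0), target), 0.0)
    d_within = np.where(has_nt, signed_diff(np.where(has_nt, nontarget, 0.0), target), 0.0)
    bias = np.where(has_prev, dog(d_between, params.attract_amp, params.attract_width), 0.0)
    bias -= np.where(has_nt, dog(d_within, params.repulse_amp, params.repulse_width), 0.0)

    noise = vonmises_ori_noise(rng, params.kappa, n)
    guesses = rng.uniform(0.0, 180.0, n)

    response = np.where(
        comp == 0,
        target + bias + noise,
        np.where(comp == 1, np.where(has_nt, nontarget, 0.0) + noise, guesses),
    )
    out = table.copy()
    out["response"] = wrap_ori(response)
    return out


def envelope(times, params: NeuralParams):
    """Piecewise-linear rise/fall envelope over (onset, peak, offset)."""
    t = np.asarray(times, dtype=float)
    h = np.zeros_like(t)
    rise = (t >= params.signal_onset) & (t < params.signal_peak)
    fall = (t >= params.signal_peak) & (t <= params.signal_offset)
    h[rise] = (t[rise] - params.signal_onset) / (params.signal_peak - params.signal_onset)
    h[fall] = (params.signal_offset - t[fall]) / (params.signal_offset - params.signal_peak)
    return h


def generate_patterns(params: NeuralParams):
    """Fixed orthonormal channel patterns (u, v) carrying cos/sin tuning.

    Deterministic given ``params.seed``; shared between grating-1 and
    grating-2 epochs so classifiers trained on either event share geometry.
    """
    rng = np.random.default_rng(params.seed)
    k = params.n_pattern_channels or params.n_channels
    if not 2 <= k <= params.n_channels:
        raise ValueError("n_pattern_channels must be in [2, n_channels]")
    a = rng.standard_normal((k, 2))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix QR sign ambiguity
    u = np.zeros(params.n_channels)
    v = np.zeros(params.n_channels)
    u[:k] = q[:, 0]
    v[:k] = q[:, 1]
    return u, v


def _fibonacci_sphere(n):
    """Deterministic, roughly even channel layout on the unit sphere."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_epochs(table, params: NeuralParams, which_event="grating2"):
    """Orientation-tuned multichannel epochs for one grating event.

    Per trial: ``snr * [cos(2θ_enc) u + sin(2θ_enc) v] h(t)`` plus a lingering
    previous-target pattern ``linger_amp * [cos(2θ_prev) u + sin(2θ_prev) v]
    h(t)`` plus white Gaussian noise.  ``θ_enc = θ + repulse_shift * s`` with
    ``s = -sign(Δ_inducer)`` when ``lo < |Δ_inducer| <= hi`` (shift away from
    the inducer), else 0.  Trials where the chosen grating is absent are pure
    noise.
    """
    if which_event not in ("grating1", "grating2"):
        raise ValueError("which_event must be 'grating1' or 'grating2'")
    n_trials = len(table)
    n_t = int(round((params.t_end - params.t_start) * params.sfreq)) + 1
    times = params.t_start + np.arange(n_t) / params.sfreq

    theta = table["ori1" if which_event == "grating1" else "ori2"].to_numpy(dtype=float)
    present = np.isfinite(theta)
    prev_target = table["prev_target_ori"].to_numpy(dtype=float)

    if params.shift_inducer == "prev_target":
        inducer = prev_target
    else:
        inducer = table["ori2" if which_event == "grating1" else "ori1"].to_numpy(dtype=float)

    have = present & np.isfinite(inducer)
    delta = np.where(have, signed_diff(np.where(have, inducer, 0.0), np.where(present, theta, 0.0)), np.nan)
    lo, hi = params.shift_range
    applies = have & (np.abs(delta) > lo) & (np.abs(delta) <= hi) & (delta != 0.0)
    shift_sign = np.where(applies, -np.sign(delta), 0.0)
    theta_enc = np.where(present, theta, 0.0) + params.repulse_shift * shift_sign

    u, v = generate_patterns(params)
    h = envelope(times, params)

    amp = np.where(present, params.snr, 0.0)
    tuning = amp[:, None] * (
        np.cos(np.radians(2.0 * theta_enc))[:, None] * u[None, :]
        + np.sin(np.radians(2.0 * theta_enc))[:, None] * v[None, :]
    )
    linger_mask = present & np.isfinite(prev_target)
    th_p = np.where(linger_mask, prev_target, 0.0)
    linger = (params.linger_amp * linger_mask)[:, None] * (
        np.cos(np.radians(2.0 * th_p))[:, None] * u[None, :]
        + np.sin(np.radians(2.0 * th_p))[:, None] * v[None, :]
    )

    event_id = 1 if which_event == "grating1" else 2
    noise_rng = np.random.default_rng([params.seed, event_id])
    data = (tuning + linger)[:, :, None] * h[None, None, :]
    data += params.noise_sd * noise_rng.standard_normal((n_trials, params.n_channels, n_t))

    names = [f"CH{i:03d}" for i in range(params.n_channels)]
    types = ["generic"] * params.n_channels
    positions = _fibonacci_sphere(params.n_channels)
    info = {"which_event": which_event, "params": asdict(params)}
    return EpochsData(data, times, params.sfreq, names, types, positions, info)


def write_trial_table(table, path):
    """CSV with the fixed column order; absent values as empty fields."""
    table.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path):
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df[TRIAL_COLUMNS]
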