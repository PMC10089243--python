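"""Neural asymmetry and bias scores relative to an inducer orientation.

Given classifier evidence aligned to the presented orientation, these tools
quantify whether the decoded representation is displaced toward (attractive)
or away from (repulsive) an *inducer* — the other grating on the same trial,
or the (non)target of the previous trial.

Sign conventions (used consistently across the package):

* signed deltas are inducer − presented wrapped to (−90, 90];
* "clockwise" (CW) denotes the negative-offset side, so the CW evidence bins
  are offsets −72..−18 and CW-inducer trials are those with delta < 0;
* per sign group the asymmetry score is mean evidence in the CW bins minus
  mean in the CCW bins (18..72), and the neural bias score is the CW-group
  minus the CCW-group asymmetry, so attraction is positive and repulsion
  negative (verified by injected-shift simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import signed_diff
from .decoding import EvidenceTensor, RelativeEvidence, align_evidence, cosine_evidence

INDUCERS = ("same_trial_other_grating", "prev_trial_target", "prev_trial_nontarget")

#: behaviorally informed |delta| selection windows
WITHIN_TRIAL_RANGE = (10.0, 50.0)   # open at both ends
BETWEEN_TRIAL_RANGE = (0.0, 60.0)   # (0, 60]


@dataclass
class InducerSelection:
    """Trials selected for a neural-bias analysis, with signed deltas."""

    trial_index: np.ndarray
    deltas: np.ndarray
    inducer: str
    delta_range: tuple
    exclusions: dict = field(default_factory=dict)

    @property
    def signs(self):
        return np.sign(self.deltas).astype(int)

    @property
    def n_selected(self):
        return int(self.trial_index.size)


def select_inducer_trials(table, inducer, delta_range, event="grating2", closed="right"):
    """Select trials whose inducer-presented distance lies in the given range.

    ``event`` names the presented grating being decoded.  ``delta_range``
    (lo, hi) bounds |delta|; ``closed="right"`` keeps lo < |delta| <= hi,
    ``closed="neither"`` keeps lo < |delta| < hi.  Exact-zero deltas are
    always excluded (no sign).  Exclusion reasons are counted: first-of-block
    (prev-trial inducers), otherwise-undefined inducers, absent presented
    grating, out-of-range deltas.
    """
    if inducer not in INDUCERS:
        raise ValueError(f"inducer must be one of {INDUCERS}")
    if closed not in ("right", "neither"):
        raise ValueError("closed must be 'right' or 'neither'")
    presented = table["ori1" if event == "grating1" else "ori2"].to_numpy(dtype=float)
    if inducer == "same_trial_other_grating":
        ind = table["ori2" if event == "grating1" else "ori1"].to_numpy(dtype=float)
    elif inducer == "prev_trial_target":
        ind = table["prev_target_ori"].to_numpy(dtype=float)
    else:
        ind = table["prev_nontarget_ori"].to_numpy(dtype=float)

    trial_index = table["trial_index"].to_numpy()
    first_of_block = table["prev_target_ori"].isna().to_numpy()

    exclusions = {}
    ok = np.isfinite(presented)
    exclusions["presented_absent"] = int((~ok).sum())
    und = ok & ~np.isfinite(ind)
    if inducer.startswith("prev_trial"):
        exclusions["first_of_block"] = int((und & first_of_block).sum())
        exclusions["inducer_undefined"] = int((und & ~first_of_block).sum())
    else:
        exclusions["inducer_undefined"] = int(und.sum())
    ok &= np.isfinite(ind)

    delta = np.where(ok, signed_diff(np.where(ok, ind, 0.0), np.where(ok, presented, 0.0)), np.nan)
    lo, hi = delta_range
    in_range = np.abs(delta) > lo
    in_range &= np.abs(delta) <= hi if closed == "right" else np.abs(delta) < hi
    in_range &= delta != 0.0
    exclusions["out_of_range"] = int((ok & ~in_range).sum())
    keep = ok & in_range

    deltas = delta[keep]
    if (deltas < 0).sum() == 0 or (deltas > 0).sum() == 0:
        raise ValueError(
            f"empty sign group: {int((deltas < 0).sum())} CW (delta<0) and "
            f"{int((deltas > 0).sum())} CCW (delta>0) trials selected"
        )
    return InducerSelection(
        trial_index=trial_index[keep],
        deltas=deltas,
        inducer=inducer,
        delta_range=tuple(delta_range),
        exclusions=exclusions,
    )


@dataclass
class AsymmetryResult:
    """Asymmetry time courses and the CW-minus-CCW neural bias score.

    ``trial_asym`` holds the per-trial CW-minus-CCW-bin evidence difference
    (trials x time) so permutation nulls can regroup trials by flipped delta
    signs without re-decoding.
    """

    times: np.ndarray
    asym_cw: np.ndarray
    asym_ccw: np.ndarray
    neural_bias: np.ndarray
    window: tuple
    window_mean: float
    n_cw: int
    n_ccw: int
    trial_asym: np.ndarray
    trial_deltas: np.ndarray
    trial_index: np.ndarray

    def to_frame(self):
        return pd.DataFrame(
            {
                "time": self.times,
                "asym_cw": self.asym_cw,
                "asym_ccw": self.asym_ccw,
                "neural_bias": self.neural_bias,
            }
        )

    def summary(self):
        return {
            "window": list(self.window),
            "window_mean": self.window_mean,
            "n_cw": self.n_cw,
            "n_ccw": self.n_ccw,
        }


CW_BINS = (-72.0, -54.0, -36.0, -18.0)
CCW_BINS = (18.0, 36.0, 54.0, 72.0)


def signed_group_difference(deltas, values):
    """CW-group minus CCW-group mean of per-trial values (CW = delta < 0).

    The neural-bias statistic over per-trial asymmetries; also the statistic
    handed to sign-flip permutation nulls.  Returns NaN if a group is empty.
    """
    deltas = np.asarray(deltas, dtype=float)
    values = np.asarray(values, dtype=float)
    cw = deltas < 0
    ccw = deltas > 0
    if not cw.any() or not ccw.any():
        return np.nan
    return float(values[cw].mean(axis=0) - values[ccw].mean(axis=0))


def asymmetry_score(
    rel: RelativeEvidence,
    sel: InducerSelection,
    cw_bins=CW_BINS,
    ccw_bins=CCW_BINS,
    window=(0.25, 0.60),
):
    """Asymmetry and neural-bias time courses for an inducer selection.

    Offsets 0 and 90 take part in neither bin set.  ``rel`` must be aligned
    to the presented orientation; only trials present in both ``rel`` and
    ``sel`` are used.
    """
    cw_bins = np.asarray(cw_bins, dtype=float)
    ccw_bins = np.asarray(ccw_bins, dtype=float)
    if cw_bins.size == 0 or ccw_bins.size == 0:
        raise ValueError("bin sets must be non-empty")
    cw_idx = _offset_indices(rel.offsets, cw_bins)
    ccw_idx = _offset_indices(rel.offsets, ccw_bins)

    pos = {t: i for i, t in enumerate(rel.trial_index)}
    keep = [i for i, t in enumerate(sel.trial_index) if t in pos]
    if not keep:
        raise ValueError("no overlap between evidence trials and selection")
    rel_rows = np.array([pos[sel.trial_index[i]] for i in keep])
    deltas = sel.deltas[np.array(keep)]

    ev = rel.evidence[rel_rows]
    trial_asym = ev[:, cw_idx, :].mean(axis=1) - ev[:, ccw_idx, :].mean(axis=1)

    cw_group = deltas < 0
    ccw_group = deltas > 0
    if not cw_group.any() or not ccw_group.any():
        raise ValueError("empty CW or CCW inducer group after matching trials")
    asym_cw = trial_asym[cw_group].mean(axis=0)
    asym_ccw = trial_asym[ccw_group].mean(axis=0)
    neural_bias = asym_cw - asym_ccw

    tsel = (rel.times >= window[0] - 1e-9) & (rel.times <= window[1] + 1e-9)
    if not tsel.any():
        raise ValueError("analysis window contains no time points")
    return AsymmetryResult(
        times=rel.times.copy(),
        asym_cw=asym_cw,
        asym_ccw=asym_ccw,
        neural_bias=neural_bias,
        window=tuple(window),
        window_mean=float(neural_bias[tsel].mean()),
        n_cw=int(cw_group.sum()),
        n_ccw=int(ccw_group.sum()),
        trial_asym=trial_asym,
        trial_deltas=deltas,
        trial_index=sel.trial_index[np.array(keep)],
    )


def _offset_indices(offsets, wanted):
    idx = []
    for w in wanted:
        hit = np.flatnonzero(np.isclose(offsets, w))
        if hit.size != 1:
            raise ValueError(f"offset {w} not present in relative evidence")
        idx.append(int(hit[0]))
    return np.array(idx)


def cross_decode_evidence(ev: EvidenceTensor, prev_target):
    """Cosine evidence for the *previous* trial's target orientation.

    Trains nothing new: the class evidence (from a classifier trained on the
    presented orientation) is re-aligned to the previous target and convolved
    with a cosine.  Negative window means indicate a sign-reversed lingering
    trace of the previous stimulus.  Returns ``(scores, rel)`` where scores
    is kept-trials x time.
    """
    rel = align_evidence(ev, prev_target)
    return cosine_evidence(rel), rel
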