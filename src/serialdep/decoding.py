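"""Spatiotemporal multivariate decoding of binned orientation from epochs.

The decoder follows a sliding-window spatiotemporal scheme: channel values
over a trailing window of samples are concatenated into one feature vector
per trial and time point (after approximately matching channel-type
magnitudes), reduced per time point by PCA fit on the training folds only,
and classified with a 10-class linear discriminant analysis under stratified
cross-validation.  Per trial, class and time point the pipeline emits an
*evidence* value: the negated, class-mean-centered Euclidean distance to the
training class mean in the discriminant space (larger = more consistent with
that class; the class axis sums to zero).  Evidence re-aligned to an
arbitrary orientation yields representational-similarity curves whose cosine
convolution gives a scalar decoding-evidence time course; aligning to the
previous trial's target instead of the presented orientation implements
cross-decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .circstats import signed_diff
from .containers import EpochsData

#: Magnetometer magnitudes are matched to gradiometers by a fixed factor.
DEFAULT_CHANNEL_SCALE = {"gradiometer": 1.0, "magnetometer": 20.0, "generic": 1.0}


@dataclass(frozen=True)
class ClassBins:
    """Equally spaced, right-open orientation class bins over [0, 180)."""

    n_classes: int = 10

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def width(self):
        return 180.0 / self.n_classes

    @property
    def edges(self):
        return np.arange(self.n_classes) * self.width

    @property
    def centers(self):
        return self.edges + self.width / 2.0

    def assign(self, ori):
        """Map orientations to class indices (right-open bins [k*w, (k+1)*w))."""
        ori = np.asarray(ori, dtype=float)
        return np.floor((ori % 180.0) / self.width).astype(int)


@dataclass
class FeatureTensor:
    """Trials x features x time sliding-window feature stack."""

    data: np.ndarray
    times: np.ndarray

    def crop(self, tmin=None, tmax=None, decim=1):
        """Restrict to times in [tmin, tmax], optionally taking every ``decim``-th point."""
        keep = np.ones(self.times.size, dtype=bool)
        if tmin is not None:
            keep &= self.times >= tmin - 1e-9
        if tmax is not None:
            keep &= self.times <= tmax + 1e-9
        idx = np.flatnonzero(keep)[::decim]
        return FeatureTensor(self.data[:, :, idx], self.times[idx])


@dataclass
class EvidenceTensor:
    """Trials x class x time classifier evidence (class axis sums to zero)."""

    evidence: np.ndarray
    class_bins: ClassBins
    times: np.ndarray
    cv_fold_of_trial: np.ndarray
    labels: np.ndarray = None  # orientation labels used for training (degrees)
    info: dict = field(default_factory=dict)


@dataclass
class RelativeEvidence:
    """Evidence re-indexed to offsets relative to an alignment orientation.

    ``offsets`` are class-center minus alignment-bin-center wrapped to
    (−90, 90] (for 10 classes: −72, −54, ..., 72, 90).  Re-alignment permutes
    the class axis per trial; trials whose aligner was undefined are dropped
    and recorded in ``n_dropped``.
    """

    evidence: np.ndarray  # kept trials x offsets x time
    offsets: np.ndarray
    times: np.ndarray
    trial_index: np.ndarray  # indices into the original trial axis
    n_dropped: int = 0


def build_features(epochs: EpochsData, window_len=30, scale=None):
    """Concatenate a trailing sliding window of scaled channel data.

    The feature vector at time t stacks all channels over samples
    (t − window_len + 1, ..., t); output is restricted to time points where
    the full window exists.  Channel-type scaling (default: magnetometers
    x20) is applied first.  No baseline subtraction is performed, so slowly
    varying signals from earlier events remain decodable.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if window_len > epochs.n_times:
        raise ValueError("window_len longer than the epoch")
    scale = dict(DEFAULT_CHANNEL_SCALE if scale is None else scale)
    factors = np.array([scale[t] for t in epochs.channel_types])
    x = epochs.data * factors[None, :, None]
    # (trials, channels, n_valid, window) -> (trials, channels*window, n_valid)
    sw = np.lib.stride_tricks.sliding_window_view(x, window_len, axis=2)
    n_tr, n_ch, n_valid, _ = sw.shape
    feats = sw.transpose(0, 1, 3, 2).reshape(n_tr, n_ch * window_len, n_valid)
    return FeatureTensor(np.ascontiguousarray(feats), epochs.times[window_len - 1 :])


def stratified_folds(y, n_folds, seed):
    """Seeded stratified fold assignment; returns a list of (train, test) index arrays."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def decode_cv(
    feats: FeatureTensor,
    labels,
    class_bins: ClassBins = ClassBins(),
    n_folds=10,
    var_kept=0.90,
    seed=0,
    shrinkage="auto",
    folds=None,
):
    """Cross-validated LDA class evidence per trial, class and time point.

    Per time point and fold: PCA keeping ``var_kept`` of the *training*
    variance (None = no reduction), LDA (eigen solver, shrinkage of the
    within-class covariance toward its diagonal) fit on the reduced training
    data; test trials are projected into the (n_classes − 1)-dimensional
    discriminant space and their Euclidean distances to the training class
    means are negated and centered across classes to give evidence.

    Labels are orientations in degrees; every class must have at least
    ``n_folds`` members.  ``folds`` may supply precomputed (train, test)
    splits (test-trial labels are then never used).
    """
    labels = np.asarray(labels, dtype=float)
    x = feats.data
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    if labels.shape != (x.shape[0],) or not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite, one per trial")
    y = class_bins.assign(labels)
    classes = np.arange(class_bins.n_classes)
    counts = np.bincount(y, minlength=class_bins.n_classes)
    if folds is None:
        if counts.min() < n_folds:
            bad = {int(c): int(counts[c]) for c in classes if counts[c] < n_folds}
            raise ValueError(
                f"stratification infeasible: classes with fewer than {n_folds} "
                f"trials: {bad}"
            )
        folds = stratified_folds(y, n_folds, seed)

    n_trials, _, n_times = x.shape
    evidence = np.zeros((n_trials, class_bins.n_classes, n_times))
    cv_fold = np.full(n_trials, -1)
    n_components = []
    n_discriminant = None

    for fold_i, (tr, te) in enumerate(folds):
        cv_fold[te] = fold_i
        y_tr = y[tr]
        for ti in range(n_times):
            x_tr = x[tr, :, ti]
            x_te = x[te, :, ti]
            if var_kept is not None:
                pca = PCA(n_components=var_kept, svd_solver="full")
                x_tr = pca.fit_transform(x_tr)
                x_te = pca.transform(x_te)
                n_components.append(x_tr.shape[1])
            lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
            lda.fit(x_tr, y_tr)
            z_tr = lda.transform(x_tr)
            z_te = lda.transform(x_te)
            n_discriminant = z_tr.shape[1]
            means = np.vstack([z_tr[y_tr == c].mean(axis=0) for c in classes])
            d = cdist(z_te, means)
            evidence[te, :, ti] = -(d - d.mean(axis=1, keepdims=True))

    info = {
        "n_discriminant": int(n_discriminant),
        "mean_n_components": float(np.mean(n_components)) if n_components else None,
        "var_kept": var_kept,
        "n_folds": len(folds),
        "seed": seed,
    }
    return EvidenceTensor(evidence, class_bins, feats.times.copy(), cv_fold, labels, info)


def align_evidence(ev: EvidenceTensor, align_to):
    """Re-index the class axis so offset 0 is the bin containing ``align_to``.

    ``align_to`` is one orientation per trial (degrees); NaN trials are
    dropped and counted.  With ``align_to`` = presented orientation this
    yields standard representational-similarity curves; with the previous
    trial's target it implements cross-decoding.
    """
    align_to = np.asarray(align_to, dtype=float)
    if align_to.shape != (ev.evidence.shape[0],):
        raise ValueError("align_to must provide one orientation per trial")
    kept = np.flatnonzero(np.isfinite(align_to))
    if kept.size == 0:
        raise ValueError("all alignment orientations are undefined")
    bins = ev.class_bins.assign(align_to[kept])

    n = ev.class_bins.n_classes
    w = ev.class_bins.width
    steps = np.arange(n)
    offs = signed_diff(steps * w, 0.0)
    order = np.argsort(offs)
    class_idx = (bins[:, None] + steps[order][None, :]) % n
    rel = ev.evidence[kept[:, None], class_idx, :]
    return RelativeEvidence(
        evidence=rel,
        offsets=offs[order],
        times=ev.times.copy(),
        trial_index=kept,
        n_dropped=int(align_to.size - kept.size),
    )


def cosine_evidence(rel: RelativeEvidence):
    """Cosine-convolved evidence: trials x time scalar score.

    ``score(trial, t) = mean_k evidence(trial, k, t) * cos(2 * offset_k)``.
    Positive scores mean evidence concentrates at the aligned orientation;
    class-axis centering makes the score invariant to additive offsets.
    """
    w = np.cos(np.radians(2.0 * rel.offsets))
    return (rel.evidence * w[None, :, None]).mean(axis=1)


def window_mean(scores, times, window=(0.25, 0.60)):
    """Mean of a trials x time score over a time window (inclusive), then over trials."""
    times = np.asarray(times)
    sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError("empty analysis window")
    return float(np.mean(scores[..., sel]))


def searchlight_decode(
    epochs: EpochsData,
    labels,
    class_bins: ClassBins = ClassBins(),
    neighborhood=48,
    window_len=30,
    scale=None,
    time_window=(0.25, 0.60),
    n_folds=10,
    var_kept=0.90,
    seed=0,
):
    """Per-channel decoding map from sensor neighborhoods.

    For each channel, decoding runs on that channel plus its
    ``neighborhood − 1`` nearest neighbors (Euclidean distance on channel
    positions); the map value is the cosine evidence aligned to the presented
    orientation, averaged over trials and ``time_window``.
    """
    if not np.all(np.isfinite(epochs.channel_positions)):
        raise ValueError("searchlight requires finite channel positions")
    if not 1 <= neighborhood <= epochs.n_channels:
        raise ValueError("neighborhood must be in [1, n_channels]")
    pos = epochs.channel_positions
    dmat = cdist(pos, pos)
    out = np.zeros(epochs.n_channels)
    for ch in range(epochs.n_channels):
        sel = np.argsort(dmat[ch], kind="stable")[:neighborhood]
        sub = EpochsData(
            epochs.data[:, sel, :],
            epochs.times,
            epochs.sfreq,
            [epochs.channel_names[i] for i in sel],
            [epochs.channel_types[i] for i in sel],
            pos[sel],
            dict(epochs.info),
        )
        feats = build_features(sub, window_len=window_len, scale=scale)
        feats = feats.crop(*time_window)
        ev = decode_cv(feats, labels, class_bins, n_folds=n_folds, var_kept=var_kept, seed=seed)
        sc = cosine_evidence(align_evidence(ev, labels))
        out[ch] = float(sc.mean())
    return out
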