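"""Decoding pipeline: features, cross-validated LDA evidence, alignment, searchlight."""

import numpy as np
import pytest
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

import serialdep as sd
from serialdep.decoding import DEFAULT_CHANNEL_SCALE


def _epochs(n_trials=8, n_channels=4, n_times=12, sfreq=50.0, seed=0, types=None):
    rng = np.random.default_rng(seed)
    return sd.EpochsData(
        rng.normal(size=(n_trials, n_channels, n_times)),
        np.arange(n_times) / sfreq,
        sfreq,
        [f"C{i}" for i in range(n_channels)],
        types or ["generic"] * n_channels,
        rng.normal(size=(n_channels, 3)),
    )


class TestFeatures:
    def test_spatiotemporal_dimension_306_sensors(self):
        ep = _epochs(n_trials=2, n_channels=306, n_times=40)
        feats = sd.build_features(ep, window_len=30)
        assert feats.data.shape[1] == 9180
        assert feats.data.shape[2] == 40 - 30 + 1

    def test_window_one_is_scaled_identity(self):
        types = ["gradiometer", "magnetometer", "generic", "generic"]
        ep = _epochs(types=types)
        feats = sd.build_features(ep, window_len=1)
        factors = np.array([DEFAULT_CHANNEL_SCALE[t] for t in types])
        assert np.allclose(feats.data, ep.data * factors[None, :, None])
        assert np.array_equal(feats.times, ep.times)

    def test_constant_signal_gives_constant_features(self):
        ep = _epochs()
        ep.data[:] = ep.data[:, :, :1]
        feats = sd.build_features(ep, window_len=5)
        assert np.allclose(feats.data, feats.data[:, :, :1])

    def test_window_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            sd.build_features(_epochs(n_times=12), window_len=13)


class TestClassBins:
    def test_right_open_18_degree_bins(self):
        bins = sd.ClassBins(10)
        assert bins.width == 18.0
        assert np.array_equal(bins.assign([0, 17.999, 18, 179.9, 180.0]), [0, 0, 1, 9, 0])
        assert np.allclose(bins.centers, np.arange(10) * 18 + 9)


def _lda_oracle(x_tr, y_tr, x_te):
    """Independent linear-algebra route: generalized eigenvectors of (Sb, Sw)."""
    classes = np.unique(y_tr)
    sw = sum(
        (y_tr == c).sum() / len(y_tr) * np.cov(x_tr[y_tr == c].T, bias=True)
        for c in classes
    )
    sb = np.cov(x_tr.T, bias=True) - sw
    w, v = eigh(sb, sw)
    v = v[:, np.argsort(w)[::-1]][:, : len(classes) - 1]
    z_tr, z_te = x_tr @ v, x_te @ v
    means = np.array([z_tr[y_tr == c].mean(axis=0) for c in classes])
    d = cdist(z_te, means)
    return -(d - d.mean(axis=1, keepdims=True))


class TestDecodeCV:
    def test_lda_distances_match_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2, 1))
        x[:4, 0, 0] += 3
        labels = np.array([10.0] * 4 + [120.0] * 4)
        folds = [
            (np.array([0, 1, 4, 5]), np.array([2, 3, 6, 7])),
            (np.array([2, 3, 6, 7]), np.array([0, 1, 4, 5])),
        ]
        ev = sd.decode_cv(
            sd.FeatureTensor(x, np.array([0.0])), labels, sd.ClassBins(2),
            var_kept=None, shrinkage=None, folds=folds,
        )
        bins = sd.ClassBins(2)
        y = bins.assign(labels)
        for tr, te in folds:
            expected = _lda_oracle(x[tr, :, 0], y[tr], x[te, :, 0])
            assert np.allclose(ev.evidence[te, :, 0], expected, atol=1e-8)

    def test_discriminant_dimension_and_centering(self, tuned_run):
        ev = tuned_run["evidence"]
        assert ev.info["n_discriminant"] == 9  # number of classes minus one
        assert np.allclose(ev.evidence.sum(axis=1), 0.0, atol=1e-9)

    def test_two_separated_classes_recovered(self):
        """Far-separated classes with signal >> noise: argmax is right on >95% of trials."""
        rng = np.random.default_rng(9)
        x = 0.1 * rng.normal(size=(60, 8, 1))
        y = np.repeat([0, 1], 30)
        x[y == 0, 0, 0] += 5.0
        x[y == 1, 1, 0] += 5.0
        labels = np.where(y == 0, 30.0, 120.0)
        ev = sd.decode_cv(sd.FeatureTensor(x, np.zeros(1)), labels, sd.ClassBins(2),
                          n_folds=5, var_kept=None, seed=0)
        best = ev.evidence[:, :, 0].argmax(axis=1)
        assert (best == sd.ClassBins(2).assign(labels)).mean() > 0.95

    def test_tuned_simulation_beats_chance(self, tuned_run):
        """At snr ~ noise the argmax class is far above the 10% chance level."""
        ev = tuned_run["evidence"]
        y = ev.class_bins.assign(tuned_run["labels"])
        best = ev.evidence.mean(axis=2).argmax(axis=1)
        assert (best == y).mean() > 0.3

    def test_small_class_rejected_with_counts(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 4, 1))
        labels = rng.uniform(0, 180, 30)
        with pytest.raises(ValueError, match="fewer than"):
            sd.decode_cv(sd.FeatureTensor(x, np.zeros(1)), labels, sd.ClassBins(10))

    def test_cross_validation_hygiene(self):
        """With fixed folds, test-fold labels never influence the fit."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 6, 2))
        labels = np.tile(np.repeat([10.0, 100.0], 10), 2)
        y = sd.ClassBins(2).assign(labels)
        folds = sd.decoding.stratified_folds(y, 4, seed=0)
        ev1 = sd.decode_cv(sd.FeatureTensor(x, np.zeros(2)), labels, sd.ClassBins(2),
                           var_kept=None, folds=folds)
        corrupted = labels.copy()
        corrupted[folds[0][1]] = (corrupted[folds[0][1]] + 90) % 180
        ev2 = sd.decode_cv(sd.FeatureTensor(x, np.zeros(2)), corrupted, sd.ClassBins(2),
                           var_kept=None, folds=folds)
        assert np.array_equal(ev1.evidence[folds[0][1]], ev2.evidence[folds[0][1]])


class TestAlignment:
    def test_alignment_is_pure_permutation(self, tuned_run):
        ev, rel = tuned_run["evidence"], tuned_run["rel"]
        assert np.allclose(
            np.sort(rel.evidence, axis=1),
            np.sort(ev.evidence[rel.trial_index], axis=1),
        )
        assert np.array_equal(
            np.sort(rel.offsets), [-72, -54, -36, -18, 0, 18, 36, 54, 72, 90]
        )

    def test_evidence_peaks_at_zero_offset(self, tuned_run):
        rel = tuned_run["rel"]
        curve = rel.evidence.mean(axis=(0, 2))
        assert rel.offsets[np.argmax(curve)] == 0

    def test_aligning_to_bin_zero_center_is_identity(self, tuned_run):
        ev = tuned_run["evidence"]
        rel = sd.align_evidence(ev, np.full(ev.evidence.shape[0], 9.0))
        order = np.argsort((rel.offsets % 180) / 18).astype(int)
        assert np.allclose(rel.evidence[:, order, :], ev.evidence)

    def test_undefined_aligners_dropped(self, tuned_run):
        ev = tuned_run["evidence"]
        align = tuned_run["labels"].copy()
        align[:5] = np.nan
        rel = sd.align_evidence(ev, align)
        assert rel.n_dropped == 5 and rel.trial_index[0] == 5
        with pytest.raises(ValueError):
            sd.align_evidence(ev, np.full_like(align, np.nan))


class TestCosineEvidence:
    def _rel(self, values):
        offsets = np.array([-72, -54, -36, -18, 0, 18, 36, 54, 72, 90.0])
        ev = np.array(values, dtype=float)[None, :, None]
        return sd.RelativeEvidence(ev, offsets, np.array([0.0]), np.array([0]))

    def test_flat_evidence_scores_zero(self):
        assert sd.cosine_evidence(self._rel(np.ones(10)))[0, 0] == pytest.approx(0.0)

    def test_cosine_tuning_scores_half(self):
        offsets = np.array([-72, -54, -36, -18, 0, 18, 36, 54, 72, 90.0])
        rel = self._rel(np.cos(np.radians(2 * offsets)))
        assert sd.cosine_evidence(rel)[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_linearity_under_sign_flip(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=10)
        a = sd.cosine_evidence(self._rel(vals))[0, 0]
        b = sd.cosine_evidence(self._rel(-vals))[0, 0]
        assert a == pytest.approx(-b)


class TestChanceLevel:
    def test_permuted_labels_score_at_chance(self, tuned_run):
        rng = np.random.default_rng(4)
        labels = tuned_run["labels"]
        perm = rng.permutation(labels.size)
        ep = tuned_run["epochs"]
        feats = sd.build_features(ep, window_len=10).crop(0.40, 0.45)
        ev = sd.decode_cv(feats, labels[perm], sd.ClassBins(10), seed=0)
        null = sd.alignment_shuffle_null(ev, labels[perm], window=(0.40, 0.45),
                                         n_iter=300, seed=5)
        assert abs(null.z) < 2.5


class TestSearchlight:
    def test_degenerate_neighborhood_equals_whole_array(self):
        rng = np.random.default_rng(6)
        tab = sd.generate_trial_table(120, 120, (0, 0, 1, 0), seed=6)
        npar = sd.NeuralParams(n_channels=8, sfreq=50.0, t_start=-0.1, t_end=0.75,
                               snr=2.0, seed=6)
        ep = sd.generate_epochs(tab, npar, "grating1")
        labels = tab["ori1"].to_numpy()
        kw = dict(window_len=5, time_window=(0.3, 0.4), n_folds=5, seed=0)
        mp = sd.searchlight_decode(ep, labels, sd.ClassBins(10), neighborhood=8, **kw)
        assert np.allclose(mp, mp[0], atol=1e-6)

    def test_localized_pattern_lights_up_its_channels(self):
        tab = sd.generate_trial_table(120, 120, (0, 0, 1, 0), seed=7)
        npar = sd.NeuralParams(n_channels=24, sfreq=50.0, t_start=-0.1, t_end=0.75,
                               snr=3.0, n_pattern_channels=6, seed=7)
        ep = sd.generate_epochs(tab, npar, "grating1")
        labels = tab["ori1"].to_numpy()
        mp = sd.searchlight_decode(ep, labels, sd.ClassBins(10), neighborhood=4,
                                   window_len=5, time_window=(0.3, 0.4), n_folds=5, seed=0)
        # neighborhoods containing pattern channels must dominate the map
        pos = ep.channel_positions
        dmat = cdist(pos, pos)
        contains = np.array([
            np.any(np.argsort(dmat[ch], kind="stable")[:4] < 6) for ch in range(24)
        ])
        assert mp[contains].mean() > mp[~contains].mean() + 3 * mp[~contains].std()
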