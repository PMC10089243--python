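"""Permutation inference: sign-flip shuffle nulls and 1-D cluster tests.

Two procedures:

* :func:`signflip_shuffle_null` — a null distribution for bias scores that
  depend on signed angular distances: each iteration randomly flips the sign
  of every trial's delta (per subject), recomputes the subject statistic and
  averages across subjects.  The null is z-scored and the observed statistic
  expressed as a z value with a two-tailed p (an empirical permutation p is
  reported alongside).
* :func:`cluster_permutation_1d` — one-sample cluster-based permutation test
  for subject x time (or subject x bin) series against zero: pointwise
  t statistics are thresholded, contiguous supra-threshold runs of equal sign
  form clusters whose mass (summed t) is compared against the max-cluster
  null obtained under random per-subject sign flips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class NullDistribution:
    """Permutation null with observed value, z score and two-tailed p.

    ``p_two_tailed`` is the normal tail probability of the z-scored observed
    statistic (the headline value); ``p_empirical`` is the permutation
    estimate ``(b + 1) / (m + 1)`` counting null values at least as extreme
    (two-tailed around the null mean) — never exactly zero.
    """

    null_values: np.ndarray
    observed: float
    z: float
    p_two_tailed: float
    p_empirical: float
    n_iter: int
    seed: int

    def to_json(self, path=None):
        d = {
            "observed": self.observed,
            "z": self.z,
            "p_two_tailed": self.p_two_tailed,
            "p_empirical": self.p_empirical,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        if path is not None:
            with open(path, "w") as f:
                json.dump(d, f, indent=2)
        return d


def signflip_shuffle_null(statistic, subject_deltas, subject_aux=None, n_iter=10000, seed=0):
    """Sign-flip shuffle null for a delta-dependent bias statistic.

    ``statistic(deltas, aux)`` maps one subject's signed per-trial deltas
    (plus auxiliary per-trial data, e.g. signed errors or per-trial
    asymmetries) to a scalar.  The observed value is the across-subject mean
    without flips; each of ``n_iter`` iterations flips each trial's delta
    sign independently (per subject) and recomputes the mean statistic.
    """
    if len(subject_deltas) < 1:
        raise ValueError("need at least one subject")
    deltas = [np.asarray(d, dtype=float) for d in subject_deltas]
    if subject_aux is None:
        aux = [None] * len(deltas)
    else:
        aux = list(subject_aux)
        if len(aux) != len(deltas):
            raise ValueError("subject_aux length mismatch")

    vals = [statistic(d, a) for d, a in zip(deltas, aux)]
    if not np.all(np.isfinite(vals)):
        raise ValueError("statistic returned a non-finite observed value")
    observed = float(np.mean(vals))

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for it in range(n_iter):
        acc = 0.0
        for d, a in zip(deltas, aux):
            signs = rng.integers(0, 2, size=d.size) * 2 - 1
            v = statistic(d * signs, a)
            if not np.isfinite(v):
                raise ValueError(f"statistic returned a non-finite value at iteration {it}")
            acc += v
        null[it] = acc / len(deltas)

    mu = null.mean()
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null distribution (zero variance)")
    z = (observed - mu) / sd
    p_z = float(2.0 * sps.norm.sf(abs(z)))
    b = int(np.sum(np.abs(null - mu) >= abs(observed - mu)))
    p_emp = (b + 1) / (n_iter + 1)
    return NullDistribution(null, observed, float(z), min(p_z, 1.0), p_emp, n_iter, seed)


@dataclass
class ClusterResult:
    """Clusters of contiguous supra-threshold points with permutation p values.

    ``clusters`` holds (start, stop, mass) with *stop exclusive* (Python
    slice convention); mass is the summed pointwise t within the run.
    """

    clusters: list
    p_per_cluster: np.ndarray
    threshold_stat: float
    t_obs: np.ndarray
    null_max_mass: np.ndarray
    n_iter: int
    seed: int
    excluded_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_json(self, path=None):
        d = {
            "threshold_stat": self.threshold_stat,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "clusters": [
                {"start": int(s), "stop": int(e), "mass": float(m), "p": float(p)}
                for (s, e, m), p in zip(self.clusters, self.p_per_cluster)
            ],
            "excluded_points": self.excluded_points.tolist(),
        }
        if path is not None:
            with open(path, "w") as f:
                json.dump(d, f, indent=2)
        return d


def find_clusters(t, threshold, tail="two"):
    """Maximal contiguous runs where t exceeds the threshold.

    For ``tail="two"`` positive (t > thr) and negative (t < −thr) runs are
    found separately; ``"greater"``/``"less"`` keep one sign.  Returns a list
    of (start, stop, mass) with stop exclusive and mass = sum of t in run.
    """
    t = np.asarray(t, dtype=float)
    masks = []
    if tail in ("two", "greater"):
        masks.append(t > threshold)
    if tail in ("two", "less"):
        masks.append(t < -threshold)
    clusters = []
    for mask in masks:
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):
            clusters.append((int(s), int(e), float(t[s:e].sum())))
    clusters.sort(key=lambda c: c[0])
    return clusters


def _one_sample_t(x):
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return t


def cluster_permutation_1d(subject_series, n_iter=10000, alpha_threshold=0.05, seed=0, tail="two"):
    """One-sample cluster-based permutation test of a subjects x points series.

    Pointwise one-sample t values against zero are thresholded at the t
    quantile for ``alpha_threshold`` (per tail); cluster mass is the summed
    t within each contiguous supra-threshold run, and the null is the
    maximum absolute cluster mass under random per-subject sign flips.
    Cluster p values use the (b + 1)/(m + 1) estimator.  Points with zero
    variance across subjects are excluded with a warning.  Intended for five
    or more subjects.
    """
    x = np.asarray(subject_series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("subject_series must be (>=2 subjects) x (>=2 points)")
    if tail == "one":
        tail = "greater"
    if tail not in ("two", "greater", "less"):
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    n, p = x.shape
    df = n - 1

    var0 = np.flatnonzero(x.std(axis=0) == 0)
    if var0.size:
        warnings.warn(
            f"{var0.size} point(s) with zero variance across subjects excluded "
            "from cluster formation",
            RuntimeWarning,
        )

    if tail == "two":
        threshold = float(sps.t.ppf(1.0 - alpha_threshold / 2.0, df))
    else:
        threshold = float(sps.t.ppf(1.0 - alpha_threshold, df))

    t_obs = _one_sample_t(x)
    t_obs = np.where(np.isfinite(t_obs), t_obs, 0.0)
    t_masked = t_obs.copy()
    t_masked[var0] = 0.0
    clusters = find_clusters(t_masked, threshold, tail)

    rng = np.random.default_rng(seed)
    ss = (x**2).sum(axis=0)
    null_max = np.zeros(n_iter)
    for it in range(n_iter):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        m = signs @ x / n
        var = (ss - n * m**2) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        t = np.where(np.isfinite(t), t, 0.0)
        t[var0] = 0.0
        cl = find_clusters(t, threshold, tail)
        null_max[it] = max((abs(c[2]) for c in cl), default=0.0)

    p_vals = np.array(
        [(np.sum(null_max >= abs(mass)) + 1) / (n_iter + 1) for (_, _, mass) in clusters]
    )
    return ClusterResult(
        clusters=clusters,
        p_per_cluster=p_vals,
        threshold_stat=threshold,
        t_obs=t_obs,
        null_max_mass=null_max,
        n_iter=n_iter,
        seed=seed,
        excluded_points=var0,
    )


def alignment_shuffle_null(ev, align_to, window=(0.25, 0.60), n_iter=1000, seed=0):
    """Null for a decoding-evidence window mean by shuffling the aligner.

    Permutes the alignment orientations across trials (breaking the
    trial-evidence correspondence) and recomputes the trial- and window-
    averaged cosine evidence.  A cheap chance-level reference that reuses the
    fitted classifier evidence.
    """
    from .decoding import align_evidence, cosine_evidence, window_mean

    align_to = np.asarray(align_to, dtype=float)
    rel = align_evidence(ev, align_to)
    observed = window_mean(cosine_evidence(rel), rel.times, window)

    kept = np.flatnonzero(np.isfinite(align_to))
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for it in range(n_iter):
        shuffled = np.full(align_to.size, np.nan)
        shuffled[kept] = align_to[kept][rng.permutation(kept.size)]
        rel_s = align_evidence(ev, shuffled)
        null[it] = window_mean(cosine_evidence(rel_s), rel_s.times, window)

    mu = null.mean()
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null distribution (zero variance)")
    z = (observed - mu) / sd
    p_z = float(2.0 * sps.norm.sf(abs(z)))
    b = int(np.sum(np.abs(null - mu) >= abs(observed - mu)))
    return NullDistribution(null, observed, float(z), min(p_z, 1.0), (b + 1) / (n_iter + 1), n_iter, seed)
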