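"""Behavioral serial-dependence statistics for continuous orientation reports.

Three tools:

* :func:`circular_error` — signed report error on the orientation circle;
* :func:`bias_curve` — the performance-bias curve: mean signed error binned
  by the angular distance between the target and an inducer orientation,
  using 64 overlapping quantile bins (25% of trials each), sign-flipped and
  folded into 32 bins over absolute distance, summarized by the *summed
  bias* (positive = attraction toward the inducer, negative = repulsion);
* :func:`fit_mixture` — EM fit of the classic three-component continuous-
  report model: a target-centered von Mises, a nontarget-centered von Mises
  ("swap errors") with the same concentration, and a uniform guess component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .circstats import resultant_length, signed_diff


def circular_error(response, reference):
    """Signed circular distance response − reference, mapped to (−90, 90].

    The report error convention used throughout: positive error means the
    response is clockwise of the reference on the doubled-angle circle
    (antipodes map to +90).
    """
    response = np.asarray(response, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if not (np.all(np.isfinite(response)) and np.all(np.isfinite(reference))):
        raise ValueError("circular_error requires finite inputs")
    return signed_diff(response, reference)


@dataclass
class BiasCurve:
    """Folded performance-bias curve.

    ``raw_centers``/``raw_means`` are the 64 overlapping bins on (−90, 90);
    ``bin_centers``/``bin_means`` the 32 folded bins on (0, 90), where folded
    mean k = 0.5 * (raw mean at +c_k − raw mean at −c_k).  ``summed_bias``
    (degrees) is the sum of the folded means.
    """

    bin_centers: np.ndarray
    bin_means: np.ndarray
    n_per_bin: int
    raw_centers: np.ndarray
    raw_means: np.ndarray
    summed_bias: float

    def to_frame(self):
        return pd.DataFrame(
            {"center": self.bin_centers, "mean": self.bin_means, "n": self.n_per_bin}
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def _raw_centers(n_bins_raw):
    # centers offset by half a step: none falls on 0 or +-90, fold pairs exact
    return -90.0 + (np.arange(n_bins_raw) + 0.5) * 180.0 / n_bins_raw


def bias_curve(errors, deltas, n_bins_raw=64, bin_frac=0.25):
    """Performance bias as a function of inducer-target angular distance.

    ``deltas`` are signed circular differences (inducer − target) in
    (−90, 90]: positive = inducer clockwise of target, so an attractive bias
    appears as positive bin means at positive deltas.  Each of the
    ``n_bins_raw`` raw bins holds the ``round(bin_frac * n)`` trials whose
    wrapped distance to the bin center is smallest (ties broken by trial
    order); wrapping removes edge artefacts.  Error signs are flipped for
    negative-center bins before mirrored centers are averaged ("folded") into
    ``n_bins_raw/2`` bins over absolute distance.
    """
    errors = np.asarray(errors, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    if errors.shape != deltas.shape or errors.ndim != 1:
        raise ValueError("errors and deltas must be matching 1-D arrays")
    n = errors.size
    if n < 8:
        raise ValueError("bias_curve needs at least 8 trials")
    if n_bins_raw % 2:
        raise ValueError("n_bins_raw must be even")
    m = int(round(bin_frac * n))
    if m < 1:
        raise ValueError("bin_frac * n must round to at least one trial per bin")
    if np.ptp(deltas) == 0:
        raise ValueError("degenerate binning: all deltas identical")

    centers = _raw_centers(n_bins_raw)
    # wrapped distance of every trial to every bin center, (n_bins_raw, n)
    dist = np.abs(signed_diff(deltas[None, :], centers[:, None]))
    order = np.argsort(dist, axis=1, kind="stable")[:, :m]
    raw_means = errors[order].mean(axis=1)

    half = n_bins_raw // 2
    # raw index half+k has center +c_k; its mirror −c_k sits at index half−1−k
    folded = 0.5 * (raw_means[half:] - raw_means[half - 1 :: -1])
    return BiasCurve(
        bin_centers=centers[half:].copy(),
        bin_means=folded,
        n_per_bin=m,
        raw_centers=centers,
        raw_means=raw_means,
        summed_bias=float(folded.sum()),
    )


def summed_bias(errors, deltas, n_bins_raw=64, bin_frac=0.25):
    """Scalar attraction(+)/repulsion(−) index: sum of folded bias-bin means."""
    return bias_curve(errors, deltas, n_bins_raw=n_bins_raw, bin_frac=bin_frac).summed_bias


# ---------------------------------------------------------------------------
# von Mises mixture model


def _vm_logpdf_deg(err, kappa):
    """log density over orientation error in degrees, von Mises on the doubled circle."""
    c = np.cos(np.radians(2.0 * np.asarray(err, dtype=float)))
    # log I0(kappa) = log(i0e(kappa)) + kappa, overflow-safe
    return kappa * (c - 1.0) - np.log(180.0 * i0e(kappa))


def _a1(kappa):
    return i1e(kappa) / i0e(kappa)


def _a1inv(r):
    """Invert the mean-resultant function A1(kappa) = R (Best & Fisher start, Newton polish)."""
    r = float(min(max(r, 0.0), 1.0 - 1e-12))
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    k = min(max(k, 1e-6), 1e6)
    for _ in range(25):
        a = _a1(k)
        da = 1.0 - a / k - a * a  # d A1 / d kappa
        if da <= 0:
            break
        step = (a - r) / da
        k_new = min(max(k - step, 1e-8), 1e8)
        if abs(k_new - k) < 1e-10 * max(1.0, k):
            k = k_new
            break
        k = k_new
    return k


@dataclass
class MixtureFit:
    """EM fit of the target/swap/guess von Mises mixture."""

    kappa: float
    p_target: float
    p_guess: float
    p_swap: float
    trial_weights: np.ndarray  # (n, 3) posterior responsibilities (target, swap, guess)
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path=None):
        d = {
            "kappa": self.kappa,
            "p_target": self.p_target,
            "p_guess": self.p_guess,
            "p_swap": self.p_swap,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        if path is not None:
            with open(path, "w") as f:
                json.dump(d, f, indent=2)
        return d


def fit_mixture(
    errors_to_target,
    errors_to_nontarget: Optional[np.ndarray] = None,
    init=None,
    max_iter=500,
    tol=1e-8,
    kappa_min=1.0,
):
    """Maximum-likelihood mixture fit by EM.

    ``errors_to_target`` are signed errors in (−90, 90]; ``errors_to_nontarget``
    may be None (no swap component) or contain NaN for trials without a
    nontarget — those trials carry zero swap responsibility.  ``init`` may be
    a dict with keys among {kappa, p_target, p_swap, p_guess}; the default is
    a method-of-moments kappa and weights (0.8, 0.1, 0.1).  Non-convergence
    returns the best fit with ``converged=False`` rather than raising.

    ``kappa_min`` floors the concentration (init and M-step): a von Mises
    with kappa near 0 is indistinguishable from the uniform guess component,
    so without the floor the fit is unidentified on near-uniform data.  The
    constrained M-step keeps EM monotone.
    """
    e_t = np.asarray(errors_to_target, dtype=float)
    n = e_t.size
    if n < 3:
        raise ValueError("fit_mixture needs at least 3 trials")
    if not np.all(np.isfinite(e_t)):
        raise ValueError("errors_to_target must be finite")
    if errors_to_nontarget is None:
        e_nt = np.full(n, np.nan)
    else:
        e_nt = np.asarray(errors_to_nontarget, dtype=float)
        if e_nt.shape != e_t.shape:
            raise ValueError("errors_to_nontarget shape mismatch")
    has_nt = np.isfinite(e_nt)
    any_swap = bool(has_nt.any())

    init = dict(init or {})
    kappa = max(float(init.get("kappa", _a1inv(resultant_length(e_t)))), kappa_min)
    if any_swap:
        p = np.array(
            [init.get("p_target", 0.8), init.get("p_swap", 0.1), init.get("p_guess", 0.1)]
        )
    else:
        p = np.array([init.get("p_target", 0.9), 0.0, init.get("p_guess", 0.1)])
    p = p / p.sum()

    log_guess = -np.log(180.0)
    ll_prev = -np.inf
    ll_path = []
    converged = False
    w = np.zeros((n, 3))
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space
        log_parts = np.full((n, 3), -np.inf)
        if p[0] > 0:
            log_parts[:, 0] = np.log(p[0]) + _vm_logpdf_deg(e_t, kappa)
        if p[1] > 0:
            lp = np.full(n, -np.inf)
            lp[has_nt] = np.log(p[1]) + _vm_logpdf_deg(e_nt[has_nt], kappa)
            log_parts[:, 1] = lp
        if p[2] > 0:
            log_parts[:, 2] = np.log(p[2]) + log_guess
        mx = log_parts.max(axis=1)
        lse = mx + np.log(np.exp(log_parts - mx[:, None]).sum(axis=1))
        ll = float(lse.sum())
        w = np.exp(log_parts - lse[:, None])
        ll_path.append(ll)

        # M-step
        p = w.mean(axis=0)
        if not any_swap:
            p[1] = 0.0
            p = p / p.sum()
        wt = w[:, 0].sum() + w[has_nt, 1].sum()
        if wt > 0:
            # components have fixed mean zero: use the cosine moment, not |resultant|
            c = (w[:, 0] * np.cos(np.radians(2.0 * e_t))).sum()
            c += (w[has_nt, 1] * np.cos(np.radians(2.0 * e_nt[has_nt]))).sum()
            kappa = max(_a1inv(max(c / wt, 0.0)), kappa_min)

        if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 1:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    return MixtureFit(
        kappa=float(kappa),
        p_target=float(p[0]),
        p_guess=float(p[2]),
        p_swap=float(p[1]),
        trial_weights=w,
        loglik=float(ll_prev),
        converged=converged,
        n_iter=it,
        loglik_path=np.asarray(ll_path),
    )
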