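"""Circular statistics on the 180-degree orientation circle.

Orientations are 180-degree periodic: a grating at 10 degrees is identical to
one at 190 degrees.  All circular statistics are therefore computed on the
doubled-angle circle (angles multiplied by 2 live on a conventional 360-degree
circle), and signed differences are mapped to (-90, 90] degrees.  Exact
antipodes (difference of exactly 90 degrees) map to +90 — this tie-break is
applied once here and inherited everywhere.
"""

from __future__ import annotations

import numpy as np

ORI_PERIOD = 180.0


def wrap_ori(angles):
    """Fold orientations into [0, 180)."""
    return np.asarray(angles, dtype=float) % ORI_PERIOD


def signed_diff(a, b):
    """Signed circular difference a - b on the orientation circle.

    Returns values in (-90, 90]; antipodal pairs map to +90.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % ORI_PERIOD
    return np.where(d > 90.0, d - ORI_PERIOD, d)


def dog(delta, amp, width):
    """Derivative-of-Gaussian bias curve.

    ``dog(delta, a, w) = a * (delta/w) * exp(0.5 - delta**2 / (2 w**2))`` —
    normalized so the peak value is exactly ``a`` (degrees) at ``delta == w``.
    An odd function of ``delta``: attraction toward an inducer clockwise of
    the target appears as a positive error at positive delta.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    delta = np.asarray(delta, dtype=float)
    return amp * (delta / width) * np.exp(0.5 - delta**2 / (2.0 * width**2))


def dog_window_mean(center, halfwidth, amp, width):
    """Exact mean of :func:`dog` over the window [center-halfwidth, center+halfwidth].

    The DoG has the antiderivative ``-a * w * exp(0.5 - x^2/(2 w^2))``, so the
    window average is available in closed form.  This is the expected value of
    a quantile-binned bias estimate when deltas are uniform over the window.
    """
    if halfwidth <= 0:
        return dog(center, amp, width)
    lo = np.asarray(center, dtype=float) - halfwidth
    hi = np.asarray(center, dtype=float) + halfwidth

    def antider(x):
        return -amp * width * np.exp(0.5 - x**2 / (2.0 * width**2))

    return (antider(hi) - antider(lo)) / (2.0 * halfwidth)


def vonmises_ori_noise(rng, kappa, size):
    """Draw orientation-scale noise (degrees) from a von Mises on the doubled circle.

    ``kappa`` is the concentration on the doubled-angle circle; ``np.inf``
    yields exactly zero noise (the "noiseless" flag).
    """
    if np.isinf(kappa):
        return np.zeros(size)
    return np.degrees(rng.vonmises(0.0, kappa, size)) / 2.0


def resultant_length(ori, weights=None):
    """Mean resultant length of orientations on the doubled-angle circle."""
    ang = np.radians(2.0 * np.asarray(ori, dtype=float))
    z = np.exp(1j * ang)
    if weights is None:
        return float(np.abs(z.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.abs((w * z).sum()) / w.sum())


def kuiper_uniform_test(ori, period=ORI_PERIOD):
    """Kuiper's test of uniformity for circular data on [0, period).

    Rotation-invariant analogue of the Kolmogorov-Smirnov test.  Returns
    ``(V, p)`` with the Stephens (1970) finite-sample corrected asymptotic
    tail probability.
    """
    u = np.sort((np.asarray(ori, dtype=float) % period) / period)
    n = u.size
    if n < 8:
        raise ValueError("kuiper_uniform_test needs at least 8 observations")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    v = d_plus + d_minus
    lam = v * (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n))
    j = np.arange(1, 101)
    p = 2.0 * np.sum((4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2))
    return float(v), float(min(max(p, 0.0), 1.0))


def rayleigh_uniform_test(ori):
    """Rayleigh test of uniformity on the doubled-angle circle.

    Sensitive to a unimodal departure from uniformity.  Returns ``(z, p)``.
    """
    ori = np.asarray(ori, dtype=float)
    n = ori.size
    r = resultant_length(ori)
    z = n * r**2
    # Zar's finite-n correction to the exp(-z) tail approximation
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))
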