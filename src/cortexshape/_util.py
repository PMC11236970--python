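"""Small shared numerical helpers (sub-pixel peak fits, circular interpolation)."""

from __future__ import annotations

import numpy as np


def parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location by 3-point parabola around index ``i``.

    Returns (offset, value); offset in [-1, 1] relative to ``i``.
    Falls back to (0, y[i]) at array edges or degenerate curvature.
    """
    if i <= 0 or i >= len(y) - 1:
        return 0.0, float(y[i])
    y0, y1, y2 = float(y[i - 1]), float(y[i]), float(y[i + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0 or not np.isfinite(denom):
        return 0.0, y1
    off = 0.5 * (y0 - y2) / denom
    off = float(np.clip(off, -1.0, 1.0))
    val = y1 - 0.25 * (y0 - y2) * off
    return off, float(val)


def gaussian_peak_1d(s: np.ndarray, y: np.ndarray, halfwidth: int = 3):
    """Locate a 1D peak by a local Gaussian fit around the discrete maximum.

    Fits ``a * exp(-(s-mu)^2 / 2 w^2) + c`` over ``+-halfwidth`` samples
    around the argmax.  Returns ``(mu, amplitude_plus_offset, width)``.
    Raises ValueError when no usable peak exists (flat or edge-pinned).
    """
    from scipy.optimize import curve_fit

    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    i = int(np.argmax(y))
    if i < 1 or i > len(y) - 2:
        raise ValueError("peak lies at the profile edge")
    lo, hi = max(0, i - halfwidth), min(len(y), i + halfwidth + 1)
    ss, yy = s[lo:hi], y[lo:hi]
    if np.ptp(yy) <= 0:
        raise ValueError("flat profile, no peak")
    ds = abs(s[1] - s[0])

    def model(x, a, mu, w, c):
        return a * np.exp(-0.5 * ((x - mu) / w) ** 2) + c

    p0 = (float(y[i] - yy.min()), float(s[i]), 1.5 * ds, float(yy.min()))
    try:
        popt, _ = curve_fit(
            model, ss, yy, p0=p0,
            bounds=([0.0, ss[0] - ds, 0.25 * ds, -np.inf],
                    [np.inf, ss[-1] + ds, 20.0 * ds * halfwidth, np.inf]),
            maxfev=2000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological profiles
        raise ValueError(f"Gaussian peak fit failed: {exc}") from exc
    a, mu, w, c = popt
    return float(mu), float(a + c), float(w)


def interp_periodic(theta_query: np.ndarray, theta: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``values(theta)`` periodic on [-pi, pi).

    ``theta`` must be sorted ascending within one period.
    """
    theta = np.asarray(theta, dtype=float)
    values = np.asarray(values, dtype=float)
    two_pi = 2.0 * np.pi
    tq = np.mod(np.asarray(theta_query, dtype=float) - theta[0], two_pi) + theta[0]
    t_ext = np.concatenate([theta, theta[:1] + two_pi])
    v_ext = np.concatenate([values, values[:1]])
    return np.interp(tq, t_ext, v_ext)
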