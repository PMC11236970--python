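"""Deformation spectra, autocorrelation size and local curvature.

Works on the deformation amplitude ``u(theta, t) = R(theta, t) - <R>_theta``
sampled on a uniform angle grid (see
:func:`cortexshape.contour_shape.radial_decomposition`):

- angular power spectrum ``<|u(q)|^2>_t`` and its log-log scaling
  exponent alpha (q^-4: bending/elasticity dominated; q^-2: tension
  dominated);
- a fit of the fluctuation form ``A / (kappa q^4 + gamma q^2)``;
- the characteristic deformation size theta_c, the smallest first zero
  of the circular angular autocorrelation of u over frames;
- signed local curvature of the contour by a Pratt algebraic circle fit
  through three separated vertices.

FFT normalization: ``power(q) = c_q |FFT(u)(q)|^2 / N`` one-sided, with
c_q = 2 for 0 < q < N/2 and 1 at q = 0 and the Nyquist mode, so that
``sum_q power(q) = N * var(u)`` (Parseval) and a pure mode
``u = a cos(q theta)`` carries ``power(q) = a^2 N / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from cortexshape.contour_shape import MembraneContour


@dataclass
class DeformationSpectrum:
    q: np.ndarray                 # integer angular wavenumbers (one-sided)
    power: np.ndarray             # <|u(q)|^2>_t, um^2 (normalization above)
    n_frames_averaged: int
    alpha: float | None = None
    kappa_fit: float | None = None    # arbitrary units unless calibrated
    gamma_fit: float | None = None
    amplitude_fit: float | None = None


@dataclass
class DeformationSize:
    theta_c_deg: float
    t_prime: int                  # frame index at which theta_c is attained
    acf: np.ndarray               # normalized ACF of that frame, acf(0) = 1
    dtheta_deg: np.ndarray
    first_zero_per_frame: np.ndarray  # degrees; NaN where no zero-crossing


@dataclass
class CurvatureProfile:
    curvature_per_um: np.ndarray  # signed, one value per vertex
    separation: int
    collinear: np.ndarray         # flags where the triplet was collinear


# ---------------------------------------------------------------------------
# power spectrum and fits
# ---------------------------------------------------------------------------

def deformation_power_spectrum(
    u_series: np.ndarray, frames: slice | np.ndarray | None = None
) -> DeformationSpectrum:
    """Time-averaged one-sided angular power spectrum of u(theta, t).

    ``u_series`` has shape (n_frames, N) on a uniform theta grid;
    ``frames`` selects the frames to average (default: all; the study
    convention is the first 20 post-activation frames).
    """
    u = np.atleast_2d(np.asarray(u_series, dtype=float))
    if frames is not None:
        u = u[frames]
    if u.shape[0] < 1:
        raise ValueError("need at least one frame")
    N = u.shape[1]
    U = np.fft.rfft(u, axis=1)
    p = np.abs(U) ** 2 / N
    weights = np.full(p.shape[1], 2.0)
    weights[0] = 1.0
    if N % 2 == 0:
        weights[-1] = 1.0
    power = (p * weights[None, :]).mean(axis=0)
    q = np.arange(power.shape[0])
    return DeformationSpectrum(q=q, power=power, n_frames_averaged=u.shape[0])


def fit_scaling_exponent(
    spectrum: DeformationSpectrum, q_range: tuple[int, int] | None = None
) -> float:
    """Scaling exponent alpha of a q^-alpha fit to the power spectrum.

    Least-squares slope of log power vs log q; the default range is all
    q >= 2 (q = 0 and 1 are area / translation artifacts and are removed
    at decomposition).  Zero-power modes are excluded with a warning.
    """
    q, p = spectrum.q, spectrum.power
    lo, hi = (2, int(q.max())) if q_range is None else q_range
    sel = (q >= lo) & (q <= hi)
    if (p[sel] <= 0).any():
        warnings.warn("zero-power modes excluded from the scaling fit",
                      stacklevel=2)
        sel &= p > 0
    if sel.sum() < 4:
        raise ValueError("need at least 4 modes with positive power")
    slope, _ = np.polyfit(np.log(q[sel]), np.log(p[sel]), 1)
    alpha = -float(slope)
    spectrum.alpha = alpha
    return alpha


def fit_fluctuation_model(
    spectrum: DeformationSpectrum, q_range: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Fit ``power = A / (kappa q^4 + gamma q^2)`` in log space.

    kappa and gamma are constrained non-negative; the amplitude A carries
    the overall scale, so kappa and gamma are reported in arbitrary
    units unless the spectrum is calibrated.  A one-parameter (degenerate)
    fit is reported when the other parameter hits its zero bound.

    Returns ``(kappa_fit, gamma_fit)``; the fitted amplitude is stored on
    the spectrum.
    """
    q, p = spectrum.q, spectrum.power
    lo, hi = (2, int(q.max())) if q_range is None else q_range
    sel = (q >= lo) & (q <= hi) & (p > 0)
    if sel.sum() < 5:
        raise ValueError("need at least 5 modes with positive power")
    qq, pp = q[sel].astype(float), p[sel]
    logp = np.log(pp)

    # parameters: log A, and the shape weight w in [0, 1] with
    # kappa = w / A, gamma = (1 - w) / A
    def resid(params):
        logA, w = params
        denom = w * qq**4 + (1.0 - w) * qq**2
        return logA - np.log(denom) - logp

    best = None
    for w0 in (0.05, 0.5, 0.95):
        logA0 = np.log(pp[0] * (w0 * qq[0] ** 4 + (1 - w0) * qq[0] ** 2))
        sol = least_squares(resid, x0=[logA0, w0],
                            bounds=([-np.inf, 0.0], [np.inf, 1.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success and best.cost > 1e3:
        raise RuntimeError(
            f"fluctuation-model fit did not converge (residual {best.cost:.3g})"
        )
    logA, w = best.x
    A = float(np.exp(logA))
    kappa = float(w / A)
    gamma = float((1.0 - w) / A)
    spectrum.kappa_fit, spectrum.gamma_fit, spectrum.amplitude_fit = kappa, gamma, A
    return kappa, gamma


# ---------------------------------------------------------------------------
# angular autocorrelation deformation size
# ---------------------------------------------------------------------------

def angular_autocorrelation(u: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Circular (wrap-around) angular autocorrelation of one frame.

    ``acf(k) = <u(theta + k dtheta) u(theta)>_theta``; normalized by
    acf(0) by default (the zero-crossing location is unaffected).
    """
    u = np.asarray(u, dtype=float)
    U = np.fft.rfft(u)
    acf = np.fft.irfft(np.abs(U) ** 2, n=len(u)) / len(u)
    if normalize:
        if acf[0] <= 0:
            raise ValueError("zero-variance frame has no autocorrelation")
        acf = acf / acf[0]
    return acf


def _first_zero_deg(acf: np.ndarray) -> float:
    """First zero crossing of the ACF (degrees), linear interpolation;
    NaN when the ACF stays positive over the half period."""
    n = len(acf)
    half = n // 2
    for k in range(1, half + 1):
        if acf[k] == 0.0:
            return 360.0 * k / n
        if acf[k - 1] > 0 > acf[k]:
            frac = acf[k - 1] / (acf[k - 1] - acf[k])
            return 360.0 * (k - 1 + frac) / n
    return np.nan


def angular_autocorrelation_size(u_series: np.ndarray) -> DeformationSize:
    """Characteristic deformation size theta_c.

    Per frame, the first zero of the circular ACF of u(theta) is found by
    sign change with linear interpolation; theta_c is the smallest first
    zero over frames and t' the frame attaining it.  Frames whose ACF has
    no zero crossing are skipped; if every frame skips, an error is
    raised.
    """
    u = np.atleast_2d(np.asarray(u_series, dtype=float))
    if u.shape[0] < 1:
        raise ValueError("need at least one frame")
    zeros = np.array([
        _first_zero_deg(angular_autocorrelation(frame)) for frame in u
    ])
    if np.all(np.isnan(zeros)):
        raise ValueError("no frame has an autocorrelation zero crossing")
    t_prime = int(np.nanargmin(zeros))
    acf = angular_autocorrelation(u[t_prime])
    n = u.shape[1]
    return DeformationSize(
        theta_c_deg=float(zeros[t_prime]),
        t_prime=t_prime,
        acf=acf,
        dtheta_deg=360.0 * np.arange(n) / n,
        first_zero_per_frame=zeros,
    )


# ---------------------------------------------------------------------------
# Pratt circle-fit local curvature
# ---------------------------------------------------------------------------

def pratt_circle_fit(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Pratt) circle fit; returns (cx, cy, radius).

    Radius is inf for collinear points.  With exactly three points this
    is the circumscribed circle.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    x0, y0 = x.mean(), y.mean()
    xs, ys = x - x0, y - y0
    z = xs**2 + ys**2
    Z = np.column_stack([z, xs, ys, np.ones_like(xs)])
    M = Z.T @ Z
    B = np.array([[0.0, 0.0, 0.0, -2.0],
                  [0.0, 1.0, 0.0, 0.0],
                  [0.0, 0.0, 1.0, 0.0],
                  [-2.0, 0.0, 0.0, 0.0]])
    from scipy.linalg import eig

    vals, vecs = eig(M, B)
    vals = np.real(vals)
    good = np.isfinite(vals) & (vals > -1e-10)
    if not good.any():
        return x0, y0, np.inf
    idx = np.where(good)[0][np.argmin(vals[good])]
    A, Bc, Cc, D = np.real(vecs[:, idx])
    if abs(A) < 1e-12 * max(1.0, abs(Bc), abs(Cc)):
        return x0, y0, np.inf
    cx = -Bc / (2 * A) + x0
    cy = -Cc / (2 * A) + y0
    r2 = (Bc**2 + Cc**2 - 4 * A * D) / (4 * A**2)
    return float(cx), float(cy), float(np.sqrt(max(r2, 0.0)))


def local_curvature(contour: MembraneContour, separation: int = 5) -> CurvatureProfile:
    """Signed local curvature at every vertex from a Pratt circle fit.

    The circle passes through the vertex and its ``+-separation``
    neighbors; the sign comes from the local turning direction (positive
    where the counter-clockwise contour turns left, so a circle has
    curvature +1/R everywhere).  Collinear triplets give curvature 0 and
    are flagged.
    """
    if separation < 1:
        raise ValueError("separation must be >= 1 vertex")
    v = contour.vertices
    n = len(v)
    prv = np.roll(v, separation, axis=0)
    nxt = np.roll(v, -separation, axis=0)
    curv = np.zeros(n)
    collinear = np.zeros(n, dtype=bool)
    cross = ((v[:, 0] - prv[:, 0]) * (nxt[:, 1] - v[:, 1])
             - (v[:, 1] - prv[:, 1]) * (nxt[:, 0] - v[:, 0]))
    for i in range(n):
        _, _, r = pratt_circle_fit(np.vstack([prv[i], v[i], nxt[i]]))
        if not np.isfinite(r) or r <= 0:
            collinear[i] = True
            continue
        curv[i] = np.sign(cross[i]) / r
    return CurvatureProfile(curvature_per_um=curv, separation=separation,
                            collinear=collinear)


def total_turning(contour: MembraneContour, profile: CurvatureProfile) -> float:
    """Integral of curvature along arc length; 2*pi for a simple CCW contour."""
    v = contour.vertices
    seg = np.hypot(*(np.roll(v, -1, axis=0) - v).T)
    ds = 0.5 * (seg + np.roll(seg, 1))
    return float(np.sum(profile.curvature_per_um * ds))
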