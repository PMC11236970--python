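"""Sub-resolution cortex thickness from two-channel radial profiles.

The cortical actin shell (thickness h ~ 0.3 um) is below the resolution
of the microscope (PSF SD sigma ~ 0.119 um), so h cannot be read off an
intensity profile directly.  Instead it is inferred from the distance
Delta between the membrane-fluorescence peak and the actin-fluorescence
peak along the inward normal.  For a shell of thickness h starting at
the membrane, blurred with a Gaussian PSF over a fluorescent interior
(I_V) and exterior (I_out), the actin peak sits at h/2 plus a shift

    delta = (sigma^2 / h) * ln r,   r = (I_out - I_S) / (I_V - I_S),

toward the liposome center, so h = 2 * (Delta - delta).  Because delta
itself depends on h, the pair of relations is a quadratic in h,

    h^2 - 2 Delta h + 2 sigma^2 ln r = 0,

solved exactly here; the physical root is h = Delta + sqrt(Delta^2 -
2 sigma^2 ln r), the branch with h -> 2 Delta as sigma -> 0.

The PSF width sigma is calibrated by fitting 2D Gaussians to
sub-resolution bead images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cortexshape.contour_shape import MembraneContour, radial_decomposition


class ThicknessError(RuntimeError):
    pass


@dataclass
class RadialProfile:
    """Averaged two-channel intensity profile along the inward normal.

    ``s`` is the signed distance along the inward normal in micrometres,
    0 at the membrane peak, positive toward the liposome center.
    """

    s: np.ndarray
    I_memb: np.ndarray
    I_act: np.ndarray
    delta_peak_um: float        # membrane-peak to actin-peak distance
    I_S: float                  # actin cortex peak intensity
    I_V: float                  # interior plateau
    I_out: float                # exterior plateau
    n_rays: int

    def __post_init__(self):
        if not (self.I_S > self.I_V and self.I_S > self.I_out):
            raise ThicknessError(
                "cortex is not the brightest radial feature "
                f"(I_S={self.I_S:.3g}, I_V={self.I_V:.3g}, I_out={self.I_out:.3g})"
            )


def _ls_quadratic_peak(s, y, i, halfwidth, log=False):
    """Peak location/value by least-squares parabola around index i."""
    xx = s[i - halfwidth:i + halfwidth + 1]
    yy = y[i - halfwidth:i + halfwidth + 1]
    if log:
        if np.any(yy <= 0):
            log = False
        else:
            yy = np.log(yy)
    coef = np.polyfit(xx, yy, 2)
    if coef[0] >= 0:
        return float(s[i]), float(y[i])
    mu = -coef[1] / (2 * coef[0])
    mu = float(np.clip(mu, xx[0], xx[-1]))
    val = float(np.polyval(coef, mu))
    return mu, (float(np.exp(val)) if log else val)


@dataclass
class ThicknessEstimate:
    h_um: float
    delta_shift_um: float       # implied peak shift delta
    sigma_psf_um: float
    delta_peak_um: float
    n_profiles: int = 0


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

def normal_intensity_profiles(
    contour: MembraneContour,
    membrane_image: np.ndarray,
    actin_image: np.ndarray,
    pixel_size_um: float,
    depth_um: float = 1.5,
    n_rays: int = 120,
    step_um: float | None = None,
) -> RadialProfile:
    """Average membrane / actin line profiles along inward normals.

    Profiles are sampled by bilinear interpolation at ``n_rays`` angles,
    aligned at the per-ray membrane peak (local Gaussian fit), then
    averaged.  The interior and exterior plateaus I_V and I_out are
    medians of the inner / outer profile tails; Delta comes from a local
    Gaussian fit to the averaged actin peak.

    Rays where the membrane peak cannot be located are dropped; more
    than 50% dropped is an error.
    """
    from cortexshape._util import parabolic_peak

    if step_um is None:
        step_um = 0.25 * pixel_size_um
    theta, R, _, R_mean = radial_decomposition(contour, n_theta=n_rays)
    center_px = contour.center_of_mass / pixel_size_um
    memb = np.asarray(membrane_image, dtype=float)
    act = np.asarray(actin_image, dtype=float)
    if np.ptp(act) <= 0:
        raise ThicknessError("blank actin channel: no radial actin signal")

    s = np.arange(-depth_um, depth_um + step_um / 2, step_um)  # inward positive
    n_s = len(s)
    aligned_m = np.full((n_rays, n_s), np.nan)
    aligned_a = np.full((n_rays, n_s), np.nan)
    kept = 0
    for k in range(n_rays):
        rho_um = R[k] - s  # positive s goes inward
        cols = center_px[0] + rho_um * np.cos(theta[k]) / pixel_size_um
        rows = center_px[1] + rho_um * np.sin(theta[k]) / pixel_size_um
        pm = ndimage.map_coordinates(memb, [rows, cols], order=3, mode="nearest")
        pa = ndimage.map_coordinates(act, [rows, cols], order=3, mode="nearest")
        i_m = int(np.argmax(pm))
        i_a = int(np.argmax(pa))
        if not (0 < i_m < n_s - 1 and 0 < i_a < n_s - 1):
            continue
        vals_m = pm[i_m - 1:i_m + 2]
        if np.all(vals_m > 0):
            # log-parabola: exact sub-sample location for a Gaussian ridge
            off_m, _ = parabolic_peak(np.log(vals_m), 1)
        else:
            off_m, _ = parabolic_peak(pm, i_m)
        mu_m = s[i_m] + off_m * step_um
        # re-center both channels at the per-ray membrane peak
        aligned_m[kept] = np.interp(s + mu_m, s, pm, left=np.nan, right=np.nan)
        aligned_a[kept] = np.interp(s + mu_m, s, pa, left=np.nan, right=np.nan)
        kept += 1
    if kept < n_rays / 2:
        raise ThicknessError(
            f"membrane peak found on only {kept}/{n_rays} rays"
        )
    with np.errstate(invalid="ignore"):
        mean_m = np.nanmean(aligned_m[:kept], axis=0)
        mean_a = np.nanmean(aligned_a[:kept], axis=0)
    valid = np.isfinite(mean_m) & np.isfinite(mean_a)
    s, mean_m, mean_a = s[valid], mean_m[valid], mean_a[valid]

    # peak distance and height from the noise-suppressed averaged profiles;
    # least-squares quadratic over +-3 samples (log for the Gaussian
    # membrane ridge) balances sub-sample accuracy against shot noise
    i_m = int(np.argmax(mean_m))
    i_a = int(np.argmax(mean_a))
    hw = 3
    if not (hw <= i_m < len(s) - hw and hw <= i_a < len(s) - hw):
        raise ThicknessError("averaged peak lies at the profile edge; "
                             "increase depth_um")
    mu_m, _ = _ls_quadratic_peak(s, mean_m, i_m, hw, log=True)
    mu_a, I_S = _ls_quadratic_peak(s, mean_a, i_a, hw)
    delta = mu_a - mu_m

    tail = max(3, int(0.15 * len(s)))
    I_out = float(np.median(mean_a[:tail]))      # most-outside samples
    I_V = float(np.median(mean_a[-tail:]))       # deepest samples
    return RadialProfile(
        s=s, I_memb=mean_m, I_act=mean_a,
        delta_peak_um=float(delta),
        I_S=float(I_S), I_V=I_V, I_out=I_out,
        n_rays=kept,
    )


# ---------------------------------------------------------------------------
# PSF calibration from beads
# ---------------------------------------------------------------------------

def psf_sigma_from_beads(
    bead_image: np.ndarray,
    pixel_size_um: float,
    min_separation_px: float | None = None,
    threshold_rel: float = 0.3,
    patch_px: int = 6,
) -> tuple[float, np.ndarray]:
    """PSF standard deviation from 2D Gaussian fits to isolated beads.

    Detects local maxima, rejects overlapping and saturated spots, fits
    a symmetric 2D Gaussian to each remaining spot, and returns the mean
    sigma in micrometres plus the per-spot values.  Requires at least 3
    usable spots.
    """
    from scipy.optimize import curve_fit
    from skimage.feature import peak_local_max

    img = np.asarray(bead_image, dtype=float)
    if min_separation_px is None:
        min_separation_px = 2 * patch_px
    peaks = peak_local_max(img, min_distance=int(min_separation_px),
                           threshold_rel=threshold_rel)
    sigmas = []
    H, W = img.shape
    for py, px in peaks:
        lo_r, hi_r = py - patch_px, py + patch_px + 1
        lo_c, hi_c = px - patch_px, px + patch_px + 1
        if lo_r < 0 or lo_c < 0 or hi_r > H or hi_c > W:
            continue
        patch = img[lo_r:hi_r, lo_c:hi_c]
        # saturated spot: a flat-topped plateau at the patch maximum
        if np.sum(patch >= patch.max() * (1 - 1e-9)) > 2:
            continue
        rr, cc = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]

        def gauss2d(coords, a, r0, c0, s, off):
            r, c = coords
            return (a * np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / (2 * s**2))
                    + off).ravel()

        p0 = (float(patch.max() - patch.min()), patch_px, patch_px, 1.5,
              float(patch.min()))
        try:
            popt, _ = curve_fit(gauss2d, (rr, cc), patch.ravel(), p0=p0,
                                maxfev=2000)
        except RuntimeError:
            continue
        s_fit = abs(popt[3])
        if 0.2 < s_fit < patch_px:
            sigmas.append(s_fit * pixel_size_um)
    if len(sigmas) < 3:
        raise ThicknessError(
            f"only {len(sigmas)} usable bead spots found (need >= 3)"
        )
    sigmas = np.asarray(sigmas)
    return float(sigmas.mean()), sigmas


# ---------------------------------------------------------------------------
# thickness from the two-peak geometry
# ---------------------------------------------------------------------------

def thickness_from_profile(
    delta_peak_um: float,
    sigma_um: float,
    I_S: float,
    I_V: float,
    I_out: float,
    n_profiles: int = 0,
) -> ThicknessEstimate:
    """Cortex thickness from the peak distance Delta with PSF correction.

    Solves ``h^2 - 2 Delta h + 2 sigma^2 ln r = 0`` exactly, with
    ``r = (I_out - I_S)/(I_V - I_S)``, and returns the physical root
    ``h = Delta + sqrt(Delta^2 - 2 sigma^2 ln r)`` (the branch recovering
    h = 2 Delta in the sigma -> 0 limit).  The implied shift
    ``delta = (sigma^2/h) ln r`` is reported alongside.
    """
    if delta_peak_um <= 0:
        raise ThicknessError("need a positive membrane-to-actin peak distance")
    if sigma_um <= 0:
        raise ThicknessError("need a positive PSF sigma")
    if not (I_S > I_V and I_S > I_out):
        raise ThicknessError("intensity ordering violated: require I_S > I_V "
                             "and I_S > I_out")
    r = (I_out - I_S) / (I_V - I_S)
    if r <= 0:
        raise ThicknessError("intensity ordering violated: contrast ratio "
                             "r must be positive")
    log_r = np.log(r)
    disc = delta_peak_um**2 - 2.0 * sigma_um**2 * log_r
    if disc < 0:
        raise ThicknessError(
            "profile inconsistent with the two-peak model: Delta = "
            f"{delta_peak_um:.3g} um is too small for sigma = {sigma_um:.3g} "
            f"um and contrast ratio r = {r:.3g}"
        )
    h = delta_peak_um + np.sqrt(disc)
    delta_shift = sigma_um**2 / h * log_r
    return ThicknessEstimate(
        h_um=float(h), delta_shift_um=float(delta_shift),
        sigma_psf_um=float(sigma_um), delta_peak_um=float(delta_peak_um),
        n_profiles=n_profiles,
    )


def estimate_thickness(
    profile: RadialProfile,
    sigma_um: float,
    peak_correction: bool = True,
    max_iter: int = 50,
    tol_um: float = 1e-4,
) -> ThicknessEstimate:
    """Thickness from an extracted radial profile.

    When ``peak_correction`` is on (default), the finite-thickness
    attenuation of the observed cortex peak is corrected
    self-consistently: for h comparable to sigma the blurred peak does
    not reach the cortex plateau intensity, so using the observed peak
    height as I_S biases h low.  The plateau intensity and h are
    iterated to joint consistency with the observed peak height and
    position:

        I_peak = I_out (1 - a) + I_V b + I_S (a - b),
        a = Phi(Delta/sigma), b = Phi((Delta - h)/sigma).
    """
    from scipy.stats import norm

    if not peak_correction:
        return thickness_from_profile(profile.delta_peak_um, sigma_um,
                                      profile.I_S, profile.I_V,
                                      profile.I_out,
                                      n_profiles=profile.n_rays)
    delta = profile.delta_peak_um
    if delta <= 0 or sigma_um <= 0:
        raise ThicknessError("need positive peak distance and PSF sigma")
    I_peak = profile.I_S
    a = norm.cdf(delta / sigma_um)
    h = 2.0 * delta          # ideal-geometry starting point
    I_S = I_peak
    log_r = 0.0
    for _ in range(max_iter):
        b = norm.cdf((delta - h) / sigma_um)
        if a - b <= 1e-6:
            break
        I_S_new = (I_peak - profile.I_out * (1 - a) - profile.I_V * b) / (a - b)
        if not (I_S_new > profile.I_V and I_S_new > profile.I_out):
            break
        r = (profile.I_out - I_S_new) / (profile.I_V - I_S_new)
        log_r = np.log(r)
        disc = max(delta**2 - 2.0 * sigma_um**2 * log_r, 0.0)
        h_new = delta + np.sqrt(disc)
        converged = abs(h_new - h) < tol_um
        h, I_S = h_new, I_S_new
        if converged:
            break
    return ThicknessEstimate(
        h_um=float(h), delta_shift_um=float(sigma_um**2 / h * log_r),
        sigma_psf_um=float(sigma_um), delta_peak_um=float(delta),
        n_profiles=profile.n_rays,
    )


def thickness_from_images(
    contour: MembraneContour,
    membrane_image: np.ndarray,
    actin_image: np.ndarray,
    pixel_size_um: float,
    sigma_um: float,
    **profile_kwargs,
) -> ThicknessEstimate:
    """Convenience pipeline: profiles -> corrected thickness estimate."""
    prof = normal_intensity_profiles(contour, membrane_image, actin_image,
                                     pixel_size_um, **profile_kwargs)
    return estimate_thickness(prof, sigma_um)
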