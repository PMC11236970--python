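"""Ground-truth synthetic liposome scenes for every analysis stage.

No raw microscopy data accompany the measurements this package
re-implements, so each estimator is validated against scenes built here
with known ground truth:

- near-circular contours whose angular mode amplitudes are drawn from a
  Helfrich-like spectrum ``<|a_q|^2> ~ 1/(kappa q^4 + gamma q^2)``;
- two-channel (membrane / actin) renderings of a contour with a cortex
  shell of finite thickness h, Gaussian PSF blur and Poisson-Gaussian
  noise;
- speckle image pairs advected by analytic flows with known divergence;
- filament textures with a prescribed nematic order;
- polarized cortical intensity patterns with an exact target polarity;
- sub-resolution bead images for PSF calibration.

All randomness flows from the explicit ``seed`` argument of each
generator; there is no hidden global state.  Coordinates follow the
image convention: x = column * pixel size, y = row * pixel size, angles
counter-clockwise from +x.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special
from scipy.optimize import brentq
from scipy.stats import norm

from cortexshape._util import interp_periodic
from cortexshape.contour_shape import MembraneContour, polarity_from_vertex_intensity

DEFAULT_PIXEL_SIZE_UM = 0.0938   # spinning-disk configuration used throughout
DEFAULT_FRAME_INTERVAL_S = 6.0
DEFAULT_PSF_SIGMA_UM = 0.119     # PSF standard deviation from bead calibration


class SceneError(RuntimeError):
    """Raised when a requested scene cannot be generated."""


@dataclass
class SceneTruth:
    """Ground truth recorded alongside a generated scene."""

    radius_um: float
    mode_amplitudes: dict[int, complex] = field(default_factory=dict)
    cortex_thickness_um: float = 0.0
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM
    polarity_true: float = 0.0
    order_param_true: float = 0.0
    flow_divergence_per_s: float = 0.0
    seed: int = 0
    # per-frame mode amplitudes for contour series (frame 0 == mode_amplitudes)
    mode_amplitude_series: list[dict[int, complex]] = field(default_factory=list)
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.cortex_thickness_um < 0 or self.psf_sigma_um < 0:
            raise ValueError("lengths must be non-negative")
        if abs(self.order_param_true) > 1:
            raise ValueError("|order_param_true| must be <= 1")
        for q in (0, 1):
            if self.mode_amplitudes.get(q, 0) != 0:
                raise ValueError("modes q=0 (area) and q=1 (translation) "
                                 "are excluded from deformation sampling")

    def to_json(self) -> str:
        def enc(d):
            return {str(q): [a.real, a.imag] for q, a in d.items()}
        payload = {
            "radius_um": self.radius_um,
            "mode_amplitudes": enc(self.mode_amplitudes),
            "cortex_thickness_um": self.cortex_thickness_um,
            "psf_sigma_um": self.psf_sigma_um,
            "polarity_true": self.polarity_true,
            "order_param_true": self.order_param_true,
            "flow_divergence_per_s": self.flow_divergence_per_s,
            "seed": self.seed,
            "mode_amplitude_series": [enc(d) for d in self.mode_amplitude_series],
            "intensities": self.intensities,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        raw = json.loads(text)
        def dec(d):
            return {int(q): complex(a[0], a[1]) for q, a in d.items()}
        raw["mode_amplitudes"] = dec(raw["mode_amplitudes"])
        raw["mode_amplitude_series"] = [dec(d) for d in raw["mode_amplitude_series"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# contour sampling from the fluctuation spectrum
# ---------------------------------------------------------------------------

def helfrich_mode_variance(q: np.ndarray, kappa: float, gamma: float) -> np.ndarray:
    """Unnormalized per-quadrature mode variance 1/(kappa q^4 + gamma q^2)."""
    q = np.asarray(q, dtype=float)
    return 1.0 / (kappa * q**4 + gamma * q**2)


def contour_from_modes(
    radius_um: float,
    mode_amplitudes: dict[int, complex],
    n_vertices: int = 360,
    center_um: tuple[float, float] = (0.0, 0.0),
    frame: int = 0,
) -> MembraneContour:
    """Polar contour r(theta) = R + sum_q Re[a_q e^{i q theta}]."""
    theta = np.linspace(-np.pi, np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, float(radius_um))
    for q, a in mode_amplitudes.items():
        r += np.real(a * np.exp(1j * q * theta))
    if r.min() <= 0:
        raise SceneError("mode amplitudes too large: contour crosses the origin")
    x = center_um[0] + r * np.cos(theta)
    y = center_um[1] + r * np.sin(theta)
    return MembraneContour(np.column_stack([x, y]), frame=frame)


def sample_contour_series(
    radius_um: float,
    kappa: float,
    gamma: float,
    n_modes: int = 12,
    n_frames: int = 1,
    seed: int = 0,
    amplitude_rms_um: float | None = None,
    n_vertices: int = 360,
    max_attempts: int = 50,
) -> tuple[list[MembraneContour], SceneTruth]:
    """Draw contour frames with Helfrich-distributed angular modes.

    Each frame gets independent complex amplitudes ``a_q`` (q = 2..n_modes;
    q=0 and q=1 are excluded as area / translation modes) with per-
    quadrature variance proportional to ``1/(kappa q^4 + gamma q^2)``.
    ``amplitude_rms_um`` sets the RMS of u(theta) per frame (default 2% of
    the radius).  Frames whose contour would self-intersect (r <= 0) are
    rejected and resampled, failing after ``max_attempts``.
    """
    if kappa < 0 or gamma < 0 or (kappa == 0 and gamma == 0):
        raise ValueError("need kappa >= 0, gamma >= 0, not both zero")
    if n_modes < 2 or n_frames < 1:
        raise ValueError("need n_modes >= 2 and n_frames >= 1")
    rng = np.random.default_rng(seed)
    if amplitude_rms_um is None:
        amplitude_rms_um = 0.02 * radius_um
    qs = np.arange(2, n_modes + 1)
    var = helfrich_mode_variance(qs, kappa, gamma)
    # E[u^2] = sum_q s_q^2 for a_q = x + i y with Var x = Var y = s_q^2
    scale = amplitude_rms_um**2 / var.sum()
    s_q = np.sqrt(scale * var)

    contours, series = [], []
    for k in range(n_frames):
        for attempt in range(max_attempts):
            re = rng.normal(0.0, s_q)
            im = rng.normal(0.0, s_q)
            amps = {int(q): complex(r_, i_) for q, r_, i_ in zip(qs, re, im)}
            try:
                c = contour_from_modes(radius_um, amps, n_vertices, frame=k)
            except SceneError:
                continue
            contours.append(c)
            series.append(amps)
            break
        else:
            raise SceneError(
                f"failed to draw a simple contour in {max_attempts} attempts; "
                "reduce amplitude_rms_um"
            )
    truth = SceneTruth(
        radius_um=radius_um,
        mode_amplitudes=series[0],
        mode_amplitude_series=series,
        seed=seed,
    )
    return contours, truth


# ---------------------------------------------------------------------------
# two-channel rendering
# ---------------------------------------------------------------------------

@dataclass
class PoissonGaussianNoise:
    """Shot noise (Poisson, scaled by a gain) plus Gaussian read noise.

    ``peak_photons`` is the expected photon count at unit intensity;
    the default gives SNR ~ 20 at the cortex peak, mimicking
    spinning-disk confocal data.
    """

    peak_photons: float = 400.0
    read_sigma: float = 0.01

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        shot = rng.poisson(np.clip(image, 0, None) * self.peak_photons)
        out = shot / self.peak_photons
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, image.shape)
        return out


def render_two_channel_frame(
    contour: MembraneContour,
    cortex_thickness_um: float,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    intensities: dict[str, float] | None = None,
    noise_model: PoissonGaussianNoise | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    image_shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render the membrane and actin channels of a liposome mid-plane.

    The membrane channel is an infinitely thin shell on the contour
    convolved with a Gaussian PSF of SD ``psf_sigma_um``.  The actin
    channel is a cortical shell of thickness h immediately inside the
    membrane (plateau intensity I_S) over a uniform interior I_V and
    exterior I_out, convolved with the same PSF, then degraded with
    Poisson-Gaussian noise when a noise model is given.

    The blur is applied analytically along the contour normal (exact for
    locally straight / gently curved shells): with s the signed inward
    depth from the membrane,

        I_act(s) = I_out + (I_S - I_out) Phi(s/sigma)
                   - (I_S - I_V) Phi((s - h)/sigma)

    which places the blurred actin peak at ``h/2 + (sigma^2/h) ln r``
    inside the membrane peak (r the intensity contrast ratio), the
    geometry assumed by the thickness estimator.

    The contour must be star-shaped about its center of mass (the signed
    depth is computed radially).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    h = float(cortex_thickness_um)
    if h < 0:
        raise ValueError("cortex_thickness_um must be >= 0")
    I = dict(I_S=1.0, I_V=0.35, I_out=0.05, I_memb=1.0)
    if intensities:
        I.update(intensities)
    if I["I_out"] >= I["I_S"] or I["I_V"] >= I["I_S"]:
        raise ValueError(
            "the cortex must be the brightest radial feature: "
            "require I_S > I_V and I_S > I_out"
        )
    if 0 < h < pixel_size_um:
        warnings.warn(
            "cortex thickness below one pixel: sub-resolution regime "
            "(valid and intended)", stacklevel=2,
        )

    # radial profile of the true contour about its center of mass
    v = contour.vertices - contour.center_of_mass
    ang = np.arctan2(v[:, 1], v[:, 0])
    rad = np.hypot(v[:, 0], v[:, 1])
    order = np.argsort(ang)
    ang_s, rad_s = ang[order], rad[order]

    margin_um = 4.0 * psf_sigma_um + h + 5 * pixel_size_um
    extent_um = rad.max() + margin_um
    if image_shape is None:
        n = 2 * int(np.ceil(extent_um / pixel_size_um)) + 1
        image_shape = (n, n)
    else:
        half = min(image_shape) * pixel_size_um / 2.0
        if half < extent_um:
            raise ValueError("image too small to contain the contour plus "
                             "a 3-sigma margin")
    cy = (image_shape[0] - 1) / 2.0
    cx = (image_shape[1] - 1) / 2.0

    rows, cols = np.mgrid[0:image_shape[0], 0:image_shape[1]]
    dx = (cols - cx) * pixel_size_um
    dy = (rows - cy) * pixel_size_um
    theta_pix = np.arctan2(dy, dx)
    rho_pix = np.hypot(dx, dy)
    R_theta = interp_periodic(theta_pix.ravel(), ang_s, rad_s).reshape(theta_pix.shape)
    s = R_theta - rho_pix  # signed inward depth from membrane (um)

    sig = max(psf_sigma_um, 1e-9)
    memb = I["I_memb"] * np.exp(-0.5 * (s / sig) ** 2)
    actin = (
        I["I_out"]
        + (I["I_S"] - I["I_out"]) * norm.cdf(s / sig)
        - (I["I_S"] - I["I_V"]) * norm.cdf((s - h) / sig)
    )
    if noise_model is not None:
        rng = np.random.default_rng(seed)
        memb = noise_model.apply(memb, rng)
        actin = noise_model.apply(actin, rng)

    truth = SceneTruth(
        radius_um=float(rad.mean()),
        cortex_thickness_um=h,
        psf_sigma_um=psf_sigma_um,
        seed=seed,
        intensities=I,
    )
    return memb, actin, truth


# ---------------------------------------------------------------------------
# speckle flows for PIV validation
# ---------------------------------------------------------------------------

@dataclass
class TranslationFlow:
    """Uniform flow v = (vx, vy) um/s; divergence 0."""
    vx_um_s: float
    vy_um_s: float

    def velocity(self, x, y):
        return (np.full_like(np.asarray(x, float), self.vx_um_s),
                np.full_like(np.asarray(y, float), self.vy_um_s))

    divergence_per_s = 0.0


@dataclass
class RadialContractionFlow:
    """u_r = -k r about a center; divergence -2k everywhere."""
    k_per_s: float
    center_um: tuple[float, float] = (0.0, 0.0)

    def velocity(self, x, y):
        return (-self.k_per_s * (np.asarray(x, float) - self.center_um[0]),
                -self.k_per_s * (np.asarray(y, float) - self.center_um[1]))

    @property
    def divergence_per_s(self):
        return -2.0 * self.k_per_s


@dataclass
class SwirlFlow:
    """Rigid rotation omega about a center; divergence 0."""
    omega_per_s: float
    center_um: tuple[float, float] = (0.0, 0.0)

    def velocity(self, x, y):
        rx = np.asarray(x, float) - self.center_um[0]
        ry = np.asarray(y, float) - self.center_um[1]
        return -self.omega_per_s * ry, self.omega_per_s * rx

    divergence_per_s = 0.0


@dataclass
class FlowTruth:
    """Analytic displacement truth for a rendered speckle pair."""
    flow: object
    dt_s: float

    def displacement_um(self, x_um, y_um):
        ux, uy = self.flow.velocity(x_um, y_um)
        return ux * self.dt_s, uy * self.dt_s

    @property
    def divergence(self) -> float:
        """Divergence of the displacement field (dimensionless)."""
        return float(self.flow.divergence_per_s * self.dt_s)


def _stamp_gaussians(shape, pos_px, sigma_px, amplitude, rng=None):
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * sigma_px))
    win = np.arange(-half, half + 1)
    for (px, py), a in zip(pos_px, amplitude):
        r0, c0 = int(round(py)), int(round(px))
        rows = r0 + win
        cols = c0 + win
        rsel = (rows >= 0) & (rows < shape[0])
        csel = (cols >= 0) & (cols < shape[1])
        if not (rsel.any() and csel.any()):
            continue
        gy = np.exp(-0.5 * ((rows[rsel] - py) / sigma_px) ** 2)
        gx = np.exp(-0.5 * ((cols[csel] - px) / sigma_px) ** 2)
        img[np.ix_(rows[rsel], cols[csel])] += a * np.outer(gy, gx)
    return img


def make_speckle_pair(
    flow_spec,
    n_particles: int,
    dt_s: float,
    image_shape: tuple[int, int],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    particle_sigma_px: float = 1.5,
    max_displacement_px: float | None = None,
    noise_model: PoissonGaussianNoise | None = None,
) -> tuple[np.ndarray, np.ndarray, FlowTruth]:
    """Speckle frame pair advected by an analytic flow.

    ``flow_spec`` is one of :class:`TranslationFlow`,
    :class:`RadialContractionFlow`, :class:`SwirlFlow`.  Frame B particles
    are frame A particles advected over ``dt_s``; the analytic
    displacement field (and its exact divergence) is returned as truth.

    Raises SceneError when any particle displacement exceeds
    ``max_displacement_px`` (half the PIV search window, when supplied).
    """
    if n_particles < 100:
        raise ValueError("need at least 100 particles for meaningful PIV")
    rng = np.random.default_rng(seed)
    H, W = image_shape
    x_px = rng.uniform(0, W - 1, n_particles)
    y_px = rng.uniform(0, H - 1, n_particles)
    amp = rng.uniform(0.5, 1.0, n_particles)
    x_um, y_um = x_px * pixel_size_um, y_px * pixel_size_um
    ux, uy = flow_spec.velocity(x_um, y_um)
    dx_px = ux * dt_s / pixel_size_um
    dy_px = uy * dt_s / pixel_size_um
    dmax = float(np.hypot(dx_px, dy_px).max())
    if max_displacement_px is not None and dmax > max_displacement_px:
        raise SceneError(
            f"maximum particle displacement {dmax:.1f} px exceeds the "
            f"allowed half search window of {max_displacement_px:.1f} px"
        )
    frame_a = _stamp_gaussians(image_shape, np.column_stack([x_px, y_px]),
                               particle_sigma_px, amp)
    frame_b = _stamp_gaussians(image_shape,
                               np.column_stack([x_px + dx_px, y_px + dy_px]),
                               particle_sigma_px, amp)
    if noise_model is not None:
        frame_a = noise_model.apply(frame_a, rng)
        frame_b = noise_model.apply(frame_b, rng)
    return frame_a, frame_b, FlowTruth(flow=flow_spec, dt_s=dt_s)


# ---------------------------------------------------------------------------
# filament textures with controlled nematic order
# ---------------------------------------------------------------------------

def _vonmises_kappa_for_order(m: float) -> float:
    """Concentration of a von Mises distribution on 2*theta with mean
    resultant <cos 2theta> = m."""
    if m <= 0:
        return 0.0
    if m >= 0.999:
        return np.inf
    f = lambda k: special.i1e(k) / special.i0e(k) - m
    return brentq(f, 1e-8, 1e4)


def make_filament_texture(
    order_param_target: float,
    n_filaments: int,
    length_px: float,
    image_shape: tuple[int, int],
    seed: int = 0,
    axis_deg: float = 0.0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Anti-aliased filament texture with a prescribed nematic order.

    Filament orientations are drawn independently from a von Mises
    distribution on the doubled angle whose mean resultant
    ``<cos 2(theta - axis)>`` equals ``order_param_target``.

    Returns ``(image, realized_order, angles)`` where ``realized_order``
    is the per-draw value ``mean(cos 2(theta_i - axis))`` and ``angles``
    the drawn filament orientations (radians).
    """
    if not 0.0 <= order_param_target <= 1.0:
        raise ValueError("order_param_target must lie in [0, 1]")
    if n_filaments < 1:
        raise SceneError("degenerate texture: no filaments requested")
    from skimage.draw import line_aa

    rng = np.random.default_rng(seed)
    axis = np.deg2rad(axis_deg)
    kappa = _vonmises_kappa_for_order(order_param_target)
    if np.isinf(kappa):
        angles = np.full(n_filaments, axis)
    else:
        angles = axis + 0.5 * rng.vonmises(0.0, kappa, n_filaments)
    angles = (angles + np.pi / 2) % np.pi - np.pi / 2  # headless, [-pi/2, pi/2)

    H, W = image_shape
    img = np.zeros(image_shape, dtype=float)
    half = length_px / 2.0
    margin = half + 2
    if 2 * margin >= min(H, W):
        raise SceneError("image too small for the requested filament length")
    # keep whole segments inside the image so drawn angles match the truth
    cx = rng.uniform(margin, W - 1 - margin, n_filaments)
    cy = rng.uniform(margin, H - 1 - margin, n_filaments)
    for x0, y0, th in zip(cx, cy, angles):
        # y grows with row index, so a CCW angle from +x maps to +row drift
        rr, cc, val = line_aa(
            int(round(y0 - half * np.sin(th))), int(round(x0 - half * np.cos(th))),
            int(round(y0 + half * np.sin(th))), int(round(x0 + half * np.cos(th))),
        )
        img[rr, cc] += val
    realized = float(np.cos(2.0 * (angles - axis)).mean())
    return img, realized, angles


# ---------------------------------------------------------------------------
# polarized cortical intensity
# ---------------------------------------------------------------------------

_PROFILE_FAMILIES = ("cosine", "step", "vonmises")


def make_polarized_cortex(
    contour: MembraneContour,
    polarity_target: float,
    profile: str = "vonmises",
    axis_deg: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Per-vertex cortical actin intensity with an exact target polarity.

    The profile contrast is solved (bisection on the actual polygon sum)
    so that the intensity-weighted centroid offset normalized by the mean
    radius equals ``polarity_target`` within 1e-6.  Families:

    - ``cosine``: I = 1 + c cos(theta - axis); max attainable polarity 0.5
      on a circle;
    - ``step``: unit intensity on an arc of half-width w (w = pi/2, one
      half-circle, gives polarity 2/pi);
    - ``vonmises``: I = exp(kappa cos(theta - axis)); approaches 1.

    Raises SceneError when the target exceeds the family's attainable
    range, stating the maximum.
    """
    if not 0.0 <= polarity_target < 1.0:
        raise ValueError("polarity_target must lie in [0, 1)")
    if profile not in _PROFILE_FAMILIES:
        raise ValueError(f"unknown profile {profile!r}; choose from {_PROFILE_FAMILIES}")
    v = contour.vertices - contour.center_of_mass
    theta = np.arctan2(v[:, 1], v[:, 0])
    axis = np.deg2rad(axis_deg)
    dtheta = theta - axis

    def intensity(param):
        if profile == "cosine":
            return 1.0 + param * np.cos(dtheta)
        if profile == "step":
            wrapped = (dtheta + np.pi) % (2 * np.pi) - np.pi
            # half-vertex linear edge keeps the polarity continuous in the
            # arc width so the bisection can hit the target exactly
            edge = np.pi / len(theta)
            return np.clip(0.5 + (param - np.abs(wrapped)) / edge, 0.0, 1.0) + 1e-12
        return np.exp(param * np.cos(dtheta))

    def achieved(param):
        return polarity_from_vertex_intensity(contour, intensity(param))

    if polarity_target == 0.0:
        return intensity(0.0 if profile != "step" else np.pi), achieved(
            0.0 if profile != "step" else np.pi)

    if profile == "cosine":
        lo, hi = 0.0, 1.0
        p_max = achieved(hi)
        if polarity_target > p_max:
            raise SceneError(
                f"cosine profile cannot reach polarity {polarity_target:.3f}; "
                f"maximum attainable is {p_max:.4f}"
            )
    elif profile == "step":
        lo, hi = np.pi, 1e-3     # polarity increases as the arc narrows
        p_max = achieved(hi)
        if polarity_target > p_max:
            raise SceneError(
                f"step profile cannot reach polarity {polarity_target:.3f} at "
                f"this vertex count; maximum attainable is {p_max:.4f}"
            )
    else:
        lo, hi = 0.0, 700.0      # exp overflow guard
        p_max = achieved(hi)
        if polarity_target > p_max:
            raise SceneError(
                f"vonmises profile cannot reach polarity {polarity_target:.3f}; "
                f"maximum attainable is {p_max:.4f}"
            )
    param = brentq(lambda p: achieved(p) - polarity_target, lo, hi, xtol=1e-12)
    I = intensity(param)
    return I, achieved(param)


# ---------------------------------------------------------------------------
# bead images for PSF calibration
# ---------------------------------------------------------------------------

def make_bead_image(
    n_beads: int,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    amplitude: float = 1.0,
    noise_model: PoissonGaussianNoise | None = None,
    min_separation_sigma: float = 6.0,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, SceneTruth]:
    """Isolated Gaussian bead spots of known PSF width.

    Bead centers are rejection-sampled with pairwise separation at least
    ``min_separation_sigma * sigma``; raises SceneError when the requested
    count cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma_um / pixel_size_um
    min_sep = min_separation_sigma * sigma_px
    H, W = image_shape
    margin = 5 * sigma_px + 2
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n_beads:
        attempts += 1
        if attempts > max_attempts:
            raise SceneError(
                f"cannot place {n_beads} beads with separation >= "
                f"{min_sep:.1f} px in a {H}x{W} image"
            )
        x = rng.uniform(margin, W - 1 - margin)
        y = rng.uniform(margin, H - 1 - margin)
        if all(np.hypot(x - px, y - py) >= min_sep for px, py in placed):
            placed.append((x, y))
    img = _stamp_gaussians(image_shape, placed, sigma_px,
                           np.full(n_beads, amplitude))
    if noise_model is not None:
        img = noise_model.apply(img, rng)
    truth = SceneTruth(radius_um=1.0, psf_sigma_um=psf_sigma_um, seed=seed)
    return img, truth


# ---------------------------------------------------------------------------
# scene I/O: multi-page TIFF per channel + JSON truth sidecar
# ---------------------------------------------------------------------------

def save_scene(
    directory: str | Path,
    name: str,
    channels: dict[str, np.ndarray],
    truth: SceneTruth,
) -> None:
    """Write a scene as one multi-page TIFF per channel plus a truth JSON."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for channel, stack in channels.items():
        tifffile.imwrite(directory / f"{name}_{channel}.tif",
                         np.asarray(stack, dtype=np.float32))
    (directory / f"{name}_truth.json").write_text(truth.to_json())


def load_scene(directory: str | Path, name: str,
               channels: tuple[str, ...] = ("membrane", "actin")):
    """Read back a scene written by :func:`save_scene`."""
    import tifffile

    directory = Path(directory)
    stacks = {c: tifffile.imread(directory / f"{name}_{c}.tif") for c in channels}
    truth = SceneTruth.from_json((directory / f"{name}_truth.json").read_text())
    return stacks, truth
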