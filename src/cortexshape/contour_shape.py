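"""Membrane contour extraction and shape metrics for liposome timelapses.

The membrane channel of a GUV mid-plane image shows a closed bright ring.
This module extracts that ring as a sub-pixel closed polyline, decomposes
it into a radial profile R(theta) about the contour center of mass, and
computes the two headline shape metrics:

- circularity ``C = 4*pi*A / L**2`` (1 for a circle) and membrane strain
  ``eps_memb = 1 - C``;
- actin polarity ``P_act = |r_act - r_c| / R``, the normalized offset of
  the actin-intensity-weighted membrane centroid from the liposome
  center of mass.

Coordinates are physical (micrometres), x = column * pixel size,
y = row * pixel size, angles counter-clockwise from +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from cortexshape._util import interp_periodic, parabolic_peak

#: Liposomes with mean radius below this are excluded from cohort summaries
#: (analysis restricted to large liposomes where deformation is significant).
DEFAULT_SIZE_GATE_UM = 17.5


class ContourError(RuntimeError):
    """Raised when a usable membrane contour cannot be extracted."""


@dataclass
class MembraneContour:
    """Closed, simple, counter-clockwise membrane polyline for one frame.

    Attributes
    ----------
    vertices : (N, 2) array of (x, y) positions in micrometres.
    frame : frame index in the source timelapse.
    """

    vertices: np.ndarray
    frame: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be an (N>=3, 2) array")
        # enforce counter-clockwise orientation (positive shoelace area)
        if _shoelace_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v
        if self.area <= 0:
            raise ValueError("degenerate contour: non-positive area")

    @property
    def center_of_mass(self) -> np.ndarray:
        """Vertex-average center r_c = N^-1 sum(r_i)."""
        return self.vertices.mean(axis=0)

    @property
    def area(self) -> float:
        """Enclosed polygon area (um^2, shoelace formula)."""
        return abs(_shoelace_area(self.vertices))

    @property
    def perimeter(self) -> float:
        """Closed-polygon perimeter (um)."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def mean_radius(self) -> float:
        """Mean vertex distance from the center of mass (um)."""
        rel = self.vertices - self.center_of_mass
        return float(np.hypot(rel[:, 0], rel[:, 1]).mean())


@dataclass
class ShapeMetrics:
    circularity: float
    membrane_strain: float
    mean_radius_um: float
    max_radius_um: float
    max_radial_deformation: float  # R_max / <R>
    polarity: float | None = None


def _shoelace_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def _initial_circle(image: np.ndarray) -> tuple[float, float, float]:
    """Rough (cx, cy, r) estimate of the membrane ring, in pixels."""
    from skimage.filters import threshold_otsu

    smoothed = ndimage.gaussian_filter(image.astype(float), 2.0)
    if np.ptp(smoothed) <= 0:
        raise ContourError("blank image: no membrane signal")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if mask.sum() < 20:
        raise ContourError("no membrane ring above threshold")
    lbl, n = ndimage.label(mask)
    if n > 1:  # keep the largest connected component (largest liposome)
        sizes = ndimage.sum_labels(mask, lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    r = float(np.hypot(rows - cy, cols - cx).mean())
    if r < 3:
        raise ContourError("membrane ring too small to trace")
    return float(cx), float(cy), r


def extract_contour(
    membrane_image: np.ndarray,
    pixel_size_um: float,
    init_circle: tuple[float, float, float] | None = None,
    n_vertices: int = 360,
    smooth_sigma_px: float = 1.0,
    search_factor: float = 0.5,
    gap_fraction: float = 0.1,
    frame: int = 0,
) -> MembraneContour:
    """Trace the membrane intensity ridge as a closed sub-pixel contour.

    Casts ``n_vertices`` rays from the current center estimate, locates
    the radial intensity peak on each ray with a parabolic sub-pixel fit,
    and iterates the center twice.  Rays whose peak contrast is too low
    count as gaps; more than ``gap_fraction`` of gaps is an error.

    Parameters
    ----------
    init_circle : optional (cx_px, cy_px, r_px) initialization; estimated
        from an Otsu threshold of the ring when omitted.
    search_factor : radial search half-range as a fraction of the current
        radius estimate.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = ndimage.gaussian_filter(np.asarray(membrane_image, dtype=float),
                                  smooth_sigma_px)
    if init_circle is None:
        cx, cy, r0 = _initial_circle(img)
    else:
        cx, cy, r0 = map(float, init_circle)

    theta = np.linspace(-np.pi, np.pi, n_vertices, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    background = float(np.median(img))

    radii = np.full(n_vertices, r0)
    for _ in range(3):  # center refinement iterations
        lo = np.maximum(radii * (1.0 - search_factor), 1.0)
        hi = radii * (1.0 + search_factor)
        n_s = 2 * int(np.ceil((hi - lo).max() / 0.25)) + 1
        frac = np.linspace(0.0, 1.0, n_s)
        rho = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
        rows = cy + rho * sin_t[:, None]
        cols = cx + rho * cos_t[:, None]
        prof = ndimage.map_coordinates(img, [rows, cols], order=3, mode="nearest")
        peak_idx = np.argmax(prof, axis=1)
        peak_val = prof[np.arange(n_vertices), peak_idx]
        contrast = peak_val - background
        ok = contrast > 0.2 * max(np.median(contrast), 1e-12)
        if ok.sum() < (1.0 - gap_fraction) * n_vertices:
            bad_theta = np.degrees(theta[~ok])
            raise ContourError(
                "broken membrane ring: no ridge found on "
                f"{int((~ok).sum())}/{n_vertices} rays "
                f"(first gap near theta = {bad_theta[0]:.0f} deg)"
            )
        new_r = np.empty(n_vertices)
        for k in range(n_vertices):
            i = int(peak_idx[k])
            vals = prof[k, max(0, i - 1):i + 2] - background
            if len(vals) == 3 and np.all(vals > 0):
                # log-parabolic interpolation: exact for a Gaussian ridge
                off, _ = parabolic_peak(np.log(vals), 1)
            else:
                off, _ = parabolic_peak(prof[k], i)
            new_r[k] = rho[k, 0] + (i + off) * (rho[k, 1] - rho[k, 0])
        # fill gap rays by periodic interpolation from good neighbors
        if not ok.all():
            new_r[~ok] = interp_periodic(theta[~ok], theta[ok], new_r[ok])
        radii = new_r
        x = cx + radii * cos_t
        y = cy + radii * sin_t
        cx, cy = float(x.mean()), float(y.mean())
        # tighten the search once the ridge is locked on
        search_factor = max(0.15, 0.5 * search_factor)

    vertices_px = np.column_stack([x, y])
    return MembraneContour(vertices_px * pixel_size_um, frame=frame)


# ---------------------------------------------------------------------------
# radial decomposition and shape metrics
# ---------------------------------------------------------------------------

def radial_decomposition(
    contour: MembraneContour, n_theta: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Radial profile about the center of mass on a uniform angle grid.

    Returns ``(theta, R, u, R_mean)`` with ``theta`` uniform on
    ``(-pi, pi]``, ``R(theta)`` by ray casting with linear interpolation,
    and the deformation amplitude ``u = R - <R>_theta``.

    Raises ContourError when the contour is not star-shaped about its
    center of mass (a ray crossing the polyline more than once).
    """
    v = contour.vertices - contour.center_of_mass
    ang = np.arctan2(v[:, 1], v[:, 0])
    rad = np.hypot(v[:, 0], v[:, 1])
    dang = np.diff(np.concatenate([ang, ang[:1]]))
    dang = (dang + np.pi) % (2 * np.pi) - np.pi
    if not (np.all(dang > 0) or np.all(dang < 0)):
        bad = int(np.argmin(np.sign(dang.sum()) * dang))
        raise ContourError(
            "contour is not star-shaped about its center of mass "
            f"(backtracking near theta = {np.degrees(ang[bad]):.1f} deg)"
        )
    order = np.argsort(ang)
    ang_s, rad_s = ang[order], rad[order]
    if n_theta is None:
        n_theta = len(rad)
    theta = -np.pi + 2 * np.pi * (np.arange(n_theta) + 1) / n_theta  # (-pi, pi]
    R = interp_periodic(theta, ang_s, rad_s)
    R_mean = float(R.mean())
    return theta, R, R - R_mean, R_mean


def shape_metrics(
    contour: MembraneContour, initial_radius_um: float | None = None
) -> ShapeMetrics:
    """Circularity, membrane strain and maximum radial deformation.

    ``C = 4*pi*A/L**2`` from the closed polygon; ``eps_memb = 1 - C``.
    At N=360 vertices the polygonal discretization error on a circle is
    below 1e-4 in C.
    """
    A, L = contour.area, contour.perimeter
    if A <= 0:
        raise ValueError("degenerate contour with non-positive area")
    C = 4.0 * np.pi * A / L**2
    _, R, _, R_mean = radial_decomposition(contour)
    return ShapeMetrics(
        circularity=float(C),
        membrane_strain=float(1.0 - C),
        mean_radius_um=R_mean,
        max_radius_um=float(R.max()),
        max_radial_deformation=float(R.max() / R_mean),
    )


def polarity_from_vertex_intensity(
    contour: MembraneContour,
    intensities: np.ndarray,
    initial_radius_um: float | None = None,
) -> float:
    """Actin polarity from per-vertex cortical intensities.

    ``r_act = sum(r_i * I_i) / sum(I_i)``;
    ``P_act = |r_act - r_c| / R`` with R the initial-frame mean radius
    (the contour's own mean radius when not supplied).
    """
    I = np.asarray(intensities, dtype=float)
    if I.shape[0] != contour.vertices.shape[0]:
        raise ValueError("one intensity per contour vertex required")
    total = I.sum()
    if total <= 0:
        raise ValueError("all-zero actin intensity along the contour")
    r_act = (contour.vertices * I[:, None]).sum(axis=0) / total
    R = contour.mean_radius if initial_radius_um is None else initial_radius_um
    return float(np.hypot(*(r_act - contour.center_of_mass)) / R)


def sample_contour_intensity(
    contour: MembraneContour,
    image: np.ndarray,
    pixel_size_um: float,
    band_px: float = 3.0,
    n_band: int = 7,
) -> np.ndarray:
    """Mean image intensity in a band normal to the contour at each vertex.

    The band extends ``+-band_px`` pixels along the inward/outward normal;
    intensities are bilinearly interpolated.
    """
    v_px = contour.vertices / pixel_size_um
    nxt = np.roll(v_px, -1, axis=0)
    prv = np.roll(v_px, 1, axis=0)
    tang = nxt - prv
    tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.linspace(-band_px, band_px, n_band)
    cols = v_px[:, 0][:, None] + normal[:, 0][:, None] * offsets[None, :]
    rows = v_px[:, 1][:, None] + normal[:, 1][:, None] * offsets[None, :]
    samples = ndimage.map_coordinates(
        np.asarray(image, dtype=float), [rows, cols], order=1, mode="nearest"
    )
    return samples.mean(axis=1)


def actin_polarity(
    contour: MembraneContour,
    actin_image: np.ndarray,
    pixel_size_um: float,
    band_px: float = 3.0,
    initial_radius_um: float | None = None,
) -> float:
    """Actin polarity P_act of one frame from the actin channel image."""
    I = sample_contour_intensity(contour, actin_image, pixel_size_um, band_px)
    return polarity_from_vertex_intensity(contour, I, initial_radius_um)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

@dataclass
class MetricTimeseries:
    table: pd.DataFrame                 # per-frame metrics
    max_membrane_strain: float
    max_polarity: float
    initial_radius_um: float
    baseline_frame: int = 0


def metric_timeseries(
    contours: list[MembraneContour],
    actin_stack: np.ndarray | None,
    pixel_size_um: float,
    band_px: float = 3.0,
    activation_frame: int | None = None,
    subtract_baseline: bool = False,
) -> MetricTimeseries:
    """Per-frame shape metrics and their maxima over the observation window.

    The polarity denominator is the initial-frame mean radius, fixed for
    the whole series.  When ``activation_frame`` is given, the baseline
    frame is the last pre-activation frame; baseline subtraction of the
    strain is optional and off by default.
    """
    if len(contours) < 2:
        raise ValueError("need at least 2 frames for a time series")
    baseline = 0 if activation_frame is None else max(0, activation_frame - 1)
    R0 = shape_metrics(contours[baseline]).mean_radius_um
    rows = []
    for k, c in enumerate(contours):
        m = shape_metrics(c, initial_radius_um=R0)
        p = np.nan
        if actin_stack is not None:
            p = actin_polarity(c, actin_stack[k], pixel_size_um, band_px, R0)
        rows.append(
            dict(frame=c.frame, circularity=m.circularity,
                 eps_memb=m.membrane_strain, P_act=p,
                 R_mean_um=m.mean_radius_um, R_max_um=m.max_radius_um,
                 R_max_over_mean=m.max_radial_deformation)
        )
    table = pd.DataFrame(rows)
    eps = table["eps_memb"].to_numpy(copy=True)
    if subtract_baseline:
        eps = eps - eps[baseline]
    pol = table["P_act"].to_numpy()
    return MetricTimeseries(
        table=table,
        max_membrane_strain=float(np.nanmax(eps)),
        max_polarity=float(np.nanmax(pol)) if np.isfinite(pol).any() else np.nan,
        initial_radius_um=R0,
        baseline_frame=baseline,
    )


def passes_size_gate(mean_radius_um: float,
                     cutoff_um: float = DEFAULT_SIZE_GATE_UM) -> bool:
    """Cohort inclusion rule: only liposomes at or above the radius cutoff."""
    return mean_radius_um >= cutoff_um


def contours_to_frame(contours: list[MembraneContour]) -> pd.DataFrame:
    """Serialize contours as a long-format table (frame, vertex, x_um, y_um)."""
    parts = []
    for c in contours:
        n = len(c.vertices)
        parts.append(pd.DataFrame({
            "frame": np.full(n, c.frame, dtype=int),
            "vertex": np.arange(n),
            "x_um": c.vertices[:, 0],
            "y_um": c.vertices[:, 1],
        }))
    return pd.concat(parts, ignore_index=True)
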