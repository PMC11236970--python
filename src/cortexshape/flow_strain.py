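"""Multi-pass cross-correlation PIV, compressive strain, cortical flow.

Displacement of the actin network between consecutive frames is measured
by windowed normalized cross-correlation (particle image velocimetry):
a cascade of interrogation/search window pairs, each coarse pass seeding
the next finer pass, with sub-pixel peak localization by 3-point
Gaussian interpolation.  Low-quality vectors (weak or ambiguous
correlation peaks, or normalized-median outliers) are marked invalid
rather than zero.

The mean compressive strain of the network is the time-accumulated,
area-averaged negative part of the displacement-field divergence inside
the liposome:

    eps(t) = - sum_{t' <= t} [ int_mask min(div u(r, t'), 0) dA / int_mask dA ]

so eps grows only where the network compresses and is non-decreasing.
The cortical flow speed is the mean displacement magnitude in a thin
band inside the membrane contour, in um/min, with a tangential / normal
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cortexshape._util import interp_periodic, parabolic_peak
from cortexshape.contour_shape import MembraneContour

#: Interrogation/search window cascade (px).  The finest
#: interrogation window is 48 px for volume network contraction; 16 or
#: 32 px suit cortical flow measurement.
DEFAULT_WINDOW_CASCADE = ((100, 200), (60, 120), (48, 96))


@dataclass
class QualityParams:
    """Vector acceptance thresholds.

    ``corr_min``: minimum normalized correlation at the primary peak.
    ``noise``: minimum relative prominence of the primary peak over the
    secondary peak, ``1 - c2/c1``.
    ``outlier_threshold``: normalized-median-test threshold on the
    residual against the 8 neighboring vectors.

    These mirror the nominal correlation/noise/threshold settings of
    common PIV tools (0.6 / 0.20 / 5); exact equivalence to any specific
    plugin is not claimed.
    """

    corr_min: float = 0.6
    noise: float = 0.20
    outlier_threshold: float = 5.0


@dataclass
class DisplacementField:
    """Per-frame-pair PIV vector field on a regular grid.

    Grid positions are in um; displacements u, v in um.  ``valid`` marks
    vectors that passed the quality filter; invalid entries are NaN.
    """

    x_um: np.ndarray            # (nx,) grid columns
    y_um: np.ndarray            # (ny,) grid rows
    u_um: np.ndarray            # (ny, nx)
    v_um: np.ndarray            # (ny, nx)
    quality: np.ndarray         # correlation at the accepted peak
    valid: np.ndarray
    window_cascade: tuple = DEFAULT_WINDOW_CASCADE
    pixel_size_um: float = 1.0

    @property
    def speed_um(self) -> np.ndarray:
        return np.hypot(self.u_um, self.v_um)


@dataclass
class StrainSeries:
    t_s: np.ndarray
    epsilon: np.ndarray         # cumulative compressive strain, eps(0) = 0
    strain_rate: np.ndarray     # 1/s, forward difference
    mask: np.ndarray


# ---------------------------------------------------------------------------
# single-pair PIV
# ---------------------------------------------------------------------------

def _ncc_peak(template: np.ndarray, search: np.ndarray):
    """Normalized cross-correlation of a template inside a search window.

    Returns (dy, dx, c1, prominence) where (dy, dx) is the sub-pixel
    displacement of the template center relative to the search center,
    or None for a featureless window.
    """
    from skimage.feature import match_template

    if template.std() < 1e-12 or search.std() < 1e-12:
        return None
    ncc = match_template(search, template, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    c1 = float(ncc[iy, ix])
    # secondary peak outside a 3-px exclusion zone around the primary
    masked = ncc.copy()
    masked[max(0, iy - 3):iy + 4, max(0, ix - 3):ix + 4] = -np.inf
    c2 = float(masked.max()) if np.isfinite(masked).any() else -1.0
    prominence = 1.0 - max(c2, 0.0) / c1 if c1 > 0 else 0.0
    # 3-point Gaussian (log-parabolic) sub-pixel interpolation per axis
    def subpix(vals, i):
        if 0 < i < len(vals) - 1 and np.all(vals > 0):
            l0, l1, l2 = np.log(vals)
            denom = l0 - 2 * l1 + l2
            if denom < 0:
                return float(np.clip(0.5 * (l0 - l2) / denom, -1, 1))
        off, _ = parabolic_peak(vals, i)
        return off
    vy = ncc[max(0, iy - 1):iy + 2, ix]
    vx = ncc[iy, max(0, ix - 1):ix + 2]
    oy = subpix(vy, 1 if iy > 0 else 0) if len(vy) == 3 else 0.0
    ox = subpix(vx, 1 if ix > 0 else 0) if len(vx) == 3 else 0.0
    off = (np.asarray(search.shape) - np.asarray(template.shape)) / 2.0
    dy = iy + oy - off[0]
    dx = ix + ox - off[1]
    return dy, dx, c1, prominence


def _clip_window(img, r0, c0, half):
    H, W = img.shape
    lo_r, hi_r = int(round(r0 - half)), int(round(r0 + half))
    lo_c, hi_c = int(round(c0 - half)), int(round(c0 + half))
    if lo_r < 0 or lo_c < 0 or hi_r > H or hi_c > W:
        return None
    return img[lo_r:hi_r, lo_c:hi_c]


def _median_outlier_filter(u, v, valid, threshold, eps=0.1):
    """Normalized median test (8-neighbor) marking outlier vectors invalid."""
    ny, nx = u.shape
    out = valid.copy()
    for r in range(ny):
        for c in range(nx):
            if not valid[r, c]:
                continue
            nb_u, nb_v = [], []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < ny and 0 <= cc < nx and valid[rr, cc]:
                        nb_u.append(u[rr, cc])
                        nb_v.append(v[rr, cc])
            if len(nb_u) < 3:
                continue
            med_u, med_v = np.median(nb_u), np.median(nb_v)
            res_u = np.median(np.abs(np.asarray(nb_u) - med_u))
            res_v = np.median(np.abs(np.asarray(nb_v) - med_v))
            ru = abs(u[r, c] - med_u) / (res_u + eps)
            rv = abs(v[r, c] - med_v) / (res_v + eps)
            if max(ru, rv) > threshold:
                out[r, c] = False
    return out


def piv_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_cascade=DEFAULT_WINDOW_CASCADE,
    pixel_size_um: float = 1.0,
    quality_params: QualityParams | None = None,
    overlap: float = 0.5,
) -> DisplacementField:
    """Multi-pass PIV displacement field between two frames.

    ``window_cascade`` is an ordered list of (interrogation, search)
    window sizes in pixels with strictly decreasing interrogation sizes;
    each pass's field seeds the search offsets of the next.  The
    returned grid and displacements come from the final pass.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    sizes = [w for w, _ in window_cascade]
    if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
        raise ValueError("cascade interrogation sizes must strictly decrease")
    qp = quality_params or QualityParams()

    prev = None  # (grid_r, grid_c, u_px, v_px, valid)
    for interr, search in window_cascade:
        step = max(4, int(round(interr * (1.0 - overlap))))
        half_t = interr / 2
        half_s = search / 2
        r_nodes = np.arange(half_t, a.shape[0] - half_t + 1e-9, step)
        c_nodes = np.arange(half_t, a.shape[1] - half_t + 1e-9, step)
        if len(r_nodes) == 0 or len(c_nodes) == 0:
            raise ValueError(f"interrogation window {interr} px does not fit "
                             "in the frame")
        ny, nx = len(r_nodes), len(c_nodes)
        u = np.full((ny, nx), np.nan)
        v = np.full((ny, nx), np.nan)
        q = np.zeros((ny, nx))
        valid = np.zeros((ny, nx), dtype=bool)

        if prev is not None:
            pr, pc, pu, pv, pvalid = prev
            seed_u = _interp_seed(pr, pc, pu, pvalid, r_nodes, c_nodes)
            seed_v = _interp_seed(pr, pc, pv, pvalid, r_nodes, c_nodes)
        else:
            seed_u = np.zeros((ny, nx))
            seed_v = np.zeros((ny, nx))

        for i, r0 in enumerate(r_nodes):
            for j, c0 in enumerate(c_nodes):
                template = _clip_window(a, r0, c0, half_t)
                if template is None:
                    continue
                sr = r0 + round(seed_v[i, j])
                sc = c0 + round(seed_u[i, j])
                region = _clip_window(b, sr, sc, half_s)
                if region is None:
                    region = _clip_window(b, r0, c0, half_s)
                    sr, sc = r0, c0
                    if region is None:
                        continue
                res = _ncc_peak(template, region)
                if res is None:
                    continue
                dy, dx, c1, prom = res
                if c1 < qp.corr_min or prom < qp.noise:
                    continue
                u[i, j] = dx + (sc - c0)
                v[i, j] = dy + (sr - r0)
                q[i, j] = c1
                valid[i, j] = True
        valid = _median_outlier_filter(u, v, valid, qp.outlier_threshold)
        u[~valid] = np.nan
        v[~valid] = np.nan
        prev = (r_nodes, c_nodes, u, v, valid)

    r_nodes, c_nodes, u, v, valid = prev
    return DisplacementField(
        x_um=c_nodes * pixel_size_um,
        y_um=r_nodes * pixel_size_um,
        u_um=u * pixel_size_um,
        v_um=v * pixel_size_um,
        quality=q,
        valid=valid,
        window_cascade=tuple(window_cascade),
        pixel_size_um=pixel_size_um,
    )


def _interp_seed(pr, pc, values, valid, r_nodes, c_nodes):
    """Nearest-valid interpolation of a coarse field onto a finer grid."""
    filled = values.copy()
    if (~valid).any() and valid.any():
        idx = ndimage.distance_transform_edt(
            ~valid, return_distances=False, return_indices=True)
        filled = values[tuple(idx)]
    elif not valid.any():
        return np.zeros((len(r_nodes), len(c_nodes)))
    from scipy.interpolate import RegularGridInterpolator

    f = RegularGridInterpolator((pr, pc), filled, bounds_error=False,
                                fill_value=None, method="linear")
    rr, cc = np.meshgrid(r_nodes, c_nodes, indexing="ij")
    return f(np.stack([rr, cc], axis=-1))


# ---------------------------------------------------------------------------
# divergence and cumulative compressive strain
# ---------------------------------------------------------------------------

def _fill_invalid(field: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Nearest-neighbor fill of invalid vectors, for differencing only."""
    if valid.all():
        return field
    if not valid.any():
        raise ValueError("displacement field has no valid vectors")
    idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    return field[tuple(idx)]


def divergence(field: DisplacementField,
               smooth_nodes: float = 1.0) -> np.ndarray:
    """Discrete divergence du/dx + dv/dy by central differences (2nd order).

    Invalid vectors are filled from neighbors for differencing only;
    they stay invalid in the field itself.  ``smooth_nodes`` applies a
    Gaussian pre-smoothing (in grid nodes) to the vector components
    before differencing — standard PIV strain post-processing that
    suppresses node-to-node correlation noise; it is exact for linear
    fields and negligible for fields varying on scales well above the
    grid spacing.  Set to 0 for raw central differences.
    """
    if len(field.x_um) < 3 or len(field.y_um) < 3:
        raise ValueError("PIV grid too coarse for central differencing "
                         "(< 3 nodes across)")
    u = _fill_invalid(field.u_um, field.valid)
    v = _fill_invalid(field.v_um, field.valid)
    if smooth_nodes > 0:
        u = ndimage.gaussian_filter(u, smooth_nodes, mode="nearest")
        v = ndimage.gaussian_filter(v, smooth_nodes, mode="nearest")
    du_dx = np.gradient(u, field.x_um, axis=1)
    dv_dy = np.gradient(v, field.y_um, axis=0)
    return du_dx + dv_dy


def cumulative_compressive_strain(
    fields: list[DisplacementField],
    mask: np.ndarray,
    dt_s: float,
) -> StrainSeries:
    """Cumulative compressive strain eps(t) and strain rate.

    ``mask`` selects the liposome interior on the PIV grid.  Positive
    (expansive) divergence is clipped to zero before area-averaging, so
    only compression contributes and eps is non-decreasing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty integration mask")
    eps = [0.0]
    for f in fields:
        div = divergence(f)
        if mask.shape != div.shape:
            raise ValueError("mask shape does not match the PIV grid")
        compressive = np.minimum(div[mask], 0.0)
        eps.append(eps[-1] - compressive.mean())
    eps = np.asarray(eps)
    t = dt_s * np.arange(len(eps))
    rate = np.diff(eps) / dt_s
    rate = np.append(rate, rate[-1] if len(rate) else 0.0)
    return StrainSeries(t_s=t, epsilon=eps, strain_rate=rate, mask=mask)


def interior_mask(field: DisplacementField, contour: MembraneContour,
                  margin_um: float = 0.0) -> np.ndarray:
    """Grid mask of nodes inside a membrane contour (radial test)."""
    xx, yy = np.meshgrid(field.x_um, field.y_um)
    return _depth_inside(contour, xx, yy) > margin_um


def _depth_inside(contour: MembraneContour, xx, yy):
    c = contour.center_of_mass
    v = contour.vertices - c
    ang = np.arctan2(v[:, 1], v[:, 0])
    rad = np.hypot(v[:, 0], v[:, 1])
    order = np.argsort(ang)
    theta = np.arctan2(yy - c[1], xx - c[0])
    rho = np.hypot(xx - c[0], yy - c[1])
    R = interp_periodic(theta.ravel(), ang[order], rad[order]).reshape(theta.shape)
    return R - rho


# ---------------------------------------------------------------------------
# cortical flow speed
# ---------------------------------------------------------------------------

@dataclass
class CorticalFlow:
    speed_um_per_min: float
    tangential_um_per_min: float
    normal_um_per_min: float
    n_vectors: int
    per_frame_speed: np.ndarray = field(default_factory=lambda: np.array([]))


def cortical_flow_speed(
    fields: list[DisplacementField],
    contours: list[MembraneContour],
    band_width_um: float,
    dt_s: float,
) -> CorticalFlow:
    """Mean cortical flow speed in a band inside the membrane contour.

    Vectors whose grid node lies within ``band_width_um`` inside the
    contour are averaged; the speed is converted to um/min and the mean
    absolute tangential / normal components are reported (tangential and
    normal relative to the local radial direction from the liposome
    center).
    """
    speeds, tangs, norms, counts = [], [], [], 0
    for f, contour in zip(fields, contours):
        xx, yy = np.meshgrid(f.x_um, f.y_um)
        depth = _depth_inside(contour, xx, yy)
        sel = (depth >= 0) & (depth <= band_width_um) & f.valid
        if not sel.any():
            continue
        c = contour.center_of_mass
        rx, ry = xx[sel] - c[0], yy[sel] - c[1]
        rn = np.maximum(np.hypot(rx, ry), 1e-12)
        nx_, ny_ = rx / rn, ry / rn          # outward normal
        tx, ty = -ny_, nx_                   # CCW tangent
        u, v = f.u_um[sel], f.v_um[sel]
        speeds.append(np.hypot(u, v).mean())
        tangs.append(np.abs(u * tx + v * ty).mean())
        norms.append(np.abs(u * nx_ + v * ny_).mean())
        counts += int(sel.sum())
    if counts == 0:
        raise ValueError(
            "no valid PIV vectors inside the cortical band; use a smaller "
            "final PIV window or a wider band"
        )
    to_per_min = 60.0 / dt_s
    return CorticalFlow(
        speed_um_per_min=float(np.mean(speeds) * to_per_min),
        tangential_um_per_min=float(np.mean(tangs) * to_per_min),
        normal_um_per_min=float(np.mean(norms) * to_per_min),
        n_vectors=counts,
        per_frame_speed=np.asarray(speeds) * to_per_min,
    )
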