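"""Raw layer thickness and its three-component tilt correction.

Raw thickness ``T'`` is the depth difference between a layer's two
delimiting surfaces along the A-scan.  Because the retina is tilted with
respect to the A-scan axis, ``T'`` overestimates the true orthogonal
thickness; the correction ``T = T' cos(alpha)`` uses a total tilt angle
``alpha`` combining three fitted components:

* **global tilt** ``gamma`` — the angle between the A-scan axis and the
  normal ``U`` of a least-squares plane through all valid OB_RPE points
  (whole-scan tilt, e.g. from pupil-eccentric beam entry);
* **spherical tilt** ``sigma(x, y)`` — from the eye's curvature, modelled
  by the sphere of revolution of a circle fitted to the central B-scan of
  the OB_RPE; ``V`` points from each retinal point to the sphere centre;
* **local tilt** ``lambda(x, y)`` — the inclination of the plane fitted to
  a small window of the layer's medial surface in the flattened volume
  (``W`` is its normal).

``alpha`` is the angle between the A-scan axis and the (unweighted) vector
sum ``U + V + W`` of the three unit normals, all oriented into the
hemisphere of the A-scan axis.  All fits are performed in physical µm
coordinates so the anisotropic x/y pitch cannot bias the normals.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from .core import SegmentedOCT, ThicknessGrid, TiltField, layer_surfaces, LAYERS, TOTAL


class DegenerateFitError(ValueError):
    """Raised when a surface fit has no unique solution."""


class SphericalFitError(ValueError):
    """Raised when the fitted circle's radius exceeds the configured
    maximum (near-zero curvature)."""


def _a_frame_coords_um(oct_: SegmentedOCT):
    """Pixel-centre (x, y) grids in µm, scan-centred, y up (A-frame)."""
    x, y = oct_.pixel_coords_mm()
    return x * 1000.0, y * 1000.0


def raw_thickness(oct_: SegmentedOCT, layer_id: str) -> ThicknessGrid:
    """Thickness along the A-scan: depth of the outer minus the inner
    delimiting surface (µm)."""
    inner, outer = layer_surfaces(layer_id)
    vals = oct_.surfaces[:, :, outer] - oct_.surfaces[:, :, inner]
    if (vals[oct_.valid_mask] < -1e-6).any():
        raise ValueError(f"surface order violated for layer {layer_id}")
    return ThicknessGrid(np.maximum(vals, 0.0), oct_.valid_mask.copy(), layer_id,
                         frame="native", extent_mm=oct_.extent_mm)


def fit_global_tilt(oct_: SegmentedOCT) -> tuple[np.ndarray, float]:
    """Least-squares plane through all valid OB_RPE points.

    Returns the unit normal ``U`` (A-frame, positive z component) and the
    global tilt angle ``gamma`` in degrees.
    """
    x, y = _a_frame_coords_um(oct_)
    m = oct_.valid_mask
    if m.sum() < 3:
        raise DegenerateFitError("need at least 3 valid OB_RPE points")
    # height above the deepest point, A-frame (z up = -depth)
    h = -oct_.surfaces[:, :, -1]
    X = np.column_stack([x[m], y[m], np.ones(m.sum())])
    coef, _, rank, _ = np.linalg.lstsq(X, h[m], rcond=None)
    if rank < 3:
        raise DegenerateFitError("OB_RPE points are collinear")
    a, b = coef[0], coef[1]
    U = np.array([-a, -b, 1.0]) / np.hypot(np.hypot(a, b), 1.0)
    gamma = np.degrees(np.arctan(np.hypot(a, b)))
    return U, float(gamma)


def _fit_circle_xz(x: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle through (x, z) points.

    Returns (x0, z0, R).  Raises DegenerateFitError on a singular system
    (collinear points).
    """
    xm, zm = x.mean(), z.mean()
    xc, zc = x - xm, z - zm          # centred coordinates for conditioning
    A = np.column_stack([2 * xc, 2 * zc, np.ones_like(xc)])
    b = xc ** 2 + zc ** 2
    try:
        sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        raise DegenerateFitError("circle fit failed")
    if rank < 3:
        raise DegenerateFitError("points are collinear; circle is degenerate")
    x0, z0, c = sol
    R = np.sqrt(c + x0 ** 2 + z0 ** 2)
    # geometric (Gauss-Newton) refinement of the algebraic solution
    for _ in range(20):
        dx, dz = xc - x0, zc - z0
        d = np.hypot(dx, dz)
        r = d - R
        J = np.column_stack([-dx / d, -dz / d, -np.ones_like(d)])
        try:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        x0, z0, R = x0 + step[0], z0 + step[1], R + step[2]
        if np.abs(step).max() < 1e-9 * max(R, 1.0):
            break
    return float(x0 + xm), float(z0 + zm), float(R)


def fit_spherical_tilt(oct_: SegmentedOCT, max_radius_mm: float = 500.0
                       ) -> tuple[tuple, np.ndarray, np.ndarray]:
    """Eye-curvature sphere from the central B-scan of the OB_RPE.

    A circle is fitted (least squares) to the valid ``(x, z)`` points of
    the B-scan crossing the scan centre; the sphere is its surface of
    revolution about the vertical axis through the circle centre.  Returns
    ``(sphere, V_map, sigma_map)`` where ``sphere = (center_xyz_um, R_um)``
    in A-frame coordinates, ``V_map`` holds unit vectors from each OB_RPE
    point toward the sphere centre and ``sigma_map`` their angles to the
    A-scan axis in degrees.

    Raises ``SphericalFitError`` when the fitted radius exceeds
    ``max_radius_mm`` (callers may substitute V = A, sigma = 0).
    """
    rows, _ = oct_.shape
    irow = rows // 2
    x, y = _a_frame_coords_um(oct_)
    m = oct_.valid_mask[irow]
    if m.sum() < 3:
        raise DegenerateFitError("central B-scan has fewer than 3 valid points")
    h_line = -oct_.surfaces[irow, :, -1]
    try:
        x0, h0, R = _fit_circle_xz(x[irow][m], h_line[m])
    except DegenerateFitError:
        raise SphericalFitError("radius exceeds configured maximum (flat B-scan)")
    if R > max_radius_mm * 1000.0:
        raise SphericalFitError(
            f"fitted radius {R / 1000:.1f} mm exceeds configured maximum "
            f"{max_radius_mm} mm")
    if h0 < np.median(h_line[m]):
        # centre below the retina: convex fit, reject as non-eye-like
        raise SphericalFitError("fitted sphere curves the wrong way")
    center = (x0, float(y[irow, 0]), h0)
    h = -oct_.surfaces[:, :, -1]
    d = np.stack([center[0] - x, center[1] - y, center[2] - h], axis=-1)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    V = d / norm
    sigma = np.degrees(np.arccos(np.clip(V[..., 2], -1.0, 1.0)))
    return (center, R), V, sigma


def flatten(oct_: SegmentedOCT) -> SegmentedOCT:
    """Shift every A-scan so the OB_RPE depth becomes zero.

    Raw thickness is invariant under this per-A-scan z displacement.
    """
    shifted = oct_.surfaces - oct_.surfaces[:, :, -1][:, :, None]
    return SegmentedOCT(
        surfaces=shifted, valid_mask=oct_.valid_mask.copy(),
        voxel_pitch_um=oct_.voxel_pitch_um, eye=oct_.eye,
        fovea_xy_mm=oct_.fovea_xy_mm, papilla_xy_mm=oct_.papilla_xy_mm,
        subject_id=oct_.subject_id, group=oct_.group, seed=oct_.seed,
        truth=oct_.truth)


def medial_surface(oct_flat: SegmentedOCT, layer_id: str) -> np.ndarray:
    """Depth grid midway between the layer's delimiting surfaces."""
    inner, outer = layer_surfaces(layer_id)
    return 0.5 * (oct_flat.surfaces[:, :, inner] + oct_flat.surfaces[:, :, outer])


def fit_local_tilt(oct_flat: SegmentedOCT, layer_id: str,
                   window_mm: float = 0.5,
                   min_valid_fraction: float = 0.5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point plane fit to a ``window_mm`` square of the layer's medial
    surface in the flattened volume.

    The fit is solved in closed form from windowed moments (masked
    normalized box filters), which is exactly the least-squares plane over
    the valid in-window samples up to uniform weighting.  Windows are
    truncated at the grid border; points whose window holds fewer than
    ``min_valid_fraction`` valid samples are marked invalid (lambda = NaN).

    Returns ``(W_map, lambda_map)``: unit normals (A-frame) and tilt
    angles in degrees.
    """
    px_um, py_um = oct_flat.voxel_pitch_um[0], oct_flat.voxel_pitch_um[1]
    wx = max(3, int(round(window_mm * 1000.0 / px_um)) | 1)
    wy = max(3, int(round(window_mm * 1000.0 / py_um)) | 1)
    if min(wx, wy) < 3:
        raise ValueError("window must span at least 3 x 3 grid points")
    size = (wy, wx)

    x, y = _a_frame_coords_um(oct_flat)
    h = -medial_surface(oct_flat, layer_id)
    m = oct_flat.valid_mask.astype(float)
    hm = np.where(oct_flat.valid_mask, h, 0.0)

    def box(a):
        return uniform_filter(a, size=size, mode="constant", cval=0.0)

    # border truncation: renormalise by the in-bounds window fraction
    frac_in = box(np.ones_like(m))
    w = box(m) / frac_in                      # valid fraction of the window
    with np.errstate(invalid="ignore", divide="ignore"):
        Em = box(m)
        Ex = box(x * m) / Em
        Ey = box(y * m) / Em
        Eh = box(hm) / Em
        Cxx = box(x * x * m) / Em - Ex ** 2
        Cyy = box(y * y * m) / Em - Ey ** 2
        Cxy = box(x * y * m) / Em - Ex * Ey
        Cxh = box(x * hm) / Em - Ex * Eh
        Cyh = box(y * hm) / Em - Ey * Eh
        det = Cxx * Cyy - Cxy ** 2
        a = (Cyy * Cxh - Cxy * Cyh) / det
        b = (Cxx * Cyh - Cxy * Cxh) / det

    ok = (w >= min_valid_fraction) & oct_flat.valid_mask & np.isfinite(a) & np.isfinite(b)
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    norm = np.sqrt(a ** 2 + b ** 2 + 1.0)
    W = np.stack([-a / norm, -b / norm, 1.0 / norm], axis=-1)
    lam = np.degrees(np.arctan(np.hypot(a, b)))
    lam[~ok] = np.nan
    return W, lam


def total_tilt(U: np.ndarray, V_map: np.ndarray, W_map: np.ndarray) -> np.ndarray:
    """Angle (degrees) between the A-scan axis and ``U + V + W``.

    Each normal is flipped into the A hemisphere (positive z component)
    before summation; the sum of three same-hemisphere unit vectors cannot
    vanish.
    """
    def orient(n):
        n = np.asarray(n, dtype=float)
        sign = np.where(n[..., 2:3] < 0, -1.0, 1.0)
        return n * sign

    s = orient(np.broadcast_to(U, V_map.shape)) + orient(V_map) + orient(W_map)
    norm = np.linalg.norm(s, axis=-1)
    if (norm < 1e-12).any():
        raise ValueError("vector sum vanished; normals are not oriented")
    return np.degrees(np.arccos(np.clip(s[..., 2] / norm, -1.0, 1.0)))


def correct_thickness(t_raw: ThicknessGrid, alpha_map: np.ndarray) -> ThicknessGrid:
    """Orthogonal thickness ``T = T' cos(alpha)``; points with alpha >= 90
    degrees (or undefined alpha) become invalid."""
    alpha = np.asarray(alpha_map, dtype=float)
    if alpha.shape != t_raw.shape:
        raise ValueError("alpha map shape mismatch")
    ok = t_raw.valid_mask & np.isfinite(alpha) & (alpha < 90.0)
    vals = np.where(ok, t_raw.values * np.cos(np.radians(np.where(ok, alpha, 0.0))), 0.0)
    return ThicknessGrid(vals, ok, t_raw.layer_id, frame=t_raw.frame,
                         extent_mm=t_raw.extent_mm)


def tilt_correct_subject(oct_: SegmentedOCT, layers=None,
                         max_radius_mm: float = 500.0,
                         window_mm: float = 0.5,
                         spherical_fallback: bool = True
                         ) -> tuple[dict, dict]:
    """Full correction chain for one subject.

    Fits global and spherical tilt once, then per requested layer fits the
    local tilt on the flattened volume, combines the three normals and
    corrects the raw thickness.  ``TOTAL`` uses a zero local tilt (the
    total retina has no meaningful single medial surface undulation scale;
    its correction combines global and spherical components only).

    Returns ``(thickness, tilt)`` dicts keyed by layer id; ``thickness``
    holds corrected `ThicknessGrid`s, ``tilt`` the per-layer `TiltField`.
    """
    layers = list(layers) if layers is not None else list(LAYERS) + [TOTAL]
    U, gamma = fit_global_tilt(oct_)
    try:
        (center, R), V, sigma = fit_spherical_tilt(oct_, max_radius_mm)
        sphere_center = tuple(c / 1000.0 for c in center)
        sphere_radius = R / 1000.0
    except SphericalFitError:
        if not spherical_fallback:
            raise
        V = np.zeros(oct_.shape + (3,))
        V[..., 2] = 1.0
        sigma = np.zeros(oct_.shape)
        sphere_center, sphere_radius = None, None
    flat = flatten(oct_)

    thickness, tilt = {}, {}
    flatA = np.zeros(oct_.shape + (3,))
    flatA[..., 2] = 1.0
    for lid in layers:
        t_raw = raw_thickness(oct_, lid)
        if lid == TOTAL:
            W, lam = flatA, np.zeros(oct_.shape)
        else:
            W, lam = fit_local_tilt(flat, lid, window_mm=window_mm)
        alpha = total_tilt(U, V, W)
        alpha = np.where(np.isfinite(lam), alpha, np.nan)
        thickness[lid] = correct_thickness(t_raw, alpha)
        tilt[lid] = TiltField(U=U, gamma_deg=gamma, V_map=V, sigma_map=sigma,
                              W_map=W, lambda_map=lam, alpha_map=alpha,
                              sphere_center_mm=sphere_center,
                              sphere_radius_mm=sphere_radius, layer_id=lid)
    return thickness, tilt
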