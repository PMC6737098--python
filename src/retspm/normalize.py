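"""Spatial normalization of thickness maps onto a canonical anatomical frame.

Every subject's map is mirrored to right-eye orientation, translated so the
fovea centre lands on the output-grid centre, rotated so the maculopapillar
axis (fovea -> papilla) lies at the canonical angle theta, and scaled so the
papilla sits at the canonical distance s from the fovea.  The defaults
theta = 6.766 deg and s = 4.377 mm are study-sample means kept as
configuration; the angle is measured from the +x (temporal -> nasal) axis
toward the superior direction (+y, i.e. upward on the grid).

Thickness values are transported, never rescaled: the similarity transform
acts on x-y geometry only, since thickness is a z-quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ThicknessGrid


@dataclass
class NormalizationParams:
    target_theta_deg: float = 6.766
    target_s_mm: float = 4.377
    output_shape: tuple[int, int] = (128, 512)
    output_extent_mm: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self):
        if self.target_s_mm <= 0:
            raise ValueError("target_s_mm must be positive")

    @property
    def canonical_papilla_mm(self) -> tuple[float, float]:
        th = np.radians(self.target_theta_deg)
        return (self.target_s_mm * np.cos(th), self.target_s_mm * np.sin(th))


@dataclass
class SimilarityTransform:
    """Maps native scan-centred mm coordinates to canonical mm coordinates:
    ``p' = scale * R(rotation) @ (p + translation)``."""

    translation_mm: tuple[float, float]
    rotation_deg: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, p):
        p = np.asarray(p, dtype=float)
        th = np.radians(self.rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return self.scale * (R @ (p + np.asarray(self.translation_mm)))

    def inverse(self, q):
        q = np.asarray(q, dtype=float)
        th = np.radians(self.rotation_deg)
        R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        return (R @ (q / self.scale)) - np.asarray(self.translation_mm)


def flip_if_left_eye(grid: ThicknessGrid, eye: str, landmarks=None):
    """Mirror a left eye horizontally so temporal/nasal sides match right
    eyes; identity for right eyes.  ``landmarks`` is an optional sequence of
    (x, y) mm points mirrored alongside (x -> -x).

    Returns the grid alone, or ``(grid, landmarks)`` if landmarks given.
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    if eye == "right":
        out, lms = grid, landmarks
    else:
        out = ThicknessGrid(grid.values[:, ::-1].copy(),
                            grid.valid_mask[:, ::-1].copy(),
                            grid.layer_id, frame=grid.frame,
                            extent_mm=grid.extent_mm)
        lms = None if landmarks is None else [(-x, y) for x, y in landmarks]
    return out if landmarks is None else (out, lms)


def compute_transform(c_m, c_p, params: NormalizationParams) -> SimilarityTransform:
    """Similarity transform sending the fovea ``c_m`` to the output centre,
    the maculopapillar axis to ``target_theta_deg`` and the papilla to
    ``target_s_mm`` from the fovea."""
    c_m = np.asarray(c_m, dtype=float)
    c_p = np.asarray(c_p, dtype=float)
    d = c_p - c_m
    s = float(np.hypot(*d))
    if s < 1e-9:
        raise ValueError("fovea and papilla coincide; transform undefined")
    phi = np.degrees(np.arctan2(d[1], d[0]))
    rot = params.target_theta_deg - phi
    # wrap to (-180, 180] for a canonical representation
    rot = (rot + 180.0) % 360.0 - 180.0
    return SimilarityTransform(translation_mm=tuple(-c_m), rotation_deg=float(rot),
                               scale=params.target_s_mm / s)


def apply_transform(grid: ThicknessGrid, t: SimilarityTransform,
                    params: NormalizationParams) -> ThicknessGrid:
    """Resample onto the canonical output grid by inverse mapping with
    bilinear interpolation.

    Mask handling is conservative: an output pixel is invalid if any of its
    four bilinear source neighbours is invalid or out of bounds.
    """
    rows_o, cols_o = params.output_shape
    w_o, h_o = params.output_extent_mm
    xo = (np.arange(cols_o) + 0.5) * (w_o / cols_o) - w_o / 2.0
    yo = h_o / 2.0 - (np.arange(rows_o) + 0.5) * (h_o / rows_o)
    Xo, Yo = np.meshgrid(xo, yo)

    th = np.radians(t.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    # inverse similarity: p = R^T (q / scale) - translation
    qx, qy = Xo / t.scale, Yo / t.scale
    px = c * qx + s * qy - t.translation_mm[0]
    py = -s * qx + c * qy - t.translation_mm[1]

    rows_i, cols_i = grid.shape
    w_i, h_i = grid.extent_mm
    col = (px + w_i / 2.0) / (w_i / cols_i) - 0.5
    row = (h_i / 2.0 - py) / (h_i / rows_i) - 0.5
    coords = np.stack([row.ravel(), col.ravel()])

    vals = np.where(grid.valid_mask, grid.values, 0.0)
    out = map_coordinates(vals, coords, order=1, mode="constant", cval=0.0)
    wgt = map_coordinates(grid.valid_mask.astype(float), coords, order=1,
                          mode="constant", cval=0.0)
    inb = ((coords[0] >= 0) & (coords[0] <= rows_i - 1)
           & (coords[1] >= 0) & (coords[1] <= cols_i - 1))
    ok = (wgt >= 1.0 - 1e-9) & inb
    return ThicknessGrid(np.where(ok, out, 0.0).reshape(rows_o, cols_o),
                         ok.reshape(rows_o, cols_o), grid.layer_id,
                         frame="normalized", extent_mm=params.output_extent_mm)


def normalize_subject(grids: dict, fovea_xy, papilla_xy, eye: str,
                      params: NormalizationParams) -> dict:
    """Flip, compute the landmark transform once, and resample every layer
    grid of one subject into the canonical frame."""
    first = True
    out = {}
    for lid, g in grids.items():
        if first:
            _, (c_m, c_p) = flip_if_left_eye(g, eye, [fovea_xy, papilla_xy])
            t = compute_transform(c_m, c_p, params)
            first = False
        gf = flip_if_left_eye(g, eye)
        out[lid] = apply_transform(gf, t, params)
    return out
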