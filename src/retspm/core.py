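"""Core containers for segmented OCT volumes and thickness maps.

Coordinate conventions used throughout the package:

* Grids are indexed ``[row, col]``; row 0 is the superior edge of the scan,
  column 0 the temporal edge after right-eye standardization.
* Physical coordinates are expressed in millimetres in an ``(x, y)`` frame
  whose origin is the scan centre, with ``x`` increasing with column index
  (temporal -> nasal for a right eye) and ``y`` increasing upward (superior),
  i.e. opposite to the row index.
* Pixel centres sit at ``(i + 0.5) * pitch`` from the grid edge.
* Depth ``z`` is in micrometres and increases away from the pupil; the
  A-scan axis ``A`` is the unit vector pointing from the retina toward the
  pupil, so surface normals are oriented to have a positive component
  along ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Retinal layers in anatomical order, innermost first.  Layer ``k`` (0-based)
#: is delimited by surfaces ``k`` and ``k + 1`` of the 11-surface stack;
#: surface 0 is the ILM and surface 10 the outer boundary of the RPE (OB_RPE).
LAYERS = ("NFL", "GCL", "IPL", "INL", "OPL", "ONL", "IS/OS", "OSL", "OPR", "RPE")

#: The nine non-RPE layers used in cross-layer tests.
NEURAL_LAYERS = LAYERS[:-1]

#: Pseudo-layer spanning ILM to OB_RPE.
TOTAL = "TOTAL"

N_SURFACES = 11

ALL_LAYERS = LAYERS + (TOTAL,)


def layer_surfaces(layer_id: str) -> tuple[int, int]:
    """Return (inner, outer) 0-based surface indices delimiting ``layer_id``."""
    if layer_id == TOTAL:
        return 0, N_SURFACES - 1
    try:
        k = LAYERS.index(layer_id)
    except ValueError:
        raise ValueError(f"unknown layer {layer_id!r}; expected one of {ALL_LAYERS}")
    return k, k + 1


@dataclass
class SegmentedOCT:
    """One subject's segmented OCT volume as an 11-surface depth grid.

    Parameters
    ----------
    surfaces : ndarray, shape (rows, cols, 11)
        Depth in µm of each delimiting surface, non-decreasing along the last
        axis at valid points.
    valid_mask : ndarray of bool, shape (rows, cols)
        False where segmentation failed.
    voxel_pitch_um : tuple of float
        (x, y, z) pitch in µm.  x is the within-B-scan (column) pitch.
    eye : {"right", "left"}
    fovea_xy_mm, papilla_xy_mm : tuple of float
        Landmark coordinates in the scan-centred mm frame (see module notes).
        The papilla may lie outside the scanned extent.
    """

    surfaces: np.ndarray
    valid_mask: np.ndarray
    voxel_pitch_um: tuple[float, float, float]
    eye: str = "right"
    fovea_xy_mm: tuple[float, float] = (0.0, 0.0)
    papilla_xy_mm: tuple[float, float] = (4.377, 0.516)
    subject_id: str = ""
    group: str = ""
    seed: Optional[int] = None
    truth: Optional[dict] = None  # ground-truth fields for synthetic subjects

    def __post_init__(self):
        self.surfaces = np.asarray(self.surfaces, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.surfaces.ndim != 3 or self.surfaces.shape[2] != N_SURFACES:
            raise ValueError("surfaces must have shape (rows, cols, 11)")
        if self.valid_mask.shape != self.surfaces.shape[:2]:
            raise ValueError("valid_mask shape mismatch")
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.surfaces.shape[:2]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the scanned area in mm."""
        rows, cols = self.shape
        return (cols * self.voxel_pitch_um[0] / 1000.0,
                rows * self.voxel_pitch_um[1] / 1000.0)

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate grids (x_mm, y_mm), scan-centred frame."""
        rows, cols = self.shape
        w, h = self.extent_mm
        x = (np.arange(cols) + 0.5) * (w / cols) - w / 2.0
        y = h / 2.0 - (np.arange(rows) + 0.5) * (h / rows)
        return np.meshgrid(x, y)

    def check_monotone(self, atol: float = 1e-6) -> None:
        """Raise if surface depths decrease along the surface axis at any
        valid point."""
        d = np.diff(self.surfaces, axis=2)
        bad = (d < -atol) & self.valid_mask[:, :, None]
        if bad.any():
            raise ValueError(
                f"surface order violated at {int(bad.any(axis=2).sum())} valid points")


@dataclass
class ThicknessGrid:
    """A per-layer 2D thickness field in µm with validity mask.

    ``frame`` records where in the pipeline the grid lives: ``native`` (scanner
    frame), ``normalized`` (canonical anatomical frame) or ``resampled``
    (analysis resolution).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    layer_id: str
    frame: str = "native"
    extent_mm: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.frame not in ("native", "normalized", "resampled"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        rows, cols = self.shape
        return (self.extent_mm[0] / cols, self.extent_mm[1] / rows)

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        w, h = self.extent_mm
        x = (np.arange(cols) + 0.5) * (w / cols) - w / 2.0
        y = h / 2.0 - (np.arange(rows) + 0.5) * (h / rows)
        return np.meshgrid(x, y)

    def masked(self) -> np.ndarray:
        """Values with invalid points set to NaN."""
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out

    def with_values(self, values: np.ndarray, **kw) -> "ThicknessGrid":
        d = dict(values=values, valid_mask=self.valid_mask,
                 layer_id=self.layer_id, frame=self.frame,
                 extent_mm=self.extent_mm)
        d.update(kw)
        return ThicknessGrid(**d)


@dataclass
class TiltField:
    """Per-subject tilt decomposition: the three fitted normals and their
    angles to the A-scan axis, all in degrees.

    U/gamma: global tilt (plane fit to OB_RPE); V/sigma: spherical tilt
    (eye-curvature sphere); W/lambda: local tilt of one layer's medial
    surface; alpha: angle of the vector sum U + V + W.
    """

    U: np.ndarray                      # (3,) unit vector
    gamma_deg: float
    V_map: Optional[np.ndarray]        # (rows, cols, 3)
    sigma_map: Optional[np.ndarray]    # degrees
    W_map: Optional[np.ndarray]
    lambda_map: Optional[np.ndarray]
    alpha_map: Optional[np.ndarray]
    sphere_center_mm: Optional[tuple[float, float, float]] = None
    sphere_radius_mm: Optional[float] = None
    layer_id: Optional[str] = None
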