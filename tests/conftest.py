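import math

import numpy as np
import pytest

from retspm.core import SegmentedOCT
from retspm.synthetic import CohortSpec, TiltParams


def quiet_spec(**kw) -> CohortSpec:
    """A reduced cohort spec without stochastic nuisances, for geometry and
    determinism tests."""
    defaults = dict(
        n_patients=2, n_controls=2, dropout_rate=0.0,
        sd_global_frac=0.0, sd_local_frac=0.0,
        left_eye_fraction=0.0, fovea_jitter_mm=0.0,
        papilla_s_sd_mm=0.0, papilla_theta_sd_deg=0.0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


def no_tilt_params() -> TiltParams:
    return TiltParams(global_tilt_deg_range=(0.0, 0.0),
                      sphere_radius_mm=math.inf, sphere_radius_sd_mm=0.0,
                      sphere_center_jitter_mm=0.0, undulation_amp_um=0.0)


@pytest.fixture
def flat_slab_oct():
    """Untilted parallel stack: 11 flat surfaces 30 µm apart (300 µm total)."""
    rows, cols = 64, 256
    surfaces = np.zeros((rows, cols, 11))
    for k in range(11):
        surfaces[:, :, k] = 200.0 + 30.0 * k
    return SegmentedOCT(surfaces, np.ones((rows, cols), bool),
                        voxel_pitch_um=(6000.0 / cols, 6000.0 / rows, 3.5))


def make_slab(z_outer: np.ndarray, t_raw, pitch_um) -> SegmentedOCT:
    """Stack of 11 surfaces with OB_RPE at ``z_outer`` and equal per-layer
    along-A-scan thickness ``t_raw / 10``."""
    rows, cols = z_outer.shape
    surfaces = np.empty((rows, cols, 11))
    surfaces[:, :, 10] = z_outer
    for k in range(9, -1, -1):
        surfaces[:, :, k] = surfaces[:, :, k + 1] - np.asarray(t_raw) / 10.0
    return SegmentedOCT(surfaces, np.ones((rows, cols), bool), pitch_um)


def grid_coords_um(rows, cols, pitch_um):
    """Pixel-centre (x, y) grids in µm, scan-centred, y up."""
    x = (np.arange(cols) + 0.5) * pitch_um[0] - cols * pitch_um[0] / 2.0
    y = rows * pitch_um[1] / 2.0 - (np.arange(rows) + 0.5) * pitch_um[1]
    return np.meshgrid(x, y)
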