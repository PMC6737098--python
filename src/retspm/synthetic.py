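"""Synthetic two-group retinal OCT cohorts with known ground truth.

Emulates the acquisition geometry of a 6 x 6 mm macular raster scan
(128 B-scans x 512 A-scans, voxel pitch 11.71875 x 46.875 x 3.5 µm) and
produces, per subject, the 11 delimiting surfaces of the 10-layer retinal
stack together with a segmentation-validity mask and fovea/papilla
landmarks.

The generative model, per subject:

1.  Per-layer *true orthogonal thickness* ``T = baseline + group effect +
    subject noise`` (µm).  Baselines are radially symmetric analytic
    templates around the fovea: inner layers carry a parafoveal ring and a
    foveal pit (inverted Gaussian), the ONL peaks at the fovea, outer
    bands are flat.  Templates are scaled so the control-group scan-mean
    total retinal thickness equals ``total_mean_um`` exactly.
2.  Group effects are isotropic Gaussian blobs (``EffectBlob``); the blob
    radius is its half-width at half maximum and its support is the disc
    of that radius.
3.  Subject noise has two components per layer: a scalar between-subject
    offset (subjects differ in overall thickness) and a spatially smooth
    zero-mean field obtained by Gaussian-filtering white noise to a known
    FWHM, so the field smoothness assumed downstream is controllable.
4.  Tilt: a global plane (uniform tilt angle, random azimuth), the sag of
    an eye-curvature sphere, and a smooth low-amplitude undulation of the
    outer RPE boundary.  Surfaces are stacked from the OB_RPE upward with
    the along-A-scan thickness ``T / cos(theta)`` where ``theta`` is the
    layer's analytic orientation angle, so the true orthogonal thickness
    remains exactly known.
5.  Segmentation dropout as smooth random blobs covering ``dropout_rate``
    of the area; left eyes are mirrored whole (grids and landmarks).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import LAYERS, N_SURFACES, SegmentedOCT

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Scan-mean target thickness per layer before total normalization (µm).
DEFAULT_LAYER_MEANS_UM = {
    "NFL": 38.0, "GCL": 34.0, "IPL": 32.0, "INL": 32.0, "OPL": 27.0,
    "ONL": 63.0, "IS/OS": 24.0, "OSL": 15.0, "OPR": 10.0, "RPE": 16.0,
}


@dataclass
class EffectBlob:
    """A localized group effect: isotropic Gaussian thickness change.

    ``radius_mm`` is the half-width at half maximum of the profile
    ``amplitude * exp(-ln2 * r^2 / radius^2)``; the blob's nominal support
    is the disc ``r <= radius_mm``.  Negative amplitude = thinning.
    """

    center_xy_mm: tuple[float, float]
    radius_mm: float
    amplitude_um: float
    layer_id: str

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.layer_id not in LAYERS:
            raise ValueError(f"unknown layer {self.layer_id!r}")

    def profile(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        r2 = (x_mm - self.center_xy_mm[0]) ** 2 + (y_mm - self.center_xy_mm[1]) ** 2
        return self.amplitude_um * np.exp(-math.log(2.0) * r2 / self.radius_mm ** 2)

    def support(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        r2 = (x_mm - self.center_xy_mm[0]) ** 2 + (y_mm - self.center_xy_mm[1]) ** 2
        return r2 <= self.radius_mm ** 2


def default_effects() -> list[EffectBlob]:
    """Patient-group effect set: parafoveal thinning of inner layers and
    OSL/OPR with mild RPE thickening, sized so the scan-mean total-retina
    deficit is close to 5 µm."""
    return [
        EffectBlob((0.3, 0.9), 0.80, -13.0, "NFL"),
        EffectBlob((-0.8, 0.1), 0.80, -14.0, "GCL"),
        EffectBlob((-0.7, -0.8), 0.70, -10.0, "IPL"),
        EffectBlob((0.9, -0.3), 0.75, -11.0, "INL"),
        EffectBlob((-0.5, 0.6), 0.90, -8.0, "ONL"),
        EffectBlob((0.8, 0.8), 0.90, -7.0, "OSL"),
        EffectBlob((-0.4, -0.3), 0.70, -6.0, "OPR"),
        EffectBlob((1.2, 0.0), 0.90, 4.0, "RPE"),
    ]


@dataclass
class TiltParams:
    """Tilt geometry of a simulated acquisition.

    ``global_tilt_deg_range`` bounds the uniform draw of the whole-scan
    plane tilt; ``sphere_radius_mm`` is the apparent eye-curvature radius
    of the OB_RPE as seen by the scanner (about 35 mm reproduces corner
    tilts of a few degrees on a 6 mm scan); ``undulation_amp_um`` is the
    SD of the smooth undulation of the OB_RPE surface.
    """

    global_tilt_deg_range: tuple[float, float] = (0.0, 3.0)
    sphere_radius_mm: float = 35.0
    sphere_radius_sd_mm: float = 3.0
    sphere_center_jitter_mm: float = 0.3
    undulation_amp_um: float = 3.0
    undulation_fwhm_mm: float = 1.5


@dataclass
class CohortSpec:
    """Full description of a simulated two-group cohort.

    Noise fractions are relative to each layer's mean thickness:
    ``sd_global_frac`` scales the per-subject scalar offset (dominates the
    between-subject SD of scan-mean thickness, ~13 µm for the total retina
    at the default), ``sd_local_frac`` the smooth within-scan field.
    """

    n_patients: int = 19
    n_controls: int = 24
    grid: tuple[int, int] = (128, 512)
    scan_extent_mm: tuple[float, float] = (6.0, 6.0)
    voxel_pitch_um: tuple[float, float, float] = (11.71875, 46.875, 3.5)
    layer_means_um: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_MEANS_UM))
    total_mean_um: float = 286.5
    sd_global_frac: float = 0.13
    sd_local_frac: float = 0.08
    noise_smoothness_fwhm_mm: float = 1.0
    effects: list = field(default_factory=default_effects)
    tilt: TiltParams = field(default_factory=TiltParams)
    dropout_rate: float = 0.02
    dropout_fwhm_mm: float = 0.8
    left_eye_fraction: float = 4.0 / 43.0
    fovea_jitter_mm: float = 0.15
    papilla_s_mm: float = 4.377
    papilla_s_sd_mm: float = 0.25
    papilla_theta_deg: float = 6.766
    papilla_theta_sd_deg: float = 1.5
    clamp_floor_um: float = 0.5
    on_negative: str = "clamp"          # or "resample"
    pit_depth: float = 0.95             # fractional pit depth of inner layers
    pit_sigma_mm: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.sd_global_frac, self.sd_local_frac) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.on_negative not in ("clamp", "resample"):
            raise ValueError("on_negative must be 'clamp' or 'resample'")
        missing = set(LAYERS) - set(self.layer_means_um)
        if missing:
            raise ValueError(f"layer_means_um missing {missing}")

    def pixel_coords_mm(self, fovea_xy=(0.0, 0.0)):
        rows, cols = self.grid
        w, h = self.scan_extent_mm
        x = (np.arange(cols) + 0.5) * (w / cols) - w / 2.0 - fovea_xy[0]
        y = h / 2.0 - (np.arange(rows) + 0.5) * (h / rows) - fovea_xy[1]
        return np.meshgrid(x, y)


# ---------------------------------------------------------------------------
# smooth random fields

_KNORM_CACHE: dict = {}


def _kernel_norm(shape, sigma_px) -> float:
    key = (shape, tuple(np.atleast_1d(sigma_px)))
    if key not in _KNORM_CACHE:
        imp = np.zeros(shape)
        imp[tuple(s // 2 for s in shape)] = 1.0
        k = gaussian_filter(imp, sigma_px, mode="wrap")
        _KNORM_CACHE[key] = float(np.sqrt((k ** 2).sum()))
    return _KNORM_CACHE[key]


def smooth_unit_field(rng: np.random.Generator, shape, sigma_px) -> np.ndarray:
    """White noise Gaussian-filtered to ``sigma_px`` and rescaled to unit
    pointwise variance (circular boundary, stationary by construction)."""
    w = rng.standard_normal(shape)
    f = gaussian_filter(w, sigma_px, mode="wrap")
    return f / _kernel_norm(shape, sigma_px)


def _sigma_px(fwhm_mm: float, spec: CohortSpec) -> tuple[float, float]:
    rows, cols = spec.grid
    w, h = spec.scan_extent_mm
    return (fwhm_mm * FWHM_TO_SIGMA / (h / rows), fwhm_mm * FWHM_TO_SIGMA / (w / cols))


# ---------------------------------------------------------------------------
# baseline templates

def _templates(spec: CohortSpec, x: np.ndarray, y: np.ndarray) -> dict:
    """Unit-mean spatial templates per layer; x, y are fovea-centred mm."""
    r = np.hypot(x, y)
    pit = np.exp(-r ** 2 / (2.0 * spec.pit_sigma_mm ** 2))

    def ring(mu, s):
        return np.exp(-(r - mu) ** 2 / (2.0 * s ** 2))

    w = spec.scan_extent_mm[0]
    nasal = (x + w / 2.0) / w  # 0 at temporal edge, 1 at nasal edge
    t = {
        "NFL": (0.6 + 0.8 * nasal + 0.3 * ring(1.5, 0.6)) * (1 - 0.9 * pit),
        "GCL": (1 + 1.2 * ring(1.0, 0.45)) * (1 - spec.pit_depth * pit),
        "IPL": (1 + 1.0 * ring(1.0, 0.45)) * (1 - spec.pit_depth * pit),
        "INL": (1 + 1.0 * ring(1.2, 0.50)) * (1 - spec.pit_depth * pit),
        "OPL": (1 + 0.6 * ring(1.2, 0.50)) * (1 - 0.8 * pit),
        "ONL": 1 + 1.1 * np.exp(-r ** 2 / (2.0 * 0.6 ** 2)),
        "IS/OS": 1 + 0.15 * np.exp(-r ** 2 / (2.0 * 0.5 ** 2)),
        "OSL": np.ones_like(r),
        "OPR": np.ones_like(r),
        "RPE": np.ones_like(r),
    }
    for k in t:
        t[k] = np.clip(t[k], 0.02, None)
    return t


def baseline_thickness(spec: CohortSpec, fovea_xy=(0.0, 0.0)) -> dict:
    """Per-layer baseline thickness fields (µm), scaled so the scan-mean
    total equals ``spec.total_mean_um``."""
    x, y = spec.pixel_coords_mm(fovea_xy)
    t = _templates(spec, x, y)
    total = sum(spec.layer_means_um.values())
    scale = spec.total_mean_um / total
    return {k: spec.layer_means_um[k] * scale * t[k] / t[k].mean() for k in LAYERS}


# ---------------------------------------------------------------------------
# subject generation

def _subject_seed(seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0])


def generate_subject(spec: CohortSpec, group: str, subject_seed: int,
                     subject_id: str = "") -> SegmentedOCT:
    """Simulate one subject's segmented OCT volume.

    ``group`` is ``"patient"`` or ``"control"``; effect blobs apply to
    patients only.  The returned object carries a ``truth`` dict with the
    true orthogonal thickness, the applied per-layer tilt angle and the
    effect field, all in the subject's native (possibly mirrored) frame.
    """
    if group not in ("patient", "control"):
        raise ValueError("group must be 'patient' or 'control'")
    for attempt in range(20):
        rng = np.random.default_rng(_subject_seed(subject_seed, attempt)
                                    if attempt else subject_seed)
        oct_, n_clamped = _generate_once(spec, group, rng, subject_seed, subject_id)
        if n_clamped == 0 or spec.on_negative == "clamp":
            if n_clamped:
                warnings.warn(
                    f"clamped {n_clamped} negative thickness points to "
                    f"{spec.clamp_floor_um} µm", stacklevel=2)
            return oct_
    raise RuntimeError("could not draw a subject without negative thickness")


def _generate_once(spec, group, rng, subject_seed, subject_id):
    rows, cols = spec.grid
    w_mm, h_mm = spec.scan_extent_mm

    fovea = rng.normal(0.0, spec.fovea_jitter_mm, size=2)
    fovea = tuple(np.clip(fovea, -0.4, 0.4))
    x, y = spec.pixel_coords_mm()          # scan-centred mm
    base = baseline_thickness(spec, fovea)

    sig_noise = _sigma_px(spec.noise_smoothness_fwhm_mm, spec)
    truth_T, effect_fields = {}, {}
    n_clamped = 0
    for k in LAYERS:
        m = spec.layer_means_um[k] * spec.total_mean_um / sum(spec.layer_means_um.values())
        t = base[k] + rng.normal(0.0, spec.sd_global_frac * m)
        if spec.sd_local_frac > 0:
            t = t + spec.sd_local_frac * m * smooth_unit_field(rng, spec.grid, sig_noise)
        eff = np.zeros_like(t)
        if group == "patient":
            for blob in spec.effects:
                if blob.layer_id == k:
                    eff += blob.profile(x - fovea[0], y - fovea[1])
        t = t + eff
        neg = t < spec.clamp_floor_um
        n_clamped += int(neg.sum())
        truth_T[k] = np.where(neg, spec.clamp_floor_um, t)
        effect_fields[k] = eff

    # --- tilt geometry (depth z in µm, increasing away from the pupil) ---
    tp = spec.tilt
    gamma = rng.uniform(*tp.global_tilt_deg_range)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    gx, gy = np.tan(np.radians(gamma)) * np.array([np.cos(phi), np.sin(phi)])
    if math.isfinite(tp.sphere_radius_mm):
        R_mm = max(rng.normal(tp.sphere_radius_mm, tp.sphere_radius_sd_mm), 15.0)
    else:
        R_mm = math.inf
    cx, cy = rng.uniform(-tp.sphere_center_jitter_mm, tp.sphere_center_jitter_mm, 2)
    rho2 = ((x - cx) ** 2 + (y - cy) ** 2)
    if math.isinf(R_mm):
        sag_um = np.zeros_like(x)
    else:
        sag_um = (np.sqrt(R_mm ** 2 - rho2) - R_mm) * 1000.0  # <= 0, edges shallower
    und_um = np.zeros_like(x)
    if tp.undulation_amp_um > 0:
        und_um = tp.undulation_amp_um * smooth_unit_field(
            rng, spec.grid, _sigma_px(tp.undulation_fwhm_mm, spec))
    z_obrpe = 500.0 + (gx * x + gy * y) * 1000.0 + sag_um + und_um

    # analytic slope of z_obrpe (µm per mm -> dimensionless /1000)
    if math.isinf(R_mm):
        dzdx = np.full_like(x, gx * 1000.0)
        dzdy = np.full_like(x, gy * 1000.0)
    else:
        dzdx = gx * 1000.0 - (x - cx) * 1000.0 / np.sqrt(R_mm ** 2 - rho2)
        dzdy = gy * 1000.0 - (y - cy) * 1000.0 / np.sqrt(R_mm ** 2 - rho2)
    if tp.undulation_amp_um > 0:
        gu = np.gradient(und_um, w_mm / cols, axis=1), np.gradient(und_um, -h_mm / rows, axis=0)
        dzdx = dzdx + gu[0]
        dzdy = dzdy + gu[1]

    # per-layer orientation: OB_RPE slope + slope of the layer's medial
    # surface relative to OB_RPE (from the thickness stack itself)
    depth_above = np.zeros_like(x)     # cumulative thickness outward of layer
    theta, t_raw = {}, {}
    for k in reversed(LAYERS):
        medial = -(depth_above + truth_T[k] / 2.0)
        mdx = np.gradient(medial, w_mm / cols, axis=1)
        mdy = np.gradient(medial, -h_mm / rows, axis=0)
        slope = np.hypot(dzdx + mdx, dzdy + mdy) / 1000.0
        theta[k] = np.degrees(np.arctan(slope))
        t_raw[k] = truth_T[k] / np.cos(np.radians(theta[k]))
        depth_above = depth_above + t_raw[k]

    surfaces = np.empty((rows, cols, N_SURFACES))
    surfaces[:, :, N_SURFACES - 1] = z_obrpe
    for i, k in enumerate(reversed(LAYERS)):
        idx = N_SURFACES - 2 - i
        surfaces[:, :, idx] = surfaces[:, :, idx + 1] - t_raw[k]

    # --- dropout ---
    valid = np.ones((rows, cols), dtype=bool)
    if spec.dropout_rate > 0:
        f = smooth_unit_field(rng, spec.grid, _sigma_px(spec.dropout_fwhm_mm, spec))
        valid = f <= np.quantile(f, 1.0 - spec.dropout_rate)

    # --- landmarks (right-eye anatomical frame: nasal = +x, superior = +y) ---
    s = max(rng.normal(spec.papilla_s_mm, spec.papilla_s_sd_mm), 1.0)
    th = np.radians(rng.normal(spec.papilla_theta_deg, spec.papilla_theta_sd_deg))
    papilla = (fovea[0] + s * np.cos(th), fovea[1] + s * np.sin(th))

    eye = "left" if rng.uniform() < spec.left_eye_fraction else "right"
    truth = {"thickness": truth_T, "tilt_deg": theta, "effect": effect_fields,
             "gamma_deg": gamma, "sphere_radius_mm": R_mm, "n_clamped": n_clamped}
    if eye == "left":
        surfaces = surfaces[:, ::-1, :].copy()
        valid = valid[:, ::-1].copy()
        fovea = (-fovea[0], fovea[1])
        papilla = (-papilla[0], papilla[1])
        truth = {"thickness": {k: v[:, ::-1].copy() for k, v in truth_T.items()},
                 "tilt_deg": {k: v[:, ::-1].copy() for k, v in theta.items()},
                 "effect": {k: v[:, ::-1].copy() for k, v in effect_fields.items()},
                 "gamma_deg": gamma, "sphere_radius_mm": R_mm, "n_clamped": n_clamped}

    pitch = (w_mm * 1000.0 / cols, h_mm * 1000.0 / rows, spec.voxel_pitch_um[2])
    return SegmentedOCT(
        surfaces=surfaces, valid_mask=valid, voxel_pitch_um=pitch,
        eye=eye, fovea_xy_mm=tuple(fovea), papilla_xy_mm=tuple(papilla),
        subject_id=subject_id, group=group, seed=subject_seed, truth=truth,
    ), n_clamped


def generate_cohort(spec: CohortSpec) -> list[tuple[SegmentedOCT, str]]:
    """Simulate the full cohort; reproducible from ``spec.seed``."""
    out = []
    for i in range(spec.n_patients + spec.n_controls):
        group = "patient" if i < spec.n_patients else "control"
        sid = f"{'AD' if group == 'patient' else 'C'}{i:03d}"
        out.append((generate_subject(spec, group, _subject_seed(spec.seed, i), sid),
                    group))
    return out


# ---------------------------------------------------------------------------
# analysis-resolution simulators (thickness maps directly, no acquisition
# geometry) -- used for statistical calibration where only the normalized
# map statistics matter

def simulate_null_maps(n: int, shape: tuple[int, int], extent_mm: tuple[float, float],
                       smoothness_fwhm_mm: float, sd_um: float,
                       rng: np.random.Generator) -> np.ndarray:
    """``n`` zero-mean smooth noise maps with pointwise SD ``sd_um`` and
    known smoothness (Gaussian kernel of the given FWHM on white noise)."""
    rows, cols = shape
    sig = (smoothness_fwhm_mm * FWHM_TO_SIGMA / (extent_mm[1] / rows),
           smoothness_fwhm_mm * FWHM_TO_SIGMA / (extent_mm[0] / cols))
    return np.stack([sd_um * smooth_unit_field(rng, shape, sig) for _ in range(n)])


def simulate_effect_cohort(n_patients: int, n_controls: int, shape, extent_mm,
                           smoothness_fwhm_mm: float, sd_local_um: float,
                           sd_global_um: float, blob: EffectBlob,
                           rng: np.random.Generator,
                           baseline_um: float = 34.0):
    """Two groups of analysis-resolution thickness maps with a planted blob
    in the patient group.  Returns (patient_maps, control_maps, support)."""
    rows, cols = shape
    w, h = extent_mm
    xs = (np.arange(cols) + 0.5) * (w / cols) - w / 2.0
    ys = h / 2.0 - (np.arange(rows) + 0.5) * (h / rows)
    x, y = np.meshgrid(xs, ys)

    def draw(n, with_blob):
        maps = simulate_null_maps(n, shape, extent_mm, smoothness_fwhm_mm,
                                  sd_local_um, rng)
        maps += baseline_um + rng.normal(0.0, sd_global_um, size=(n, 1, 1))
        if with_blob:
            maps += blob.profile(x, y)
        return maps

    return draw(n_patients, True), draw(n_controls, False), blob.support(x, y)


# ---------------------------------------------------------------------------
# per-subject container I/O

def write_subject(directory, oct_: SegmentedOCT) -> Path:
    """Write the documented subject container: ``surfaces.npy`` (rows x cols
    x 11, float µm), ``valid_mask.npy`` (bool) and ``meta.json``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "surfaces.npy", oct_.surfaces)
    np.save(d / "valid_mask.npy", oct_.valid_mask)
    meta = {
        "subject_id": oct_.subject_id, "group": oct_.group, "eye": oct_.eye,
        "fovea_xy_mm": list(oct_.fovea_xy_mm), "papilla_xy_mm": list(oct_.papilla_xy_mm),
        "voxel_pitch_um": list(oct_.voxel_pitch_um), "seed": oct_.seed,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def read_subject(directory) -> SegmentedOCT:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    return SegmentedOCT(
        surfaces=np.load(d / "surfaces.npy"),
        valid_mask=np.load(d / "valid_mask.npy"),
        voxel_pitch_um=tuple(meta["voxel_pitch_um"]), eye=meta["eye"],
        fovea_xy_mm=tuple(meta["fovea_xy_mm"]),
        papilla_xy_mm=tuple(meta["papilla_xy_mm"]),
        subject_id=meta["subject_id"], group=meta["group"], seed=meta["seed"],
    )


def export_surface_tiff(oct_: SegmentedOCT, surface_index: int, path) -> None:
    """Dump one surface's depth grid as a float TIFF for visual inspection."""
    import tifffile
    tifffile.imwrite(str(path), oct_.surfaces[:, :, surface_index].astype(np.float32))
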