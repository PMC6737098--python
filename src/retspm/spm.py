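"""Pixelwise group-difference statistical parametric mapping with
random-field-theory thresholding and a max-statistic permutation fallback.

The map statistic is the two-sample pooled-variance t per pixel,
Gaussianized by the tail-probability-preserving transform
``z = Phi^-1(F_t,df(t))`` so that the resulting field is treated as a
unit-variance Gaussian random field.  Family-wise control at level alpha
uses height thresholding: the critical value ``Z_c`` solves
``E[EC](z) = alpha`` with the 2D Euler-characteristic density

    rho_2(z) = (4 ln 2) (2 pi)^(-3/2) z exp(-z^2 / 2)

scaled by the search region's resel count (area term; optional boundary
terms are available but off by default).  Where the Gaussian assumptions
fail, the non-parametric permutation test recomputes the z map under
random relabelings and corrects each pixel by the null distribution of the
in-region extremum (strong FWE control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .preprocess import SearchRegion

_4LN2 = 4.0 * math.log(2.0)


@dataclass
class Moments:
    """Per-pixel group moments over the subjects valid at each pixel."""

    mean_patient: np.ndarray
    mean_control: np.ndarray
    sd_patient: np.ndarray
    sd_control: np.ndarray
    n_patient: int
    n_control: int
    valid_mask: np.ndarray          # pixels valid in *all* subjects

    @property
    def df(self) -> int:
        return self.n_patient + self.n_control - 2

    @property
    def diff(self) -> np.ndarray:
        """Patient-minus-control mean difference map."""
        return self.mean_patient - self.mean_control


def _stack(maps) -> np.ndarray:
    a = np.asarray(maps, dtype=float)
    if a.ndim != 3:
        raise ValueError("expected a (subjects, rows, cols) stack")
    return a


def groupwise_mean_maps(patient_maps, control_maps,
                        patient_valid=None, control_valid=None) -> Moments:
    """Per-pixel mean and SD (n-1 denominator) per group.

    Pixels not valid in every subject are excluded from the common mask
    (group statistics require data from all subjects at a pixel).
    """
    p = _stack(patient_maps)
    c = _stack(control_maps)
    if p.shape[0] < 2 or c.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    valid = np.ones(p.shape[1:], dtype=bool)
    for v in (patient_valid, control_valid):
        if v is not None:
            valid &= np.all(np.asarray(v, dtype=bool), axis=0)
    return Moments(
        mean_patient=p.mean(axis=0), mean_control=c.mean(axis=0),
        sd_patient=p.std(axis=0, ddof=1), sd_control=c.std(axis=0, ddof=1),
        n_patient=p.shape[0], n_control=c.shape[0], valid_mask=valid)


def t_map(moments: Moments) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per pixel (patient - control).

    Returns (t, defined_mask); pixels with zero pooled variance are
    undefined.
    """
    n1, n2 = moments.n_patient, moments.n_control
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * moments.sd_patient ** 2 + (n2 - 1) * moments.sd_control ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    defined = moments.valid_mask & (se > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(defined, moments.diff / np.where(se > 0, se, 1.0), 0.0)
    return t, defined


def z_from_t(t: np.ndarray, df: int) -> np.ndarray:
    """Gaussianize t by preserving tail probability: z = Phi^-1(F_t(t)).

    Computed through the survival function of |t| for numerical stability
    in the far tails.  Negative z = thinner in patients (sign preserved).
    """
    t = np.asarray(t, dtype=float)
    sf = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(sf, 1e-300, 1.0))
    return np.sign(t) * z


def z_map(moments: Moments) -> tuple[np.ndarray, np.ndarray]:
    """Gaussianized group-difference map; returns (z, defined_mask)."""
    t, defined = t_map(moments)
    z = np.where(defined, z_from_t(t, moments.df), 0.0)
    return z, defined


def ec_expected(z: float, resels: float, resels1: float = 0.0,
                resels0: float = 0.0) -> float:
    """Expected Euler characteristic of the excursion set above ``z`` for a
    2D unit Gaussian field (area term; optional 1D/0D boundary terms)."""
    rho2 = _4LN2 * (2.0 * math.pi) ** -1.5 * z * math.exp(-z * z / 2.0)
    rho1 = math.sqrt(_4LN2) / (2.0 * math.pi) * math.exp(-z * z / 2.0)
    rho0 = stats.norm.sf(z)
    return resels * rho2 + resels1 * rho1 + resels0 * rho0


def rft_threshold(resels: float, alpha_fwe: float = 0.05,
                  resels1: float = 0.0, resels0: float = 0.0) -> float:
    """Critical height ``Z_c`` solving ``E[EC](z) = alpha`` (one-sided).

    Boundary resel terms default to zero (area-style counting)."""
    if resels <= 0:
        raise ValueError("resels must be positive")
    if not 0.0 < alpha_fwe < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    def f(z):
        return ec_expected(z, resels, resels1, resels0) - alpha_fwe

    lo, hi = 1.0, 10.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("no root of the EC equation in (1, 10)")
    return float(brentq(f, lo, hi, xtol=1e-10))


def height_threshold(z: np.ndarray, zc: float, region: np.ndarray,
                     direction: str = "thinner") -> np.ndarray:
    """Supra-threshold mask inside the search region.

    ``direction='thinner'`` tests -z > Zc (thinner in patients),
    ``'thicker'`` tests z > Zc.
    """
    if direction not in ("thinner", "thicker"):
        raise ValueError("direction must be 'thinner' or 'thicker'")
    s = -z if direction == "thinner" else z
    return (s > zc) & region


def _labelings(n: int, n1: int, n_perm: int, rng: np.random.Generator,
               observed: tuple) -> list[tuple]:
    total = math.comb(n, n1)
    if total <= n_perm:
        return [tuple(c) for c in combinations(range(n), n1)]
    chosen = {observed}
    idx = np.arange(n)
    while len(chosen) < n_perm:
        chosen.add(tuple(sorted(rng.choice(idx, size=n1, replace=False).tolist())))
    out = [observed] + sorted(chosen - {observed})
    return out[:n_perm]


def permutation_test(maps, labels, region: np.ndarray,
                     direction: str = "thinner", n_perm: int = 10000,
                     seed: int = 0) -> np.ndarray:
    """Max-statistic permutation p map (FWE-corrected, one-sided).

    ``labels`` flags patients (True) vs controls; relabelings are sampled
    without replacement (exhaustive when the number of distinct labelings
    does not exceed ``n_perm``), always including the observed one.  For
    each relabeling the z map is recomputed and its in-region extremum
    recorded; a pixel's p is the fraction of null extrema at least as
    extreme as its observed statistic.  Pixels outside the region get p=1.
    """
    a = _stack(maps)
    labels = np.asarray(labels, dtype=bool)
    n, n1 = labels.size, int(labels.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    flat = a.reshape(n, -1)[:, region.ravel()]
    observed = tuple(sorted(np.flatnonzero(labels).tolist()))
    rng = np.random.default_rng(seed)
    labelings = _labelings(n, n1, n_perm, rng, observed)

    df = n - 2
    sign = -1.0 if direction == "thinner" else 1.0
    maxima = np.empty(len(labelings))
    s_obs = None
    for i, lab in enumerate(labelings):
        sel = np.zeros(n, dtype=bool)
        sel[list(lab)] = True
        g1, g2 = flat[sel], flat[~sel]
        m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
        v1 = g1.var(axis=0, ddof=1)
        v2 = g2.var(axis=0, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n - n1 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / (n - n1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, (m1 - m2) / np.where(se > 0, se, 1.0), 0.0)
        s = sign * z_from_t(t, df)
        maxima[i] = s.max()
        if lab == observed:
            s_obs = s
    p_flat = (maxima[None, :] >= s_obs[:, None] - 1e-12).mean(axis=1)
    p = np.ones(region.shape)
    p.ravel()[region.ravel()] = p_flat
    return p


def assumption_checks(patient_maps, control_maps, region: np.ndarray,
                      alpha: float = 0.05, stride: int = 1) -> dict:
    """Per-pixel Shapiro-Wilk normality (each group) and median-centred
    Levene homoscedasticity tests inside the region.

    ``stride`` subsamples the pixel lattice for speed.  Pixels where a test
    is undefined (constant data) are flagged degenerate, not violating.
    Returns masks plus the fraction of tested pixels violating each
    assumption.
    """
    p = _stack(patient_maps)
    c = _stack(control_maps)
    if p.shape[0] < 3 or c.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    rows, cols = region.shape
    norm_viol = np.zeros((rows, cols), dtype=bool)
    var_viol = np.zeros((rows, cols), dtype=bool)
    degenerate = np.zeros((rows, cols), dtype=bool)
    tested = np.zeros((rows, cols), dtype=bool)
    n_norm_fail = 0
    for i in range(0, rows, stride):
        for j in range(0, cols, stride):
            if not region[i, j]:
                continue
            xi, yi = p[:, i, j], c[:, i, j]
            if np.ptp(xi) == 0 or np.ptp(yi) == 0:
                degenerate[i, j] = True
                continue
            tested[i, j] = True
            fp = stats.shapiro(xi).pvalue < alpha
            fc = stats.shapiro(yi).pvalue < alpha
            n_norm_fail += int(fp) + int(fc)
            if fp or fc:
                norm_viol[i, j] = True
            if stats.levene(xi, yi, center="median").pvalue < alpha:
                var_viol[i, j] = True
    nt = max(int(tested.sum()), 1)
    return {
        "normality_violation": norm_viol, "variance_violation": var_viol,
        "degenerate": degenerate, "tested": tested,
        # fraction of individual per-group Shapiro tests rejecting
        "normality_fraction": n_norm_fail / (2 * nt),
        "variance_fraction": float(var_viol.sum()) / nt,
    }


# ---------------------------------------------------------------------------
# model / results interface

@dataclass
class SPMResults:
    """Fitted group-difference SPM for one layer."""

    layer_id: str
    direction: str
    z: np.ndarray
    moments: Moments
    region: SearchRegion
    zc: Optional[float]
    alpha_fwe: float
    resels: float
    sig_mask: Optional[np.ndarray]
    perm_p: Optional[np.ndarray] = None
    perm_sig_mask: Optional[np.ndarray] = None
    assumptions: Optional[dict] = None
    defined_mask: Optional[np.ndarray] = None

    @property
    def n_sig(self) -> int:
        return int(self.sig_mask.sum()) if self.sig_mask is not None else 0

    @property
    def sig_area_mm2(self) -> float:
        return self.n_sig * self.region.pixel_area_mm2

    def summary(self) -> str:
        m = self.moments
        s = self.z[self.region.circle_mask & self.defined_mask] \
            if self.defined_mask is not None else self.z[self.region.circle_mask]
        lines = [
            f"SPM results: layer {self.layer_id}, direction {self.direction}",
            "=" * 56,
            f"groups                 n={m.n_patient} patients, "
            f"n={m.n_control} controls (df={m.df})",
            f"search region          {int(self.region.circle_mask.sum())} px circle, "
            f"{self.resels:.1f} resels (area-based {self.region.resels_area:.2f})",
            f"z range in region      [{s.min():.3f}, {s.max():.3f}]",
        ]
        if self.zc is not None:
            lines.append(f"RFT critical Zc        {self.zc:.4f} "
                         f"(alpha_FWE={self.alpha_fwe})")
            lines.append(f"significant pixels     {self.n_sig} "
                         f"({self.sig_area_mm2:.3f} mm^2)")
        if self.perm_p is not None:
            pm = self.perm_p[self.region.circle_mask]
            lines.append(f"permutation min p      {pm.min():.4g} "
                         f"({int(self.perm_sig_mask.sum())} px significant)")
        if self.assumptions is not None:
            lines.append(
                f"assumption violations  normality {self.assumptions['normality_fraction']:.3f}, "
                f"homoscedasticity {self.assumptions['variance_fraction']:.3f}")
        return "\n".join(lines)


class ThicknessSPM:
    """Group-difference model for one layer's stack of preprocessed maps.

    Parameters
    ----------
    patient_maps, control_maps : (n, rows, cols) arrays
        Smoothed, spatially normalized thickness maps, one per subject.
    region : SearchRegion
        Analysis square / RFT circle masks and resel count.
    patient_valid, control_valid : optional bool stacks
        Per-subject validity; pixels not valid in all subjects are dropped
        from the search region.
    """

    def __init__(self, patient_maps, control_maps, region: SearchRegion,
                 layer_id: str = "", direction: str = "thinner",
                 alpha_fwe: float = 0.05, patient_valid=None, control_valid=None):
        self.patient_maps = _stack(patient_maps)
        self.control_maps = _stack(control_maps)
        self.region = region
        self.layer_id = layer_id
        self.direction = direction
        self.alpha_fwe = alpha_fwe
        self.moments = groupwise_mean_maps(patient_maps, control_maps,
                                           patient_valid, control_valid)

    def fit(self, method: str = "rft", n_perm: int = 10000, seed: int = 0,
            check_assumptions: bool = False, assumption_stride: int = 4
            ) -> SPMResults:
        """Compute the z map and threshold it.

        ``method`` is ``'rft'``, ``'perm'`` or ``'both'``.
        """
        if method not in ("rft", "perm", "both"):
            raise ValueError("method must be 'rft', 'perm' or 'both'")
        z, defined = z_map(self.moments)
        search = self.region.circle_mask & defined
        res = SPMResults(
            layer_id=self.layer_id, direction=self.direction, z=z,
            moments=self.moments, region=self.region, zc=None,
            alpha_fwe=self.alpha_fwe, resels=self.region.resels,
            sig_mask=None, defined_mask=defined)
        if method in ("rft", "both"):
            res.zc = rft_threshold(self.region.resels, self.alpha_fwe)
            res.sig_mask = height_threshold(z, res.zc, search, self.direction)
        if method in ("perm", "both"):
            maps = np.concatenate([self.patient_maps, self.control_maps])
            labels = np.r_[np.ones(self.moments.n_patient, bool),
                           np.zeros(self.moments.n_control, bool)]
            res.perm_p = permutation_test(maps, labels, search, self.direction,
                                          n_perm=n_perm, seed=seed)
            res.perm_sig_mask = (res.perm_p <= self.alpha_fwe) & search
            if method == "perm":
                res.sig_mask = res.perm_sig_mask
        if check_assumptions:
            res.assumptions = assumption_checks(
                self.patient_maps, self.control_maps, search,
                stride=assumption_stride)
        return res
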