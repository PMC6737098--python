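"""Whole-layer mean comparisons and thinned/thickened area and volume
indices with their cross-layer tests.

For each layer, the patient-minus-control mean difference map over the
4.8 x 4.8 mm analysis square is classified into thinned (diff < 0) and
thickened (diff > 0) regions, either for differences of any size (indices
t0 / T0) or only where |diff| exceeds one SD of the per-pixel difference
distribution of that layer over the square (t1 / T1).  Volume counterparts
v0 / V0 / v1 / V1 are the volume lost in thinned (gained in thickened)
regions as a ratio of the layer's patient-group mean volume over the
square.  Across the nine neural layers, thinned-vs-thickened dominance is
tested with a one-sample t on the per-layer differences (areas) and an
exact Wilcoxon signed-rank test (volumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import NEURAL_LAYERS


@dataclass
class LayerChangeIndices:
    """Thinned/thickened area percentages and volume ratios of one layer."""

    layer_id: str
    t0: float
    T0: float
    t1: float
    T1: float
    v0: float
    V0: float
    v1: float
    V1: float
    sd_diff_um: float

    def __post_init__(self):
        if not (self.t1 <= self.t0 + 1e-9 and self.T1 <= self.T0 + 1e-9
                and self.v1 <= self.v0 + 1e-9 and self.V1 <= self.V0 + 1e-9):
            raise ValueError(">1 SD indices must be nested within any-size indices")


def two_sample_t_from_stats(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance Student t from group summary statistics.

    Returns (t, df, p_one_sided) for the difference mean1 - mean2.
    """
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df), float(stats.t.cdf(t, df))


def one_sample_t_from_stats(mean, sd, n):
    """One-sample Student t against zero from summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    t = mean / (sd / np.sqrt(n))
    return float(t), int(n - 1), float(stats.t.sf(abs(t), n - 1) * 2.0)


def layer_mean_comparison(patient_means, control_means):
    """Two-sample pooled t across subjects' whole-scan layer means.

    Returns a dict with group moments, t, df and the one-sided p for
    thinning (patient < control).
    """
    p = np.asarray(patient_means, dtype=float)
    c = np.asarray(control_means, dtype=float)
    if p.size < 2 or c.size < 2:
        raise ValueError("need at least 2 subjects per group")
    t, df, p_one = two_sample_t_from_stats(p.mean(), p.std(ddof=1), p.size,
                                           c.mean(), c.std(ddof=1), c.size)
    return {"mean_patient": float(p.mean()), "mean_control": float(c.mean()),
            "sd_patient": float(p.std(ddof=1)), "sd_control": float(c.std(ddof=1)),
            "difference": float(p.mean() - c.mean()),
            "t": t, "df": df, "p_one_sided": p_one}


def classify_regions(diff_map: np.ndarray, square_mask: np.ndarray,
                     require_1sd: bool = False, sd_diff: float = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Thinned / thickened masks over the analysis square.

    Zero differences belong to neither mask (strict inequalities).  With
    ``require_1sd`` the masks additionally require |diff| > sd_diff, where
    ``sd_diff`` defaults to the SD of the difference distribution over the
    square's valid pixels.

    Returns (thinned, thickened, sd_diff).
    """
    d = np.asarray(diff_map, dtype=float)
    if sd_diff is None:
        sd_diff = float(d[square_mask].std(ddof=0))
    thinned = square_mask & (d < 0)
    thickened = square_mask & (d > 0)
    if require_1sd:
        big = np.abs(d) > sd_diff
        thinned &= big
        thickened &= big
    return thinned, thickened, sd_diff


def area_indices(thinned: np.ndarray, thickened: np.ndarray,
                 square_mask: np.ndarray) -> tuple[float, float]:
    """Percent of the square's valid pixels that are thinned / thickened."""
    n = square_mask.sum()
    if n == 0:
        raise ValueError("empty analysis square")
    return (100.0 * thinned.sum() / n, 100.0 * thickened.sum() / n)


def volume_indices(diff_map: np.ndarray, thinned: np.ndarray,
                   thickened: np.ndarray, mean_patient_map: np.ndarray,
                   square_mask: np.ndarray) -> tuple[float, float]:
    """Volume lost in thinned / gained in thickened regions as a ratio of
    the layer's patient-group mean volume over the square.

    Pixel area cancels between numerator and denominator, so the maps may
    be summed directly.
    """
    denom = float(mean_patient_map[square_mask].sum())
    if denom <= 0:
        raise ValueError("non-positive patient mean volume")
    v = float(-diff_map[thinned].sum()) / denom
    V = float(diff_map[thickened].sum()) / denom
    return v, V


def layer_change_indices(layer_id: str, mean_patient_map: np.ndarray,
                         mean_control_map: np.ndarray,
                         square_mask: np.ndarray) -> LayerChangeIndices:
    """All eight indices of one layer from its group mean maps."""
    diff = mean_patient_map - mean_control_map
    thin0, thick0, sd = classify_regions(diff, square_mask)
    thin1, thick1, _ = classify_regions(diff, square_mask, require_1sd=True,
                                        sd_diff=sd)
    t0, T0 = area_indices(thin0, thick0, square_mask)
    t1, T1 = area_indices(thin1, thick1, square_mask)
    v0, V0 = volume_indices(diff, thin0, thick0, mean_patient_map, square_mask)
    v1, V1 = volume_indices(diff, thin1, thick1, mean_patient_map, square_mask)
    return LayerChangeIndices(layer_id, t0, T0, t1, T1, v0, V0, v1, V1, sd)


def indices_table(indices: dict) -> "pandas.DataFrame":  # noqa: F821
    """One row per layer with the eight indices and sd_diff, ready for CSV
    export."""
    import pandas as pd
    rows = []
    for lid, idx in indices.items():
        rows.append({"layer": lid, "t0": idx.t0, "T0": idx.T0,
                     "t1": idx.t1, "T1": idx.T1, "v0": idx.v0, "V0": idx.V0,
                     "v1": idx.v1, "V1": idx.V1, "sd_diff_um": idx.sd_diff_um})
    return pd.DataFrame(rows).set_index("layer")


def cross_layer_area_test(differences) -> dict:
    """One-sample t of the nine neural layers' t-T (area) differences
    against zero."""
    d = np.asarray(differences, dtype=float)
    if d.size != len(NEURAL_LAYERS):
        raise ValueError(f"expected {len(NEURAL_LAYERS)} neural-layer differences")
    t, df, p = one_sample_t_from_stats(d.mean(), d.std(ddof=1), d.size)
    return {"mean": float(d.mean()), "sd": float(d.std(ddof=1)),
            "t": t, "df": df, "p_two_sided": p}


def cross_layer_volume_test(differences) -> dict:
    """Exact Wilcoxon signed-rank test of the nine neural layers' v-V
    (volume) differences; T is the smaller signed-rank sum."""
    d = np.asarray(differences, dtype=float)
    if d.size != len(NEURAL_LAYERS):
        raise ValueError(f"expected {len(NEURAL_LAYERS)} neural-layer differences")
    if np.all(d == 0):
        return {"mean": 0.0, "sd": 0.0, "T": 0.0, "p_exact": 1.0,
                "degenerate": True}
    res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    return {"mean": float(d.mean()), "sd": float(d.std(ddof=1)),
            "T": float(res.statistic), "p_exact": float(res.pvalue),
            "degenerate": False}
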