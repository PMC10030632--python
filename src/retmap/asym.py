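"""Polar-angle asymmetry indices and group statistics.

The cortical horizontal-vertical anisotropy (HVA) and vertical-meridian
asymmetry (VMA) are mean-normalized percent differences of wedge-ROI
surface areas:

    HVA = (horizontal - vertical) / mean(horizontal, vertical) * 100
    VMA = (lower - upper) / mean(lower, upper) * 100

Both are bounded in (-200, 200) for positive areas; a negative VMA means
more surface area for the upper than the lower vertical meridian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "hva_index",
    "vma_index",
    "bootstrap_linear_fit",
    "group_ttest",
    "TTestResult",
]


def _mean_norm_index(a: float, b: float) -> float:
    if a <= 0 or b <= 0:
        raise ValueError("surface areas must be positive")
    return (a - b) / ((a + b) / 2.0) * 100.0


def hva_index(horizontal: float, vertical: float) -> float:
    """(H - V) / mean(H, V) * 100."""
    return _mean_norm_index(horizontal, vertical)


def vma_index(lower: float, upper: float) -> float:
    """(lower - upper) / mean * 100; negative when upper exceeds lower."""
    return _mean_norm_index(lower, upper)


def bootstrap_linear_fit(
    widths: np.ndarray,
    areas: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Bootstrapped linear fits of group-mean area vs wedge width.

    ``areas`` is (n_subjects, n_widths). Subjects are resampled with
    replacement; for each resample a least-squares line is fit to the mean
    area at each width. Returns the pointwise mean fit and the 16-84
    percentile band (a 68% bootstrap CI), plus the bootstrapped mean area
    per width.
    """
    w = np.asarray(widths, dtype=float)
    a = np.atleast_2d(np.asarray(areas, dtype=float))
    if w.size < 2 or a.shape[0] < 3:
        raise ValueError("need >= 2 widths and >= 3 subjects")
    rng = np.random.default_rng(seed)
    design = np.column_stack([w, np.ones_like(w)])
    idx = rng.integers(0, a.shape[0], size=(n_boot, a.shape[0]))
    means = a[idx].mean(axis=1)  # (n_boot, n_widths)
    coef, *_ = np.linalg.lstsq(design, means.T, rcond=None)  # (2, n_boot)
    fits = design @ coef  # (n_widths, n_boot)
    return {
        "widths": w,
        "mean_fit": fits.mean(axis=1),
        "ci68": np.percentile(fits, [16, 84], axis=1),
        "mean_area": means.mean(axis=0),
        "slopes": coef[0],
    }


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    ci95: tuple[float, float]


def group_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-tailed independent-samples t-test (pooled variance) with
    Cohen's d and the CI95 of the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size + b.size < 4:
        raise ValueError("need at least 4 observations in total")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    tcrit = stats.t.ppf(0.975, df)
    diff = a.mean() - b.mean()
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        cohen_d=float(d),
        ci95=(float(diff - tcrit * se), float(diff + tcrit * se)),
    )
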