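"""Population receptive field (pRF) forward model and coarse-to-fine fitting.

A vertex's pRF is a circular 2D Gaussian in the visual field with center
(x, y) and size sigma (all in degrees). The predicted BOLD response is the
pointwise product of the Gaussian with the stimulus contrast aperture, summed
over the field, convolved with a difference-of-two-gammas hemodynamic
response function (HRF), and scaled/offset to the data by least squares.

Fitting proceeds in four stages:

1. coarse grid search over (x, y, sigma) on temporally decimated data;
2. derivative-free continuous search started from the grid optimum;
3. HRF search with pRF parameters held fixed, minimizing squared error
   averaged across vertices;
4. final pRF search per vertex with the HRF held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .stimulus import ApertureMovie

__all__ = [
    "PRFParams",
    "HRFParams",
    "PRFFit",
    "GridSpec",
    "two_gamma_hrf",
    "compute_overlap",
    "predict_timeseries",
    "variance_explained",
    "fit_prf_coarse_to_fine",
    "fit_prf_many",
]


@dataclass(frozen=True)
class PRFParams:
    x: float
    y: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.x, self.y, self.sigma]).all():
            raise ValueError("pRF parameters must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class HRFParams:
    """Difference-of-two-gammas HRF.

    delay1/delay2: time-to-peak of the response and undershoot gammas (s);
    disp1/disp2: their dispersions (s); ratio: undershoot-to-response
    amplitude ratio. Defaults are the standard double-gamma first-pass HRF.
    """

    delay1: float = 6.0
    delay2: float = 16.0
    disp1: float = 1.0
    disp2: float = 1.0
    ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.disp1 <= 0 or self.disp2 <= 0:
            raise ValueError("dispersions must be positive")
        if self.delay1 <= 0 or self.delay2 <= 0:
            raise ValueError("delays must be positive")
        if self.ratio < 0:
            raise ValueError("ratio must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.delay1, self.delay2, self.disp1, self.disp2, self.ratio]
        )


@dataclass
class PRFFit:
    params: PRFParams
    hrf: HRFParams
    r2: float
    degenerate: bool = False


def two_gamma_hrf(
    params: HRFParams, dt: float, duration: float = 32.0
) -> np.ndarray:
    """Sample the difference-of-gammas kernel at interval ``dt``, normalized
    to unit peak."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, duration + dt / 2, dt)
    pos = gamma_dist.pdf(t, params.delay1 / params.disp1, scale=params.disp1)
    neg = gamma_dist.pdf(t, params.delay2 / params.disp2, scale=params.disp2)
    h = pos - params.ratio * neg
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF (identically zero)")
    return h / peak


def compute_overlap(prf: PRFParams, movie: ApertureMovie) -> np.ndarray:
    """Per-frame overlap integral of the unit-volume pRF Gaussian with the
    aperture, in (fraction of Gaussian mass) units."""
    X, Y = movie.grid
    g = np.exp(
        -((X - prf.x) ** 2 + (Y - prf.y) ** 2) / (2 * prf.sigma**2)
    ) / (2 * np.pi * prf.sigma**2)
    g = g * movie.pixel_scale**2
    flat = movie.frames.reshape(movie.n_frames, -1)
    return flat @ g.ravel()


def apply_hrf(overlap: np.ndarray, hrf: HRFParams, tr: float) -> np.ndarray:
    kernel = two_gamma_hrf(hrf, dt=tr)
    return np.convolve(overlap, kernel)[: len(overlap)]


def predict_timeseries(
    prf: PRFParams, movie: ApertureMovie, hrf: HRFParams | None = None
) -> np.ndarray:
    """Predicted BOLD time series (arbitrary units, one sample per TR).

    The movie must already be at TR resolution (one frame per volume).
    Amplitude and baseline are fit to data separately, so no normalization
    is applied here.
    """
    hrf = hrf or HRFParams()
    return apply_hrf(compute_overlap(prf, movie), hrf, movie.tr)


def percent_signal_change(raw: np.ndarray) -> np.ndarray:
    """Convert a raw series to percent signal change about its mean."""
    m = raw.mean()
    if m == 0:
        raise ValueError("series mean is zero")
    return (raw / m - 1.0) * 100.0


def variance_explained(pred: np.ndarray, data: np.ndarray) -> float:
    """1 - RSS/TSS, TSS about the data mean, clamped to [0, 1]."""
    pred = np.asarray(pred, dtype=float)
    data = np.asarray(data, dtype=float)
    if pred.shape != data.shape:
        raise ValueError("prediction and data must have equal length")
    tss = np.sum((data - data.mean()) ** 2)
    if tss == 0:
        warnings.warn("zero-variance data; R^2 defined as 0", RuntimeWarning)
        return 0.0
    rss = np.sum((data - pred) ** 2)
    return float(np.clip(1.0 - rss / tss, 0.0, 1.0))


def _scaled_rss(pred: np.ndarray, data: np.ndarray) -> tuple[float, float, float]:
    """RSS after fitting nonnegative gain and free offset by least squares.

    Returns (rss, gain, offset)."""
    p = pred - pred.mean()
    denom = p @ p
    if denom <= 0:
        resid = data - data.mean()
        return float(resid @ resid), 0.0, float(data.mean())
    gain = float((p @ (data - data.mean())) / denom)
    if gain < 0:
        gain = 0.0
    offset = float(data.mean() - gain * pred.mean())
    resid = data - gain * pred - offset
    return float(resid @ resid), gain, offset


def _decimate2(x: np.ndarray) -> np.ndarray:
    """Decimate by 2 with a boxcar anti-alias (average adjacent pairs)."""
    n = (len(x) // 2) * 2
    return x[:n].reshape(-1, 2).mean(axis=1)


@dataclass(frozen=True)
class GridSpec:
    """Coarse-stage search grid: x, y on a square grid spanning
    +-(extent_factor * field_radius); sigma log-spaced."""

    n_xy: int = 11
    extent_factor: float = 1.25
    sigma_min: float = 0.1
    sigma_max: float = 6.0
    n_sigma: int = 10

    def points(self, field_radius: float) -> np.ndarray:
        lim = self.extent_factor * field_radius
        xs = np.linspace(-lim, lim, self.n_xy)
        sig = np.geomspace(self.sigma_min, self.sigma_max, self.n_sigma)
        return np.array(
            [(x, y, s) for s in sig for y in xs for x in xs]
        )


class _PredictionCache:
    """Grid predictions shared across vertices (overlap stage only; the HRF
    convolution is cheap and re-applied per HRF)."""

    def __init__(self, movie: ApertureMovie, grid: GridSpec):
        self.movie = movie
        self.points = grid.points(movie.field_radius)
        self.overlaps = np.stack(
            [
                compute_overlap(PRFParams(x, y, s), movie)
                for x, y, s in self.points
            ]
        )


def _stage_objective(
    theta: np.ndarray, data: np.ndarray, movie: ApertureMovie, hrf: HRFParams
) -> float:
    x, y, log_sigma = theta
    pred = predict_timeseries(PRFParams(x, y, float(np.exp(log_sigma))), movie, hrf)
    return _scaled_rss(pred, data)[0]


def _refine(
    data: np.ndarray,
    movie: ApertureMovie,
    hrf: HRFParams,
    start: PRFParams,
) -> PRFParams:
    """Bounded derivative-free local search (Powell) from ``start``; never
    returns a point worse than the start on the stage objective."""
    lim = 1.25 * movie.field_radius
    x0 = np.array([start.x, start.y, np.log(start.sigma)])
    res = minimize(
        _stage_objective,
        x0,
        args=(data, movie, hrf),
        method="Powell",
        bounds=[(-lim, lim), (-lim, lim), (np.log(0.05), np.log(12.0))],
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 50},
    )
    best = res.x if res.fun <= _stage_objective(x0, data, movie, hrf) else x0
    return PRFParams(float(best[0]), float(best[1]), float(np.exp(best[2])))


def _grid_stage(
    data: np.ndarray, cache: _PredictionCache, hrf: HRFParams
) -> PRFParams:
    """Stage 1: brute-force grid search on decimated data."""
    kernel = two_gamma_hrf(hrf, dt=cache.movie.tr)
    data_d = _decimate2(data)
    best_rss, best_idx = np.inf, 0
    n = len(data)
    for i, ov in enumerate(cache.overlaps):
        pred = np.convolve(ov, kernel)[:n]
        rss = _scaled_rss(_decimate2(pred), data_d)[0]
        if rss < best_rss:
            best_rss, best_idx = rss, i
    x, y, s = cache.points[best_idx]
    return PRFParams(float(x), float(y), float(s))


def _fit_hrf(
    fits: list[PRFParams],
    data: np.ndarray,
    movie: ApertureMovie,
    start: HRFParams,
) -> HRFParams:
    """Stage 3: search HRF parameters minimizing squared error averaged
    across vertices, pRF parameters fixed. ``data`` is (n_vertices, n_tr)."""
    overlaps = np.stack([compute_overlap(p, movie) for p in fits])
    n = data.shape[1]

    def obj(theta: np.ndarray) -> float:
        try:
            hrf = HRFParams(*theta)
            kernel = two_gamma_hrf(hrf, dt=movie.tr)
        except ValueError:
            return np.inf
        total = 0.0
        for ov, d in zip(overlaps, data):
            pred = np.convolve(ov, kernel)[:n]
            total += _scaled_rss(pred, d)[0]
        return total / len(overlaps)

    x0 = start.as_array()
    res = minimize(
        obj,
        x0,
        method="Powell",
        bounds=[(3.0, 9.0), (10.0, 20.0), (0.5, 2.0), (0.5, 2.0), (0.0, 0.6)],
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 30},
    )
    best = res.x if res.fun <= obj(x0) else x0
    return HRFParams(*[float(v) for v in best])


def fit_prf_many(
    data: np.ndarray,
    movie: ApertureMovie,
    hrf0: HRFParams | None = None,
    grid: GridSpec | None = None,
    fit_hrf: bool = True,
    cache: "_PredictionCache | None" = None,
) -> list[PRFFit]:
    """Coarse-to-fine fit of many vertices sharing one HRF.

    ``data`` is (n_vertices, n_tr) in percent-signal-change (or any linear)
    units. Stages 1-2 run per vertex with the starting HRF; stage 3 fits a
    common HRF across vertices; stage 4 refits each vertex's pRF with the
    fitted HRF held fixed.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != movie.n_frames:
        raise ValueError("data length must match movie volume count")
    hrf0 = hrf0 or HRFParams()
    cache = cache or _PredictionCache(movie, grid or GridSpec())

    results: list[PRFFit] = []
    stage2: list[PRFParams] = []
    degenerate = np.array([np.allclose(d, d[0]) for d in data])
    for d, bad in zip(data, degenerate):
        if bad:
            stage2.append(PRFParams(0.0, 0.0, 1.0))
            continue
        p1 = _grid_stage(d, cache, hrf0)
        stage2.append(_refine(d, movie, hrf0, p1))

    hrf = hrf0
    if fit_hrf and (~degenerate).any():
        ok = [p for p, bad in zip(stage2, degenerate) if not bad]
        hrf = _fit_hrf(ok, data[~degenerate], movie, hrf0)

    for d, p2, bad in zip(data, stage2, degenerate):
        if bad:
            results.append(PRFFit(p2, hrf, r2=0.0, degenerate=True))
            continue
        p4 = _refine(d, movie, hrf, p2) if fit_hrf else p2
        pred = predict_timeseries(p4, movie, hrf)
        rss, gain, offset = _scaled_rss(pred, d)
        r2 = variance_explained(gain * pred + offset, d)
        results.append(PRFFit(p4, hrf, r2=r2))
    return results


def fit_prf_coarse_to_fine(
    data: np.ndarray,
    movie: ApertureMovie,
    hrf0: HRFParams | None = None,
    grid: GridSpec | None = None,
    fit_hrf: bool = True,
) -> PRFFit:
    """Fit a single vertex; see :func:`fit_prf_many`."""
    return fit_prf_many(
        np.atleast_2d(data), movie, hrf0=hrf0, grid=grid, fit_hrf=fit_hrf
    )[0]
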