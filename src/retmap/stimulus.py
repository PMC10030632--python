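"""Sweeping-bar contrast-aperture movies for pRF mapping.

The mapping stimulus is a high-contrast checkerboard revealed through a bar
aperture that sweeps across a circular field. Only the binary aperture matters
for the linear pRF forward model, so frames are 0/1 masks on a square pixel
grid in degrees of visual angle.

Sweep protocol: 8 sweeps, each starting at the edge of the circular field.
The four cardinal sweeps traverse the full diameter; the four diagonal sweeps
traverse half the diameter and are followed by blank (all-zero) frames for the
remaining half. The canonical order is left-to-right, bottom-to-top,
right-to-left, top-to-bottom, then the four diagonals at 45 deg spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ApertureConfig",
    "ApertureMovie",
    "make_bar_aperture",
    "downsample_to_tr",
]

#: unit drift directions of the 8 sweeps, in canonical order (degrees CCW
#: from the positive x axis). Cardinals first, then diagonals.
SWEEP_DIRECTIONS_DEG = (0.0, 90.0, 180.0, 270.0, 45.0, 135.0, 225.0, 315.0)


@dataclass(frozen=True)
class ApertureConfig:
    """Geometry and timing of the bar-aperture movie.

    ``n_volumes=None`` keeps the natural length of the 8-sweep protocol;
    an integer truncates or zero-pads the movie to that many TRs (the scanned
    runs stored 96 volumes).
    """

    field_radius: float = 7.0
    bar_width: float = 3.0
    bar_length: float = 14.0
    n_sweeps: int = 8
    drift_speed: float = 0.30
    frame_rate: float = 2.0
    tr: float = 2.0
    grid_resolution: int = 101
    n_volumes: int | None = 96

    def __post_init__(self) -> None:
        if self.field_radius <= 0:
            raise ValueError("field_radius must be positive")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        if self.bar_width < 0 or self.bar_width >= 2 * self.field_radius:
            raise ValueError("bar_width must lie in [0, field diameter)")
        if self.drift_speed <= 0 or self.frame_rate <= 0 or self.tr <= 0:
            raise ValueError("drift_speed, frame_rate and tr must be positive")
        fpt = self.frame_rate * self.tr
        if abs(fpt - round(fpt)) > 1e-9 or round(fpt) < 1:
            raise ValueError("frame_rate * tr must be a positive integer")

    @property
    def frames_per_tr(self) -> int:
        return int(round(self.frame_rate * self.tr))

    @property
    def frames_per_sweep(self) -> int:
        """Frames needed for one full-diameter traversal, rounded up to a
        whole number of TRs so sweeps stay synchronized to acquisition."""
        n = math.ceil(2 * self.field_radius / self.drift_speed * self.frame_rate)
        fpt = self.frames_per_tr
        return int(math.ceil(n / fpt) * fpt)


@dataclass
class ApertureMovie:
    """Stack of aperture frames with spatial and temporal metadata.

    ``frames`` has shape (n_frames, n, n); values in [0, 1] (binary before
    TR-averaging). Pixel centers span [-R, R] in both axes; ``pixel_scale``
    is degrees per pixel. ``timestamps`` are frame-onset times in seconds.
    """

    frames: np.ndarray
    pixel_scale: float
    timestamps: np.ndarray
    field_radius: float
    tr: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinate grids in degrees."""
        n = self.frames.shape[1]
        c = np.linspace(-self.field_radius, self.field_radius, n)
        return np.meshgrid(c, c)


def _bar_mask(
    x: np.ndarray,
    y: np.ndarray,
    direction_deg: float,
    center_pos: float,
    width: float,
    length: float,
) -> np.ndarray:
    """Binary bar mask: a strip of `width` along the drift direction and
    `length` across it, centered at signed position `center_pos` along the
    drift axis."""
    th = math.radians(direction_deg)
    along = x * math.cos(th) + y * math.sin(th)
    across = -x * math.sin(th) + y * math.cos(th)
    # strict along-axis bound so a zero-width bar is empty even when its
    # position lands exactly on a pixel center
    return (np.abs(along - center_pos) < width / 2) & (np.abs(across) <= length / 2)


def make_bar_aperture(config: ApertureConfig) -> ApertureMovie:
    """Render the 8-sweep bar movie as binary masks windowed to the field.

    Diagonal sweeps stop at the field center and are replaced by blanks for
    the second half of the sweep. The movie is truncated/zero-padded to
    ``config.n_volumes`` TRs when that is set.
    """
    n = config.grid_resolution
    R = config.field_radius
    coords = np.linspace(-R, R, n)
    x, y = np.meshgrid(coords, coords)
    disc = x**2 + y**2 <= R**2

    step = config.drift_speed / config.frame_rate
    fps = config.frames_per_sweep
    half = fps // 2

    frames: list[np.ndarray] = []
    for i, direction in enumerate(SWEEP_DIRECTIONS_DEG[: config.n_sweeps]):
        diagonal = direction % 90 != 0
        for k in range(fps):
            if diagonal and k >= half:
                frames.append(np.zeros((n, n), dtype=np.float32))
                continue
            pos = -R + k * step
            mask = _bar_mask(x, y, direction, pos, config.bar_width, config.bar_length)
            frames.append((mask & disc).astype(np.float32))

    movie = np.stack(frames)
    if config.n_volumes is not None:
        want = config.n_volumes * config.frames_per_tr
        if movie.shape[0] >= want:
            movie = movie[:want]
        else:  # pad with blanks at the end, mirroring sweep-end blanks
            pad = np.zeros((want - movie.shape[0], n, n), dtype=np.float32)
            movie = np.concatenate([movie, pad])

    timestamps = np.arange(movie.shape[0]) / config.frame_rate
    return ApertureMovie(
        frames=movie,
        pixel_scale=2 * R / (n - 1) if n > 1 else 2 * R,
        timestamps=timestamps,
        field_radius=R,
        tr=config.tr,
    )


def downsample_to_tr(movie: ApertureMovie, tr: float | None = None) -> ApertureMovie:
    """Average frames within each TR, yielding one frame per volume.

    Values of the result lie in [0, 1]. ``tr`` defaults to the movie's own
    TR and must be an integer multiple of the frame interval.
    """
    tr = movie.tr if tr is None else tr
    if movie.n_frames < 2:
        frame_dt = tr
    else:
        frame_dt = float(movie.timestamps[1] - movie.timestamps[0])
    k = tr / frame_dt
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("tr must be an integer multiple of the frame interval")
    k = int(round(k))
    n_vol = movie.n_frames // k
    if n_vol * k != movie.n_frames:
        raise ValueError("movie length is not a whole number of TRs")
    shaped = movie.frames[: n_vol * k].reshape(n_vol, k, *movie.frames.shape[1:])
    out = shaped.mean(axis=1)
    return ApertureMovie(
        frames=out,
        pixel_scale=movie.pixel_scale,
        timestamps=movie.timestamps[::k][:n_vol],
        field_radius=movie.field_radius,
        tr=tr,
    )
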