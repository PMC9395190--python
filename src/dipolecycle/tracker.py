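"""Sparse feature tracking of matrix deformation (pyramidal Lucas-Kanade).

Textured patches (fluorescent fibers, speckle) are detected with the
minimum-eigenvalue (Shi-Tomasi) corner criterion, spaced by non-maximal
suppression, and tracked frame-to-frame by iterative Lucas-Kanade on a
Gaussian image pyramid: the coarsest level captures large motion, finer
levels refine it.  Tracks failing a forward-backward consistency check
(> 1 px) are dropped.  Rigid stage drift is estimated from a sparse
feature set and its per-frame median subtracted.

Pixel displacements are converted to physical units at output (um, y-up;
rates in um/min), so all downstream analysis is unit-correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.transform import pyramid_gaussian

from .fields import VectorFieldSeries
from .synthetic import px_to_um

logger = logging.getLogger(__name__)

__all__ = ["TrackerConfig", "TrackingError", "track", "subtract_drift", "track_pair"]


class TrackingError(RuntimeError):
    """Raised when too few features can be detected or tracked."""


@dataclass(frozen=True)
class TrackerConfig:
    """Detection and pyramidal-LK parameters (values in pixels)."""

    n_features: int = 8000
    min_distance: int = 10
    window_size: int = 40
    max_iterations: int = 20
    n_pyramids: int = 2
    fb_threshold: float = 1.0      # forward-backward rejection, px
    convergence: float = 0.01      # LK update norm to stop, px
    # sparse config for rigid-drift estimation
    drift_n_features: int = 40
    drift_min_distance: int = 8
    drift_window_size: int = 20
    drift_n_pyramids: int = 1

    def __post_init__(self) -> None:
        if min(self.n_features, self.min_distance, self.window_size,
               self.max_iterations, self.n_pyramids) <= 0:
            raise ValueError("tracker parameters must be positive")
        if self.window_size <= self.min_distance:
            raise ValueError("window_size must exceed min_distance")

    def drift_config(self) -> "TrackerConfig":
        return replace(
            self,
            n_features=self.drift_n_features,
            min_distance=self.drift_min_distance,
            window_size=self.drift_window_size,
            n_pyramids=self.drift_n_pyramids,
        )


def detect_features(image: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """(N, 2) feature positions (row, col) by min-eigenvalue response."""
    response = corner_shi_tomasi(image.astype(float))
    peaks = corner_peaks(
        response,
        min_distance=config.min_distance,
        threshold_rel=0.005,
        num_peaks=config.n_features,
    )
    if len(peaks) == 0:
        raise TrackingError("no trackable features detected (image lacks texture)")
    return peaks.astype(float)


def _window_offsets(window_size: int) -> np.ndarray:
    half = window_size // 2
    r = np.arange(-half, half + 1, dtype=float)
    orow, ocol = np.meshgrid(r, r, indexing="ij")
    return np.stack([orow.ravel(), ocol.ravel()])  # (2, w*w)


def _sample(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinear sampling at coords (2, ...)."""
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def _lk_level(
    img0: np.ndarray,
    img1: np.ndarray,
    points: np.ndarray,
    guess: np.ndarray,
    config: TrackerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level of iterative LK; returns (displacement, valid)."""
    offs = _window_offsets(config.window_size)  # (2, m)
    grad_r, grad_c = np.gradient(img0.astype(float))
    base = points.T[:, :, None] + offs[:, None, :]  # (2, n, m)
    flat = base.reshape(2, -1)
    i0 = _sample(img0.astype(float), flat).reshape(points.shape[0], -1)
    gr = _sample(grad_r, flat).reshape(points.shape[0], -1)
    gc = _sample(grad_c, flat).reshape(points.shape[0], -1)
    g11 = np.sum(gr * gr, axis=1)
    g12 = np.sum(gr * gc, axis=1)
    g22 = np.sum(gc * gc, axis=1)
    det = g11 * g22 - g12**2
    valid = det > 1e-9 * (g11 + g22 + 1e-30) ** 2
    det_safe = np.where(valid, det, 1.0)

    d = guess.copy()  # (n, 2) in (row, col)
    active = valid.copy()
    for _ in range(config.max_iterations):
        if not np.any(active):
            break
        coords = base + d.T[:, :, None]
        i1 = _sample(img1.astype(float), coords.reshape(2, -1)).reshape(i0.shape)
        err = i0 - i1
        b1 = np.sum(err * gr, axis=1)
        b2 = np.sum(err * gc, axis=1)
        step_r = (g22 * b1 - g12 * b2) / det_safe
        step_c = (g11 * b2 - g12 * b1) / det_safe
        step = np.stack([step_r, step_c], axis=1)
        step[~active] = 0.0
        d = d + step
        active = active & (np.hypot(step[:, 0], step[:, 1]) > config.convergence)
    return d, valid


def track_pair(
    img0: np.ndarray, img1: np.ndarray, config: TrackerConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Track features from img0 to img1.

    Returns (points (N, 2) row/col on img0, displacements (N, 2) px),
    with forward-backward-inconsistent and out-of-bounds tracks removed.
    """
    points = detect_features(img0, config)
    n_levels = config.n_pyramids
    pyr0 = list(pyramid_gaussian(img0.astype(float), max_layer=n_levels - 1, downscale=2,
                                 preserve_range=True, channel_axis=None))
    pyr1 = list(pyramid_gaussian(img1.astype(float), max_layer=n_levels - 1, downscale=2,
                                 preserve_range=True, channel_axis=None))
    d = np.zeros_like(points)
    valid = np.ones(len(points), dtype=bool)
    for level in range(n_levels - 1, -1, -1):
        scale = 2.0**level
        d_level, v = _lk_level(pyr0[level], pyr1[level], points / scale, d / scale, config)
        d = d_level * scale
        valid &= v
    # forward-backward: track the landing points back to img0
    back, vb = _lk_back(pyr0, pyr1, points + d, -d, config)
    fb_err = np.hypot(*(points + d + back - points).T)
    valid &= vb & (fb_err < config.fb_threshold)
    # discard features whose window leaves the image
    half = config.window_size // 2
    landing = points + d
    inb = (
        (landing[:, 0] >= half) & (landing[:, 0] < img0.shape[0] - half)
        & (landing[:, 1] >= half) & (landing[:, 1] < img0.shape[1] - half)
    )
    valid &= inb
    n_req = min(config.n_features, len(points))
    if valid.sum() < max(4, 0.1 * n_req):
        raise TrackingError(
            f"only {int(valid.sum())}/{n_req} features tracked reliably "
            "(weak texture, excessive motion, or decorrelated frames)"
        )
    return points[valid], d[valid]


def _lk_back(pyr0, pyr1, points, guess, config):
    d = guess.copy()
    valid = np.ones(len(points), dtype=bool)
    n_levels = len(pyr0)
    for level in range(n_levels - 1, -1, -1):
        scale = 2.0**level
        d_level, v = _lk_level(pyr1[level], pyr0[level], points / scale, d / scale, config)
        d = d_level * scale
        valid &= v
    return d, valid


def track(
    images: np.ndarray,
    config: TrackerConfig | None = None,
    pixel_size: float = 1.0,
    dt: float = 1.0,
) -> VectorFieldSeries:
    """Displacement-rate field from an image sequence.

    ``images``: (nt, rows, cols), single channel.  Features are detected
    afresh on every frame k and tracked to frame k+1; displacements are
    divided by ``dt`` to give rates and converted from pixels (y-down) to
    physical um (y-up, origin at the image center).
    """
    images = np.asarray(images)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ValueError("need a (nt, rows, cols) stack with at least 2 frames")
    config = config or TrackerConfig()
    shape = images.shape[1:]
    frames = []
    for k in range(images.shape[0] - 1):
        pts, disp = track_pair(images[k], images[k + 1], config)
        pos_um = px_to_um(pts, shape, pixel_size)
        end_um = px_to_um(pts + disp, shape, pixel_size)
        rate = (end_um - pos_um) / dt
        frames.append(dict(x=pos_um[:, 0], y=pos_um[:, 1], u=rate[:, 0], v=rate[:, 1]))
    meta = dict(tracker="pyramidal-lk", n_pyramids=config.n_pyramids,
                window_px=config.window_size)
    return VectorFieldSeries.from_frames(frames, dt=dt, pixel_size=pixel_size, meta=meta)


def subtract_drift(
    field_series: VectorFieldSeries,
    images: np.ndarray,
    config: TrackerConfig | None = None,
) -> VectorFieldSeries:
    """Remove rigid stage drift from a tracked field.

    Drift is estimated per frame pair from a sparse feature set (robust
    median of displacements, the drift sub-config of ``config``) and
    subtracted from every vector of the corresponding frame.
    """
    config = (config or TrackerConfig()).drift_config()
    images = np.asarray(images)
    shape = images.shape[1:]
    px = field_series.pixel_size or 1.0
    data = field_series.data.copy()
    for k in range(images.shape[0] - 1):
        pts, disp = track_pair(images[k], images[k + 1], config)
        med = np.median(disp, axis=0)  # (row, col) px/frame
        drift_um_rate = np.array([med[1] * px, -med[0] * px]) / field_series.dt
        logger.info("drift frame %d: (%.3f, %.3f) um/min", k, *drift_um_rate)
        sel = data["frame"] == k
        data.loc[sel, "u_um_per_min"] -= drift_um_rate[0]
        data.loc[sel, "v_um_per_min"] -= drift_um_rate[1]
    return VectorFieldSeries(
        data=data, dt=field_series.dt, pixel_size=field_series.pixel_size,
        meta={**field_series.meta, "drift_subtracted": True},
    )
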