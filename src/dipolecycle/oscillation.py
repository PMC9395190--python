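"""Divergence kymographs, oscillation periods and front-back phase lags.

The deformation-rate field is interpolated onto a regular grid and its
divergence taken by central finite differences; the divergence is then
projected on the cell axis (averaged across a band perpendicular to it)
to form a kymograph, from which front and back traces are extracted,
autocorrelated and cross-correlated.

Conventions, chosen where the procedure leaves freedom and logged at INFO
level per call:

* correlograms use the biased estimator with coefficient normalization,
  so the autocorrelation at zero lag is exactly 1 and |c| <= 1 everywhere;
* the period is the first strict local maximum at positive lag whose
  amplitude exceeds one standard deviation of the correlogram values at
  positive lags (ties broken toward the smaller lag); traces without such
  a peak yield "no period" rather than an error;
* cross-correlation lag sign: a POSITIVE lag means the front trace leads
  the back trace (back repeats the front `lag` minutes later).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import griddata

from .fields import CellGeometrySeries, VectorFieldSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Kymograph",
    "DivergenceTrace",
    "Correlogram",
    "PeriodEstimate",
    "divergence_field",
    "kymograph",
    "extract_trace",
    "autocorrelate",
    "find_period",
    "cross_correlate",
    "phase_shift",
    "speed_series",
    "SpeedSummary",
]


@dataclass
class Kymograph:
    """Divergence projected on the cell axis: one column per frame."""

    positions: np.ndarray   # (ns,) bin centers along the axis, um
    times: np.ndarray       # (nt,) min
    values: np.ndarray      # (ns, nt), 1/min; NaN where no samples

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.positions) > 0) and np.all(np.diff(self.times) > 0)):
            raise ValueError("kymograph bins must be strictly increasing")


@dataclass
class DivergenceTrace:
    """Spatially averaged divergence over a front or back region."""

    times: np.ndarray       # (nt,) min, uniform
    values: np.ndarray      # (nt,) 1/min, mean-subtracted
    region_center: float    # offset along the axis, um
    region_width: float     # um

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class Correlogram:
    lags: np.ndarray        # min, symmetric around 0
    values: np.ndarray
    normalized: bool = True

    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.lags > 0
        return self.lags[sel], self.values[sel]


@dataclass
class PeriodEstimate:
    period: float | None    # min
    peak_value: float | None
    threshold: float

    @property
    def found(self) -> bool:
        return self.period is not None


def divergence_field(
    field_series: VectorFieldSeries,
    grid_spacing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divergence of the rate field on a regular grid, per frame.

    Scattered vectors are linearly interpolated to the grid; divergence is
    taken by central differences.  Returns (xs, ys, div) with div of shape
    (nt, len(ys), len(xs)), NaN outside the convex hull of the samples.
    """
    pos0, _ = field_series.frame(0)
    if len(pos0) < 4:
        raise ValueError("need at least 4 samples to interpolate a field")
    if np.linalg.matrix_rank(pos0 - pos0.mean(axis=0)) < 2:
        raise ValueError("degenerate sample geometry: samples are collinear")
    xs = np.arange(pos0[:, 0].min(), pos0[:, 0].max() + grid_spacing / 2, grid_spacing)
    ys = np.arange(pos0[:, 1].min(), pos0[:, 1].max() + grid_spacing / 2, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    div = np.empty((field_series.n_frames, len(ys), len(xs)))
    for n, pos, vec in field_series.frames():
        u = griddata(pos, vec[:, 0], (gx, gy), method="cubic")
        v = griddata(pos, vec[:, 1], (gx, gy), method="cubic")
        dudx = np.gradient(u, grid_spacing, axis=1)
        dvdy = np.gradient(v, grid_spacing, axis=0)
        div[n] = dudx + dvdy
    return xs, ys, div


def kymograph(
    div: tuple[np.ndarray, np.ndarray, np.ndarray],
    geometry: CellGeometrySeries,
    dt: float,
    band_halfwidth: float = 5.0,
    bin_width: float = 1.0,
) -> Kymograph:
    """Average the divergence across a band perpendicular to the cell axis.

    For each frame, grid points within ``band_halfwidth`` of the axis line
    through the cell center are binned by their signed coordinate along
    the axis; each kymograph column is the per-bin mean.
    """
    xs, ys, values = div
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    n_frames = values.shape[0]
    half_span = 0.5 * float(
        np.hypot(xs[-1] - xs[0], ys[-1] - ys[0])
    )
    edges = np.arange(-half_span, half_span + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.full((len(centers), n_frames), np.nan)
    for n in range(n_frames):
        g = geometry.row(n)
        center = np.array([g["center_x_um"], g["center_y_um"]])
        axis = np.array([g["axis_x"], g["axis_y"]])
        rel = pts - center
        s = rel @ axis
        perp = rel[:, 0] * axis[1] - rel[:, 1] * axis[0]
        vals = values[n].ravel()
        ok = (np.abs(perp) <= band_halfwidth) & np.isfinite(vals)
        idx = np.digitize(s[ok], edges) - 1
        good = (idx >= 0) & (idx < len(centers))
        sums = np.bincount(idx[good], weights=vals[ok][good], minlength=len(centers))
        counts = np.bincount(idx[good], minlength=len(centers))
        with np.errstate(invalid="ignore"):
            out[:, n] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    times = np.arange(n_frames) * dt
    keep = ~np.all(np.isnan(out), axis=1)
    return Kymograph(positions=centers[keep], times=times, values=out[keep])


def extract_trace(
    kymo: Kymograph,
    region_center: float,
    region_width: float = 3.0,
) -> DivergenceTrace:
    """Average kymograph rows within a region along the axis; mean-subtract.

    ``region_width`` defaults to 3 um, the middle of the 2-5 um range used
    for front/back averaging windows.
    """
    sel = np.abs(kymo.positions - region_center) <= region_width / 2
    if not np.any(sel):
        raise ValueError(
            f"empty region: no kymograph bins within {region_width / 2} um of {region_center}"
        )
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(kymo.values[sel], axis=0)
    vals = np.where(np.isfinite(vals), vals, 0.0)
    vals = vals - vals.mean()
    return DivergenceTrace(
        times=kymo.times, values=vals, region_center=region_center, region_width=region_width
    )


def _corr(x: np.ndarray, y: np.ndarray, dt: float) -> Correlogram:
    """Biased cross-correlation with coefficient normalization."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    full = np.correlate(y, x, mode="full")  # index shift k: sum_t x[t] y[t+k]
    n = len(x)
    lags = np.arange(-(n - 1), n) * dt
    if denom == 0:
        values = np.zeros_like(full, dtype=float)
        values[n - 1] = 1.0  # degenerate constant trace: defined lag-0 value
    else:
        values = full / denom
    return Correlogram(lags=lags, values=values, normalized=True)


def autocorrelate(trace: DivergenceTrace | np.ndarray, dt: float | None = None) -> Correlogram:
    """Normalized autocorrelation; exactly 1 at zero lag."""
    if isinstance(trace, DivergenceTrace):
        values, dt = trace.values, trace.dt
    else:
        values = np.asarray(trace, dtype=float)
        if dt is None:
            raise ValueError("dt required for bare arrays")
    return _corr(values, values, dt)


def find_period(c: Correlogram) -> PeriodEstimate:
    """First strict local maximum at positive lag above the 1-SD threshold.

    "One standard deviation" is read as the larger of (a) the standard
    deviation of the correlogram values at positive lags (self-referential
    and scale-free) and (b) the sampling noise band of the normalized
    autocorrelation estimator, 3/sqrt(N).  Band (b) is what rejects pure
    noise: the small first peaks of a white-noise correlogram sit inside
    it, while a genuine oscillation at reasonable signal-to-noise clears
    it easily.  Returns no-period when no qualifying peak exists (such
    traces are discarded upstream).
    """
    if not c.normalized:
        raise ValueError("find_period requires a normalized correlogram")
    lags, vals = c.positive()
    if len(vals) < 3:
        return PeriodEstimate(period=None, peak_value=None, threshold=np.nan)
    threshold = float(max(np.std(vals), 3.0 / np.sqrt(len(vals) + 1)))
    logger.info("find_period: 1-SD threshold over positive lags = %.4f", threshold)
    for i in range(1, len(vals) - 1):
        if vals[i] > vals[i - 1] and vals[i] >= vals[i + 1] and vals[i] > threshold:
            return PeriodEstimate(
                period=float(lags[i]), peak_value=float(vals[i]), threshold=threshold
            )
    return PeriodEstimate(period=None, peak_value=None, threshold=threshold)


def cross_correlate(
    front: DivergenceTrace | np.ndarray,
    back: DivergenceTrace | np.ndarray,
    dt: float | None = None,
    max_lag: float | None = None,
) -> tuple[float, Correlogram]:
    """Lag of the extremal-magnitude peak of the front/back cross-correlogram.

    Positive lag: the front leads the back.  The extremum may be a
    positive or a negative peak; ``max_lag`` optionally restricts the
    search window (useful when traces are short relative to the period).
    """
    if isinstance(front, DivergenceTrace):
        fvals, dt = front.values, front.dt
    else:
        fvals = np.asarray(front, dtype=float)
    if isinstance(back, DivergenceTrace):
        bvals = back.values
    else:
        bvals = np.asarray(back, dtype=float)
    if dt is None:
        raise ValueError("dt required for bare arrays")
    # _corr(f, b) peaks at the shift k that maps f onto b; when the back
    # repeats the front `L` minutes later that peak sits at k = +L.  For
    # near-periodic traces a positive peak at L and a negative one at
    # L -+ T/2 can tie in magnitude; break such ties (within 5%) toward
    # the positive peak, then toward the smaller |lag|.
    c = _corr(fvals, bvals, dt)
    sel = np.ones_like(c.lags, dtype=bool)
    if max_lag is not None:
        sel = np.abs(c.lags) <= max_lag
    lags_w, vals_w = c.lags[sel], c.values[sel]
    mag = np.abs(vals_w)
    near = mag >= 0.95 * mag.max()
    cand = np.flatnonzero(near)
    positive = cand[vals_w[cand] > 0]
    if len(positive):
        cand = positive
    idx = cand[np.argmin(np.abs(lags_w[cand]))]
    lag = float(lags_w[idx])
    logger.info("cross_correlate: extremal peak %.3f at lag %.2f min", c.values[sel][idx], lag)
    return lag, c


def phase_shift(lag: float, period: float) -> float:
    """psi = 2 pi lag / period, wrapped to (-pi, pi]."""
    if period <= 0:
        raise ValueError("period must be positive")
    psi = 2 * np.pi * lag / period
    wrapped = np.mod(psi + np.pi, 2 * np.pi) - np.pi
    if wrapped == -np.pi:
        wrapped = np.pi
    return float(wrapped)


@dataclass
class SpeedSummary:
    times: np.ndarray            # midpoints of frame intervals, min
    instantaneous: np.ndarray    # um/min, axis-projected
    persistent_speed: float      # |net axis displacement| / duration, um/min
    period: PeriodEstimate       # of the speed oscillation


def speed_series(
    positions: np.ndarray,
    axis: Sequence[float],
    dt: float,
) -> SpeedSummary:
    """Axis-projected instantaneous and persistent speed of a nucleus track.

    ``positions``: (nt, 2) um.  Instantaneous speed is the frame-to-frame
    axis-projected displacement over dt; persistent speed the net
    axis-projected displacement over the whole window divided by its
    duration.  The oscillation period comes from the autocorrelation of
    the projected increments.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise ValueError("need at least two positions")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.hypot(*ax)
    proj = positions @ ax
    inst = np.diff(proj) / dt
    persistent = abs(proj[-1] - proj[0]) / (dt * (len(proj) - 1))
    period = find_period(autocorrelate(inst, dt=dt))
    times = (np.arange(len(inst)) + 0.5) * dt
    return SpeedSummary(
        times=times, instantaneous=inst, persistent_speed=float(persistent), period=period
    )
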