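"""Synthetic matrix-deformation data with the structure the analysis assumes.

Generates the displacement-rate fields, divergence/speed traces and
textured image stacks used to exercise every downstream stage without any
microscopy data: two contraction centers ("pinches") straddling a nucleus
gap, oscillating with a period of minutes, optionally phase-shifted
front-to-back, with additive Gaussian measurement noise.

Each pinch is a Gaussian-enveloped sink

    u(x) = -A(t) * dir(x - c) * exp(-|x - c|^2 / (2 sigma^2))

whose direction blends a radial component with contraction along the
cell axis (acto-myosin pulls along the polarization direction, which is
what gives the field a well-defined dipole axis); the divergence is
available in closed form for oracle tests.  The
surrounding matrix is treated as linearly elastic and memory-free, so
displacement rates are prescribed directly rather than derived from a
force balance.

Coordinates are physical um, y-up, origin at the field center.  Image
pixel coordinates are y-down with origin at the top-left corner; the
conversion helpers :func:`um_to_px` and :func:`px_to_um` own that mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .fields import VectorFieldSeries

__all__ = [
    "DipoleFieldParams",
    "TextureParams",
    "gen_dipole_field",
    "gen_texture_sequence",
    "gen_divergence_trace",
    "gen_speed_trace",
    "pinch_kernel",
    "pinch_divergence",
    "noiseless_rate_field",
    "um_to_px",
    "px_to_um",
]


@dataclass(frozen=True)
class DipoleFieldParams:
    """Two oscillating contraction centers straddling the nucleus.

    Defaults follow the experimentally observed regime: centers ~15 um
    apart (nucleus gap), period 8 min, displacement amplitude 2.5 um over
    a contraction half-cycle, samples every 0.5 min for 48 min.
    """

    center_a: tuple[float, float] = (-7.5, 0.0)   # front pinch, um
    center_b: tuple[float, float] = (7.5, 0.0)    # back pinch, um
    period: float = 8.0                           # T, min
    amplitude: float = 2.5                        # peak-to-peak displacement, um
    phase_shift: float = 0.0                      # psi, rad; B lags A
    kernel_width: float = 5.0                     # sigma, um
    noise_sd: float = 0.0                         # um/min, per component
    anisotropy: float = 0.6                       # 0 = radial pinch, 1 = uniaxial
    dt: float = 0.5                               # frame interval, min
    duration: float = 48.0                        # min
    extent: float = 40.0                          # half-width of sample square, um
    n_samples: int = 900                          # scattered samples per frame
    sampling: Literal["grid", "scattered"] = "scattered"
    waveform: Literal["sine", "square"] = "sine"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("period", "kernel_width", "dt", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -math.pi < self.phase_shift <= math.pi:
            raise ValueError("phase_shift must lie in (-pi, pi]")

    @property
    def separation(self) -> float:
        return float(np.hypot(*(np.subtract(self.center_b, self.center_a))))


@dataclass(frozen=True)
class TextureParams:
    """Fibrous-texture image model standing in for labelled fibronectin."""

    shape: tuple[int, int] = (256, 256)  # rows, cols (px)
    pixel_size: float = 0.32             # um/px
    n_fibers: int = 220
    fiber_length: float = 40.0           # px, mean
    fiber_intensity: float = 0.6         # relative to full scale
    speckle_density: float = 0.02        # impulse fraction for fine texture
    background_noise_sd: float = 0.01    # relative intensity units
    blur_sigma: float = 1.0              # px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def pinch_kernel(
    pos: np.ndarray,
    center: np.ndarray,
    sigma: float,
    axis: np.ndarray | None = None,
    anisotropy: float = 0.0,
) -> np.ndarray:
    """Unit-amplitude inward pinch kernel K(x - c); (N, 2) -> (N, 2).

    ``anisotropy = 0`` gives the radially symmetric sink
    -(Delta/|Delta|) exp(-|Delta|^2 / 2 sigma^2) (divergence in closed
    form, used as the oracle); ``anisotropy = 1`` contracts purely along
    ``axis``, the acto-myosin pulling direction.  Intermediate values
    blend the two, which is what gives the deformation field a dipole
    axis aligned with the cell axis.
    """
    rel = np.asarray(pos, dtype=float) - np.asarray(center, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    r_safe = np.where(r > 0, r, 1.0)
    mag = np.exp(-(r**2) / (2 * sigma**2))
    direction = rel.copy()
    if anisotropy > 0:
        if axis is None:
            raise ValueError("axis required when anisotropy > 0")
        e = np.asarray(axis, dtype=float)
        e = e / np.hypot(*e)
        along = rel @ e
        direction = (1 - anisotropy) * rel + anisotropy * along[:, None] * e[None, :]
    out = -direction / r_safe[:, None] * mag[:, None]
    out[r == 0] = 0.0
    return out


def pinch_divergence(
    pos: np.ndarray,
    center: np.ndarray,
    sigma: float,
    axis: np.ndarray | None = None,
    anisotropy: float = 0.0,
) -> np.ndarray:
    """Closed-form divergence of :func:`pinch_kernel`.

    For the radial part, div = -(1/r - r/sigma^2) e^{-r^2/2 sigma^2}:
    negative near the center (contraction), changing sign at r = sigma.
    The uniaxial part replaces 1/r by 1/r - s^2/r^3 - s^2/(sigma^2 r)
    with s the coordinate along the pinch axis.
    """
    rel = np.asarray(pos, dtype=float) - np.asarray(center, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    r_safe = np.where(r > 0, r, np.finfo(float).tiny)
    env = np.exp(-(r**2) / (2 * sigma**2))
    radial = 1.0 / r_safe - r / sigma**2
    if anisotropy == 0:
        return -radial * env
    if axis is None:
        raise ValueError("axis required when anisotropy > 0")
    e = np.asarray(axis, dtype=float)
    e = e / np.hypot(*e)
    s = rel @ e
    uniax = 1.0 / r_safe - s**2 / r_safe**3 - s**2 / (sigma**2 * r_safe)
    return -((1 - anisotropy) * radial + anisotropy * uniax) * env


def noiseless_rate_field(
    params: DipoleFieldParams, pos: np.ndarray, t: float | np.ndarray
) -> np.ndarray:
    """Ground-truth displacement-rate field of the generator (no noise)."""
    e = np.subtract(params.center_a, params.center_b)
    ka = pinch_kernel(pos, np.asarray(params.center_a), params.kernel_width,
                      axis=e, anisotropy=params.anisotropy)
    kb = pinch_kernel(pos, np.asarray(params.center_b), params.kernel_width,
                      axis=e, anisotropy=params.anisotropy)
    rate_amp = params.amplitude * np.pi / params.period
    ga = rate_amp * _activation(t, params.period, 0.0, params.waveform)
    gb = rate_amp * _activation(t, params.period, params.phase_shift, params.waveform)
    return np.asarray(ga)[..., None, None] * ka + np.asarray(gb)[..., None, None] * kb


def _activation(t: np.ndarray, period: float, phase: float, waveform: str) -> np.ndarray:
    """Zero-mean periodic waveform g(t) with unit amplitude."""
    theta = 2 * np.pi * np.asarray(t, dtype=float) / period - phase
    if waveform == "sine":
        return np.cos(theta)
    if waveform == "square":
        return np.sign(np.cos(theta)) + (np.cos(theta) == 0) * 0.0
    raise ValueError(f"unknown waveform {waveform!r}")


def _sample_positions(params: DipoleFieldParams, rng: np.random.Generator) -> np.ndarray:
    e = params.extent
    if params.sampling == "grid":
        n_side = max(2, int(round(math.sqrt(params.n_samples))))
        ax = np.linspace(-e, e, n_side)
        gx, gy = np.meshgrid(ax, ax)
        return np.column_stack([gx.ravel(), gy.ravel()])
    return rng.uniform(-e, e, size=(params.n_samples, 2))


def gen_dipole_field(params: DipoleFieldParams) -> VectorFieldSeries:
    """Displacement-rate field of two phase-shifted oscillating pinches.

    Rates in um/min: u(n, t) = g_A(t) K(x_n - c_A) + g_B(t) K(x_n - c_B)
    + noise, with g_B lagging g_A by the phase shift.  The rate amplitude
    is set so the integrated displacement over a contraction half-cycle
    equals ``params.amplitude``.  Deterministic for fixed seed; sample
    positions are frozen across frames (tracked material points).
    """
    rng = np.random.default_rng(params.seed)
    pos = _sample_positions(params, rng)
    times = np.arange(0.0, params.duration + params.dt / 2, params.dt)
    # rate amplitude such that the integral of |g| over half a period
    # gives a displacement excursion of `amplitude`
    clean = noiseless_rate_field(params, pos, times)
    frames = []
    for k in range(len(times)):
        vec = clean[k]
        if params.noise_sd > 0:
            vec = vec + rng.normal(0.0, params.noise_sd, size=vec.shape)
        frames.append(dict(x=pos[:, 0], y=pos[:, 1], u=vec[:, 0], v=vec[:, 1]))
    meta = dict(
        generator="gen_dipole_field",
        seed=params.seed,
        period_min=params.period,
        phase_shift_rad=params.phase_shift,
        amplitude_um=params.amplitude,
        kernel_width_um=params.kernel_width,
        noise_sd=params.noise_sd,
    )
    return VectorFieldSeries.from_frames(frames, dt=params.dt, meta=meta)


# ---------------------------------------------------------------------------
# image-space plumbing


def um_to_px(pos_um: np.ndarray, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Physical um (y-up, centered) -> pixel (row, col), y-down, top-left origin."""
    pos_um = np.asarray(pos_um, dtype=float)
    rows = (shape[0] - 1) / 2.0 - pos_um[..., 1] / pixel_size
    cols = (shape[1] - 1) / 2.0 + pos_um[..., 0] / pixel_size
    return np.stack([rows, cols], axis=-1)


def px_to_um(pos_px: np.ndarray, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Pixel (row, col) -> physical um (x, y), inverse of :func:`um_to_px`."""
    pos_px = np.asarray(pos_px, dtype=float)
    x = (pos_px[..., 1] - (shape[1] - 1) / 2.0) * pixel_size
    y = ((shape[0] - 1) / 2.0 - pos_px[..., 0]) * pixel_size
    return np.stack([x, y], axis=-1)


def _fiber_texture(tex: TextureParams) -> np.ndarray:
    rng = np.random.default_rng(tex.seed)
    img = np.zeros(tex.shape, dtype=float)
    n_rows, n_cols = tex.shape
    for _ in range(tex.n_fibers):
        r0 = rng.uniform(0, n_rows)
        c0 = rng.uniform(0, n_cols)
        angle = rng.uniform(0, np.pi)
        length = rng.exponential(tex.fiber_length)
        n_pts = max(2, int(length))
        tline = np.linspace(0, length, n_pts)
        rr = np.clip(np.round(r0 + tline * np.sin(angle)).astype(int), 0, n_rows - 1)
        cc = np.clip(np.round(c0 + tline * np.cos(angle)).astype(int), 0, n_cols - 1)
        img[rr, cc] += tex.fiber_intensity * rng.uniform(0.5, 1.5)
    speckle = rng.random(tex.shape) < tex.speckle_density
    img[speckle] += rng.uniform(0.5, 1.0, size=int(speckle.sum()))
    img = ndimage.gaussian_filter(img, tex.blur_sigma)
    img += rng.normal(0.0, tex.background_noise_sd, size=tex.shape)
    img -= img.min()
    if img.max() > 0:
        img /= img.max()
    return img


def gen_texture_sequence(
    field_series: VectorFieldSeries,
    tex: TextureParams,
) -> tuple[np.ndarray, VectorFieldSeries]:
    """Warp a random fiber texture by the cumulative displacement field.

    Frame 0 is the raw texture; frame k is frame 0 resampled at
    x - U_k(x), where U_k is the cumulative displacement (rate * dt summed
    over frames), interpolated from the scattered samples.  Returns the
    image stack (nt, rows, cols), float in [0, 1], plus the ground-truth
    per-frame displacement field (um/min, at the scattered sample
    positions) for tracker validation.

    Raises if any cumulative displacement exceeds a 10% image margin.
    """
    from scipy.interpolate import griddata

    base = _fiber_texture(tex)
    shape = tex.shape
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = np.stack([rows, cols], axis=-1).reshape(-1, 2)
    grid_um = px_to_um(px, shape, tex.pixel_size)

    pos0, _ = field_series.frame(0)
    n_frames = field_series.n_frames
    cum_u = np.zeros((shape[0] * shape[1],))
    cum_v = np.zeros_like(cum_u)
    stack = np.empty((n_frames, *shape), dtype=float)
    stack[0] = base
    margin = 0.1 * min(shape) * tex.pixel_size
    for k in range(1, n_frames):
        _, vec = field_series.frame(k - 1)
        du = griddata(pos0, vec[:, 0], grid_um, method="linear", fill_value=0.0)
        dv = griddata(pos0, vec[:, 1], grid_um, method="linear", fill_value=0.0)
        cum_u = cum_u + du * field_series.dt
        cum_v = cum_v + dv * field_series.dt
        peak = float(np.max(np.hypot(cum_u, cum_v)))
        if peak > margin:
            raise ValueError(
                f"cumulative displacement {peak:.2f} um exceeds image margin {margin:.2f} um"
            )
        src_um = grid_um - np.column_stack([cum_u, cum_v])
        src_px = um_to_px(src_um, shape, tex.pixel_size)
        stack[k] = ndimage.map_coordinates(
            base, src_px.reshape(shape[0], shape[1], 2).transpose(2, 0, 1), order=1, mode="nearest"
        )
    return stack, field_series


def gen_divergence_trace(
    period: float,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    duration: float = 36.0,
    dt: float = 0.5,
    seed: int = 0,
    waveform: Literal["sine", "square"] = "sine",
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean periodic divergence trace plus white noise: (times, values)."""
    if duration < 2 * period:
        raise ValueError("duration must cover at least two periods")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    values = amplitude * _activation(times, period, 0.0, waveform)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    return times, values


def gen_speed_trace(
    mean_v: float,
    period: float,
    amplitude: float = 0.5,
    noise_sd: float = 0.0,
    duration: float = 60.0,
    dt: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous speed oscillating about a non-zero mean: (times, values)."""
    times, osc = gen_divergence_trace(
        period, amplitude=amplitude, noise_sd=noise_sd, duration=duration, dt=dt, seed=seed
    )
    return times, mean_v + osc
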