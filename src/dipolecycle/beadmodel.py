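"""Minimal bead models of a cell driven by two phase-shifted oscillating force dipoles.

The idealized cell is four collinear beads forming two dipolar units, A
(front pair) and B (back pair), whose lengths oscillate between ``D`` and
``D + d`` with period ``T``; unit B lags unit A by a phase shift ``psi``.
Two transport modes are provided:

* **swimmer** -- beads immersed in a Newtonian fluid at zero Reynolds
  number.  Bead velocities follow from an Oseen-type mobility matrix
  (self mobility ``1/(6 pi eta a)``, pair coupling ``1/(4 pi eta r)``)
  under the force-free swimming condition.  The gait is kinematically
  prescribed, so the cycle-averaged velocity obeys ``V ~ d^2/(L_s T)``
  with a prefactor that vanishes for reciprocal gaits (scallop theorem).

* **crawler** -- beads adhere to the surrounding elastic matrix through
  bonds of stiffness ``kappa`` that detach at a rate increasing with bond
  tension (slip bonds).  The bond stretch ``delta_i`` of each bead relaxes
  at rate ``k_off (1 + |delta_i|/delta_off)``; the velocity scale of
  adhesion kinetics is ``v_adh = delta_off * k_off``.  Beads also interact
  through the elastic matrix itself: the anchor point of bead i rides the
  matrix displacement created by the bond forces of the other beads, with
  an elastic Green's function decaying as 1/distance.  Force balance over
  the whole (inertialess, externally force-free) cell closes the dynamics.

Both modes reduce, at every instant, to a small linear solve for the
unknown cell translation velocity; trajectories are integrated with a
fixed-step RK4 scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BeadModelConfig",
    "Trajectory",
    "gait",
    "gait_rate",
    "simulate",
    "simulate_swimmer",
    "simulate_crawler",
    "velocity_response",
    "speed_trace",
    "model_multipoles",
    "sweep",
]


@dataclass(frozen=True)
class BeadModelConfig:
    """Geometry, gait and mechanics of the two-dipole bead cell.

    Lengths in um, times in min.  The scaling regime asserted by the
    velocity laws requires ``d << a << D << r``.
    """

    mode: Literal["swimmer", "crawler"] = "crawler"
    bead_radius: float = 1.0        # a
    dipole_length: float = 10.0     # D, minimum unit length
    amplitude: float = 0.5          # d, oscillation amplitude
    separation: float = 60.0        # r, distance between unit centers
    period: float = 8.0             # T
    phase_shift: float = math.pi / 2  # psi, unit B lags A
    waveform: Literal["sine", "square"] = "sine"
    ramp_fraction: float = 0.125    # smoothing of the square gait edges
    layout: Literal["auto", "centered", "chain"] = "auto"
    # crawler adhesion (slip-bond linearization): v_adh = delta_off * k_off
    k_off: float = 1.0              # 1/min, zero-force unbinding rate
    delta_off: float = 10.0         # um, bond mechanosensitivity length
    substrate_coupling: float = 2.0  # um, kappa/(4 pi E): elastic matrix coupling strength
    # numerics
    timestep: float | None = None   # default period / 2000
    n_transient_cycles: int = 3
    n_cycles: int = 10

    def __post_init__(self) -> None:
        for name in ("bead_radius", "dipole_length", "separation", "period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.mode not in ("swimmer", "crawler"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not -math.pi < self.phase_shift <= math.pi + 1e-12:
            raise ValueError("phase_shift must lie in (-pi, pi]")

    @property
    def dt(self) -> float:
        return self.period / 2000.0 if self.timestep is None else self.timestep

    @property
    def v_adh(self) -> float:
        return self.delta_off * self.k_off

    def in_scaling_regime(self) -> bool:
        """True when d << a << D << r holds loosely (factors of ~5)."""
        return (
            self.amplitude / self.dipole_length <= 0.1
            and self.bead_radius / self.dipole_length <= 0.2
            and self.separation / self.dipole_length >= 5
        )


@dataclass
class Trajectory:
    """Time series produced by a bead-model run (transients discarded)."""

    times: np.ndarray                 # (nt,), min
    bead_positions: np.ndarray        # (nt, 4), um, order (A-, A+, B-, B+)
    center: np.ndarray                # (nt,), um
    velocity: np.ndarray              # (nt,), um/min, instantaneous center velocity
    mean_velocity: float              # cycle-averaged V, um/min
    config: BeadModelConfig


# ---------------------------------------------------------------------------
# gait


def _waveform(theta: np.ndarray | float, kind: str, ramp: float) -> np.ndarray | float:
    """Periodic activation in [0, 1]; theta in radians."""
    if kind == "sine":
        return 0.5 * (1.0 + np.cos(theta))
    if kind == "square":
        # even trapezoid-like square wave: high plateau around theta = 0,
        # low around pi, linear-in-cos ramps of width ~ramp fraction
        k = 1.0 / (2.0 * math.sin(math.pi * min(ramp, 0.49)))
        return np.clip(0.5 + k * np.cos(theta), 0.0, 1.0)
    raise ValueError(f"unknown waveform {kind!r}")


def _waveform_rate(theta: np.ndarray | float, kind: str, ramp: float) -> np.ndarray | float:
    """d/dtheta of :func:`_waveform`."""
    if kind == "sine":
        return -0.5 * np.sin(theta)
    if kind == "square":
        k = 1.0 / (2.0 * math.sin(math.pi * min(ramp, 0.49)))
        raw = 0.5 + k * np.cos(theta)
        on_ramp = (raw > 0.0) & (raw < 1.0)
        return np.where(on_ramp, -k * np.sin(theta), 0.0)
    raise ValueError(f"unknown waveform {kind!r}")


def gait(t: np.ndarray | float, config: BeadModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Target lengths (L_A(t), L_B(t)) of the two dipolar units, in [D, D+d]."""
    omega = 2 * np.pi / config.period
    la = config.dipole_length + config.amplitude * _waveform(
        omega * np.asarray(t, dtype=float), config.waveform, config.ramp_fraction
    )
    lb = config.dipole_length + config.amplitude * _waveform(
        omega * np.asarray(t, dtype=float) - config.phase_shift,
        config.waveform,
        config.ramp_fraction,
    )
    return la, lb


def gait_rate(t: np.ndarray | float, config: BeadModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dL_A/dt, dL_B/dt) in um/min."""
    omega = 2 * np.pi / config.period
    th = omega * np.asarray(t, dtype=float)
    dla = config.amplitude * omega * _waveform_rate(th, config.waveform, config.ramp_fraction)
    dlb = config.amplitude * omega * _waveform_rate(
        th - config.phase_shift, config.waveform, config.ramp_fraction
    )
    return dla, dlb


def _layout(config: BeadModelConfig) -> str:
    if config.layout != "auto":
        return config.layout
    return "centered" if config.mode == "swimmer" else "chain"


def _bead_offsets(t: float, config: BeadModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Bead positions relative to the cell center, and their rates (gait frame).

    ``centered`` layout: each unit's beads stroke symmetrically about unit
    centers held at -r/2 and +r/2 (the swimmer's internal strokes).
    ``chain`` layout: an adherent cell body of fixed length spans the inner
    beads and the units protrude outward from its ends, the picture of
    protrusion/retraction at the front and back of a crawling cell.  Both
    are mirror-symmetric at every instant when psi = 0.
    """
    la, lb = gait(t, config)
    dla, dlb = gait_rate(t, config)
    r = config.separation
    if _layout(config) == "centered":
        off = np.array([-r / 2 - la / 2, -r / 2 + la / 2, r / 2 - lb / 2, r / 2 + lb / 2])
        doff = np.array([-dla / 2, dla / 2, -dlb / 2, dlb / 2])
        return off, doff
    g = r - config.dipole_length  # body length; unit centers sit ~r apart at rest
    x = np.array([-g / 2 - la, -g / 2, g / 2, g / 2 + lb])
    dx = np.array([-dla, 0.0, 0.0, dlb])
    return x - x.mean(), dx - dx.mean()


# ---------------------------------------------------------------------------
# swimmer


def swimmer_forces(t: float, config: BeadModelConfig) -> tuple[np.ndarray, float]:
    """(bead forces, cell velocity) of the force-free swimmer at time t.

    Exposed for the force-free invariant: the constraint solve imposes
    sum(F) = 0, and the returned forces let callers audit the residual.
    """
    return _swimmer_solve(t, config)


def _swimmer_rhs(t: float, config: BeadModelConfig) -> float:
    return _swimmer_solve(t, config)[1]


def _swimmer_solve(t: float, config: BeadModelConfig) -> tuple[np.ndarray, float]:
    """Instantaneous cell velocity of the force-free swimmer.

    Solves [[M, -1], [1^T, 0]] [F; xdot_c] = [u; 0] where M is the Oseen
    mobility (units absorbed: 6 pi eta = 1) and u the gait-frame bead
    velocities.  The solution is independent of the absolute cell position
    because inter-bead distances depend on the gait alone.
    """
    off, u = _bead_offsets(t, config)
    n = 4
    sep = np.abs(off[:, None] - off[None, :])
    np.fill_diagonal(sep, 1.0)
    m = 1.5 / sep
    np.fill_diagonal(m, 1.0 / config.bead_radius)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = m
    a[:n, n] = -1.0
    a[n, :n] = 1.0
    b = np.zeros(n + 1)
    b[:n] = u
    sol = np.linalg.solve(a, b)
    return sol[:n], float(sol[n])


# ---------------------------------------------------------------------------
# crawler


def _crawler_rhs(t: float, delta: np.ndarray, config: BeadModelConfig) -> tuple[np.ndarray, float]:
    """Bond-stretch rates and cell velocity of the adhesive crawler.

    State: bond stretches delta_i (um).  Substrate force on bead i is
    -kappa*delta_i; total force balance Sum delta_i = 0 is preserved by the
    returned rates.  The anchor of bead i is advected by the elastic matrix
    displacement kappa*G(|x_i-x_j|)*delta_j created by the other beads,
    with kappa*G(r) = substrate_coupling / r (dimensionless).
    """
    off, u = _bead_offsets(t, config)
    n = 4
    diff = off[:, None] - off[None, :]
    rij = np.abs(diff)
    np.fill_diagonal(rij, 1.0)
    drij = diff * (u[:, None] - u[None, :]) / rij
    eps = config.substrate_coupling / rij
    epsdot = -config.substrate_coupling * drij / rij**2
    np.fill_diagonal(eps, 0.0)
    np.fill_diagonal(epsdot, 0.0)
    k = config.k_off * (1.0 + np.abs(delta) / config.delta_off)
    # (I + eps) ddelta - xdot_c = u + epsdot @ delta - k*delta ; Sum ddelta = 0
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = np.eye(n) + eps
    a[:n, n] = -1.0
    a[n, :n] = 1.0
    b = np.zeros(n + 1)
    b[:n] = u + epsdot @ delta - k * delta
    sol = np.linalg.solve(a, b)
    return sol[:n], float(sol[n])


# ---------------------------------------------------------------------------
# integration


def _integrate(config: BeadModelConfig) -> Trajectory:
    dt = config.dt
    steps_per_cycle = max(4, int(round(config.period / dt)))
    dt = config.period / steps_per_cycle
    n_total = (config.n_transient_cycles + config.n_cycles) * steps_per_cycle
    n_keep = config.n_cycles * steps_per_cycle

    alpha = 0.0
    if config.mode == "swimmer":
        state = np.zeros(0)

        def rhs(t: float, s: np.ndarray) -> tuple[np.ndarray, float]:
            return s, _swimmer_rhs(t, config)

    else:
        state = np.zeros(4)

        def rhs(t: float, s: np.ndarray) -> tuple[np.ndarray, float]:
            return _crawler_rhs(t, s, config)

    times = np.empty(n_keep + 1)
    centers = np.empty(n_keep + 1)
    velocities = np.empty(n_keep + 1)
    beads = np.empty((n_keep + 1, 4))

    def record(idx: int, t: float, a0: float, v: float) -> None:
        times[idx] = t
        centers[idx] = a0
        velocities[idx] = v
        off, _ = _bead_offsets(t, config)
        beads[idx] = a0 + off

    t = 0.0
    for step in range(n_total + 1):
        ds1, v1 = rhs(t, state)
        if step >= n_total - n_keep:
            record(step - (n_total - n_keep), t, alpha, v1)
        if step == n_total:
            break
        ds2, v2 = rhs(t + dt / 2, state + dt / 2 * ds1)
        ds3, v3 = rhs(t + dt / 2, state + dt / 2 * ds2)
        ds4, v4 = rhs(t + dt, state + dt * ds3)
        state = state + dt / 6 * (ds1 + 2 * ds2 + 2 * ds3 + ds4)
        alpha += dt / 6 * (v1 + 2 * v2 + 2 * v3 + v4)
        t += dt

    mean_v = (centers[-1] - centers[0]) / (times[-1] - times[0])
    return Trajectory(
        times=times,
        bead_positions=beads,
        center=centers,
        velocity=velocities,
        mean_velocity=float(mean_v),
        config=config,
    )


def simulate(config: BeadModelConfig, check_convergence: bool = False) -> Trajectory:
    """Run the bead model and return its trajectory (transients discarded).

    With ``check_convergence=True`` the per-cycle displacement is compared
    against a run at half the timestep (Richardson check); a relative
    difference above 1% raises, suggesting a smaller timestep.
    """
    traj = _integrate(config)
    if check_convergence:
        fine = _integrate(replace(config, timestep=config.dt / 2))
        disp = traj.mean_velocity * config.period
        disp_fine = fine.mean_velocity * config.period
        scale = max(abs(disp_fine), 1e-12 * config.amplitude)
        if abs(disp - disp_fine) > 0.01 * scale:
            raise RuntimeError(
                "cycle displacement not converged at timestep "
                f"{config.dt:g} min; halve the timestep"
            )
        return fine
    return traj


def simulate_swimmer(config: BeadModelConfig | None = None, **kwargs) -> Trajectory:
    """Force-free low-Reynolds swimmer; V ~ (d^2/L_s T) f_s(psi), f_s(0)=0."""
    config = replace(config or BeadModelConfig(), mode="swimmer", **kwargs)
    return simulate(config)


def simulate_crawler(config: BeadModelConfig | None = None, **kwargs) -> Trajectory:
    """Substrate-adhering crawler; V ~ (d^3/(v_adh L_c T^2)) f_c(psi), f_c(0)=0."""
    config = replace(config or BeadModelConfig(), mode="crawler", **kwargs)
    return simulate(config)


# ---------------------------------------------------------------------------
# derived outputs


def velocity_response(config: BeadModelConfig, psis: Sequence[float]) -> np.ndarray:
    """Cycle-averaged velocity V(psi) over a grid of phase shifts."""
    out = np.empty(len(psis))
    for i, psi in enumerate(psis):
        out[i] = simulate(replace(config, phase_shift=float(psi))).mean_velocity
    return out


def speed_trace(trajectory: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(times, instantaneous center velocity) of a run, um/min."""
    return trajectory.times, trajectory.velocity


def sweep(
    base: BeadModelConfig,
    parameter: str,
    values: Sequence[float],
) -> "pd.DataFrame":
    """Tidy sweep: one row per run with mode, T, d, psi and V."""
    import pandas as pd

    rows = []
    for v in values:
        cfg = replace(base, **{parameter: float(v)})
        traj = simulate(cfg)
        rows.append(
            dict(
                mode=cfg.mode,
                period=cfg.period,
                amplitude=cfg.amplitude,
                phase_shift=cfg.phase_shift,
                mean_velocity=traj.mean_velocity,
            )
        )
    return pd.DataFrame(rows)


def model_multipoles(
    trajectory: Trajectory,
    config: BeadModelConfig | None = None,
    kernel_width: float = 4.0,
    grid_spacing: float = 4.0,
    margin: float = 20.0,
):
    """Matrix displacement-rate field implied by a bead trajectory.

    Each bead drags the surrounding matrix with a Gaussian-enveloped
    kernel of width ``kernel_width`` (um) moving at the bead velocity; the
    superposition is sampled on a regular 2D grid around the cell and
    returned as a :class:`~dipolecycle.fields.VectorFieldSeries` suitable
    for the multipole module.
    """
    from .fields import VectorFieldSeries

    config = config or trajectory.config
    t = trajectory.times
    dt_frame = t[1] - t[0]
    xb = trajectory.bead_positions
    vb = np.gradient(xb, t, axis=0)
    half = config.separation / 2 + config.dipole_length + margin
    xs = np.arange(-half, half + grid_spacing, grid_spacing)
    ys = np.arange(-3 * kernel_width, 3 * kernel_width + grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    frames = []
    for n in range(len(t)):
        u = np.zeros_like(gx)
        for b in range(4):
            r2 = (gx - (xb[n, b] - trajectory.center[n])) ** 2 + gy**2
            u += vb[n, b] * np.exp(-r2 / (2 * kernel_width**2))
        frames.append(
            dict(
                x=gx.ravel(),
                y=gy.ravel(),
                u=u.ravel(),
                v=np.zeros(u.size),
            )
        )
    return VectorFieldSeries.from_frames(frames, dt=float(dt_frame)), trajectory.center
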