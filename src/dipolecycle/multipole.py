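"""Dipole and quadrupole moments of the matrix deformation-rate field.

For samples n at positions x(n) with displacement rates u(n) and a
reference center c, write Delta(n) = x(n) - c.  The moment tensors are

    D_ij = sum_n Delta_i(n) u_j(n)          (um^2/min)
    S_ij = (D_ij + D_ji) / 2                (symmetrized dipole)
    Q_ijk = sum_n Delta_i(n) Delta_j(n) u_k(n)   (um^3/min)

The main dipole D is the eigenvalue of S of largest magnitude (sign
retained: contraction gives D < 0) with its eigenvector as dipole axis;
the main quadrupole Q is the full contraction of the rank-3 tensor along
the cell axis e, Q = Q_ijk e_i e_j e_k, the rank-3 analogue of e.S.e.
Trajectories in the (D, Q) plane close into cycles whose signed shoelace
area measures time-reversal asymmetry: finite area for migrating cells,
vanishing area for non-migrating ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fields import CellGeometrySeries, VectorFieldSeries

logger = logging.getLogger(__name__)

__all__ = [
    "MultipoleFrame",
    "CycleAreaResult",
    "dipole_tensor",
    "quadrupole_tensor",
    "principal_components",
    "dipole_alignment",
    "dq_trajectory",
    "cycle_area",
    "shoelace_area",
]


@dataclass
class MultipoleFrame:
    """Moments of one frame, with the conventions used to compute them."""

    s: np.ndarray             # (2, 2) symmetric dipole tensor, um^2/min
    q_tensor: np.ndarray      # (2, 2, 2) quadrupole tensor, um^3/min
    main_dipole: float        # um^2/min, signed
    main_quadrupole: float    # um^3/min, signed
    dipole_axis: np.ndarray   # (2,) unit vector
    quadrupole_axis: np.ndarray  # (2,) unit vector (the projection axis)
    center: np.ndarray        # (2,) um, reference center used
    cutoff_radius: float | None = None
    degenerate_axis: bool = False


@dataclass
class CycleAreaResult:
    absolute_area: float       # um^5/min^2, mean |signed area| per cycle
    normalized_area: float     # percent of the bounding-rectangle area
    per_cycle_areas: np.ndarray  # signed, um^5/min^2
    bounding_area: float       # um^5/min^2


def dipole_tensor(
    positions: np.ndarray, rates: np.ndarray, center: Sequence[float]
) -> np.ndarray:
    """Symmetrized dipole tensor S = (D + D^T)/2, D_ij = sum Delta_i u_j."""
    positions = np.asarray(positions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if positions.size == 0:
        raise ValueError("empty field frame")
    delta = positions - np.asarray(center, dtype=float)
    d = delta.T @ rates
    return (d + d.T) / 2.0


def quadrupole_tensor(
    positions: np.ndarray, rates: np.ndarray, center: Sequence[float]
) -> np.ndarray:
    """Quadrupole tensor Q_ijk = sum_n Delta_i Delta_j u_k (um^3/min)."""
    positions = np.asarray(positions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if positions.size == 0:
        raise ValueError("empty field frame")
    delta = positions - np.asarray(center, dtype=float)
    return np.einsum("ni,nj,nk->ijk", delta, delta, rates)


def principal_components(
    s: np.ndarray,
    q_tensor: np.ndarray,
    axis: Sequence[float],
    eigen_rule: Literal["magnitude", "signed"] = "magnitude",
) -> tuple[float, float, np.ndarray, np.ndarray, bool]:
    """Main dipole/quadrupole values and axes.

    ``eigen_rule="magnitude"`` (default) picks the eigenvalue of S of
    largest absolute value, keeping its sign; ``"signed"`` picks the
    algebraically largest.  The quadrupole scalar is the full contraction
    of Q along the cell axis.  Returns (D, Q, dipole_axis,
    quadrupole_axis, degenerate) where ``degenerate`` flags an isotropic
    S whose eigenvector direction is arbitrary.
    """
    e = np.asarray(axis, dtype=float)
    e = e / np.hypot(*e)
    evals, evecs = np.linalg.eigh(np.asarray(s, dtype=float))
    if eigen_rule == "magnitude":
        k = int(np.argmax(np.abs(evals)))
    elif eigen_rule == "signed":
        k = int(np.argmax(evals))
    else:
        raise ValueError(f"unknown eigen_rule {eigen_rule!r}")
    main_d = float(evals[k])
    axis_d = evecs[:, k]
    degenerate = bool(np.isclose(evals[0], evals[1], rtol=1e-9, atol=1e-12))
    # orient the dipole axis consistently along the cell axis
    if axis_d @ e < 0:
        axis_d = -axis_d
    main_q = float(np.einsum("ijk,i,j,k->", np.asarray(q_tensor, dtype=float), e, e, e))
    return main_d, main_q, axis_d, e.copy(), degenerate


def dipole_alignment(
    frames: Sequence[MultipoleFrame], motion_direction: Sequence[float]
) -> np.ndarray:
    """Per-frame acute angle (degrees) between dipole axis and motion."""
    m = np.asarray(motion_direction, dtype=float)
    m = m / np.hypot(*m)
    angles = []
    for fr in frames:
        cosang = abs(float(fr.dipole_axis @ m))
        angles.append(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return np.asarray(angles)


def dq_trajectory(
    field_series: VectorFieldSeries,
    geometry: CellGeometrySeries,
    cutoff_radii: Sequence[float] | None = None,
    eigen_rule: Literal["magnitude", "signed"] = "magnitude",
) -> dict[float | None, list[MultipoleFrame]]:
    """One (D, Q) point per frame, per cutoff radius.

    For each cutoff radius only samples with |Delta| <= radius enter the
    sums; ``cutoff_radii=None`` uses all samples (single entry keyed by
    None).  Q_ijk is origin-dependent when S is non-zero, so the per-frame
    cell centroid used as center is recorded in every output frame.
    Frames with a degenerate (isotropic) dipole tensor carry forward the
    previous frame's axis and are flagged.
    """
    radii: list[float | None] = list(cutoff_radii) if cutoff_radii is not None else [None]
    out: dict[float | None, list[MultipoleFrame]] = {r: [] for r in radii}
    prev_axis: dict[float | None, np.ndarray | None] = {r: None for r in radii}
    for n, pos, vec in field_series.frames():
        g = geometry.row(n)
        center = np.array([g["center_x_um"], g["center_y_um"]])
        axis = np.array([g["axis_x"], g["axis_y"]])
        delta = pos - center
        dist = np.hypot(delta[:, 0], delta[:, 1])
        for r in radii:
            sel = slice(None) if r is None else dist <= r
            p, v = pos[sel], vec[sel]
            s = dipole_tensor(p, v, center)
            qt = quadrupole_tensor(p, v, center)
            d_val, q_val, d_ax, q_ax, degen = principal_components(
                s, qt, axis, eigen_rule=eigen_rule
            )
            if degen and prev_axis[r] is not None:
                d_ax = prev_axis[r]
            prev_axis[r] = d_ax
            out[r].append(
                MultipoleFrame(
                    s=s,
                    q_tensor=qt,
                    main_dipole=d_val,
                    main_quadrupole=q_val,
                    dipole_axis=d_ax,
                    quadrupole_axis=q_ax,
                    center=center,
                    cutoff_radius=r,
                    degenerate_axis=degen,
                )
            )
    return out


def trajectory_table(frames: Sequence[MultipoleFrame], dt: float) -> pd.DataFrame:
    """Tidy (time, D, Q) table for a single-radius trajectory."""
    return pd.DataFrame(
        {
            "time_min": np.arange(len(frames)) * dt,
            "dipole_um2_per_min": [f.main_dipole for f in frames],
            "quadrupole_um3_per_min": [f.main_quadrupole for f in frames],
            "cutoff_radius_um": [f.cutoff_radius for f in frames],
        }
    )


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area of the polygon (x, y), closed last-to-first."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def cycle_area(
    d: np.ndarray,
    q: np.ndarray,
    period: float | None,
    dt: float = 1.0,
) -> CycleAreaResult:
    """Cycle areas of a D-Q trajectory.

    The trajectory is segmented into consecutive windows of one period
    (``period`` in the same time units as ``dt``); each window is closed
    last-to-first and its signed shoelace area computed.  The absolute
    area is the mean |signed area| over cycles; the normalized area is
    100 * absolute / (width x height of the axis-aligned bounding
    rectangle of the whole trajectory).  When no period is available the
    whole trajectory is treated as a single closed loop (with a warning).
    """
    d = np.asarray(d, dtype=float)
    q = np.asarray(q, dtype=float)
    if d.shape != q.shape or d.ndim != 1:
        raise ValueError("d and q must be 1-D arrays of equal length")
    if period is None:
        logger.warning("cycle_area: no period available; treating trajectory as one loop")
        n_per = len(d)
    else:
        n_per = int(round(period / dt))
        if n_per < 4:
            raise ValueError("fewer than 4 samples per cycle; reduce dt or check the period")
    n_cycles = max(1, len(d) // n_per)
    areas = []
    for k in range(n_cycles):
        seg = slice(k * n_per, min((k + 1) * n_per, len(d)))
        if seg.stop - seg.start < 4:
            continue
        areas.append(shoelace_area(d[seg], q[seg]))
    if not areas:
        raise ValueError("fewer than 4 points per cycle")
    areas = np.asarray(areas)
    absolute = float(np.mean(np.abs(areas)))
    width = float(d.max() - d.min())
    height = float(q.max() - q.min())
    bounding = width * height
    normalized = 100.0 * absolute / bounding if bounding > 0 else 0.0
    return CycleAreaResult(
        absolute_area=absolute,
        normalized_area=float(np.clip(normalized, 0.0, 100.0)),
        per_cycle_areas=areas,
        bounding_area=bounding,
    )
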