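"""Diffusion from the Einstein relation and solvent-accessible surface area.

The mean-squared displacement is a multiple-time-origin average over
unwrapped coordinates; the diffusion coefficient is the slope of its linear
regime over 2*d (d = dimensionality), with the fit window chosen explicitly
by the caller -- automatic window heuristics are offered but never applied
silently. SASA uses Shrake-Rupley sphere sampling with a deterministic
Fibonacci point set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .trajectory_io import Frame, Selection, Topology, Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "SASAResult",
    "msd",
    "diffusion_from_msd",
    "suggest_msd_window",
    "sasa",
    "sasa_trajectory",
    "fibonacci_sphere",
    "M2S_PER_NM2PS",
]

#: m^2/s per nm^2/ps
M2S_PER_NM2PS = 1e-6


@dataclass
class MSDCurve:
    """Mean-squared displacement vs lag time."""

    lag: np.ndarray          # ps
    values: np.ndarray       # nm^2
    n_origins: np.ndarray    # time origins averaged per lag

    def __post_init__(self) -> None:
        if self.values[0] != 0.0:
            raise ValueError("MSD at zero lag must vanish")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag times must increase")


@dataclass
class DiffusionEstimate:
    """Einstein-relation diffusion coefficient."""

    D: float                 # m^2/s
    D_nm2_ps: float          # same value in nm^2/ps
    window: tuple[float, float]
    slope: float             # nm^2/ps
    slope_stderr: float
    dimensionality: int


@dataclass
class SASAResult:
    """Solvent-accessible surface area, per frame and time-averaged."""

    per_frame: np.ndarray    # nm^2
    mean: float
    std: float
    probe_radius: float      # nm
    n_points: int


def msd(traj: Trajectory, selection: Selection | None = None,
        max_lag: int | None = None) -> MSDCurve:
    """Multiple-time-origin MSD of the selected sites.

    Requires unwrapped coordinates: wrapped frames do not determine true
    displacements. Generate trajectories with unwrapped output (e.g. the
    Brownian generator) or attach ``traj.unwrapped`` before calling.
    """
    if traj.unwrapped is None:
        raise ValueError(
            "trajectory has no unwrapped coordinates; the MSD needs continuous "
            "displacements -- use a generator that retains them or set "
            "traj.unwrapped explicitly")
    pos = traj.unwrapped
    if selection is not None:
        if traj.topology is None:
            raise ValueError("selection given but trajectory has no topology")
        idx = selection.atom_indices(traj.topology)
        if selection.granularity == "molecule-COM":
            mols = traj.topology.molecule_ids[idx]
            masses = traj.topology.masses[idx]
            out = []
            for m in np.unique(mols):
                sub = idx[mols == m]
                w = traj.topology.masses[sub]
                out.append(np.einsum("fas,a->fs", pos[:, sub, :], w) / w.sum())
            pos = np.stack(out, axis=1)
        else:
            pos = pos[:, idx, :]
    n_frames = pos.shape[0]
    n_lags = n_frames if max_lag is None else min(max_lag + 1, n_frames)
    values = np.zeros(n_lags)
    n_origins = np.zeros(n_lags, dtype=int)
    for tau in range(1, n_lags):
        disp = pos[tau:] - pos[:-tau]
        values[tau] = np.mean(np.sum(disp * disp, axis=-1))
        n_origins[tau] = n_frames - tau
    n_origins[0] = n_frames
    lag = traj.times[:n_lags] - traj.times[0]
    return MSDCurve(lag=lag, values=values, n_origins=n_origins)


def diffusion_from_msd(curve: MSDCurve, t0: float, t1: float,
                       d: int = 3) -> DiffusionEstimate:
    """Least-squares slope of the MSD over [t0, t1]; D = slope / (2 d).

    nm^2/ps converts to m^2/s with a factor 1e-6.
    """
    if d not in (1, 2, 3):
        raise ValueError("dimensionality must be 1, 2 or 3")
    mask = (curve.lag >= t0) & (curve.lag <= t1)
    if mask.sum() < 3:
        raise ValueError(
            f"fit window [{t0}, {t1}] ps covers {int(mask.sum())} points; need >= 3")
    fit = stats.linregress(curve.lag[mask], curve.values[mask])
    d_nm2_ps = fit.slope / (2.0 * d)
    return DiffusionEstimate(D=d_nm2_ps * M2S_PER_NM2PS, D_nm2_ps=d_nm2_ps,
                             window=(t0, t1), slope=fit.slope,
                             slope_stderr=fit.stderr, dimensionality=d)


def suggest_msd_window(curve: MSDCurve, slope_rtol: float = 0.05,
                       min_points: int = 5) -> tuple[float, float]:
    """Heuristic linear window: the longest window whose local slopes stay
    within ``slope_rtol`` of the window slope. Advisory only -- callers pick
    the fit window themselves."""
    lag, val = curve.lag[1:], curve.values[1:]
    local = np.diff(val) / np.diff(lag)
    best = None
    n = len(local)
    for i in range(n):
        for j in range(i + min_points, n + 1):
            mean_slope = (val[j - 1] - val[i]) / (lag[j - 1] - lag[i])
            if mean_slope <= 0:
                continue
            if np.all(np.abs(local[i:j - 1] - mean_slope) <= slope_rtol * mean_slope):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    if best is None:
        raise ValueError("no linear window found; fit manually")
    return float(lag[best[0]]), float(lag[best[1] - 1])


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform deterministic point set on the unit sphere."""
    k = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(frame: Frame, topology: Topology, probe_radius: float = 0.14,
         n_points: int = 960, selection: Selection | None = None) -> float:
    """Shrake-Rupley accessible area of the selected atoms in one frame, nm^2.

    Each atom's sphere (vdW radius + probe) is sampled with a Fibonacci point
    set; points inside any other atom's expanded sphere are buried. Neighbors
    are found under minimum-image periodicity. All atoms of the system
    occlude; ``selection`` only restricts whose area is summed.
    """
    radii = topology.vdw_radii
    sel_idx = (selection.atom_indices(topology) if selection is not None
               else np.arange(topology.n_atoms))
    bad = sel_idx[~np.isfinite(radii[sel_idx])]
    if bad.size:
        raise ValueError(f"atom {int(bad[0])} has no van der Waals radius")
    occluders = np.flatnonzero(np.isfinite(radii))
    box = frame.box
    wrapped = box.wrap(frame.coords)
    tree = cKDTree(wrapped[occluders], boxsize=box.lengths)
    unit = fibonacci_sphere(n_points)
    max_r = np.nanmax(radii[occluders])
    total = 0.0
    for a in sel_idx:
        r_a = radii[a] + probe_radius
        reach = r_a + max_r + probe_radius
        neigh = [occluders[k] for k in tree.query_ball_point(wrapped[a], reach)
                 if occluders[k] != a]
        points = wrapped[a] + r_a * unit
        accessible = np.ones(n_points, dtype=bool)
        for b in neigh:
            r_b = radii[b] + probe_radius
            delta = points - wrapped[b]
            delta -= box.lengths * np.round(delta / box.lengths)
            d2 = np.einsum("ij,ij->i", delta, delta)
            # points exactly on a coincident sphere's surface are kept only by
            # the lower-indexed atom, so degenerate overlaps count once
            on_surface = np.abs(d2 - r_b * r_b) <= 1e-12
            buried = (d2 < r_b * r_b - 1e-12) | (on_surface & (b < a))
            accessible &= ~buried
            if not accessible.any():
                break
        total += accessible.mean() * 4.0 * np.pi * r_a * r_a
    return float(total)


def sasa_trajectory(traj: Trajectory, probe_radius: float = 0.14,
                    n_points: int = 960,
                    selection: Selection | None = None) -> SASAResult:
    """Per-frame SASA and its time average over a trajectory."""
    if traj.topology is None:
        raise ValueError("trajectory carries no topology")
    areas = np.array([sasa(frame, traj.topology, probe_radius, n_points, selection)
                      for frame in traj])
    return SASAResult(per_frame=areas, mean=float(areas.mean()),
                      std=float(areas.std(ddof=1)) if len(areas) > 1 else 0.0,
                      probe_radius=probe_radius, n_points=n_points)
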