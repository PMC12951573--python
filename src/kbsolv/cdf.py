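"""Combined distribution functions of an angle against a distance.

A CDF is the joint 2-D histogram of one distance observable and one angle
observable sampled every frame, normalized to unit mass. Its classic use is
spotting characteristic geometries: an intramolecular hydrogen bond shows up
as density inside the rectangle angle in [150, 180] deg, distance <= 250 pm,
and ring-ring configurational preferences as bands in a plane-normal angle
versus centroid distance plot.

Distances are minimum-image and reported in pm (matching the criteria
units); angles in degrees. The default axis order is distance x angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hbond import HBCriteria
from .trajectory_io import Trajectory, minimum_image_displacement

__all__ = ["GeometrySpec", "CDF2D", "combined_distribution", "hb_region_occupancy"]

PM_PER_NM = 1000.0


@dataclass(frozen=True)
class GeometrySpec:
    """One distance and one angle observable, defined by atom indices.

    ``distance`` is a pair of atom indices. The angle is either three atom
    indices (``angle_sites``, interior angle at the middle atom) or two atom
    index rings (``plane_rings``), each of >= 3 atoms, whose best-fit plane
    normals define the angle (used for ring-ring orientation analyses).
    """

    distance: tuple[int, int]
    angle_sites: tuple[int, int, int] | None = None
    plane_rings: tuple[tuple[int, ...], tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if (self.angle_sites is None) == (self.plane_rings is None):
            raise ValueError("give exactly one of angle_sites or plane_rings")
        if self.plane_rings is not None:
            if any(len(ring) < 3 for ring in self.plane_rings):
                raise ValueError("each ring needs at least three atoms")


@dataclass
class CDF2D:
    """Normalized joint occupancy over distance (pm) and angle (deg) bins."""

    dist_edges: np.ndarray
    angle_edges: np.ndarray
    occupancy: np.ndarray  # shape (n_dist_bins, n_angle_bins)
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (len(self.dist_edges) - 1,
                                    len(self.angle_edges) - 1):
            raise ValueError("occupancy shape must match the bin grid")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancies must be non-negative")

    def distance_marginal(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    def angle_marginal(self) -> np.ndarray:
        return self.occupancy.sum(axis=0)


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through >= 3 points (least squares
    via SVD of the centred coordinates)."""
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[-1]


def _observables(traj: Trajectory, spec: GeometrySpec) -> tuple[np.ndarray, np.ndarray]:
    """(distances pm, angles deg), one sample per frame."""
    box = traj.box
    i, j = spec.distance
    n_atoms = traj.n_atoms
    needed = [i, j]
    if spec.angle_sites is not None:
        needed += list(spec.angle_sites)
    else:
        needed += [a for ring in spec.plane_rings for a in ring]
    out_of_range = [a for a in needed if not 0 <= a < n_atoms]
    if out_of_range:
        raise ValueError(f"selector atom index {out_of_range[0]} outside "
                         f"0..{n_atoms - 1}")
    delta = minimum_image_displacement(traj.coords[:, i, :], traj.coords[:, j, :], box)
    dist_pm = np.linalg.norm(delta, axis=1) * PM_PER_NM
    if spec.angle_sites is not None:
        a, b, c = spec.angle_sites
        v1 = minimum_image_displacement(traj.coords[:, a, :], traj.coords[:, b, :], box)
        v2 = minimum_image_displacement(traj.coords[:, c, :], traj.coords[:, b, :], box)
        norm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        if np.any(norm == 0):
            bad = int(np.flatnonzero(norm == 0)[0])
            raise ValueError(f"degenerate angle geometry in frame {bad}")
        cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / norm, -1.0, 1.0)
        angles = np.degrees(np.arccos(cosang))
    else:
        ring1, ring2 = spec.plane_rings
        angles = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            # make each ring whole relative to its first atom before fitting
            planes = []
            for ring in (ring1, ring2):
                ref = traj.coords[f, ring[0]]
                rel = minimum_image_displacement(traj.coords[f, list(ring)], ref, box)
                planes.append(_plane_normal(rel))
            cosang = np.clip(abs(np.dot(planes[0], planes[1])), 0.0, 1.0)
            angles[f] = np.degrees(np.arccos(cosang))
    return dist_pm, angles


def combined_distribution(traj: Trajectory, spec: GeometrySpec,
                          dist_edges: np.ndarray,
                          angle_edges: np.ndarray) -> CDF2D:
    """Histogram the per-frame (distance, angle) samples on the grid and
    normalize to unit mass.

    Samples falling outside the grid are dropped and the matrix renormalized
    over the retained ones, so the occupancy always sums to 1; widen the grid
    if full coverage matters.
    """
    dist_edges = np.asarray(dist_edges, dtype=float)
    angle_edges = np.asarray(angle_edges, dtype=float)
    if np.any(np.diff(dist_edges) <= 0) or np.any(np.diff(angle_edges) <= 0):
        raise ValueError("bin edges must increase strictly")
    dist_pm, angles = _observables(traj, spec)
    hist, _, _ = np.histogram2d(dist_pm, angles, bins=(dist_edges, angle_edges))
    total = hist.sum()
    if total == 0:
        raise ValueError("no samples fall inside the requested grid")
    return CDF2D(dist_edges=dist_edges, angle_edges=angle_edges,
                 occupancy=hist / total, n_samples=int(total))


def _overlap_fraction(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-bin fraction of each bin interval lying inside [lo, hi]."""
    left = np.maximum(edges[:-1], lo)
    right = np.minimum(edges[1:], hi)
    return np.clip(right - left, 0.0, None) / np.diff(edges)


def hb_region_occupancy(cdf: CDF2D, criteria: HBCriteria | None = None) -> float:
    """Total occupancy inside the hydrogen-bond rectangle of the CDF.

    The rectangle is angle in [angle_min, angle_max] and distance from the
    grid origin up to the criteria threshold. Bins partially covered by the
    rectangle contribute in proportion to their area overlap (which assumes
    in-bin uniformity; align bin edges with the criteria to avoid prorating).
    """
    criteria = criteria or HBCriteria()
    d_lo, d_hi = float(cdf.dist_edges[0]), criteria.dist_max_pm
    a_lo, a_hi = criteria.angle_min, criteria.angle_max
    if d_hi > cdf.dist_edges[-1] + 1e-9:
        raise ValueError("distance criterion extends beyond the grid")
    if a_lo < cdf.angle_edges[0] - 1e-9 or a_hi > cdf.angle_edges[-1] + 1e-9:
        raise ValueError("angle window extends beyond the grid")
    w_d = _overlap_fraction(cdf.dist_edges, d_lo, d_hi)
    w_a = _overlap_fraction(cdf.angle_edges, a_lo, a_hi)
    return float(np.einsum("i,ij,j->", w_d, cdf.occupancy, w_a))
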