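"""Geometric hydrogen-bond detection and run-statistics lifetimes.

A donor-heavy/H/acceptor triple is bonded when the interior angle at the
hydrogen (donor-heavy - H - acceptor, 180 deg = linear) falls inside the
criteria window and the hydrogen...acceptor minimum-image distance does not
exceed the threshold. The 250 pm default is physically a H...acceptor
criterion; a donor-heavy...acceptor variant is available through
``distance_mode`` for comparison with tools that use that convention.

Lifetimes are interval statistics on the per-triple bonded time series:
tau_existence is the mean length of maximal bonded runs, tau_formation the
mean length of unbonded runs strictly between two bonded runs, and the
stability statistic is

    %bonded lifetime = 100 * tau_existence / (tau_existence + tau_formation).

A single unbonded frame breaks a run by default; ``gap_tolerance`` forgives
interruptions up to that many frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import Frame, Topology, Trajectory, minimum_image_displacement

__all__ = [
    "HBCriteria",
    "HBondSeries",
    "HBStats",
    "find_hbonds",
    "hbond_series",
    "lifetimes",
    "percent_bonded",
    "hb_stats",
]


@dataclass(frozen=True)
class HBCriteria:
    """Geometric criteria: angle window (degrees) and distance cap (pm)."""

    angle_min: float = 150.0
    angle_max: float = 180.0
    dist_max_pm: float = 250.0
    distance_mode: str = "hydrogen-acceptor"

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_min <= self.angle_max <= 180.0:
            raise ValueError("angle window must satisfy 0 <= min <= max <= 180")
        if self.dist_max_pm <= 0:
            raise ValueError("distance threshold must be positive")
        if self.distance_mode not in ("hydrogen-acceptor", "donor-acceptor"):
            raise ValueError("distance_mode must be 'hydrogen-acceptor' "
                             "or 'donor-acceptor'")

    @property
    def dist_max_nm(self) -> float:
        return self.dist_max_pm / 1000.0


@dataclass
class HBondSeries:
    """Bonded/unbonded flags over frames for one donor-H-acceptor triple."""

    donor: int
    hydrogen: int
    acceptor: int
    bonded: np.ndarray
    frame_spacing: float

    def __post_init__(self) -> None:
        self.bonded = np.asarray(self.bonded, dtype=bool)
        if self.frame_spacing <= 0:
            raise ValueError("frame spacing must be positive")


@dataclass
class HBStats:
    """Aggregated hydrogen-bond statistics for one species pair."""

    pair: tuple[str, str]
    bonds_per_ps: float
    tau_existence: float
    tau_formation: float
    percent_bonded: float
    n_series: int
    flags: list[str] = field(default_factory=list)


def find_hbonds(frame: Frame, topology: Topology, criteria: HBCriteria,
                mode: str = "inter") -> list[tuple[int, int, int]]:
    """All donor-H-acceptor triples in one frame meeting the criteria.

    ``mode`` restricts pairs to different molecules (``"inter"``), the same
    molecule (``"intra"``) or no restriction (``"both"``).
    """
    if mode not in ("inter", "intra", "both"):
        raise ValueError("mode must be 'inter', 'intra' or 'both'")
    donors = topology.donors()
    acceptors = topology.acceptors()
    hydrogens = [(d, h) for d in donors for h in topology.bonded_hydrogens.get(int(d), [])]
    if not len(acceptors) or not hydrogens:
        raise ValueError("topology lacks hydrogen-bond roles "
                         "(donors with bonded hydrogens and acceptors required)")
    box = frame.box
    wrapped = box.wrap(frame.coords)
    acc_tree = cKDTree(wrapped[acceptors], boxsize=box.lengths)
    mol = topology.molecule_ids
    out: list[tuple[int, int, int]] = []
    for d, h in hydrogens:
        probe = d if criteria.distance_mode == "donor-acceptor" else h
        cand = acc_tree.query_ball_point(wrapped[probe], criteria.dist_max_nm)
        for ci in cand:
            a = int(acceptors[ci])
            if a == d:
                continue
            same_mol = mol[a] == mol[d]
            if (mode == "inter" and same_mol) or (mode == "intra" and not same_mol):
                continue
            v_d = minimum_image_displacement(frame.coords[d], frame.coords[h], box)
            v_a = minimum_image_displacement(frame.coords[a], frame.coords[h], box)
            norm = np.linalg.norm(v_d) * np.linalg.norm(v_a)
            if norm == 0:
                continue
            cosang = np.clip(np.dot(v_d, v_a) / norm, -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))
            if criteria.angle_min <= angle <= criteria.angle_max:
                out.append((int(d), int(h), a))
    return sorted(out)


def hbond_series(traj: Trajectory, criteria: HBCriteria | None = None,
                 pair: tuple[str, str] | None = None,
                 mode: str = "inter") -> list[HBondSeries]:
    """Per-triple bonded time series over a trajectory.

    ``pair`` restricts to triples whose donor and acceptor molecules belong
    to the two named species (in either role order). One series is returned
    for every triple bonded in at least one frame.
    """
    if traj.topology is None:
        raise ValueError("trajectory carries no topology")
    criteria = criteria or HBCriteria()
    if traj.n_frames < 2:
        raise ValueError("need at least two frames for a time series")
    spacing = float(np.median(np.diff(traj.times))) if traj.n_frames > 1 else 1.0
    if spacing <= 0:
        spacing = 1.0
    species = traj.topology.species
    flags: dict[tuple[int, int, int], np.ndarray] = {}
    for f, frame in enumerate(traj):
        for d, h, a in find_hbonds(frame, traj.topology, criteria, mode=mode):
            if pair is not None:
                found = tuple(sorted((species[d], species[a])))
                if found != tuple(sorted(pair)):
                    continue
            if (d, h, a) not in flags:
                flags[(d, h, a)] = np.zeros(traj.n_frames, dtype=bool)
            flags[(d, h, a)][f] = True
    return [HBondSeries(d, h, a, bonded, spacing)
            for (d, h, a), bonded in sorted(flags.items())]


def _runs(bonded: np.ndarray) -> tuple[list[int], list[int]]:
    """(bonded run lengths, interior unbonded run lengths)."""
    n = len(bonded)
    on_runs: list[int] = []
    off_runs: list[tuple[int, int]] = []  # (start, length) of unbonded runs
    i = 0
    while i < n:
        j = i
        while j < n and bonded[j] == bonded[i]:
            j += 1
        if bonded[i]:
            on_runs.append(j - i)
        else:
            off_runs.append((i, j - i))
        i = j
    interior = [length for start, length in off_runs
                if start > 0 and start + length < n]
    return on_runs, interior


def apply_gap_tolerance(bonded: np.ndarray, gap_tolerance: int) -> np.ndarray:
    """Fill unbonded interruptions of up to ``gap_tolerance`` frames."""
    if gap_tolerance <= 0:
        return bonded
    filled = bonded.copy()
    n = len(bonded)
    i = 0
    while i < n:
        if not filled[i]:
            j = i
            while j < n and not filled[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= gap_tolerance:
                filled[i:j] = True
            i = j
        else:
            i += 1
    return filled


def lifetimes(series: HBondSeries,
              gap_tolerance: int = 0) -> tuple[float, float, list[str]]:
    """(tau_existence, tau_formation) in ps, with qualitative flags.

    tau_existence is the mean maximal bonded run length; tau_formation the
    mean unbonded run strictly between bonded runs (leading/trailing
    unbonded stretches are censored and excluded). With no bonded run both
    are NaN (flag ``no-bonded-run``); with no interior unbonded run
    tau_formation is 0 (flag ``no-interior-gap``).
    """
    bonded = apply_gap_tolerance(series.bonded, gap_tolerance)
    on_runs, interior = _runs(bonded)
    flags: list[str] = []
    if not on_runs:
        return float("nan"), float("nan"), ["no-bonded-run"]
    tau_e = float(np.mean(on_runs)) * series.frame_spacing
    if interior:
        tau_f = float(np.mean(interior)) * series.frame_spacing
    else:
        tau_f = 0.0
        flags.append("no-interior-gap")
    return tau_e, tau_f, flags


def percent_bonded(tau_existence: float, tau_formation: float) -> float:
    """Stability statistic 100 * tau_e / (tau_e + tau_f), in percent."""
    if tau_existence < 0 or tau_formation < 0:
        raise ValueError("lifetimes must be non-negative")
    total = tau_existence + tau_formation
    if total == 0:
        raise ValueError("percent bonded is undefined when both lifetimes are zero")
    return float(min(100.0, 100.0 * tau_existence / total))


def hb_stats(series_list: list[HBondSeries], pair: tuple[str, str],
             n_frames: int, gap_tolerance: int = 0) -> HBStats:
    """Pool per-triple series into species-pair statistics.

    bonds_per_ps is the total number of bonded triple-frames divided by the
    spanned trajectory time (mean bonds present per frame over the frame
    spacing); lifetimes pool all runs across triples before averaging.
    """
    if not series_list:
        return HBStats(pair=tuple(sorted(pair)), bonds_per_ps=0.0,
                       tau_existence=float("nan"), tau_formation=float("nan"),
                       percent_bonded=float("nan"), n_series=0,
                       flags=["no-bonds"])
    spacing = series_list[0].frame_spacing
    total_bonded = sum(int(s.bonded.sum()) for s in series_list)
    bonds_per_ps = total_bonded / (n_frames * spacing)
    all_on: list[int] = []
    all_interior: list[int] = []
    for s in series_list:
        on, interior = _runs(apply_gap_tolerance(s.bonded, gap_tolerance))
        all_on.extend(on)
        all_interior.extend(interior)
    flags: list[str] = []
    tau_e = float(np.mean(all_on)) * spacing if all_on else float("nan")
    if all_interior:
        tau_f = float(np.mean(all_interior)) * spacing
    else:
        tau_f = 0.0
        flags.append("no-interior-gap")
    pb = percent_bonded(tau_e, tau_f) if np.isfinite(tau_e) else float("nan")
    return HBStats(pair=tuple(sorted(pair)), bonds_per_ps=bonds_per_ps,
                   tau_existence=tau_e, tau_formation=tau_f,
                   percent_bonded=pb, n_series=len(series_list), flags=flags)
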