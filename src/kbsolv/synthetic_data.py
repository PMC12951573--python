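"""Synthetic inputs with known answers.

Every downstream stage of the pipeline is exercised on data generated here:
uniform (ideal-gas) fluids, Metropolis Monte-Carlo Lennard-Jones mixtures
with tunable cross attractions (a controllable stand-in for preferential
solvation), Brownian walkers with a prescribed diffusion coefficient,
exactly-placed donor-H-acceptor geometries, and analytic pair-correlation
curves whose Kirkwood-Buff integrals are known in closed form or by
high-precision quadrature.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .trajectory_io import Box, Frame, Topology, Trajectory

__all__ = [
    "AnalyticRDF",
    "MixtureSpec",
    "monatomic_topology",
    "gen_ideal_gas",
    "gen_lj_mixture_mc",
    "gen_brownian",
    "gen_hb_scene",
    "gen_analytic_rdf",
]

logger = logging.getLogger(__name__)


def monatomic_topology(species_counts: dict[str, int], mass: float = 18.0,
                       vdw_radius: float = 0.15) -> Topology:
    """Topology of single-atom molecules, one species per entry, in order."""
    rows = []
    mol = 0
    for name, count in species_counts.items():
        for _ in range(count):
            rows.append(("X", mass, vdw_radius, mol, name, "none"))
            mol += 1
    df = pd.DataFrame(rows, columns=["element", "mass", "vdw_radius",
                                     "molecule_id", "species_name", "hb_role"])
    return Topology(df)


# ---------------------------------------------------------------------------
# Uniform fluid
# ---------------------------------------------------------------------------

def gen_ideal_gas(N: int, box: Box, n_frames: int, seed: int,
                  species: str = "ideal") -> Trajectory:
    """Independent uniform placements: g(r) = 1 exactly in expectation."""
    if N < 2:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n_frames, N, 3)) * box.lengths
    times = np.arange(n_frames, dtype=float)
    return Trajectory(coords, times, box, monatomic_topology({species: N}))


# ---------------------------------------------------------------------------
# Lennard-Jones mixture (Metropolis Monte Carlo, NVT)
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """A multi-component Lennard-Jones fluid in reduced units.

    ``epsilon`` maps unordered species pairs to well depths in units of the
    reference energy; unlisted pairs take the Lorentz-Berthelot combination
    of per-species values in ``self_epsilon`` (default 1.0). A single size
    parameter ``sigma`` (nm) sets the length scale for all species.
    ``temperature`` is reduced (kT over the reference energy).
    """

    species_counts: dict[str, int]
    box: Box
    sigma: float = 0.34
    temperature: float = 1.5
    epsilon: dict[tuple[str, str], float] = field(default_factory=dict)
    self_epsilon: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(c < 0 for c in self.species_counts.values()):
            raise ValueError("species counts must be non-negative")

    @property
    def n_particles(self) -> int:
        return sum(self.species_counts.values())

    def epsilon_for(self, a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        if key in self.epsilon:
            return self.epsilon[key]
        ea = self.self_epsilon.get(a, 1.0)
        eb = self.self_epsilon.get(b, 1.0)
        return float(np.sqrt(ea * eb))


def _epsilon_matrix(spec: MixtureSpec) -> tuple[np.ndarray, list[str]]:
    labels = []
    for name, count in spec.species_counts.items():
        labels.extend([name] * count)
    uniq = list(dict.fromkeys(labels))
    eps_uniq = np.array([[spec.epsilon_for(a, b) for b in uniq] for a in uniq])
    index = np.array([uniq.index(s) for s in labels])
    return eps_uniq[np.ix_(index, index)], labels


def gen_lj_mixture_mc(spec: MixtureSpec, n_sweeps: int, sample_every: int,
                      seed: int, burn_in_fraction: float = 0.2,
                      max_step: float = 0.22,
                      cutoff: float = 3.0) -> Trajectory:
    """Sample the NVT ensemble of a Lennard-Jones mixture by Metropolis
    single-particle displacements.

    Reduced units internally (sigma = 1); output coordinates are in nm with
    ``spec.sigma`` as the length scale. The first ``burn_in_fraction`` of
    sweeps is discarded; one frame is recorded every ``sample_every`` sweeps
    thereafter. The acceptance rate is logged and attached to the returned
    trajectory as ``mc_acceptance_rate``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_particles
    if n < 2:
        raise ValueError("mixture needs at least two particles")
    box_red = spec.box.lengths / spec.sigma
    if cutoff > box_red.min() / 2:
        cutoff = box_red.min() / 2
    eps, labels = _epsilon_matrix(spec)
    np.fill_diagonal(eps, 0.0)
    beta = 1.0 / spec.temperature
    rc2 = cutoff * cutoff

    pos = _initial_placement(n, box_red, rng)

    def particle_energy(i: int, xi: np.ndarray) -> float:
        delta = pos - xi
        delta -= box_red * np.round(delta / box_red)
        r2 = np.einsum("ij,ij->i", delta, delta)
        r2[i] = np.inf
        mask = r2 < rc2
        inv6 = 1.0 / r2[mask] ** 3
        return float(np.sum(4.0 * eps[i, mask] * (inv6 * inv6 - inv6)))

    burn_in = int(round(burn_in_fraction * n_sweeps))
    frames: list[np.ndarray] = []
    accepted = attempted = 0
    for sweep in range(n_sweeps):
        order = rng.integers(0, n, size=n)
        moves = rng.uniform(-max_step, max_step, size=(n, 3))
        accepts = rng.uniform(size=n)
        for k in range(n):
            i = int(order[k])
            old = pos[i].copy()
            new = np.mod(old + moves[k], box_red)
            e_old = particle_energy(i, old)
            e_new = particle_energy(i, new)
            attempted += 1
            if e_new <= e_old or accepts[k] < np.exp(-beta * (e_new - e_old)):
                pos[i] = new
                accepted += 1
        if sweep >= burn_in and (sweep - burn_in) % sample_every == 0:
            frames.append(pos.copy() * spec.sigma)
    if not frames:
        raise ValueError("no frames sampled; increase n_sweeps or lower burn-in")
    rate = accepted / attempted
    logger.info("MC acceptance rate: %.3f (%d sweeps, %d frames)",
                rate, n_sweeps, len(frames))
    topo = monatomic_topology(spec.species_counts)
    traj = Trajectory(np.stack(frames), np.arange(len(frames), dtype=float),
                      spec.box, topo)
    traj.mc_acceptance_rate = rate
    return traj


def _initial_placement(n: int, box_red: np.ndarray, rng: np.random.Generator,
                       min_sep: float = 0.85,
                       max_tries_per_particle: int = 2000) -> np.ndarray:
    """Sequential random insertion with overlap rejection; bounded retries."""
    pos = np.empty((n, 3))
    min_sep2 = min_sep * min_sep
    for i in range(n):
        for _ in range(max_tries_per_particle):
            trial = rng.uniform(0.0, 1.0, size=3) * box_red
            if i == 0:
                pos[i] = trial
                break
            delta = pos[:i] - trial
            delta -= box_red * np.round(delta / box_red)
            if np.min(np.einsum("ij,ij->i", delta, delta)) >= min_sep2:
                pos[i] = trial
                break
        else:
            raise RuntimeError(
                "could not place particles without overlap; box too dense")
    return pos


# ---------------------------------------------------------------------------
# Brownian walkers
# ---------------------------------------------------------------------------

def gen_brownian(N: int, D_true: float, dt: float, n_steps: int, box: Box,
                 seed: int, species: str = "walker") -> Trajectory:
    """Independent Gaussian walkers with per-step displacement variance
    2 * D_true * dt in each dimension.

    Unwrapped coordinates are retained on the trajectory (``.unwrapped``) so
    the Einstein-relation estimator can be applied directly.
    """
    if D_true < 0:
        raise ValueError("D_true must be non-negative")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, size=(N, 3)) * box.lengths
    steps = rng.normal(0.0, np.sqrt(2.0 * D_true * dt), size=(n_steps, N, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    coords = np.mod(unwrapped, box.lengths)
    times = np.arange(n_steps + 1, dtype=float) * dt
    topo = monatomic_topology({species: N})
    return Trajectory(coords, times, box, topo, unwrapped=unwrapped)


# ---------------------------------------------------------------------------
# Hydrogen-bond scenes
# ---------------------------------------------------------------------------

#: covalent donor-hydrogen bond length used when building scenes, nm
DH_BOND_LENGTH = 0.1


def gen_hb_scene(geometries: list[tuple], dh_bond: float = DH_BOND_LENGTH,
                 spacing: float = 2.0) -> tuple[Frame, Topology]:
    """Build a frame realizing requested donor-H-acceptor geometries exactly.

    Each geometry is ``(angle_deg, ha_distance_pm)`` or
    ``(donor_element, h_element, acceptor_element, angle_deg, ha_distance_pm)``.
    The angle is the interior donor-heavy - H - acceptor angle (180 deg =
    linear); the distance is H...acceptor. Triples are laid out on a grid
    ``spacing`` nm apart so they do not interact; donor+hydrogen form one
    molecule and the acceptor another.
    """
    parsed = []
    for geom in geometries:
        if len(geom) == 2:
            d_el, h_el, a_el = "O", "H", "O"
            angle, dist_pm = geom
        elif len(geom) == 5:
            d_el, h_el, a_el, angle, dist_pm = geom
        else:
            raise ValueError("geometry must be (angle, dist_pm) or "
                             "(D, H, A, angle, dist_pm)")
        if not 0.0 <= angle <= 180.0:
            raise ValueError(f"angle {angle} outside [0, 180] degrees")
        if dist_pm <= 0:
            raise ValueError(f"distance {dist_pm} pm must be positive")
        parsed.append((d_el, h_el, a_el, float(angle), float(dist_pm)))

    n = len(parsed)
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    box = Box(np.full(3, max(per_side, 1) * spacing + spacing))
    coords = np.empty((3 * n, 3))
    rows = []
    bonded: dict[int, list[int]] = {}
    for k, (d_el, h_el, a_el, angle, dist_pm) in enumerate(parsed):
        cell = np.array([k % per_side, (k // per_side) % per_side,
                         k // per_side ** 2], dtype=float)
        origin = spacing * (cell + 0.5)
        theta = np.deg2rad(angle)
        h = origin
        d = origin + np.array([dh_bond, 0.0, 0.0])
        r_ha = dist_pm / 1000.0  # pm -> nm
        # acceptor at angle theta from the H->D direction, in the xy plane
        a = origin + r_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
        base = 3 * k
        coords[base] = d
        coords[base + 1] = h
        coords[base + 2] = a
        rows.append((d_el, 16.0, 0.152, 2 * k, "donor_mol", "donor-heavy"))
        rows.append((h_el, 1.0, 0.11, 2 * k, "donor_mol", "hydrogen"))
        rows.append((a_el, 16.0, 0.152, 2 * k + 1, "acceptor_mol", "acceptor"))
        bonded[base] = [base + 1]
    df = pd.DataFrame(rows, columns=["element", "mass", "vdw_radius",
                                     "molecule_id", "species_name", "hb_role"])
    topo = Topology(df, bonded)
    return Frame(coords, 0.0, box), topo


# ---------------------------------------------------------------------------
# Analytic pair-correlation curves
# ---------------------------------------------------------------------------

@dataclass
class AnalyticRDF:
    """A tabulated analytic g(r) with its exact Kirkwood-Buff integral.

    ``G_infinity`` is the closed-form value of the full spatial integral
    4*pi*r^2*(g-1) dr: zero for the unit form, -4*pi*sigma^3/3 for the hard
    step, and a high-precision quadrature value (computed here, never typed
    in) for the damped oscillation.
    """

    form: str
    params: dict
    r: np.ndarray
    g: np.ndarray
    bin_width: float
    G_infinity: float

    def evaluate(self, r: np.ndarray) -> np.ndarray:
        return _ANALYTIC_FORMS[self.form](np.asarray(r, dtype=float), self.params)


def _g_unit(r: np.ndarray, params: dict) -> np.ndarray:
    return np.ones_like(r)


def _g_hard_step(r: np.ndarray, params: dict) -> np.ndarray:
    return np.where(r < params["sigma"], 0.0, 1.0)


def _g_damped_oscillation(r: np.ndarray, params: dict) -> np.ndarray:
    sigma, A = params["sigma"], params["A"]
    lam, d = params["lam"], params["d"]
    g = 1.0 + A * np.exp(-r / lam) * np.cos(2.0 * np.pi * r / d)
    return np.where(r < sigma, 0.0, np.maximum(g, 0.0))


_ANALYTIC_FORMS = {
    "unit": _g_unit,
    "hard-step": _g_hard_step,
    "damped-oscillation": _g_damped_oscillation,
}


def _damped_G_infinity(params: dict) -> float:
    """Quadrature value of the full KBI for the damped-oscillation form.

    Below sigma the pair correlation vanishes, contributing the exact
    excluded-volume term; the decaying oscillation above sigma is integrated
    adaptively out to 60 decay lengths.
    """
    sigma, A = params["sigma"], params["A"]
    lam, d = params["lam"], params["d"]

    def integrand(r: float) -> float:
        g = 1.0 + A * np.exp(-r / lam) * np.cos(2.0 * np.pi * r / d)
        g = max(g, 0.0)
        return 4.0 * np.pi * r * r * (g - 1.0)

    core = -4.0 * np.pi * sigma**3 / 3.0
    upper = sigma + 60.0 * lam
    tail, _ = quad(integrand, sigma, upper, limit=2000)
    return core + tail


def gen_analytic_rdf(form: str, params: dict | None, r_max: float,
                     bin_width: float) -> AnalyticRDF:
    """Tabulate an analytic RDF on a midpoint bin grid with its exact KBI."""
    if form not in _ANALYTIC_FORMS:
        raise ValueError(f"unknown analytic form {form!r}; "
                         f"choose from {sorted(_ANALYTIC_FORMS)}")
    params = dict(params or {})
    if form == "hard-step" and "sigma" not in params:
        raise ValueError("hard-step form requires sigma")
    if form == "damped-oscillation":
        missing = {"sigma", "A", "lam", "d"} - set(params)
        if missing:
            raise ValueError(f"damped-oscillation form requires {sorted(missing)}")
    n_bins = int(round(r_max / bin_width))
    r = (np.arange(n_bins) + 0.5) * bin_width
    g = _ANALYTIC_FORMS[form](r, params)
    if np.any(g < 0):
        raise ValueError("g(r) must be non-negative")
    if form == "unit":
        G_inf = 0.0
    elif form == "hard-step":
        G_inf = -4.0 * np.pi * params["sigma"] ** 3 / 3.0
    else:
        G_inf = _damped_G_infinity(params)
    return AnalyticRDF(form, params, r, g, bin_width, G_inf)
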