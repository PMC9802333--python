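"""Ground-truth pair laws, trajectory simulation and kinematics.

This is the synthetic-data backbone: closed-form pairwise force/potential
laws (spring, charge, orbital, discontinuous, Lennard-Jones), seeded
initial-condition sampling, velocity-Verlet integration with optional
periodic boundaries and a Langevin thermostat, central-difference
kinematics, and position-noise injection.

Conventions
-----------
``F_ij`` is the force exerted **on** particle ``i`` **by** particle ``j``
along the unit vector ``n_ij = (r_j - r_i)/||r_j - r_i||``.  For the charge
and orbital laws every distance appearing in a denominator or logarithm is
regularised to ``r + delta`` so that the force remains exactly the negative
position-gradient of the potential.  The Lennard-Jones system uses internal
units kcal/mol - Angstrom - Dalton; the consistent time unit is then
~48.888 fs and the Boltzmann constant is 0.0019872041 kcal/mol/K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LAWS",
    "KB_KCAL_MOL_K",
    "SystemSpec",
    "ParticleState",
    "Trajectory",
    "pairwise_force",
    "pairwise_potential",
    "lj_pair",
    "minimum_image",
    "net_forces",
    "sample_initial_state",
    "integrate",
    "finite_difference_kinematics",
    "add_position_noise",
]

LAWS = ("spring", "charge", "orbital", "discnt", "lj")

#: Boltzmann constant in kcal/mol/K (internal LJ unit system).
KB_KCAL_MOL_K = 0.0019872041

_DEFAULT_CONSTANTS = {
    "spring": {"k": 2.0, "L": 1.0},
    "charge": {"c": 1.0, "delta": 0.01},
    "orbital": {"delta": 0.01},
    "discnt": {"theta": 2.0},
    "lj": {
        "epsilon": 0.238,  # kcal/mol
        "sigma": 3.4,  # Angstrom
        "r_cut": 3 * 3.4,
        "box_length": 27.27,
        "temperature": 100.0,  # K
        "mass": 39.9,  # Da (argon)
    },
}


@dataclass(frozen=True)
class SystemSpec:
    """Which pair law governs a system and its constants."""

    law: str
    d: int = 2
    constants: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}; expected one of {LAWS}")
        if self.d not in (2, 3):
            raise ValueError("spatial dimension must be 2 or 3")
        merged = dict(_DEFAULT_CONSTANTS[self.law])
        merged.update(self.constants)
        object.__setattr__(self, "constants", merged)
        for name, value in merged.items():
            if name != "temperature" and value is not None and value <= 0:
                raise ValueError(f"constant {name!r} must be positive, got {value}")
        if self.law == "lj":
            box = merged.get("box_length")
            if box is not None and merged["r_cut"] > box / 2 + 1e-12:
                raise ValueError("r_cut must not exceed half the box length")

    @property
    def periodic(self):
        return self.law == "lj" and self.constants.get("box_length") is not None

    def to_json(self):
        return json.dumps({"law": self.law, "d": self.d, "constants": self.constants})

    @classmethod
    def from_json(cls, text):
        data = json.loads(text)
        return cls(law=data["law"], d=int(data["d"]), constants=data["constants"])


@dataclass
class ParticleState:
    """Positions, velocities and static properties of all particles at one time."""

    positions: np.ndarray  # (n, d)
    velocities: np.ndarray  # (n, d)
    charges: np.ndarray  # (n,)
    masses: np.ndarray  # (n,)
    t: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n, d = self.positions.shape
        if self.velocities.shape != (n, d):
            raise ValueError("velocity shape disagrees with positions")
        if self.charges.shape != (n,) or self.masses.shape != (n,):
            raise ValueError("static property shapes disagree with positions")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")

    @property
    def n(self):
        return self.positions.shape[0]

    @property
    def d(self):
        return self.positions.shape[1]


@dataclass
class Trajectory:
    """A uniform-step particle trajectory with recorded accelerations.

    ``provenance`` records how the accelerations were obtained:
    ``"integrator"`` (exact forces at record time), ``"finite-difference"``
    or ``"noisy"`` (positions corrupted, kinematics re-differenced).
    """

    positions: np.ndarray  # (T, n, d)
    velocities: np.ndarray  # (T, n, d)
    accelerations: np.ndarray  # (T, n, d)
    charges: np.ndarray  # (n,)
    masses: np.ndarray  # (n,)
    dt: float
    provenance: str = "integrator"
    box_length: float | None = None
    spec: SystemSpec | None = None

    def __post_init__(self):
        T, n, d = self.positions.shape
        for arr in (self.velocities, self.accelerations):
            if arr.shape != (T, n, d):
                raise ValueError("trajectory array shapes disagree")
        if self.dt <= 0:
            raise ValueError("step size must be positive")

    @property
    def n_steps(self):
        return self.positions.shape[0]

    @property
    def n(self):
        return self.positions.shape[1]

    @property
    def d(self):
        return self.positions.shape[2]

    def state(self, t):
        return ParticleState(
            self.positions[t], self.velocities[t], self.charges, self.masses, t=t
        )


# ---------------------------------------------------------------------------
# pair laws
# ---------------------------------------------------------------------------


def _pair_geometry(r_i, r_j):
    """Displacement i->j, distance, and unit vector; broadcasts over leading axes."""
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    disp = r_j - r_i
    dist = np.linalg.norm(disp, axis=-1)
    return disp, dist


def pairwise_force(spec, r_i, r_j, q_i=0.0, q_j=0.0, m_i=1.0, m_j=1.0):
    """Closed-form force on particle ``i`` exerted by particle ``j``.

    Accepts single positions or stacked arrays with a trailing dimension
    ``d``; scalar properties broadcast over the leading axes.
    """
    disp, dist = _pair_geometry(r_i, r_j)
    mag = _force_magnitude(spec, dist, q_i, q_j, m_i, m_j)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_ij = disp / dist[..., None]
    n_ij = np.where(dist[..., None] > 0, n_ij, 0.0)
    return np.asarray(mag)[..., None] * n_ij


def _force_magnitude(spec, dist, q_i, q_j, m_i, m_j):
    """Signed magnitude along ``n_ij`` (positive = attraction towards j)."""
    c = spec.constants
    law = spec.law
    dist = np.asarray(dist, dtype=float)
    if law == "spring":
        if np.any(dist == 0):
            raise ZeroDivisionError("coincident particles under the spring law")
        return c["k"] * (dist - c["L"])
    if law == "charge":
        reg = dist + c["delta"]
        return -c["c"] * np.asarray(q_i) * np.asarray(q_j) / reg**2
    if law == "orbital":
        reg = dist + c["delta"]
        return np.asarray(m_i) * np.asarray(m_j) / reg
    if law == "discnt":
        if np.any(dist == 0):
            raise ZeroDivisionError("coincident particles under the discnt law")
        # zero branch strictly below the threshold
        return np.where(dist < c["theta"], 0.0, dist - 1.0)
    raise ValueError(f"law {spec.law!r} has no point-mass closed form (use lj_pair)")


def pairwise_potential(spec, r_i, r_j, q_i=0.0, q_j=0.0, m_i=1.0, m_j=1.0):
    """Scalar pair potential, symmetric in ``i`` and ``j``."""
    _, dist = _pair_geometry(r_i, r_j)
    c = spec.constants
    law = spec.law
    if law == "spring":
        if np.any(dist == 0):
            raise ZeroDivisionError("coincident particles under the spring law")
        return 0.5 * c["k"] * (dist - c["L"]) ** 2
    if law == "charge":
        return c["c"] * np.asarray(q_i) * np.asarray(q_j) / (dist + c["delta"])
    if law == "orbital":
        return np.asarray(m_i) * np.asarray(m_j) * np.log(dist + c["delta"])
    if law == "discnt":
        if np.any(dist == 0):
            raise ZeroDivisionError("coincident particles under the discnt law")
        return np.where(dist < c["theta"], 0.0, 0.5 * (dist - 1.0) ** 2)
    if law == "lj":
        pot, _ = lj_pair(spec, np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float))
        return pot
    raise ValueError(f"unknown law {spec.law!r}")


def lj_pair(spec, disp):
    """Lennard-Jones potential and force for displacement(s) ``disp`` (i -> j).

    ``V(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ]``; both the potential and
    the force are exactly zero beyond the cutoff radius.
    """
    c = spec.constants
    eps, sigma, r_cut = c["epsilon"], c["sigma"], c["r_cut"]
    disp = np.asarray(disp, dtype=float)
    dist = np.linalg.norm(disp, axis=-1)
    if np.any(dist == 0):
        raise ZeroDivisionError("zero-length displacement in lj_pair")
    sr6 = (sigma / dist) ** 6
    sr12 = sr6 * sr6
    inside = dist <= r_cut
    pot = np.where(inside, 4.0 * eps * (sr12 - sr6), 0.0)
    mag = np.where(inside, -(24.0 * eps / dist) * (2.0 * sr12 - sr6), 0.0)
    force = mag[..., None] * (disp / dist[..., None])
    return pot, force


def minimum_image(r_i, r_j, box_length):
    """Componentwise displacement i -> j wrapped into [-box/2, box/2)."""
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    disp = np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float)
    return disp - box_length * np.floor(disp / box_length + 0.5)


# ---------------------------------------------------------------------------
# net forces and integration
# ---------------------------------------------------------------------------


def net_forces(spec, positions, charges, masses):
    """Net pairwise force on every particle (brute-force O(n^2) pair loop)."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if spec.law == "lj":
        box = spec.constants.get("box_length")
        if box is not None:
            disp = minimum_image(positions[:, None, :], positions[None, :, :], box)
        else:
            disp = positions[None, :, :] - positions[:, None, :]
        disp = disp.copy()
        idx = np.arange(n)
        # self-pairs: placeholder displacement, force masked below
        disp[idx, idx, :] = 1.0
        _, forces = lj_pair(spec, disp)
        forces[idx, idx, :] = 0.0
        return forces.sum(axis=1)
    r_i = positions[:, None, :]
    r_j = positions[None, :, :]
    dist = np.linalg.norm(r_j - r_i, axis=-1)
    idx = np.arange(n)
    dist[idx, idx] = np.inf  # mask self-pairs
    q_i = np.asarray(charges)[:, None]
    q_j = np.asarray(charges)[None, :]
    m_i = np.asarray(masses)[:, None]
    m_j = np.asarray(masses)[None, :]
    mag = _force_magnitude(spec, dist, q_i, q_j, m_i, m_j)
    with np.errstate(invalid="ignore"):
        n_ij = (r_j - r_i) / dist[..., None]
    n_ij[idx, idx, :] = 0.0
    mag[idx, idx] = 0.0
    return (mag[..., None] * n_ij).sum(axis=1)


def sample_initial_state(n, spec, seed=0):
    """Seeded initial conditions following the study's sampling scheme.

    Point-mass laws: ``ln m ~ U(-1, 1)``, ``q ~ U(-1, 1)``, positions and
    velocities standard normal per component.  Lennard-Jones: particles are
    placed uniformly in the box with a minimal-separation rejection step and
    velocities drawn from the Maxwell-Boltzmann distribution at the spec
    temperature; all masses equal the atomic mass constant.
    """
    if n < 2:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(seed)
    d = spec.d
    if spec.law == "lj":
        c = spec.constants
        box = c["box_length"]
        min_sep = 0.85 * c["sigma"]
        positions = _place_uniform(rng, n, d, box, min_sep)
        mass = c.get("mass", 39.9)
        masses = np.full(n, mass)
        sigma_v = np.sqrt(KB_KCAL_MOL_K * c["temperature"] / mass)
        velocities = rng.normal(0.0, sigma_v, size=(n, d))
        charges = np.zeros(n)
        return ParticleState(positions, velocities, charges, masses)
    masses = np.exp(rng.uniform(-1.0, 1.0, size=n))
    charges = rng.uniform(-1.0, 1.0, size=n)
    positions = rng.normal(size=(n, d))
    velocities = rng.normal(size=(n, d))
    return ParticleState(positions, velocities, charges, masses)


def _place_uniform(rng, n, d, box, min_sep, max_tries=20000):
    placed = np.empty((n, d))
    count = 0
    tries = 0
    while count < n:
        cand = rng.uniform(0.0, box, size=d)
        if count:
            disp = minimum_image(placed[:count], cand, box)
            if np.min(np.linalg.norm(disp, axis=-1)) < min_sep:
                tries += 1
                if tries > max_tries:
                    raise RuntimeError("could not place particles without overlap")
                continue
        placed[count] = cand
        count += 1
    return placed


def integrate(
    state0,
    spec,
    n_steps,
    dt=0.01,
    seed=0,
    thermostat=None,
    friction=1.0,
    equilibration=0,
):
    """Velocity-Verlet integration under the spec's pairwise law.

    Records per-step accelerations as net force over mass.  For periodic
    systems positions are wrapped into the box.  ``thermostat="langevin"``
    applies a seeded OU velocity update at the spec temperature during the
    first ``equilibration`` steps only; that prefix is discarded and the
    recorded production steps evolve conservatively, so finite-difference
    accelerations of the output are thermostat-free.

    Raises ``FloatingPointError`` if positions become non-finite.
    """
    if dt <= 0:
        raise ValueError("step size must be positive")
    rng = np.random.default_rng(seed)
    n, d = state0.n, state0.d
    box = spec.constants.get("box_length") if spec.periodic else None
    total = n_steps + equilibration
    pos = state0.positions.copy()
    vel = state0.velocities.copy()
    q, m = state0.charges, state0.masses
    inv_m = 1.0 / m[:, None]

    positions = np.empty((total, n, d))
    velocities = np.empty((total, n, d))
    accelerations = np.empty((total, n, d))

    acc = net_forces(spec, pos, q, m) * inv_m
    if thermostat == "langevin":
        c = spec.constants
        kT = KB_KCAL_MOL_K * c["temperature"]
        f_ou = np.exp(-friction * dt)
        sigma_ou = np.sqrt(kT / m)[:, None] * np.sqrt(1.0 - f_ou**2)
    for t in range(total):
        positions[t] = pos
        velocities[t] = vel
        accelerations[t] = acc
        vel_half = vel + 0.5 * dt * acc
        if thermostat == "langevin" and t < equilibration:
            vel_half = f_ou * vel_half + sigma_ou * rng.normal(size=(n, d))
        pos = pos + dt * vel_half
        if box is not None:
            pos = np.mod(pos, box)
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError(
                f"integration blew up at step {t}: non-finite positions"
            )
        acc = net_forces(spec, pos, q, m) * inv_m
        vel = vel_half + 0.5 * dt * acc
    return Trajectory(
        positions[equilibration:],
        velocities[equilibration:],
        accelerations[equilibration:],
        q.copy(),
        m.copy(),
        dt,
        provenance="integrator",
        box_length=box,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# kinematics and noise
# ---------------------------------------------------------------------------


def finite_difference_kinematics(positions, dt, box_length=None):
    """Central-difference velocities and accelerations at interior steps.

    Returns arrays of shape ``(T-2, ...)`` corresponding to time indices
    ``1..T-2``; the two endpoint steps carry no defined central difference
    and are dropped by downstream consumers.

    For periodic trajectories pass ``box_length``: per-step displacements
    are taken under the minimum-image convention, otherwise a boundary
    crossing of wrapped coordinates would difference into an enormous
    spurious acceleration (~box/dt^2).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 3:
        raise ValueError("need at least three time steps for central differences")
    if box_length is None:
        vel = (positions[2:] - positions[:-2]) / (2.0 * dt)
        acc = (positions[2:] - 2.0 * positions[1:-1] + positions[:-2]) / dt**2
        return vel, acc
    step = minimum_image(positions[:-1], positions[1:], box_length)
    vel = (step[1:] + step[:-1]) / (2.0 * dt)
    acc = (step[1:] - step[:-1]) / dt**2
    return vel, acc


def differenced(traj):
    """Trajectory restricted to interior steps with finite-difference kinematics."""
    vel, acc = finite_difference_kinematics(traj.positions, traj.dt, traj.box_length)
    return replace(
        traj,
        positions=traj.positions[1:-1].copy(),
        velocities=vel,
        accelerations=acc,
        provenance="finite-difference",
    )


def add_position_noise(traj, noise_scale, seed=0):
    """Corrupt positions with relative Gaussian noise and re-difference.

    The noise standard deviation is ``noise_scale`` times the per-dimension
    standard deviation of all positions in the trajectory; velocities and
    accelerations are recomputed by central differences of the noisy
    positions, so the returned trajectory has two fewer steps.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    pos_std = traj.positions.std(axis=(0, 1))  # per-dimension spread
    noisy = traj.positions + noise_scale * pos_std * rng.normal(
        size=traj.positions.shape
    )
    if traj.box_length is not None:
        noisy = np.mod(noisy, traj.box_length)
    vel, acc = finite_difference_kinematics(noisy, traj.dt, traj.box_length)
    return replace(
        traj,
        positions=noisy[1:-1],
        velocities=vel,
        accelerations=acc,
        provenance="noisy",
    )


__all__.append("differenced")
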