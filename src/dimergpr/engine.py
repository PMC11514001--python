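"""Simulation engine driven purely by model-predicted energies and forces.

A :class:`DimerPotential` bundles the six trained atomic regressors; its
total energy is the sum of the six atomic predictions and its Cartesian
forces follow from the chain rule through every atom's feature Jacobian,

    F = - sum_a J_a^T  d(mu_a)/d(features_a),

where every atomic model depends on all 18 coordinates.  On top of the
potential the engine provides damped-dynamics geometry optimisation (with
a quasi-Newton alternative), velocity-Verlet NVT dynamics with a single
Nose-Hoover thermostat, and rigid-monomer scans along the O1-O4 axis.

The same interface is satisfied by the analytic surrogate potential, so
integrators can be validated against exact forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .alf import ALFSpec, compute_all_features, feature_jacobians
from .geometry import DimerGeometry, ELEMENTS, N_ATOMS
from .gpr import AtomicGPRModel, predict_energies, predict_energy, predict_gradient
from .oracle import OraclePotentialSpec, oracle_forces, oracle_total_energy
from .units import (
    ATOMIC_MASSES,
    FORCE_OVER_MASS_TO_ACC,
    KB_KJ_MOL_K,
    MASS_VEL2_TO_KJ_MOL,
)

MASSES = np.array([ATOMIC_MASSES[el] for el in ELEMENTS])  # (6,) g/mol
N_DOF = 3 * N_ATOMS - 3  # centre-of-mass motion removed


class Potential(Protocol):
    """Anything that maps a dimer geometry to an energy and forces."""

    def total_energy(self, g: DimerGeometry) -> float: ...

    def forces(self, g: DimerGeometry) -> np.ndarray: ...


@dataclass(frozen=True)
class DimerPotential:
    """Six atomic GPR models assembled into one dimer energy/force surface."""

    atomic_models: tuple[AtomicGPRModel, ...]

    def __post_init__(self) -> None:
        if len(self.atomic_models) != N_ATOMS:
            raise ValueError("a dimer potential needs exactly six atomic models")
        idx = sorted(m.atom_index for m in self.atomic_models)
        if idx != list(range(N_ATOMS)):
            raise ValueError(f"atomic models must cover atoms 0..5 once, got {idx}")
        models = tuple(sorted(self.atomic_models, key=lambda m: m.atom_index))
        object.__setattr__(self, "atomic_models", models)

    @property
    def alfs(self) -> tuple[ALFSpec, ...]:
        return tuple(m.alf for m in self.atomic_models)

    def atomic_energies(self, g: DimerGeometry | np.ndarray) -> np.ndarray:
        feats = compute_all_features(g, self.alfs)  # (..., 6, 12)
        if feats.ndim == 2:
            return np.array([
                predict_energy(m, feats[a]) for a, m in enumerate(self.atomic_models)
            ])
        return np.stack([
            predict_energies(m, feats[:, a, :])
            for a, m in enumerate(self.atomic_models)
        ], axis=-1)

    def total_energy(self, g: DimerGeometry) -> float:
        return float(self.atomic_energies(g).sum())

    def total_energies(self, positions: np.ndarray) -> np.ndarray:
        """Batched total energies for positions of shape (n, 6, 3)."""
        return self.atomic_energies(positions).sum(-1)

    def forces(self, g: DimerGeometry) -> np.ndarray:
        pos = g.positions if isinstance(g, DimerGeometry) else np.asarray(g)
        feats = compute_all_features(pos, self.alfs)
        jacs = feature_jacobians(pos, self.alfs)    # (6, 12, 18)
        grad = np.zeros(3 * N_ATOMS)
        for a, m in enumerate(self.atomic_models):
            grad += jacs[a].T @ predict_gradient(m, feats[a])
        return -grad.reshape(N_ATOMS, 3)

    @property
    def prior_mean_total(self) -> float:
        """Sum of the six prior means: the far-field limit of the model."""
        return float(sum(m.hyperparameters.prior_mean for m in self.atomic_models))


@dataclass(frozen=True)
class OraclePotential:
    """The analytic surrogate wrapped in the engine's potential interface."""

    spec: OraclePotentialSpec = field(default_factory=OraclePotentialSpec)

    def total_energy(self, g: DimerGeometry) -> float:
        return float(oracle_total_energy(g, self.spec))

    def forces(self, g: DimerGeometry) -> np.ndarray:
        return oracle_forces(g, self.spec)


# -- geometry optimisation ----------------------------------------------------

@dataclass(frozen=True)
class OptimizationResult:
    final_geometry: DimerGeometry
    energy_trace: np.ndarray
    n_steps: int
    converged: bool
    final_max_force: float


def optimize_geometry(potential: Potential, start: DimerGeometry,
                      fmax: float = 1.0, dt: float = 0.4,
                      max_steps: int = 10_000,
                      method: str = "damped") -> OptimizationResult:
    """Minimise the predicted energy starting from ``start``.

    method 'damped' (default) runs damped dynamics: velocity-Verlet steps
    whose velocity is projected onto the force direction whenever it still
    points downhill and zeroed otherwise, so the energy trace decreases
    after each damping event.  method 'lbfgs' runs a quasi-Newton search
    on the same energy/force surface.  Convergence: max |force component|
    < ``fmax`` (kJ/mol/A).
    """
    if method == "lbfgs":
        return _optimize_lbfgs(potential, start, fmax, max_steps)
    if method != "damped":
        raise ValueError(f"unknown method {method!r}")

    pos = start.positions.copy()
    vel = np.zeros_like(pos)
    energies: list[float] = []
    last_valid = pos.copy()
    for step in range(max_steps + 1):
        g = DimerGeometry(pos)
        e = potential.total_energy(g)
        f = potential.forces(g)
        if not (np.isfinite(e) and np.all(np.isfinite(f))):
            return OptimizationResult(DimerGeometry(last_valid),
                                      np.array(energies), step, False, np.inf)
        energies.append(e)
        last_valid = pos.copy()
        max_f = float(np.abs(f).max())
        if max_f < fmax:
            return OptimizationResult(g, np.array(energies), step, True, max_f)
        if step == max_steps:
            break
        # velocity projection: keep only the component along the force
        vf = float((vel * f).sum())
        if vf > 0.0:
            vel = f * (vf / float((f * f).sum()))
        else:
            vel = np.zeros_like(vel)
        vel = vel + dt * FORCE_OVER_MASS_TO_ACC * f / MASSES[:, None]
        pos = pos + dt * vel
    g = DimerGeometry(last_valid)
    f = potential.forces(g)
    return OptimizationResult(g, np.array(energies), max_steps, False,
                              float(np.abs(f).max()))


def _optimize_lbfgs(potential: Potential, start: DimerGeometry,
                    fmax: float, max_steps: int) -> OptimizationResult:
    from scipy.optimize import minimize

    energies: list[float] = []

    def fun(x: np.ndarray):
        g = DimerGeometry(x.reshape(N_ATOMS, 3))
        e = potential.total_energy(g)
        energies.append(e)
        return e, -potential.forces(g).ravel()

    res = minimize(fun, start.positions.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_steps, "gtol": 0.1 * fmax})
    g = DimerGeometry(res.x.reshape(N_ATOMS, 3))
    max_f = float(np.abs(potential.forces(g)).max())
    return OptimizationResult(g, np.array(energies), int(res.nit),
                              max_f < fmax, max_f)


# -- molecular dynamics -------------------------------------------------------

@dataclass(frozen=True)
class ThermostatSettings:
    """Single Nose-Hoover thermostat; tau is the coupling time constant."""

    temperature: float = 298.0  # K
    tau: float = 100.0          # fs
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("coupling time constant must be positive")


@dataclass(frozen=True)
class Frame:
    time: float                 # fs
    positions: np.ndarray       # (6, 3) A
    velocities: np.ndarray      # (6, 3) A/fs
    energy: float               # predicted potential energy, kJ/mol
    temperature: float          # instantaneous kinetic temperature, K
    thermostat_xi: float        # friction coefficient, 1/fs


@dataclass(frozen=True)
class Trajectory:
    frames: tuple[Frame, ...]
    dt: float

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([f.temperature for f in self.frames])

    @property
    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])

    def total_energies(self) -> np.ndarray:
        """Potential + kinetic energy per sampled frame."""
        return self.energies + self.kinetic_energies()

    def energy_drift(self) -> float:
        """Secular total-energy drift (kJ/mol): the least-squares linear
        trend over the run times its duration.  Symplectic integration
        bounds the oscillatory part; only the trend signals a broken
        integrator."""
        t = self.times
        slope = np.polyfit(t, self.total_energies(), 1)[0]
        return float(abs(slope) * (t[-1] - t[0]))

    def kinetic_energies(self) -> np.ndarray:
        return np.array([
            0.5 * MASS_VEL2_TO_KJ_MOL * (MASSES[:, None] * f.velocities**2).sum()
            for f in self.frames
        ])

    def write_xyz(self, path: str | Path) -> None:
        from .geometry import write_xyz

        write_xyz(
            [DimerGeometry(f.positions, comment=f"t={f.time:.3f} fs "
                           f"E={f.energy:.6f} kJ/mol T={f.temperature:.2f} K")
             for f in self.frames], path)

    def write_scalars(self, path: str | Path) -> None:
        """Per-step scalar log: time (fs), energy (kJ/mol), temperature (K)."""
        with Path(path).open("w") as fh:
            fh.write("time_fs\tenergy_kj_mol\ttemperature_k\n")
            for f in self.frames:
                fh.write(f"{f.time:.6f}\t{f.energy:.10g}\t{f.temperature:.6f}\n")


def kinetic_temperature(vel: np.ndarray) -> float:
    ke = 0.5 * MASS_VEL2_TO_KJ_MOL * (MASSES[:, None] * vel**2).sum()
    return 2.0 * ke / (N_DOF * KB_KJ_MOL_K)


def maxwell_boltzmann_velocities(temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Initial velocities at ``temperature`` with the centre-of-mass drift
    removed and the kinetic temperature rescaled exactly to the target."""
    sigma = np.sqrt(KB_KJ_MOL_K * temperature /
                    (MASSES[:, None] * MASS_VEL2_TO_KJ_MOL))
    vel = rng.normal(size=(N_ATOMS, 3)) * sigma
    vel -= (MASSES[:, None] * vel).sum(0) / MASSES.sum()
    t_now = kinetic_temperature(vel)
    if t_now > 0:
        vel *= np.sqrt(temperature / t_now)
    return vel


def run_nvt(potential: Potential, start: DimerGeometry, temperature: float = 298.0,
            dt: float = 1.0, n_steps: int = 1000,
            thermostat: ThermostatSettings | None = None, seed: int = 0,
            initial_velocities: np.ndarray | None = None,
            sample_every: int = 1) -> Trajectory:
    """Velocity-Verlet NVT dynamics with a single Nose-Hoover thermostat.

    With ``thermostat.enabled = False`` the integrator reduces exactly to
    plain velocity Verlet (NVE), which is the energy-conservation
    reference mode.  Initial velocities are Maxwell-Boltzmann at the
    target temperature unless supplied.  Aborts on non-finite energies or
    forces, reporting the last ten sampled frames.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    thermostat = thermostat or ThermostatSettings(temperature=temperature)
    rng = np.random.Generator(np.random.Philox(key=seed))
    pos = start.positions.copy()
    vel = (initial_velocities.copy() if initial_velocities is not None
           else maxwell_boltzmann_velocities(temperature, rng))
    # Nose-Hoover mass: Q = N_dof kB T tau^2 (energy * time^2)
    q_nh = N_DOF * KB_KJ_MOL_K * thermostat.temperature * thermostat.tau**2
    kbt_ndof = N_DOF * KB_KJ_MOL_K * thermostat.temperature
    xi = 0.0

    def accel(f: np.ndarray) -> np.ndarray:
        return FORCE_OVER_MASS_TO_ACC * f / MASSES[:, None]

    def kinetic(v: np.ndarray) -> float:
        return 0.5 * MASS_VEL2_TO_KJ_MOL * (MASSES[:, None] * v**2).sum()

    g = DimerGeometry(pos)
    e = potential.total_energy(g)
    f = potential.forces(g)
    frames: list[Frame] = [Frame(0.0, pos.copy(), vel.copy(), e,
                                 kinetic_temperature(vel), xi)]
    for step in range(1, n_steps + 1):
        a = accel(f)
        if thermostat.enabled:
            v_half = vel + 0.5 * dt * (a - xi * vel)
            xi_half = xi + 0.5 * dt / q_nh * (2.0 * kinetic(vel) - kbt_ndof)
        else:
            v_half = vel + 0.5 * dt * a
            xi_half = 0.0
        pos = pos + dt * v_half
        g = DimerGeometry(pos)
        e = potential.total_energy(g)
        f = potential.forces(g)
        if not (np.isfinite(e) and np.all(np.isfinite(f))):
            tail = "\n".join(
                f"  t={fr.time:.2f} fs E={fr.energy:.4f} T={fr.temperature:.1f}"
                for fr in frames[-10:])
            raise FloatingPointError(
                f"non-finite energy/forces at step {step}; last frames:\n{tail}")
        a_new = accel(f)
        if thermostat.enabled:
            xi = xi_half + 0.5 * dt / q_nh * (2.0 * kinetic(v_half) - kbt_ndof)
            vel = (v_half + 0.5 * dt * a_new) / (1.0 + 0.5 * dt * xi)
        else:
            vel = v_half + 0.5 * dt * a_new
            xi = 0.0
        if step % sample_every == 0 or step == n_steps:
            frames.append(Frame(step * dt, pos.copy(), vel.copy(), e,
                                kinetic_temperature(vel), xi))
    return Trajectory(tuple(frames), dt=dt)


# -- coordinate scan ----------------------------------------------------------

@dataclass(frozen=True)
class ScanProfile:
    distances: np.ndarray                   # strictly increasing, A
    energies: np.ndarray                    # predicted, kJ/mol
    reference_energies: np.ndarray | None   # oracle, kJ/mol

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances) <= 0) and len(self.distances) > 1:
            raise ValueError("scan coordinate values must be strictly increasing")


def scan_coordinate(potential: Potential, base: DimerGeometry,
                    r_min: float, r_max: float, step: float = 0.1,
                    reference: Potential | None = None) -> ScanProfile:
    """Rigid scan along the O1-O4 axis.

    Molecule B is translated rigidly along the O1 -> O4 unit vector of the
    base geometry so |O1-O4| takes each grid value; both monomers keep
    their internal geometry.  When a reference potential is supplied its
    energies are recorded alongside the predictions.
    """
    if r_min > r_max:
        raise ValueError("r_min must not exceed r_max")
    pos = base.positions
    u = pos[3] - pos[0]
    r0 = np.linalg.norm(u)
    u = u / r0
    grid = np.arange(r_min, r_max + 0.5 * step, step) if r_max > r_min \
        else np.array([r_min])
    energies, refs = [], []
    for r in grid:
        p = pos.copy()
        p[3:] += (r - r0) * u
        g = DimerGeometry(p)
        from .geometry import min_separation

        if min_separation(g, "any") < 0.5:
            raise ValueError(f"scan point r={r:.3f} A creates a contact below 0.5 A")
        energies.append(potential.total_energy(g))
        if reference is not None:
            refs.append(reference.total_energy(g))
    return ScanProfile(np.asarray(grid, dtype=float), np.array(energies),
                       np.array(refs) if reference is not None else None)
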