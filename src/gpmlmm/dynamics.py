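"""Langevin NVT dynamics on any energy/force provider.

A minimal BAOAB-splitting Langevin integrator: deterministic
velocity-Verlet "B-A" half-steps around an exact Ornstein-Uhlenbeck
"O" step.  With zero friction it reduces to velocity Verlet (NVE).
Providers supply energies, forces, and optionally dipoles, so the same
integrator drives the analytic oracle, a trained hierarchical model, or
any toy surface.

Units: coordinates Angstrom, velocities Angstrom/fs, masses amu, energies
kcal/mol, time fs, friction ps^-1, temperature K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .geometry import Geometry, MMEnvironment
from .units import ACC_KCALMOL, KB_KCALMOL

__all__ = [
    "MDConfig",
    "Trajectory",
    "ProviderResult",
    "OracleProvider",
    "ModelProvider",
    "HarmonicWellProvider",
    "maxwell_boltzmann_velocities",
    "run_nvt",
]


@dataclass(frozen=True)
class MDConfig:
    """Integration parameters.  Defaults mirror the solvated production
    protocol: 1 fs timestep and a 1 ps^-1 Langevin friction (0 = NVE)."""

    timestep: float = 1.0  # fs
    temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1
    n_steps: int = 1000
    rng_seed: int = 0
    dipole_stride: int = 1

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dipole_stride < 1:
            raise ValueError("dipole_stride must be >= 1")


@dataclass
class Trajectory:
    """Evenly spaced trajectory with per-frame energetics and dipoles.

    ``dipoles`` holds one row per ``dipole_stride``-th frame (NaN rows are
    never stored; providers without dipoles yield an empty array).
    """

    times: np.ndarray  # (F,), fs
    coords: np.ndarray  # (F, N, 3)
    velocities: np.ndarray  # (F, N, 3)
    dipoles: np.ndarray  # (F_dip, 3) in a.u., or (0, 3)
    dipole_times: np.ndarray
    potential_energies: np.ndarray  # (F,)
    kinetic_energies: np.ndarray  # (F,)

    @property
    def timestep(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def total_energies(self) -> np.ndarray:
        return self.potential_energies + self.kinetic_energies


@dataclass(frozen=True)
class ProviderResult:
    energy: float
    forces: np.ndarray  # (N, 3) kcal/mol/A
    dipole: np.ndarray | None = None  # a.u.


class Provider(Protocol):
    def evaluate(self, coords: np.ndarray) -> ProviderResult: ...


@dataclass
class OracleProvider:
    """Analytic-reference provider in a fixed MM environment."""

    params: "object"  # OracleParams
    template: Geometry
    env: MMEnvironment = field(default_factory=MMEnvironment.empty)

    def evaluate(self, coords: np.ndarray) -> ProviderResult:
        from .oracle import toy_reference

        lab = toy_reference(
            self.template.with_coords(coords), self.env, self.params
        )
        return ProviderResult(lab.energy, lab.forces_qm, lab.dipole)


@dataclass
class ModelProvider:
    """Trained hierarchical model in a fixed MM environment."""

    model: "object"  # HierarchicalModel
    template: Geometry
    env: MMEnvironment = field(default_factory=MMEnvironment.empty)

    def evaluate(self, coords: np.ndarray) -> ProviderResult:
        out = self.model.predict(self.template.with_coords(coords), self.env)
        return ProviderResult(
            float(out["energy"]), out["forces_qm"], out.get("dipole")
        )


@dataclass
class HarmonicWellProvider:
    """Independent isotropic tethers: E = 1/2 k sum_a |r_a - r0_a|^2.
    Every degree of freedom oscillates at sqrt(k/m); handy as an exactly
    solvable reference for integrator and spectrum tests."""

    k: float  # kcal/mol/A^2
    centers: np.ndarray  # (N, 3)

    def evaluate(self, coords: np.ndarray) -> ProviderResult:
        d = coords - self.centers
        return ProviderResult(0.5 * self.k * float((d * d).sum()), -self.k * d)


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """Per-component normal draws at temperature T with the net linear
    momentum removed.  Returns (N, 3) velocities in Angstrom/fs."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if temperature == 0:
        return np.zeros((len(masses), 3))
    sigma = np.sqrt(KB_KCALMOL * temperature * ACC_KCALMOL / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    p = (masses[:, None] * v).sum(axis=0)
    return v - p / masses.sum()


def run_nvt(
    provider: Provider,
    geom: Geometry,
    config: MDConfig,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics with the BAOAB splitting.

    ``friction = 0`` reduces exactly to velocity Verlet (NVE).  The
    trajectory records one frame per step (plus the initial frame), with
    the provider's dipole sampled every ``dipole_stride`` frames.
    Bit-reproducible from ``config.rng_seed``.
    """
    if geom.masses is None:
        raise ValueError("geometry needs masses for dynamics")
    rng = np.random.default_rng(config.rng_seed)
    masses = geom.masses[:, None]
    dt = config.timestep
    gamma = config.friction * 1e-3  # ps^-1 -> fs^-1
    kbt = KB_KCALMOL * config.temperature

    x = geom.coords.copy()
    if velocities is None:
        velocities = maxwell_boltzmann_velocities(
            geom.masses, config.temperature, rng
        )
    v = velocities.copy()

    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kbt * ACC_KCALMOL / geom.masses)[:, None]
    res = provider.evaluate(x)
    _check_finite(res.forces, 0)
    f = res.forces

    n_frames = config.n_steps + 1
    times = np.arange(n_frames) * dt
    coords = np.empty((n_frames,) + x.shape)
    vels = np.empty_like(coords)
    epot = np.empty(n_frames)
    ekin = np.empty(n_frames)
    dip_list, dip_t = [], []

    def record(i, res, x, v):
        coords[i] = x
        vels[i] = v
        epot[i] = res.energy
        ekin[i] = 0.5 * float((masses * v * v).sum()) / ACC_KCALMOL
        if res.dipole is not None and i % config.dipole_stride == 0:
            dip_list.append(np.asarray(res.dipole, dtype=float))
            dip_t.append(times[i])

    record(0, res, x, v)
    acc = ACC_KCALMOL
    for step in range(1, n_frames):
        v = v + 0.5 * dt * f / masses * acc  # B
        x = x + 0.5 * dt * v  # A
        if gamma > 0:  # O (exact OU step)
            v = c1 * v + c2 * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v  # A
        res = provider.evaluate(x)
        _check_finite(res.forces, step)
        f = res.forces
        v = v + 0.5 * dt * f / masses * acc  # B
        record(step, res, x, v)

    dipoles = (
        np.stack(dip_list) if dip_list else np.zeros((0, 3))
    )
    return Trajectory(
        times=times,
        coords=coords,
        velocities=vels,
        dipoles=dipoles,
        dipole_times=np.asarray(dip_t),
        potential_energies=epot,
        kinetic_energies=ekin,
    )


def _check_finite(forces: np.ndarray, frame: int) -> None:
    if not np.all(np.isfinite(forces)):
        raise RuntimeError(f"non-finite force at frame {frame}; aborting")
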