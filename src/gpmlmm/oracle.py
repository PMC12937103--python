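"""Analytic reference engine and dataset builder.

The oracle plays the role of the quantum-chemistry engine: a harmonic
pair-spring intramolecular surface plus a linearly polarizable charge
distribution coupled to the external potential,

    E_vac = 1/2 sum_p k_p (d_p - d0_p)^2        (kcal/mol)
    q(V)  = q0 + A V                            (e; A rows sum to 0)
    E_env = (q0 . V + 1/2 V^T A V) * 627.509...  (Hartree -> kcal/mol)

so that dE/dV_a equals the charge q_a exactly, total charge is conserved
for any environment, and every force (including the Coulomb back-reaction
on MM sites) is analytic.  The vacuum surface is written in interatomic
distances rather than as a Cartesian quadratic form so that it is an
exact function of the internal-geometry descriptor; its Hessian at the
reference geometry equals the corresponding quadratic form and drives
normal-mode sampling.  It is differentiable, cheap, and close enough in
structure to the GP hypothesis space that model-recovery tests are
meaningful, while remaining an independent reference.

``normal_mode_sample`` draws thermally distributed displacements along
the non-zero-frequency normal modes of the mass-weighted Hessian, and
``build_dataset`` chains sampling, artificial-environment generation and
oracle labelling into ready-to-train samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptors import esp_descriptor
from .envgen import EnvGenConfig, make_environment
from .geometry import Geometry, MMEnvironment
from .gpr import LabelledSample
from .units import BOHR_PER_ANGSTROM, KB_KCALMOL, KCALMOL_PER_HARTREE

__all__ = [
    "OracleParams",
    "OracleLabels",
    "toy_reference",
    "normal_mode_sample",
    "build_dataset",
    "default_toy_params",
]


@dataclass(frozen=True)
class OracleParams:
    """Reference surface parameters.

    ``pair_springs``: force constants k_p (kcal/mol/A^2) over the
    lexicographic atom pairs (a < b); zero entries switch a pair off.
    ``pair_d0``: equilibrium distances (A), defaulting to the reference
    geometry's.  ``charges0``: gas-phase charges q0 (e) summing to the
    total charge.  ``response``: symmetric charge-response matrix A
    (a.u.) with rows summing to 0, mapping per-atom potentials to induced
    charges.  ``hessian`` is the (3N, 3N) PSD intramolecular Hessian of
    the spring surface at the reference, used for normal-mode sampling.
    """

    reference: Geometry
    pair_springs: np.ndarray
    charges0: np.ndarray
    response: np.ndarray
    pair_d0: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.reference.n_atoms
        n_pairs = n * (n - 1) // 2
        ks = np.asarray(self.pair_springs, dtype=float)
        q0 = np.asarray(self.charges0, dtype=float)
        a = np.asarray(self.response, dtype=float)
        if ks.shape != (n_pairs,):
            raise ValueError(f"pair_springs must have length {n_pairs}")
        if np.any(ks < 0):
            raise ValueError("pair_springs must be non-negative")
        ia, ib = np.triu_indices(n, k=1)
        d_ref = np.linalg.norm(
            self.reference.coords[ia] - self.reference.coords[ib], axis=1
        )
        d0 = d_ref if self.pair_d0 is None else np.asarray(self.pair_d0, float)
        if d0.shape != (n_pairs,):
            raise ValueError(f"pair_d0 must have length {n_pairs}")
        if q0.shape != (n,):
            raise ValueError("one gas-phase charge per atom required")
        if abs(q0.sum() - self.reference.total_charge) > 1e-9:
            raise ValueError("gas-phase charges must sum to the total charge")
        if a.shape != (n, n) or not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("response matrix must be symmetric (N, N)")
        if np.abs(a.sum(axis=1)).max() > 1e-9:
            raise ValueError("response rows must sum to 0 (charge conservation)")
        object.__setattr__(self, "pair_springs", ks)
        object.__setattr__(self, "pair_d0", d0)
        object.__setattr__(self, "charges0", q0)
        object.__setattr__(self, "response", a)

    @property
    def hessian(self) -> np.ndarray:
        """Hessian of the spring surface at the reference geometry.  With
        d0 at the reference distances this is the PSD Gauss-Newton form
        sum_p k_p j_p j_p^T plus the (then vanishing) curvature term."""
        n = self.reference.n_atoms
        ia, ib = np.triu_indices(n, k=1)
        coords = self.reference.coords
        h = np.zeros((3 * n, 3 * n))
        for p, (a, b) in enumerate(zip(ia, ib)):
            if self.pair_springs[p] == 0.0:
                continue
            u = coords[a] - coords[b]
            d = np.linalg.norm(u)
            u = u / d
            j = np.zeros(3 * n)
            j[3 * a : 3 * a + 3] = u
            j[3 * b : 3 * b + 3] = -u
            h += self.pair_springs[p] * np.outer(j, j)
            stretch = d - self.pair_d0[p]
            if stretch != 0.0:
                # second-derivative of d: (I - u u^T)/d, on the ab block
                pmat = (np.eye(3) - np.outer(u, u)) / d
                block = self.pair_springs[p] * stretch * pmat
                for (x, y, sgn) in ((a, a, 1), (b, b, 1), (a, b, -1), (b, a, -1)):
                    h[3 * x : 3 * x + 3, 3 * y : 3 * y + 3] += sgn * block
        return h

    def scaled(self, spring_factor: float = 1.1, charge_shift: float = 0.02):
        """A 'higher level of theory': stiffer springs and shifted q0 with
        the shift summing to zero.  Used as the delta-learning target."""
        n = self.reference.n_atoms
        shift = charge_shift * np.cos(2.0 * np.pi * np.arange(n) / n)
        shift -= shift.mean()
        return OracleParams(
            self.reference,
            spring_factor * self.pair_springs,
            self.charges0 + shift,
            self.response,
            self.pair_d0,
        )


@dataclass(frozen=True)
class OracleLabels:
    """Exact labels of one configuration, with the vacuum/environment split."""

    energy: float
    forces_qm: np.ndarray
    forces_mm: np.ndarray
    charges: np.ndarray
    dipole: np.ndarray
    energy_vacuum: float
    energy_environment: float
    forces_vacuum: np.ndarray
    forces_environment: np.ndarray


def toy_reference(
    geom: Geometry, env: MMEnvironment, params: OracleParams
) -> OracleLabels:
    """Evaluate the analytic reference at one configuration."""
    n = geom.n_atoms
    ia, ib = np.triu_indices(n, k=1)
    diff = geom.coords[ia] - geom.coords[ib]
    d = np.linalg.norm(diff, axis=1)
    stretch = d - params.pair_d0
    e_vac = 0.5 * float(params.pair_springs @ stretch**2)
    # F = -sum_p k_p (d_p - d0_p) grad d_p
    coef = params.pair_springs * stretch / d  # (P,)
    f_pairs = -coef[:, None] * diff  # force on atom ia from pair p
    f_vac = np.zeros((n, 3))
    np.add.at(f_vac, ia, f_pairs)
    np.add.at(f_vac, ib, -f_pairs)

    esp = esp_descriptor(geom, env, with_jacobians=True)
    v = esp.values
    q = params.charges0 + params.response @ v
    e_env_ha = float(params.charges0 @ v + 0.5 * v @ params.response @ v)
    e_env = e_env_ha * KCALMOL_PER_HARTREE
    # dE/dr = q . dV/dr (both QM and MM paths), converted to kcal/mol/A
    f_env_qm = -(q @ esp.jac_qm).reshape(n, 3) * KCALMOL_PER_HARTREE
    f_env_mm = (
        -(q @ esp.jac_mm).reshape(env.n_sites, 3) * KCALMOL_PER_HARTREE
        if not env.is_empty
        else np.zeros((0, 3))
    )
    dipole = q @ (geom.coords * BOHR_PER_ANGSTROM)
    return OracleLabels(
        energy=e_vac + e_env,
        forces_qm=f_vac + f_env_qm,
        forces_mm=f_env_mm,
        charges=q,
        dipole=dipole,
        energy_vacuum=e_vac,
        energy_environment=e_env,
        forces_vacuum=f_vac,
        forces_environment=f_env_qm,
    )


def normal_modes(params: OracleParams) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (kcal/mol/A^2/amu) and Cartesian displacement vectors of
    the mass-weighted Hessian, zero-frequency modes excluded."""
    masses = params.reference.masses
    if masses is None:
        raise ValueError("reference geometry needs masses for normal modes")
    m3 = np.repeat(masses, 3)
    hw = params.hessian / np.sqrt(np.outer(m3, m3))
    evals, evecs = np.linalg.eigh(hw)
    scale = max(float(np.abs(evals).max()), 1.0)
    nonzero = np.abs(evals) > 1e-8 * scale
    negative = nonzero & (evals < 0)
    if negative.any():
        warnings.warn(
            f"excluding {int(negative.sum())} negative-frequency modes",
            stacklevel=2,
        )
        nonzero &= evals > 0
    # Cartesian displacement per unit normal coordinate: M^{-1/2} v
    cart = evecs[:, nonzero] / np.sqrt(m3)[:, None]
    return evals[nonzero], cart


def normal_mode_sample(
    params: OracleParams,
    n: int,
    amplitude_scale: float = 1.0,
    rng: np.random.Generator | int = 0,
    temperature: float = 300.0,
    clash_cutoff: float = 0.5,
    max_retries: int = 100,
) -> list[Geometry]:
    """Random displacements along normal modes.

    Each non-zero-frequency normal coordinate is drawn from a zero-mean
    normal with the classical thermal standard deviation sqrt(kB T / w^2)
    scaled by ``amplitude_scale``.  Geometries with any interatomic
    distance below ``clash_cutoff`` are redrawn (bounded retries).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    evals, cart = normal_modes(params)
    std = amplitude_scale * np.sqrt(KB_KCALMOL * temperature / evals)
    ref = params.reference
    out: list[Geometry] = []
    for _ in range(n):
        for attempt in range(max_retries):
            qn = rng.normal(0.0, 1.0, size=len(std)) * std
            coords = ref.coords + (cart @ qn).reshape(-1, 3)
            d = np.linalg.norm(
                coords[:, None, :] - coords[None, :, :], axis=-1
            )
            iu = np.triu_indices(ref.n_atoms, k=1)
            if d[iu].min() > clash_cutoff:
                out.append(ref.with_coords(coords))
                break
        else:
            raise RuntimeError(
                f"could not draw a clash-free geometry in {max_retries} tries"
            )
    return out


def build_dataset(
    params: OracleParams,
    envgen_config: EnvGenConfig | None,
    n_samples: int,
    rng: np.random.Generator | int = 0,
    amplitude_scale: float = 1.0,
    temperature: float = 300.0,
) -> list[LabelledSample]:
    """Generate a fully labelled dataset: normal-mode-displaced geometries,
    an artificial charge environment around each (ranked by the oracle's
    gas-phase charges), and exact oracle labels including the
    vacuum/environment split.  Deterministic given the seed.
    ``envgen_config=None`` produces a vacuum dataset."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    geoms = normal_mode_sample(
        params, n_samples, amplitude_scale, rng, temperature
    )
    samples = []
    for g in geoms:
        if envgen_config is None:
            env = MMEnvironment.empty()
        else:
            env = make_environment(g, params.charges0, envgen_config, rng)
        lab = toy_reference(g, env, params)
        samples.append(
            LabelledSample(
                geom=g,
                env=env,
                energy=lab.energy,
                forces_qm=lab.forces_qm,
                forces_mm=lab.forces_mm,
                total_charge=float(params.charges0.sum()),
                dipole=lab.dipole,
                vacuum_energy=lab.energy_vacuum,
                vacuum_forces=lab.forces_vacuum,
            )
        )
    return samples


def default_toy_params(total_charge: int = 0) -> OracleParams:
    """The package's default toy molecule: a planar 4-atom fragment
    (C, O and a symmetric H pair) with pair-spring Hessian, so that
    permutational symmetrization over the two hydrogens is exercised."""
    symbols = ("C", "O", "H", "H")
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.22, 0.0, 0.0],
            [-0.55, 0.94, 0.0],
            [-0.55, -0.94, 0.0],
        ]
    )
    geom = Geometry(symbols, coords, total_charge=total_charge)
    n = geom.n_atoms
    # pair springs in lexicographic order: (0,1) C=O, (0,2)/(0,3) C-H,
    # (1,2)/(1,3) geminal couplings, (2,3) H..H.  Pure distance springs
    # leave out-of-plane motion of a planar fragment at zero frequency, so
    # normal-mode sampling stays in-plane and the surface is an exact
    # function of internal distances.
    springs = np.array([600.0, 350.0, 350.0, 60.0, 60.0, 45.0])
    q0 = np.array([0.3, -0.6, 0.15, 0.15])
    q0 = q0 + (total_charge - q0.sum()) / n
    # symmetric response, rows sum to zero, H pair equivalent
    a_resp = -0.08 * (np.eye(n) - 0.25)
    return OracleParams(geom, springs, q0, a_resp)
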