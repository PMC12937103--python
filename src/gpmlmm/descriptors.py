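"""Configuration descriptors and their analytic Jacobians.

Two descriptors encode a solvated configuration:

* the inverse-distance (ID) vector — the strict upper triangle of the
  matrix 1/||r_a - r_b|| over ML-region atoms, which encodes the internal
  geometry and is invariant under rigid motions;
* the electrostatic-potential (ESP) vector — the Coulomb potential of the
  MM point charges evaluated at each ML atom, in atomic units, which
  encodes the environment.

Pairs (a, b) of the ID vector are ordered lexicographically with a < b.
All Jacobians are closed-form; finite differences are used only as test
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, GeometryError, MMEnvironment, MIN_SITE_SEPARATION
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "IDDescriptor",
    "ESPDescriptor",
    "inverse_distance_descriptor",
    "esp_descriptor",
    "pair_index",
]


def pair_index(n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    """Lexicographic (a, b), a < b index arrays of the flattened ID vector."""
    return np.triu_indices(n_atoms, k=1)


@dataclass(frozen=True)
class IDDescriptor:
    """Inverse-distance descriptor.

    ``values``: 1/d_ab in 1/Angstrom, length n(n-1)/2.
    ``jacobian``: d(values)/d(coords), shape (n_pairs, 3 n_atoms), or None.
    """

    values: np.ndarray
    jacobian: np.ndarray | None = None


@dataclass(frozen=True)
class ESPDescriptor:
    """Per-atom external electrostatic potential, atomic units (e/Bohr).

    Jacobians are taken with respect to Cartesian coordinates in Angstrom,
    so their unit is (e/Bohr)/Angstrom.
    """

    values: np.ndarray
    jac_qm: np.ndarray | None = None
    jac_mm: np.ndarray | None = None


def inverse_distance_descriptor(
    geom: Geometry, with_jacobian: bool = False
) -> IDDescriptor:
    """Compute the ID descriptor (and optionally its Jacobian) of ``geom``."""
    coords = geom.coords
    n = geom.n_atoms
    ia, ib = pair_index(n)
    diff = coords[ia] - coords[ib]  # (P, 3)
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist <= MIN_SITE_SEPARATION):
        k = int(np.argmin(dist))
        raise GeometryError(
            f"degenerate geometry: atoms {ia[k]} and {ib[k]} coincide"
        )
    values = 1.0 / dist
    jac = None
    if with_jacobian:
        # d(1/d)/dr_a = -(r_a - r_b)/d^3 ; nonzero only for atoms a and b
        g = -diff / dist[:, None] ** 3  # (P, 3) gradient w.r.t. atom ia
        jac = np.zeros((len(values), 3 * n))
        rows = np.arange(len(values))
        for c in range(3):
            jac[rows, 3 * ia + c] = g[:, c]
            jac[rows, 3 * ib + c] = -g[:, c]
    return IDDescriptor(values, jac)


def esp_descriptor(
    geom: Geometry, env: MMEnvironment, with_jacobians: bool = False
) -> ESPDescriptor:
    """Electrostatic potential of the MM charges at each ML atom.

    V_a = sum_m q_m / ||r_a - r_m|| with distances converted to Bohr, so
    the values are in e/Bohr.  An empty environment gives a zero vector
    (and zero Jacobians).
    """
    n = geom.n_atoms
    if env.is_empty:
        zeros_qm = np.zeros((n, 3 * n)) if with_jacobians else None
        zeros_mm = np.zeros((n, 0)) if with_jacobians else None
        return ESPDescriptor(np.zeros(n), zeros_qm, zeros_mm)
    env.check_distinct_from(geom)
    diff = geom.coords[:, None, :] - env.coords[None, :, :]  # (N, M, 3) Angstrom
    dist = np.linalg.norm(diff, axis=-1)  # (N, M)
    values = (env.charges[None, :] / (dist * BOHR_PER_ANGSTROM)).sum(axis=1)
    jac_qm = jac_mm = None
    if with_jacobians:
        m = env.n_sites
        # dV_a/dr_a = -q_m (r_a - r_m)/(d^3) / bohr_per_ang  (coords in Angstrom)
        g = (
            -env.charges[None, :, None]
            * diff
            / dist[:, :, None] ** 3
            / BOHR_PER_ANGSTROM
        )  # (N, M, 3): contribution of site m to dV_a/dr_a
        jac_qm = np.zeros((n, 3 * n))
        jac_qm[np.arange(n)[:, None], (3 * np.arange(n))[:, None] + np.arange(3)] = (
            g.sum(axis=1)
        )
        jac_mm = (-g).reshape(n, 3 * m)  # dV_a/dr_m = -dV_a/dr_a per site
    return ESPDescriptor(values, jac_qm, jac_mm)
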