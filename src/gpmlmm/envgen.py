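"""Artificial solvent environments: layered ESP-style grids around the
molecule, |V|-weighted stochastic point selection, damped random charges,
and neutralization.

The construction mimics sampling solvent electrostatics without any
solvent model: four layers of points on fused atom-centred spheres
(a Merz-Singh-Kollman-style construction), thinned to a minimum
point-point spacing, are ranked by the molecular electrostatic potential
estimated from fixed atomic charges; a stochastic subset biased toward
strong-potential regions receives normally distributed charges, damped
so that no single point-charge interaction exceeds ``damp_a``, and the
mean charge is subtracted so each environment is exactly neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Geometry, GeometryError, MMEnvironment
from .units import BOHR_PER_ANGSTROM, BONDI_VDW_RADII

__all__ = [
    "EnvGenConfig",
    "GridPoints",
    "build_layered_grid",
    "mulliken_esp",
    "select_points",
    "assign_charges",
    "make_environment",
]


class EnvGenError(ValueError):
    """Invalid environment-generation configuration or degenerate input."""


@dataclass(frozen=True)
class EnvGenConfig:
    """Parameters of the artificial-environment pipeline.

    Defaults follow the study protocol: layers start ``min_distance`` = 3 A
    from the molecule, spaced by ``interlayer`` = 2 A, up to a
    ``max_cutoff`` of 11 A; points closer than ``thinning_distance`` =
    1.3 A to an accepted point are discarded; ``n_select`` = 3000 points
    receive charges drawn from N(0, ``charge_sigma`` = 0.2 e) and damped
    with ``damp_a`` = 0.1.  ``use_vdw_radii`` adds per-element Bondi radii
    to the layer offsets (set False for a flat offset from the nuclei).
    """

    min_distance: float = 3.0
    interlayer: float = 2.0
    max_cutoff: float = 11.0
    thinning_distance: float = 1.3
    n_layers: int = 4
    n_select: int = 3000
    charge_sigma: float = 0.2
    damp_a: float = 0.1
    surface_density: float = 1.0  # points per A^2
    use_vdw_radii: bool = True
    vdw_radii: dict | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance >= self.max_cutoff:
            raise EnvGenError("min_distance must be < max_cutoff")
        for name in ("min_distance", "interlayer", "max_cutoff",
                     "thinning_distance", "surface_density"):
            if getattr(self, name) <= 0:
                raise EnvGenError(f"{name} must be > 0")
        if self.n_select < 1:
            raise EnvGenError("n_select must be >= 1")

    def radius(self, symbol: str, layer: int) -> float:
        base = 0.0
        if self.use_vdw_radii:
            table = self.vdw_radii or BONDI_VDW_RADII
            base = table[symbol]
        return base + self.min_distance + layer * self.interlayer


@dataclass(frozen=True)
class GridPoints:
    """Accepted grid points (Angstrom) with their layer index."""

    coords: np.ndarray
    layer_index: np.ndarray


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, near-equal-area spiral lattice on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_layered_grid(geom: Geometry, config: EnvGenConfig) -> GridPoints:
    """Construct the layered fused-sphere grid around ``geom``.

    Per layer, points sit on the outer surface of the union of atom-centred
    spheres (points inside any other atom's same-layer sphere are removed),
    points farther than ``max_cutoff`` from every atom are removed, and a
    greedy thinning pass (layer-major, generation order) enforces the
    minimum point-point spacing.
    """
    candidates = []
    layers = []
    for layer in range(config.n_layers):
        radii = np.array([config.radius(s, layer) for s in geom.symbols])
        for a, center in enumerate(geom.coords):
            n_pts = max(int(np.ceil(config.surface_density * 4.0 * np.pi
                                    * radii[a] ** 2)), 8)
            pts = center + radii[a] * _fibonacci_sphere(n_pts)
            # fused-surface rule: discard points strictly inside any other
            # atom's sphere of the same layer
            d = np.linalg.norm(pts[:, None, :] - geom.coords[None, :, :], axis=-1)
            inside = (d < radii[None, :] - 1e-9).any(axis=1)
            keep = pts[~inside]
            # cutoff: keep points within max_cutoff of at least one atom
            dmin = np.linalg.norm(
                keep[:, None, :] - geom.coords[None, :, :], axis=-1
            ).min(axis=1)
            keep = keep[dmin <= config.max_cutoff + 1e-9]
            candidates.append(keep)
            layers.append(np.full(len(keep), layer))
    pts = np.concatenate(candidates, axis=0)
    lay = np.concatenate(layers)
    if len(pts) == 0:
        raise EnvGenError("no grid points survive the fused-surface/cutoff rules")

    # greedy thinning in deterministic order
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=config.thinning_distance)
    accepted = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        if any(accepted[j] for j in neighbors[i] if j < i):
            continue
        accepted[i] = True
    if not accepted.any():
        raise EnvGenError("thinning removed every grid point")
    return GridPoints(pts[accepted], lay[accepted])


def mulliken_esp(
    geom: Geometry, atom_charges: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Molecular ESP at external points from fixed atomic charges (a.u.)."""
    atom_charges = np.asarray(atom_charges, dtype=float)
    if atom_charges.shape != (geom.n_atoms,):
        raise EnvGenError("one charge per QM atom required")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(points[:, None, :] - geom.coords[None, :, :], axis=-1)
    if np.any(d <= 1e-6):
        i, a = np.argwhere(d <= 1e-6)[0]
        raise GeometryError(f"singular ESP: point {i} coincides with atom {a}")
    return (atom_charges[None, :] / (d * BOHR_PER_ANGSTROM)).sum(axis=1)


def select_points(
    potentials: np.ndarray, n_select: int, rng: np.random.Generator
) -> np.ndarray:
    """Stochastic selection biased toward strong potential.

    p_i = |V_i| / sum|V_j|; uniform xi in [0, 1) are drawn and the indices
    of the ``n_select`` smallest ratios xi_i/p_i are returned (points with
    p_i = 0 are never selected).
    """
    v = np.abs(np.asarray(potentials, dtype=float))
    total = v.sum()
    if total <= 0:
        raise EnvGenError("degenerate weights: all potentials are zero")
    p = v / total
    n_pos = int((p > 0).sum())
    if n_select > n_pos:
        raise EnvGenError(
            f"cannot select {n_select} of {n_pos} nonzero-weight points"
        )
    xi = rng.random(len(p))
    with np.errstate(divide="ignore"):
        ratio = np.where(p > 0, xi / np.where(p > 0, p, 1.0), np.inf)
    order = np.argsort(ratio, kind="stable")
    return np.sort(order[:n_select])


def damping(x, a: float = 0.1):
    """f_damp(x) = (2a/pi) arctan(x/a): odd, monotone, |f| < a."""
    return (2.0 * a / np.pi) * np.arctan(np.asarray(x, dtype=float) / a)


def assign_charges(
    potentials: np.ndarray, config: EnvGenConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw, damp and neutralize external charges at the selected points.

    q ~ N(0, charge_sigma); the damped charge is f_damp(q V)/V, which
    bounds each point's interaction |q~ V| by damp_a; at V = 0 the analytic
    limit (2/pi) q applies.  The mean is subtracted so charges sum to 0.
    """
    v = np.asarray(potentials, dtype=float)
    q = rng.normal(0.0, config.charge_sigma, size=v.shape)
    a = config.damp_a
    qt = np.where(
        v != 0.0,
        damping(q * v, a) / np.where(v != 0.0, v, 1.0),
        (2.0 / np.pi) * q,
    )
    return qt - qt.mean()


def make_environment(
    geom: Geometry,
    atom_charges: np.ndarray,
    config: EnvGenConfig,
    rng: np.random.Generator | int | None = None,
) -> MMEnvironment:
    """Full pipeline: grid, ESP ranking, stochastic selection, damped
    neutral charges.  Fully reproducible from the seed."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    grid = build_layered_grid(geom, config)
    pot = mulliken_esp(geom, atom_charges, grid.coords)
    n_pos = int((np.abs(pot) > 0).sum())
    n_sel = min(config.n_select, n_pos)
    idx = select_points(pot, n_sel, rng)
    charges = assign_charges(pot[idx], config, rng)
    return MMEnvironment(grid.coords[idx], charges)
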