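"""Core molecular containers: the ML (QM) region and the MM point-charge environment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ATOMIC_MASSES

__all__ = ["Geometry", "MMEnvironment", "GeometryError"]

#: two sites closer than this (Angstrom) are treated as coincident
MIN_SITE_SEPARATION = 1e-6


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent molecular input."""


@dataclass(frozen=True)
class Geometry:
    """ML(QM)-region geometry.

    Parameters
    ----------
    symbols:
        Element symbols, one per atom.
    coords:
        Cartesian positions in Angstrom, shape ``(n_atoms, 3)``.
    masses:
        Atomic masses in amu; looked up from the element table when omitted.
    total_charge:
        Integer total charge of the ML region, in e.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray
    masses: np.ndarray | None = None
    total_charge: int = 0

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(self.coords, dtype=float)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must have shape (n, 3), got {coords.shape}")
        if len(self.symbols) != coords.shape[0]:
            raise GeometryError("number of symbols does not match coords")
        if coords.shape[0] < 2:
            raise GeometryError("a geometry needs at least two atoms")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        iu = np.triu_indices(coords.shape[0], k=1)
        if np.any(d[iu] <= MIN_SITE_SEPARATION):
            a, b = np.argwhere(
                (d <= MIN_SITE_SEPARATION) & ~np.eye(len(d), dtype=bool)
            )[0]
            raise GeometryError(f"degenerate geometry: atoms {a} and {b} coincide")
        if self.masses is None:
            try:
                masses = np.array([ATOMIC_MASSES[s] for s in self.symbols])
            except KeyError:
                masses = None
        else:
            masses = np.ascontiguousarray(self.masses, dtype=float)
            if masses.shape != (coords.shape[0],):
                raise GeometryError("masses shape mismatch")
        object.__setattr__(self, "masses", masses)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.symbols, coords, self.masses, self.total_charge)

    def permuted(self, perm: np.ndarray) -> "Geometry":
        """Geometry with atoms reordered as ``coords[perm]``."""
        perm = np.asarray(perm, dtype=int)
        masses = None if self.masses is None else self.masses[perm]
        return Geometry(
            tuple(self.symbols[p] for p in perm),
            self.coords[perm],
            masses,
            self.total_charge,
        )


@dataclass(frozen=True)
class MMEnvironment:
    """External point charges representing the solvent.

    ``coords`` in Angstrom, ``charges`` in e.  May be empty (vacuum).
    """

    coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    charges: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(self.coords, dtype=float).reshape(-1, 3)
        charges = np.ascontiguousarray(self.charges, dtype=float).reshape(-1)
        if coords.shape[0] != charges.shape[0]:
            raise GeometryError("MM coords and charges length mismatch")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def is_empty(self) -> bool:
        return self.coords.shape[0] == 0

    @classmethod
    def empty(cls) -> "MMEnvironment":
        return cls()

    def check_distinct_from(self, geom: Geometry) -> None:
        if self.is_empty:
            return
        d = np.linalg.norm(
            geom.coords[:, None, :] - self.coords[None, :, :], axis=-1
        )
        if np.any(d <= MIN_SITE_SEPARATION):
            a, m = np.argwhere(d <= MIN_SITE_SEPARATION)[0]
            raise GeometryError(
                f"singular ESP: QM atom {a} coincides with MM site {m}"
            )
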