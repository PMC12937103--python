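"""Readers and writers for the standard text formats and HDF5 archives.

Formats: plain XYZ (2 header lines), extended XYZ with key=value fields
on the comment line (per-frame time, energy and dipole), 4-column
point-charge text (x y z q in Angstrom and e), 2-column spectrum text
with a JSON metadata sidecar, and self-describing HDF5 archives for
datasets and trained models (bit-exact round trips).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import Geometry, MMEnvironment
from .gpr import HierarchicalModel, LabelledSample, TrainedModel, _FeatureSet
from .kernels import KernelSpec
from .spectra import Spectrum

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_extxyz_trajectory",
    "write_extxyz_trajectory",
    "read_point_charges",
    "write_point_charges",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "save_hierarchical",
    "load_hierarchical",
    "write_spectrum",
    "read_spectrum",
]


class ParseError(ValueError):
    """Malformed input file; the message names file, line and field."""


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def read_xyz(path) -> Geometry:
    """Read a single-frame XYZ file (symbol x y z, Angstrom)."""
    frames = _read_xyz_frames(path, max_frames=1)
    symbols, coords, _ = frames[0]
    return Geometry(symbols, coords)


def write_xyz(path, geom: Geometry, comment: str = "") -> None:
    with open(path, "w") as fh:
        _write_frame(fh, geom.symbols, geom.coords, comment)


def _write_frame(fh, symbols, coords, comment) -> None:
    fh.write(f"{len(symbols)}\n{comment}\n")
    for s, (x, y, z) in zip(symbols, coords):
        fh.write(f"{s} {x:.12f} {y:.12f} {z:.12f}\n")


def _read_xyz_frames(path, max_frames=None):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            lineno += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + nat >= len(lines) + 1:
            raise ParseError(f"{path}:{lineno}: truncated frame")
        comment = lines[i + 1].rstrip("\n")
        symbols, coords = [], []
        for k in range(nat):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno + 2 + k}: expected 'symbol x y z'"
                )
            symbols.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno + 2 + k}: non-numeric coordinate"
                ) from exc
        frames.append((tuple(symbols), np.array(coords), comment))
        i += 2 + nat
        lineno += 2 + nat
        if max_frames and len(frames) >= max_frames:
            break
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


# ---------------------------------------------------------------------------
# extended XYZ trajectories with per-frame dipole/energy/time fields
# ---------------------------------------------------------------------------


def _parse_comment_fields(comment: str, path, lineno) -> dict:
    fields = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, val = token.split("=", 1)
        val = val.strip('"')
        try:
            fields[key] = (
                np.array([float(v) for v in val.split(",")])
                if "," in val
                else float(val)
            )
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: non-numeric value for field '{key}'"
            ) from exc
    return fields


def write_extxyz_trajectory(path, trajectory, symbols) -> None:
    """Write a Trajectory as extended XYZ; dipoles/energies/times go into
    comment-line key=value fields."""
    dip_by_time = {
        float(t): d for t, d in zip(trajectory.dipole_times, trajectory.dipoles)
    }
    with open(path, "w") as fh:
        for i, t in enumerate(trajectory.times):
            parts = [f"time={t:.6f}", f"energy={trajectory.potential_energies[i]:.12f}"]
            d = dip_by_time.get(float(t))
            if d is not None:
                parts.append("dipole=" + ",".join(f"{x:.12f}" for x in d))
            _write_frame(fh, symbols, trajectory.coords[i], " ".join(parts))


def read_extxyz_trajectory(path):
    """Read an extended-XYZ trajectory; returns (symbols, coords (F,N,3),
    times (F,), dipoles (F_dip,3), dipole_times, energies)."""
    frames = _read_xyz_frames(path)
    symbols = frames[0][0]
    coords = np.stack([f[1] for f in frames])
    times, energies, dipoles, dip_times = [], [], [], []
    lineno = 1
    for k, (_, _, comment) in enumerate(frames):
        fields = _parse_comment_fields(comment, path, lineno)
        times.append(fields.get("time", float(k)))
        energies.append(fields.get("energy", np.nan))
        if "dipole" in fields:
            dipoles.append(fields["dipole"])
            dip_times.append(times[-1])
        lineno += 2 + len(symbols)
    return (
        symbols,
        coords,
        np.array(times),
        np.stack(dipoles) if dipoles else np.zeros((0, 3)),
        np.array(dip_times),
        np.array(energies),
    )


# ---------------------------------------------------------------------------
# point charges
# ---------------------------------------------------------------------------


def read_point_charges(path) -> MMEnvironment:
    """Read a 4-column x y z q text file (Angstrom, e); '#' comments allowed."""
    coords, charges = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 columns (x y z q), got {len(parts)}"
                )
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                bad = next(p for p in parts if not _is_float(p))
                raise ParseError(
                    f"{path}:{lineno}: non-numeric field {bad!r}"
                ) from exc
            coords.append(vals[:3])
            charges.append(vals[3])
    return MMEnvironment(np.array(coords).reshape(-1, 3), np.array(charges))


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_point_charges(path, env: MMEnvironment) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z q (Angstrom, e)\n")
        for (x, y, z), q in zip(env.coords, env.charges):
            fh.write(f"{x:.12f} {y:.12f} {z:.12f} {q:.12f}\n")


# ---------------------------------------------------------------------------
# dataset archive
# ---------------------------------------------------------------------------


def save_dataset(path, samples: list[LabelledSample]) -> None:
    """HDF5 archive with one group per sample and declared units."""
    with h5py.File(path, "w") as f:
        f.attrs["energy_unit"] = "kcal/mol"
        f.attrs["force_unit"] = "kcal/mol/angstrom"
        f.attrs["length_unit"] = "angstrom"
        f.attrs["n_samples"] = len(samples)
        for i, s in enumerate(samples):
            g = f.create_group(f"sample_{i:06d}")
            g.create_dataset("symbols", data=np.array(s.geom.symbols, dtype="S4"))
            g.create_dataset("coords", data=s.geom.coords)
            if s.geom.masses is not None:
                g.create_dataset("masses", data=s.geom.masses)
            g.create_dataset("mm_coords", data=s.env.coords)
            g.create_dataset("mm_charges", data=s.env.charges)
            g.attrs["energy"] = s.energy
            g.attrs["total_charge"] = s.total_charge
            g.create_dataset("forces_qm", data=s.forces_qm)
            if s.forces_mm is not None:
                g.create_dataset("forces_mm", data=s.forces_mm)
            if s.dipole is not None:
                g.create_dataset("dipole", data=s.dipole)
            if s.vacuum_energy is not None:
                g.attrs["vacuum_energy"] = s.vacuum_energy
            if s.vacuum_forces is not None:
                g.create_dataset("vacuum_forces", data=s.vacuum_forces)


def load_dataset(path) -> list[LabelledSample]:
    samples = []
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_samples"])
        for i in range(n):
            g = f[f"sample_{i:06d}"]
            symbols = tuple(s.decode() for s in g["symbols"][()])
            geom = Geometry(
                symbols,
                g["coords"][()],
                g["masses"][()] if "masses" in g else None,
            )
            env = MMEnvironment(g["mm_coords"][()], g["mm_charges"][()])
            samples.append(
                LabelledSample(
                    geom=geom,
                    env=env,
                    energy=float(g.attrs["energy"]),
                    forces_qm=g["forces_qm"][()],
                    total_charge=float(g.attrs["total_charge"]),
                    forces_mm=g["forces_mm"][()] if "forces_mm" in g else None,
                    dipole=g["dipole"][()] if "dipole" in g else None,
                    vacuum_energy=(
                        float(g.attrs["vacuum_energy"])
                        if "vacuum_energy" in g.attrs
                        else None
                    ),
                    vacuum_forces=(
                        g["vacuum_forces"][()] if "vacuum_forces" in g else None
                    ),
                )
            )
    return samples


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------


def _save_model_group(g, model: TrainedModel) -> None:
    g.attrs["kind"] = model.kind
    g.attrs["lengthscale"] = model.spec.lengthscale
    g.attrs["theta"] = model.spec.theta
    g.attrs["sigma_e"] = model.sigma_e
    g.attrs["sigma_f"] = model.sigma_f
    g.attrs["sigma_q"] = model.sigma_q
    g.attrs["energy_offset"] = model.energy_offset
    g.attrs["energy_unit"] = model.energy_unit
    g.attrs["force_unit"] = model.force_unit
    g.attrs["n"] = model.features.n
    g.attrs["s"] = model.features.s
    g.attrs["n_atoms"] = model.features.n_atoms
    g.create_dataset("symbols", data=np.array(model.symbols, dtype="S4"))
    perms = np.asarray(model.spec.permutations, dtype=int)
    g.create_dataset(
        "permutations",
        data=perms if perms.size else np.zeros((0, model.features.n_atoms), int),
    )
    g.create_dataset("chi", data=model.features.chi)
    g.create_dataset("jchi", data=model.features.jchi)
    if model.features.v is not None:
        g.create_dataset("v", data=model.features.v)
        g.create_dataset("jv", data=model.features.jv)
    if model.alpha_e is not None:
        g.create_dataset("alpha_e", data=model.alpha_e)
    g.create_dataset("alpha_f", data=model.alpha_f)
    if model.alpha_q is not None:
        g.create_dataset("alpha_q", data=model.alpha_q)


def _load_model_group(g) -> TrainedModel:
    perms = g["permutations"][()]
    spec = KernelSpec(
        float(g.attrs["lengthscale"]),
        float(g.attrs["theta"]),
        tuple(tuple(int(i) for i in p) for p in perms),
    )
    feats = _FeatureSet(
        chi=g["chi"][()],
        jchi=g["jchi"][()],
        v=g["v"][()] if "v" in g else None,
        jv=g["jv"][()] if "jv" in g else None,
        n=int(g.attrs["n"]),
        s=int(g.attrs["s"]),
        n_atoms=int(g.attrs["n_atoms"]),
    )
    return TrainedModel(
        kind=str(g.attrs["kind"]),
        spec=spec,
        sigma_e=float(g.attrs["sigma_e"]),
        sigma_f=float(g.attrs["sigma_f"]),
        sigma_q=float(g.attrs["sigma_q"]),
        features=feats,
        symbols=tuple(s.decode() for s in g["symbols"][()]),
        alpha_e=g["alpha_e"][()] if "alpha_e" in g else None,
        alpha_f=g["alpha_f"][()],
        alpha_q=g["alpha_q"][()] if "alpha_q" in g else None,
        energy_offset=float(g.attrs["energy_offset"]),
        energy_unit=str(g.attrs["energy_unit"]),
        force_unit=str(g.attrs["force_unit"]),
    )


def save_model(path, model: TrainedModel) -> None:
    with h5py.File(path, "w") as f:
        _save_model_group(f.create_group("model"), model)


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        return _load_model_group(f["model"])


def save_hierarchical(path, model: HierarchicalModel) -> None:
    with h5py.File(path, "w") as f:
        _save_model_group(f.create_group("vacuum"), model.vacuum)
        for name in ("environment", "delta_vacuum", "delta_environment"):
            m = getattr(model, name)
            if m is not None:
                _save_model_group(f.create_group(name), m)


def load_hierarchical(path) -> HierarchicalModel:
    with h5py.File(path, "r") as f:
        kw = {"vacuum": _load_model_group(f["vacuum"])}
        for name in ("environment", "delta_vacuum", "delta_environment"):
            if name in f:
                kw[name] = _load_model_group(f[name])
    return HierarchicalModel(**kw)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def write_spectrum(path, spectrum: Spectrum) -> None:
    """2-column text (cm^-1, intensity) plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1 intensity\n")
        for w, s in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.6f} {s:.10e}\n")
    meta = {k: _jsonable(v) for k, v in spectrum.metadata.items()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    data = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Spectrum(data[:, 0], data[:, 1], meta)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
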