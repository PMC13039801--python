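"""File formats: XYZ, labeled extended-XYZ, trajectories, model archives.

The labeled dialect is plain extended-XYZ: the comment line carries
``E_ref=<Hartree>`` (the reference molecular energy) and each atom line
carries two trailing columns, the raw per-atom energy ``E_raw`` and the
absolute per-atom integration error ``L_abs``, both in Hartree.
Coordinates are always Å.  Floats are written with ``repr`` so every
round trip is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .elements import mass_of, normalize_symbol

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _r(v) -> str:
    """Exact (shortest round-trip) decimal representation of a float."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Geometry:
    """One molecular configuration: element symbols + Cartesian coords (Å)."""

    elements: list[str]
    coords: np.ndarray
    tag: str | None = None

    def __post_init__(self):
        self.elements = [normalize_symbol(e) for e in self.elements]
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if n < 2:
            raise ValueError(f"a Geometry needs at least 2 atoms, got {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for e in self.elements:
            mass_of(e)  # raises on unknown symbols

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])

    def copy(self) -> "Geometry":
        return Geometry(list(self.elements), self.coords.copy(), self.tag)


@dataclass
class LabeledConfiguration:
    """Geometry plus per-atom raw energies / integration errors (Hartree)."""

    geometry: Geometry
    raw_atomic_energies: np.ndarray
    abs_integration_errors: np.ndarray
    ref_molecular_energy: float

    def __post_init__(self):
        n = self.geometry.n_atoms
        self.raw_atomic_energies = np.asarray(self.raw_atomic_energies, float)
        self.abs_integration_errors = np.asarray(self.abs_integration_errors, float)
        if self.raw_atomic_energies.shape != (n,):
            raise ValueError("raw_atomic_energies length mismatch")
        if self.abs_integration_errors.shape != (n,):
            raise ValueError("abs_integration_errors length mismatch")
        if np.any(self.abs_integration_errors < 0):
            raise ValueError("abs_integration_errors must be >= 0")
        self.ref_molecular_energy = float(self.ref_molecular_energy)


@dataclass
class Trajectory:
    """Ordered MD frames with per-frame scalars and optional forces."""

    frames: list[Geometry] = field(default_factory=list)
    steps: list[int] = field(default_factory=list)
    potential_energies: list[float] = field(default_factory=list)  # Ha
    kinetic_energies: list[float] = field(default_factory=list)  # Ha
    temperatures: list[float] = field(default_factory=list)  # K
    forces: list[np.ndarray] = field(default_factory=list)  # Ha/Bohr

    def append(self, step, geometry, epot, ekin, temp, forces=None):
        if self.steps and step <= self.steps[-1]:
            raise ValueError("frame step indices must be strictly increasing")
        if self.frames and geometry.elements != self.frames[0].elements:
            raise ValueError("all frames must share the element list")
        self.steps.append(int(step))
        self.frames.append(geometry)
        self.potential_energies.append(float(epot))
        self.kinetic_energies.append(float(ekin))
        self.temperatures.append(float(temp))
        if forces is not None:
            self.forces.append(np.asarray(forces, float))

    def __len__(self):
        return len(self.frames)


# ---------------------------------------------------------------------------
# XYZ


def _iter_xyz_frames(lines: list[str]):
    i, nline = 0, len(lines)
    while i < nline:
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if natoms < 1:
            raise ParseError(f"line {i + 1}: non-positive atom count {natoms}")
        if i + 1 + natoms >= nline + 1 and i + 1 + natoms > nline:
            raise ParseError(f"line {i + 1}: frame truncated ({natoms} atoms declared)")
        comment = lines[i + 1].rstrip("\n") if i + 1 < nline else ""
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) != natoms:
            raise ParseError(f"line {i + 1}: frame truncated ({natoms} atoms declared)")
        yield i, comment, body
        i += 2 + natoms


def read_xyz(path) -> list[Geometry]:
    """Read a (possibly multi-frame) standard XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    geoms = []
    for start, comment, body in _iter_xyz_frames(lines):
        elements, coords = [], []
        for off, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"line {start + 3 + off}: expected 'El x y z'")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {start + 3 + off}: non-numeric coordinate")
            try:
                elements.append(normalize_symbol(parts[0]))
            except (ValueError, KeyError):
                raise ParseError(f"line {start + 3 + off}: bad element {parts[0]!r}")
            coords.append(xyz)
        try:
            geoms.append(Geometry(elements, np.array(coords), tag=comment or None))
        except KeyError as exc:
            raise ParseError(f"frame at line {start + 1}: {exc}")
    return geoms


def write_xyz(path, geometries: Iterable[Geometry]) -> None:
    with open(path, "w") as fh:
        for g in geometries:
            fh.write(f"{g.n_atoms}\n{g.tag or ''}\n")
            for el, (x, y, z) in zip(g.elements, g.coords):
                fh.write(f"{el} {_r(x)} {_r(y)} {_r(z)}\n")


# ---------------------------------------------------------------------------
# Labeled extended-XYZ


def _parse_comment_keys(comment: str) -> dict[str, str]:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_labeled_dataset(path) -> list[LabeledConfiguration]:
    """Read the labeled extended-XYZ dialect (E_ref + E_raw/L_abs columns)."""
    with open(path) as fh:
        lines = fh.readlines()
    configs = []
    for start, comment, body in _iter_xyz_frames(lines):
        keys = _parse_comment_keys(comment)
        if "E_ref" not in keys:
            raise ParseError(f"line {start + 2}: comment line lacks E_ref=<Hartree>")
        try:
            eref = float(keys["E_ref"])
        except ValueError:
            raise ParseError(f"line {start + 2}: non-numeric E_ref {keys['E_ref']!r}")
        elements, coords, eraw, labs = [], [], [], []
        for off, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 6:
                raise ParseError(
                    f"line {start + 3 + off}: expected 'El x y z E_raw L_abs'"
                )
            try:
                vals = [float(v) for v in parts[1:6]]
            except ValueError:
                raise ParseError(f"line {start + 3 + off}: non-numeric field")
            elements.append(parts[0])
            coords.append(vals[:3])
            eraw.append(vals[3])
            labs.append(vals[4])
        geom = Geometry(elements, np.array(coords), tag=keys.get("tag"))
        configs.append(
            LabeledConfiguration(geom, np.array(eraw), np.array(labs), eref)
        )
    return configs


def write_labeled_dataset(
    path, configs: Sequence[LabeledConfiguration], corrected=None
) -> None:
    """Write the labeled dialect; ``corrected`` optionally appends an E_corr
    column (list of per-config arrays)."""
    with open(path, "w") as fh:
        for ci, cfg in enumerate(configs):
            g = cfg.geometry
            comment = f"E_ref={_r(cfg.ref_molecular_energy)}"
            if g.tag:
                comment += f" tag={g.tag}"
            fh.write(f"{g.n_atoms}\n{comment}\n")
            for a in range(g.n_atoms):
                x, y, z = g.coords[a]
                row = (
                    f"{g.elements[a]} {_r(x)} {_r(y)} {_r(z)} "
                    f"{_r(cfg.raw_atomic_energies[a])} "
                    f"{_r(cfg.abs_integration_errors[a])}"
                )
                if corrected is not None:
                    row += f" {_r(corrected[ci][a])}"
                fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Trajectory output


def write_trajectory(xyz_path, csv_path, traj: Trajectory) -> None:
    """Extended-XYZ frames (with force columns when present) + CSV scalars."""
    with open(xyz_path, "w") as fh:
        for k, g in enumerate(traj.frames):
            fh.write(
                f"{g.n_atoms}\nstep={traj.steps[k]} "
                f"E_pot={_r(traj.potential_energies[k])} "
                f"E_kin={_r(traj.kinetic_energies[k])} T={_r(traj.temperatures[k])}\n"
            )
            for a in range(g.n_atoms):
                x, y, z = g.coords[a]
                row = f"{g.elements[a]} {_r(x)} {_r(y)} {_r(z)}"
                if traj.forces:
                    fx, fy, fz = traj.forces[k][a]
                    row += f" {_r(fx)} {_r(fy)} {_r(fz)}"
                fh.write(row + "\n")
    with open(csv_path, "w") as fh:
        fh.write("step,E_pot_Ha,E_kin_Ha,T_K\n")
        for k in range(len(traj)):
            fh.write(
                f"{traj.steps[k]},{_r(traj.potential_energies[k])},"
                f"{_r(traj.kinetic_energies[k])},{_r(traj.temperatures[k])}\n"
            )


# ---------------------------------------------------------------------------
# Model archive (single-file JSON, versioned)


def save_model(model, path) -> None:
    """Serialize a fitted MolecularGPRResults to a self-describing JSON file."""
    payload = {"format": "alfpot-model", "version": MODEL_FORMAT_VERSION}
    payload.update(model.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    from .gpr import MolecularGPRResults

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted or non-model file {path}: {exc}") from None
    if payload.get("format") != "alfpot-model":
        raise ValueError(f"{path} is not an alfpot model archive")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload.get('version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return MolecularGPRResults.from_dict(payload)
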