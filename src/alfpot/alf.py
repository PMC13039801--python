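"""Atomic local frames (ALF) and rotation/translation-invariant features.

Each atom A gets a right-handed local frame built from two bonded
neighbours: the x-axis atom and the xy-plane atom.  The feature vector
of A is then (d1, d2, valence angle) followed by spherical coordinates
(r, θ, φ) of every remaining atom in ascending global index — 3N−6
values in total.  φ is azimuthal and therefore periodic.

Distance-valued features are expressed in Bohr and angles in radians:
with kernel weights searched in the unit box [0, 1], atomic units give
the composite kernel chemically sensible length scales (sub-Å) that a
radius capped at 1 Å⁻² could not reach.  B-matrices are reported as
feature-unit per Å, matching the Cartesian coordinates.

Frame-atom selection rule (deterministic, mass-priority):

* x-axis atom  = bonded neighbour of highest atomic mass (ties broken
  by lowest index);
* xy-plane atom = next-highest-mass bonded neighbour; if A has a single
  neighbour X, the heaviest neighbour-of-X excluding A is used.

This convention is a stand-in for priority rules used elsewhere in the
ALF literature; any deterministic choice works because the features are
exact internal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .elements import covalent_radius_of, mass_of
from .io import Geometry
from .units import BOHR_PER_ANGSTROM

BOND_SCALE = 1.2  # bonded iff distance < 1.2 × sum of covalent radii


class DegenerateFrameError(ValueError):
    pass


@dataclass(frozen=True)
class ALFDefinition:
    """Per-atom (x_axis_atom, xy_plane_atom) indices; None entries only in
    the diatomic distance-only degenerate mode."""

    x_axis: tuple[int, ...]
    xy_plane: tuple[int, ...]
    diatomic: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.x_axis)

    def others(self, atom: int) -> list[int]:
        """Remaining atoms in ascending global index."""
        excl = {atom, self.x_axis[atom], self.xy_plane[atom]}
        return [i for i in range(self.n_atoms) if i not in excl]

    def packed(self):
        """int64 arrays (alf_x, alf_p, others) for the jit core."""
        n = self.n_atoms
        alf_x = np.asarray(self.x_axis, dtype=np.int64)
        alf_p = np.asarray(self.xy_plane, dtype=np.int64)
        others = np.empty((n, max(n - 3, 0)), dtype=np.int64)
        for a in range(n):
            others[a] = self.others(a)
        return alf_x, alf_p, others


@dataclass
class FeatureVector:
    values: np.ndarray
    periodic_mask: np.ndarray  # bool, True at azimuthal angles


def n_features(n_atoms: int, diatomic: bool = False) -> int:
    return 1 if diatomic else 3 * n_atoms - 6


def periodic_mask(nfeat: int) -> np.ndarray:
    """True at 1-based indices d with d > 3 and d mod 3 == 0."""
    d = np.arange(1, nfeat + 1)
    return (d > 3) & (d % 3 == 0) if nfeat > 1 else np.zeros(1, bool)


def infer_connectivity(geometry: Geometry) -> list[tuple[int, int]]:
    """Distance-based bond detection; raises if any atom ends up isolated."""
    n = geometry.n_atoms
    radii = np.array([covalent_radius_of(e) for e in geometry.elements])
    bonds = []
    bonded = np.zeros(n, bool)
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = BOND_SCALE * (radii[i] + radii[j])
            if np.linalg.norm(geometry.coords[i] - geometry.coords[j]) < cutoff:
                bonds.append((i, j))
                bonded[i] = bonded[j] = True
    for i in range(n):
        if not bonded[i]:
            raise ValueError(
                f"atom {i} ({geometry.elements[i]}) has no bonded neighbour "
                f"within {BOND_SCALE}x covalent-radius cutoff"
            )
    return bonds


def build_alf(
    geometry: Geometry, bonds: list[tuple[int, int]] | None = None
) -> ALFDefinition:
    """Deterministic mass-priority ALF for every atom.

    For N = 2 the distance-only degenerate mode is returned (one feature,
    no frame); it must be explicitly expected by downstream consumers.
    """
    n = geometry.n_atoms
    if n == 2:
        return ALFDefinition((1, 0), (1, 0), diatomic=True)
    if bonds is None:
        bonds = infer_connectivity(geometry)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        neigh[i].append(j)
        neigh[j].append(i)

    def by_priority(cands):
        return sorted(cands, key=lambda k: (-mass_of(geometry.elements[k]), k))

    x_axis, xy_plane = [], []
    for a in range(n):
        ranked = by_priority(neigh[a])
        xa = ranked[0]
        if len(ranked) >= 2:
            pa = ranked[1]
        else:
            second = by_priority([k for k in neigh[xa] if k != a])
            if not second:
                raise ValueError(
                    f"cannot build ALF for atom {a}: single neighbour "
                    f"{xa} has no further neighbours"
                )
            pa = second[0]
        x_axis.append(xa)
        xy_plane.append(pa)
    return ALFDefinition(tuple(x_axis), tuple(xy_plane))


def _features_B(geometry: Geometry, alf: ALFDefinition):
    """Features (distances in Bohr, angles in rad) and B-matrices per Å."""
    coords_b = geometry.coords * BOHR_PER_ANGSTROM
    try:
        if alf.diatomic:
            feats, B = _core.diatomic_features_and_jacobian(coords_b)
        else:
            alf_x, alf_p, others = alf.packed()
            feats, B = _core.features_and_jacobian_all(coords_b, alf_x, alf_p, others)
    except ValueError as exc:
        raise DegenerateFrameError(str(exc)) from None
    return feats, B * BOHR_PER_ANGSTROM


def _features_B_single(geometry: Geometry, alf: ALFDefinition, atom: int):
    coords_b = geometry.coords * BOHR_PER_ANGSTROM
    if alf.diatomic:
        feats, B = _core.diatomic_features_and_jacobian(coords_b)
        return feats[atom], B[atom] * BOHR_PER_ANGSTROM
    try:
        feats, B = _core.features_and_jacobian_single(
            coords_b,
            np.int64(atom),
            np.int64(alf.x_axis[atom]),
            np.int64(alf.xy_plane[atom]),
            np.asarray(alf.others(atom), dtype=np.int64),
        )
    except ValueError as exc:
        raise DegenerateFrameError(str(exc)) from None
    return feats, B * BOHR_PER_ANGSTROM


def featurize(geometry: Geometry, alf: ALFDefinition, atom: int) -> FeatureVector:
    """ALF feature vector of one atom (3N−6 values, or 1 in diatomic mode)."""
    feats, _ = _features_B_single(geometry, alf, atom)
    return FeatureVector(np.asarray(feats).copy(), periodic_mask(np.asarray(feats).size))


def featurize_all(geometry: Geometry, alf: ALFDefinition) -> np.ndarray:
    """(N, F) feature matrix for all atoms at once."""
    feats, _ = _features_B(geometry, alf)
    return feats


def feature_jacobian(geometry: Geometry, alf: ALFDefinition, atom: int) -> np.ndarray:
    """B-matrix of one atom model: (F, 3N) d(feature)/d(Cartesian) in 1/Å
    (distances are dimensionless ratios per Å)."""
    _, B = _features_B_single(geometry, alf, atom)
    return np.asarray(B).copy()
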