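"""Synthetic partitioned potential-energy surfaces and labeled datasets.

A :class:`ToyPES` is an analytic valence force field (harmonic bonds and
angles, cosine torsions, per-element baseline energies) whose total
energy is partitioned *exactly* over atoms:

* bond term      → ½ to each bonded atom,
* angle term     → apex atom,
* torsion term   → ½ to each of the two central atoms,
* baseline       → its own atom.

The per-atom energies therefore sum to the molecular energy before any
noise, emulating a topological energy partition.  ``label_configs``
then adds a small Gaussian per-atom integration noise (heavy atoms get
5× the hydrogen level, mirroring the wider energy range of heavy
atoms), stores its absolute value as the per-atom integration error and
keeps the exact total as the reference energy — so the dataset carries
a nonzero recovery error whose correction is exactly testable.

These toys exist to exercise the training/force/MD machinery and its
invariants; they make no claim of reproducing ab initio energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import mass_of
from .io import Geometry, LabeledConfiguration
from .units import KB_MDUNIT_PER_K, MDUNIT_PER_HARTREE

BASELINE_HA = {"H": -0.5, "C": -37.8, "N": -54.4, "O": -75.0}

DEFAULT_NOISE_SD = 1e-4  # Ha, hydrogen-level integration noise
HEAVY_NOISE_FACTOR = 5.0


# ---------------------------------------------------------------------------
# internal-coordinate values and gradients


def _bond(coords, i, j):
    d = coords[j] - coords[i]
    r = np.linalg.norm(d)
    g = d / r
    return r, g  # dr/d(r_j) = g, dr/d(r_i) = -g


def _angle(coords, i, j, k):
    """Valence angle at apex j, with gradients on i, j, k."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    ru, rv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / ru, v / rv
    c = np.clip(uh @ vh, -1.0, 1.0)
    th = np.arccos(c)
    s = max(np.sin(th), 1e-12)
    gi = (c * uh - vh) / (ru * s)
    gk = (c * vh - uh) / (rv * s)
    return th, gi, -(gi + gk), gk


def _dihedral(coords, i, j, k, l):
    """Signed dihedral about bond j–k in (−π, π], with gradients."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(np.cross(n1, n2) @ b2 / nb2, n1 @ n2)
    sq1 = max(n1 @ n1, 1e-24)
    sq2 = max(n2 @ n2, 1e-24)
    gi = -nb2 / sq1 * n1
    gl = nb2 / sq2 * n2
    s12 = (b1 @ b2) / (nb2 * nb2)
    s32 = (b3 @ b2) / (nb2 * nb2)
    gj = -(1.0 + s12) * gi + s32 * gl
    gk = s12 * gi - (1.0 + s32) * gl
    return phi, gi, gj, gk, gl


def dihedral_angle(coords, i, j, k, l) -> float:
    """Signed dihedral (radians, (−π, π])."""
    return float(_dihedral(np.asarray(coords, float), i, j, k, l)[0])


# ---------------------------------------------------------------------------
# Toy PES


@dataclass
class ToyPES:
    """Analytic valence force field with an exact atomic partition."""

    elements: list[str]
    bonds: list[tuple]  # (i, j, k_b [Ha/Å²], r0 [Å])
    angles: list[tuple]  # (i, j, k, k_a [Ha/rad²], th0 [rad]); apex j
    torsions: list[tuple]  # (i, j, k, l, V [Ha], n, gamma [rad])
    baselines: np.ndarray = field(default=None)  # per-atom Ha

    def __post_init__(self):
        if self.baselines is None:
            self.baselines = np.array([BASELINE_HA[e] for e in self.elements])

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atomic_energies(self, coords) -> np.ndarray:
        """Exact per-atom partition (Ha); sums to ``energy`` identically."""
        coords = np.asarray(coords, float)
        e = self.baselines.copy()
        for i, j, kb, r0 in self.bonds:
            r, _ = _bond(coords, i, j)
            term = 0.5 * kb * (r - r0) ** 2
            e[i] += 0.5 * term
            e[j] += 0.5 * term
        for i, j, k, ka, th0 in self.angles:
            th = _angle(coords, i, j, k)[0]
            e[j] += 0.5 * ka * (th - th0) ** 2
        for i, j, k, l, V, n, gam in self.torsions:
            phi = _dihedral(coords, i, j, k, l)[0]
            term = V * (1.0 + np.cos(n * phi - gam))
            e[j] += 0.5 * term
            e[k] += 0.5 * term
        return e

    def energy(self, coords) -> float:
        return float(self.atomic_energies(coords).sum())

    def gradient(self, coords) -> np.ndarray:
        """Analytic dE/dx (Ha/Å), shape (N, 3)."""
        coords = np.asarray(coords, float)
        g = np.zeros_like(coords)
        for i, j, kb, r0 in self.bonds:
            r, gj = _bond(coords, i, j)
            pref = kb * (r - r0)
            g[j] += pref * gj
            g[i] -= pref * gj
        for i, j, k, ka, th0 in self.angles:
            th, gi, gj, gk = _angle(coords, i, j, k)
            pref = ka * (th - th0)
            g[i] += pref * gi
            g[j] += pref * gj
            g[k] += pref * gk
        for i, j, k, l, V, n, gam in self.torsions:
            phi, gi, gj, gk, gl = _dihedral(coords, i, j, k, l)
            pref = -V * n * np.sin(n * phi - gam)
            g[i] += pref * gi
            g[j] += pref * gj
            g[k] += pref * gk
            g[l] += pref * gl
        return g

    def energy_gradient(self, coords):
        """(E [Ha], dE/dx [Ha/Å]) — same interface as a fitted model, so
        the toy surface can drive the MD/optimization machinery directly."""
        return self.energy(coords), self.gradient(coords)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])


# ---------------------------------------------------------------------------
# geometry construction (internal z-matrix placement)


def _place_zmatrix(rows):
    """rows: list of (ref_r, bond), (ref_r, bond, ref_a, angle),
    (ref_r, bond, ref_a, angle, ref_d, torsion); first row is ()."""
    coords = [np.zeros(3)]
    for idx, row in enumerate(rows[1:], start=1):
        if idx == 1:
            coords.append(np.array([row[1], 0.0, 0.0]))
        elif idx == 2:
            rj, r = row[0], row[1]
            ra, ang = row[2], row[3]
            b = coords[rj]
            axis = coords[ra] - b
            axis /= np.linalg.norm(axis)
            coords.append(b + r * (np.cos(np.pi - ang) * -axis
                                   + np.sin(np.pi - ang) * np.array([0.0, 1.0, 0.0])))
            # place in xy-plane at the requested valence angle
            u = coords[ra] - b
            u /= np.linalg.norm(u)
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords[-1] = b + r * (np.cos(ang) * u + np.sin(ang) * perp)
        else:
            rj, r, ra, ang, rd, tor = row
            b, a, d = coords[rj], coords[ra], coords[rd]
            e1 = b - a
            e1 /= np.linalg.norm(e1)
            q = d - a
            q = q - (q @ e1) * e1
            if np.linalg.norm(q) < 1e-10:
                q = np.array([0.0, 1.0, 0.0]) - e1[1] * e1
            q /= np.linalg.norm(q)
            e3 = np.cross(e1, q)
            pos = b + r * (
                -np.cos(ang) * e1
                + np.sin(ang) * (np.cos(tor) * q + np.sin(tor) * e3)
            )
            coords.append(pos)
    return np.array(coords)


TET = 1.9106332362490186  # tetrahedral angle, rad


def make_toy(kind: str):
    """Reproducible toy molecule + PES.

    Kinds: ``diatomic`` (2-atom distance-only mode), ``chain4``,
    ``chain5`` (two torsions), ``glycine-like`` (7 atoms, two torsions,
    ≥2 metastable conformers).  Returns (equilibrium Geometry, ToyPES).
    """
    if kind in ("diatomic", "diatomic-mode"):
        els = ["C", "H"]
        pes = ToyPES(els, bonds=[(0, 1, 0.8, 1.0)], angles=[], torsions=[])
        g = Geometry(els, np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
        return g, pes
    if kind == "chain4":
        els = ["O", "C", "C", "H"]
        pes = ToyPES(
            els,
            bonds=[(0, 1, 0.5, 1.40), (1, 2, 0.5, 1.50), (2, 3, 0.4, 1.09)],
            angles=[(0, 1, 2, 0.1, TET), (1, 2, 3, 0.1, TET)],
            torsions=[(0, 1, 2, 3, 0.005, 3, 0.0)],
        )
        coords = _place_zmatrix([
            (), (0, 1.40), (1, 1.50, 0, TET), (2, 1.09, 1, TET, 0, np.pi / 3),
        ])
        return Geometry(els, coords), pes
    if kind in ("chain5", "chain5-with-torsion"):
        els = ["O", "C", "C", "C", "H"]
        pes = ToyPES(
            els,
            bonds=[(0, 1, 0.5, 1.40), (1, 2, 0.5, 1.50),
                   (2, 3, 0.5, 1.50), (3, 4, 0.4, 1.09)],
            angles=[(0, 1, 2, 0.1, TET), (1, 2, 3, 0.1, TET), (2, 3, 4, 0.1, TET)],
            torsions=[(0, 1, 2, 3, 0.005, 3, 0.0), (1, 2, 3, 4, 0.005, 3, 0.0)],
        )
        coords = _place_zmatrix([
            (), (0, 1.40), (1, 1.50, 0, TET),
            (2, 1.50, 1, TET, 0, np.pi / 3),
            (3, 1.09, 2, TET, 1, np.pi / 3),
        ])
        return Geometry(els, coords), pes
    if kind == "glycine-like":
        els = ["N", "C", "C", "O", "H", "H", "H"]
        pes = ToyPES(
            els,
            bonds=[(0, 1, 0.5, 1.47), (1, 2, 0.5, 1.50), (2, 3, 0.5, 1.40),
                   (0, 4, 0.4, 1.01), (1, 5, 0.4, 1.09), (3, 6, 0.4, 0.96)],
            angles=[(0, 1, 2, 0.1, TET), (1, 2, 3, 0.1, TET),
                    (1, 0, 4, 0.1, TET), (0, 1, 5, 0.1, TET),
                    (2, 3, 6, 0.1, TET)],
            # n=2 backbone torsion -> two metastable conformers at ±π/2
            torsions=[(0, 1, 2, 3, 0.006, 2, 0.0), (1, 2, 3, 6, 0.004, 3, 0.0)],
        )
        coords = _place_zmatrix([
            (), (0, 1.47), (1, 1.50, 0, TET),
            (2, 1.40, 1, TET, 0, np.pi / 2),
            (0, 1.01, 1, TET, 2, np.pi),
            (1, 1.09, 0, TET, 2, 2 * np.pi / 3),
            (3, 0.96, 2, TET, 1, np.pi / 3),
        ])
        return Geometry(els, coords), pes
    raise ValueError(f"unknown toy kind {kind!r}")


# ---------------------------------------------------------------------------
# labeling and sampling


def label_configs(
    pes: ToyPES, geometries, noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0
) -> list[LabeledConfiguration]:
    """Exact partition + per-atom Gaussian integration noise.

    Heavy atoms draw noise with 5× the hydrogen standard deviation.  The
    reference molecular energy is the exact total, so the recovery error
    of each configuration equals minus the summed noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sd = np.array(
        [noise_sd * (1.0 if e == "H" else HEAVY_NOISE_FACTOR) for e in pes.elements]
    )
    out = []
    for g in geometries:
        exact = pes.atomic_energies(g.coords)
        draw = rng.normal(0.0, 1.0, size=pes.n_atoms) * sd
        out.append(
            LabeledConfiguration(g, exact + draw, np.abs(draw), float(exact.sum()))
        )
    return out


def sample_configs(
    pes: ToyPES,
    start: Geometry,
    n: int,
    T_eff: float,
    seed: int = 0,
    dt: float = 0.5,
    friction: float = 0.01,
    stride: int = 40,
    burnin: int = 500,
) -> list[Geometry]:
    """Langevin sampling on the analytic toy PES.

    ``T_eff`` is an effective temperature in Kelvin-equivalent units of
    the toy surface (the toys are floppier than real molecules, so these
    temperatures are not claimed physical).  BAOAB splitting, thinned
    every ``stride`` steps after ``burnin`` steps.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = pes.masses[:, None]
    x = start.coords.copy()
    kT = KB_MDUNIT_PER_K * T_eff
    v = rng.normal(size=x.shape) * np.sqrt(kT / m)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT / m)
    f = -pes.gradient(x) * MDUNIT_PER_HARTREE
    out = []
    step = 0
    while len(out) < n:
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        f = -pes.gradient(x) * MDUNIT_PER_HARTREE
        v += 0.5 * dt * f / m
        step += 1
        if step > burnin and step % stride == 0:
            out.append(Geometry(list(start.elements), x.copy()))
    return out
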