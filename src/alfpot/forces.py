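"""Analytic Cartesian forces from the molecular GP energy.

The force on atom A along global axis κ is the chain rule through each
atomic model's feature vector:

    F_{A,κ} = −Σ_models Σ_i ω_i (∂k_i/∂R) · (∂R/∂κ_A),

with ∂R/∂κ_A the B-matrix rows of the ALF features and the kernel
derivative w.r.t. the test features R^j

    ∂k/∂R_d^j = k · 2 θ_d (R_d^i − R_d^j)          (non-periodic d)
    ∂k/∂R_d^j = k · 0.5 θ_d sin(R_d^i − R_d^j)     (periodic d).

Because every feature is rotation/translation invariant, the resulting
force field carries zero net force and zero net torque.  Forces are
reported in Ha/Bohr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alf import periodic_mask
from .io import Geometry
from .units import BOHR_PER_ANGSTROM


@dataclass
class ForceField:
    forces: np.ndarray  # (N, 3) Ha/Bohr
    energy: float  # Ha
    max_force: float  # Ha/Bohr, largest component magnitude


def kernel_gradient(r_i, r_j, params, mask=None) -> np.ndarray:
    """∂k(R^i, R^j)/∂R^j for one training/test feature pair."""
    from .gpr import kernel as _kernel

    xi = np.atleast_1d(np.asarray(getattr(r_i, "values", r_i), float))
    xj = np.atleast_1d(np.asarray(getattr(r_j, "values", r_j), float))
    if xi.shape != xj.shape:
        raise ValueError("feature length mismatch")
    if mask is None:
        mask = getattr(r_i, "periodic_mask", None)
        if mask is None:
            mask = periodic_mask(xi.size)
    mask = np.asarray(mask, bool)
    k = _kernel(xi, xj, params, mask)
    delta = xi - xj
    grad = k * params.theta * 2.0 * delta
    grad[mask] = k * params.theta[mask] * 0.5 * np.sin(delta[mask])
    return grad


def forces(results, geometry: Geometry) -> ForceField:
    """Analytic forces of a fitted model at one geometry (Ha/Bohr)."""
    results._check_geometry(geometry)
    energy, grad_ang = results.energy_gradient(geometry.coords)
    f = -np.asarray(grad_ang) / BOHR_PER_ANGSTROM
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force prediction")
    return ForceField(f, float(energy), float(np.max(np.abs(f))))


def validate_forces(results, geometry: Geometry, h: float = 1e-5) -> float:
    """Max relative deviation between analytic forces and central finite
    differences of the energy (step ``h`` in Å).

    The differenced energies exclude the model's constant far-field
    offset (the aggregate prior mean) where the model supports it:
    a constant leaves the derivative unchanged but would dominate the
    floating-point budget at the ~1e2-Ha absolute energy scale.
    """
    if not (1e-7 <= h <= 1e-4):
        raise ValueError("finite-difference step h must lie in [1e-7, 1e-4] Å")
    ff = forces(results, geometry)
    try:
        def energy(c):
            return results.energy_gradient(c, include_mean=False)[0]

        energy(geometry.coords)
    except TypeError:  # plain providers (e.g. analytic toy surfaces)
        def energy(c):
            return results.energy_gradient(c)[0]

    n = geometry.n_atoms
    fd = np.empty((n, 3))
    coords = geometry.coords
    for a in range(n):
        for c in range(3):
            cp = coords.copy()
            cp[a, c] += h
            ep = energy(cp)
            cp[a, c] -= 2 * h
            em = energy(cp)
            fd[a, c] = -(ep - em) / (2 * h) / BOHR_PER_ANGSTROM
    scale = max(np.max(np.abs(fd)), 1e-30)
    return float(np.max(np.abs(fd - ff.forces)) / scale)
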