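"""Model deployment: molecular dynamics, stability scoring, geometry
optimization and structural analysis.

MD runs velocity-Verlet in Å / fs / amu with energies converted from
Hartree once at the boundary.  Thermostats: Nosé–Hoover (deterministic,
production) and Langevin/BAOAB (stochastic, sampling).  A run is
declared unstable the first time any bond of the reference connectivity
is stretched beyond 1.65× or compressed below 1/1.65× its equilibrium
length; the *stability* of a run is the simulated time until that
event (or the cap), and the *robustness* of a model is the mean
stability over repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alf import infer_connectivity
from .io import Geometry, Trajectory
from .sampler import superposed_rmsd
from .synthetic import dihedral_angle
from .units import (
    BOHR_PER_ANGSTROM,
    KB_MDUNIT_PER_K,
    MDUNIT_PER_HARTREE,
)

BOND_RATIO_LIMIT = 1.65
DEFAULT_FMAX = 0.00045  # Ha/Bohr


# ---------------------------------------------------------------------------
# containers


@dataclass
class StabilityReport:
    bonds: list[tuple[int, int]]
    equilibrium_lengths: np.ndarray  # Å
    max_ratio: np.ndarray  # per step, max(b/b0, b0/b)
    crash_step: int | None
    crash_reason: str | None  # 'bond-ratio' | 'non-finite' | None
    dt: float  # fs
    steps_run: int

    @property
    def stability_time_ps(self) -> float:
        """τ: simulated time until instability, ps (cap if no crash)."""
        t = self.crash_step if self.crash_step is not None else self.steps_run
        return t * self.dt / 1000.0

    @property
    def crashed(self) -> bool:
        return self.crash_step is not None


@dataclass
class RobustnessScore:
    stabilities_ps: np.ndarray
    n_sim: int

    @property
    def mean_ps(self) -> float:
        return float(np.mean(self.stabilities_ps))


# ---------------------------------------------------------------------------
# helpers


def maxwell_boltzmann_velocities(masses, T, seed=0, zero_momentum=True):
    """Å/fs velocities at temperature T (K) with zero total momentum."""
    rng = np.random.default_rng(seed)
    m = np.asarray(masses, float)[:, None]
    v = rng.normal(size=(len(masses), 3)) * np.sqrt(KB_MDUNIT_PER_K * max(T, 0.0) / m)
    if zero_momentum:
        v -= (m * v).sum(axis=0) / m.sum()
    return v


def kinetic_energy_md(masses, v):
    return 0.5 * float((np.asarray(masses)[:, None] * v * v).sum())


def _bond_table(reference: Geometry):
    bonds = infer_connectivity(reference)
    b0 = np.array(
        [np.linalg.norm(reference.coords[i] - reference.coords[j]) for i, j in bonds]
    )
    return bonds, b0


# ---------------------------------------------------------------------------
# MD


def run_nvt(
    model,
    start: Geometry,
    T: float,
    steps: int,
    dt: float = 0.25,
    thermostat: str | None = "nose_hoover",
    seed: int = 0,
    reference: Geometry | None = None,
    friction: float = 0.01,
    tau_factor: float = 100.0,
    traj_stride: int | None = None,
    store_forces: bool = False,
    velocities: np.ndarray | None = None,
):
    """Propagate NVT (or NVE with ``thermostat=None``) dynamics.

    ``model`` is anything exposing ``energy_gradient(coords) ->
    (E [Ha], dE/dx [Ha/Å])`` — a fitted :class:`MolecularGPRResults` or
    a :class:`ToyPES`.  Bond-stability is monitored every step against
    the connectivity and equilibrium lengths of ``reference`` (default:
    the start geometry); the run halts at the first violation.

    Returns (Trajectory, StabilityReport).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if thermostat not in (None, "none", "nose_hoover", "langevin"):
        raise ValueError(f"unknown thermostat {thermostat!r}")
    if thermostat == "none":
        thermostat = None

    reference = reference if reference is not None else start
    bonds, b0 = _bond_table(reference)
    bi = np.array([b[0] for b in bonds])
    bj = np.array([b[1] for b in bonds])

    masses = start.masses
    m = masses[:, None]
    ndof = 3 * start.n_atoms if thermostat == "langevin" else 3 * start.n_atoms - 3
    kT = KB_MDUNIT_PER_K * T

    x = start.coords.copy()
    if velocities is not None:
        v = np.array(velocities, float)
    else:
        v = maxwell_boltzmann_velocities(masses, T, seed=seed)
    rng = np.random.default_rng(seed + 1)

    # Nosé–Hoover single thermostat, coupling time tau_factor·dt
    Q = ndof * kT * (tau_factor * dt) ** 2 if kT > 0 else 1.0
    vxi = 0.0
    # Langevin OU coefficients
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0) * kT / m)

    if traj_stride is None:
        traj_stride = max(1, steps // 500)
    traj = Trajectory()

    def record(step, epot, f_ang):
        ek_md = kinetic_energy_md(masses, v)
        temp = 2.0 * ek_md / (ndof * KB_MDUNIT_PER_K)
        traj.append(
            step,
            Geometry(list(start.elements), x.copy()),
            epot,
            ek_md / MDUNIT_PER_HARTREE,
            temp,
            (-f_ang / BOHR_PER_ANGSTROM) if store_forces else None,
        )

    def nh_half():
        nonlocal v, vxi
        ek = kinetic_energy_md(masses, v)
        vxi += 0.25 * dt * (2.0 * ek - ndof * kT) / Q
        v = v * np.exp(-0.5 * dt * vxi)
        ek = kinetic_energy_md(masses, v)
        vxi += 0.25 * dt * (2.0 * ek - ndof * kT) / Q

    epot, grad = model.energy_gradient(x)
    f_md = -np.asarray(grad) * MDUNIT_PER_HARTREE
    max_ratio = np.empty(steps)
    crash_step = None
    crash_reason = None
    record(0, epot, np.asarray(grad))

    step = 0
    for step in range(1, steps + 1):
        if thermostat == "nose_hoover":
            nh_half()
        v = v + 0.5 * dt * f_md / m
        if thermostat == "langevin":
            x = x + 0.5 * dt * v
            v = c1 * v + c2 * rng.normal(size=v.shape)
            x = x + 0.5 * dt * v
        else:
            x = x + dt * v
        epot, grad = model.energy_gradient(x)
        if not (np.isfinite(epot) and np.all(np.isfinite(grad))):
            crash_step, crash_reason = step, "non-finite"
            max_ratio[step - 1 :] = np.inf
            break
        f_md = -np.asarray(grad) * MDUNIT_PER_HARTREE
        v = v + 0.5 * dt * f_md / m
        if thermostat == "nose_hoover":
            nh_half()

        blen = np.linalg.norm(x[bi] - x[bj], axis=1)
        ratio = np.maximum(blen / b0, b0 / blen)
        max_ratio[step - 1] = ratio.max()
        if step % traj_stride == 0:
            record(step, epot, np.asarray(grad))
        if max_ratio[step - 1] > BOND_RATIO_LIMIT:
            crash_step, crash_reason = step, "bond-ratio"
            break

    steps_run = step if steps > 0 else 0
    report = StabilityReport(
        bonds, b0, max_ratio[:steps_run].copy(), crash_step, crash_reason, dt, steps_run
    )
    return traj, report


def run_nve(model, start, T, steps, dt=0.25, seed=0, **kw):
    """Microcanonical run (thermostat off); T only sets initial velocities."""
    return run_nvt(model, start, T, steps, dt=dt, thermostat=None, seed=seed, **kw)


def robustness(
    model,
    starts,
    T: float,
    cap_ps: float = 1000.0,
    dt: float = 0.25,
    seeds=None,
    thermostat: str = "nose_hoover",
    reference: Geometry | None = None,
) -> RobustnessScore:
    """Mean stability time over one run per start geometry (ps)."""
    starts = list(starts)
    if not starts:
        raise ValueError("need at least one start geometry")
    if seeds is None:
        seeds = list(range(len(starts)))
    steps = int(round(cap_ps * 1000.0 / dt))
    taus = []
    for g, s in zip(starts, seeds):
        _, rep = run_nvt(
            model, g, T, steps, dt=dt, thermostat=thermostat, seed=s,
            reference=reference,
        )
        taus.append(rep.stability_time_ps)
    return RobustnessScore(np.asarray(taus), len(starts))


# ---------------------------------------------------------------------------
# geometry optimization


@dataclass
class OptimizationResult:
    geometry: Geometry
    energy_trace: list[float] = field(default_factory=list)  # Ha
    max_force_trace: list[float] = field(default_factory=list)  # Ha/Bohr
    converged: bool = False
    n_steps: int = 0

    @property
    def final_max_force(self) -> float:
        return self.max_force_trace[-1] if self.max_force_trace else np.nan


def bfgs_optimize(
    model, start: Geometry, fmax: float = DEFAULT_FMAX, max_steps: int = 1000
) -> OptimizationResult:
    """BFGS minimization until the largest force component ≤ ``fmax``
    (Ha/Bohr) or ``max_steps`` iterations."""
    shape = start.coords.shape

    def fun(xflat):
        e, g = model.energy_gradient(xflat.reshape(shape))
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during optimization")
        return e, np.asarray(g).reshape(-1)

    gtol_ang = fmax * BOHR_PER_ANGSTROM  # Ha/Å equivalent of fmax
    trace_e, trace_f = [], []

    e0, g0 = fun(start.coords.reshape(-1))
    trace_e.append(e0)
    trace_f.append(np.max(np.abs(g0)) / BOHR_PER_ANGSTROM)
    if trace_f[-1] <= fmax:
        return OptimizationResult(start.copy(), trace_e, trace_f, True, 0)

    def cb(xk):
        e, g = fun(xk)
        trace_e.append(e)
        trace_f.append(np.max(np.abs(g)) / BOHR_PER_ANGSTROM)

    res = minimize(
        fun, start.coords.reshape(-1), jac=True, method="BFGS",
        options={"gtol": gtol_ang, "maxiter": max_steps, "norm": np.inf},
        callback=cb,
    )
    x = res.x
    # polish with a second start if the line search stalled short of fmax
    tries = 0
    while trace_f[-1] > fmax and tries < 3 and len(trace_e) < max_steps:
        res = minimize(
            fun, x, jac=True, method="BFGS",
            options={"gtol": gtol_ang, "maxiter": max_steps - len(trace_e),
                     "norm": np.inf},
            callback=cb,
        )
        x = res.x
        tries += 1
    e, g = fun(x)
    trace_e.append(e)
    trace_f.append(np.max(np.abs(g)) / BOHR_PER_ANGSTROM)
    geom = Geometry(list(start.elements), x.reshape(shape), start.tag)
    return OptimizationResult(
        geom, trace_e, trace_f, bool(trace_f[-1] <= fmax), len(trace_e) - 1
    )


def perturb_geometry(g: Geometry, max_disp: float = 0.25, seed: int = 0) -> Geometry:
    """Uniform random Cartesian displacements in [−max_disp, +max_disp] Å."""
    rng = np.random.default_rng(seed)
    disp = rng.uniform(-max_disp, max_disp, size=g.coords.shape)
    return Geometry(list(g.elements), g.coords + disp, g.tag)


# ---------------------------------------------------------------------------
# structural analysis


@dataclass
class StructuralMetrics:
    rmsd: float  # Å, after optimal superposition
    dihedrals_a: list[float]  # degrees, (−180, 180]
    dihedrals_b: list[float]


def structural_metrics(a: Geometry, b: Geometry, dihedral_specs=()) -> StructuralMetrics:
    """Superposition RMSD plus signed dihedrals (degrees) of both
    geometries for each (i, j, k, l) spec."""
    if a.elements != b.elements:
        raise ValueError("element lists differ")

    def dihedrals(g):
        out = []
        for (i, j, k, l) in dihedral_specs:
            deg = np.degrees(dihedral_angle(g.coords, i, j, k, l))
            if deg <= -180.0:
                deg += 360.0
            out.append(float(deg))
        return out

    return StructuralMetrics(
        superposed_rmsd(a.coords, b.coords), dihedrals(a), dihedrals(b)
    )
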