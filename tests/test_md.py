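import numpy as np
import pytest

from alfpot import (
    Geometry,
    bfgs_optimize,
    make_toy,
    perturb_geometry,
    robustness,
    run_nve,
    run_nvt,
    structural_metrics,
)
from alfpot.md import RobustnessScore, maxwell_boltzmann_velocities


class _ZeroForce:
    """Mock force provider: free flight."""

    def energy_gradient(self, coords):
        return 0.0, np.zeros_like(coords)


def test_mock_linear_stretch_crashes_at_one_ps():
    # a C-C bond grows linearly, crossing the 1.65 ratio between steps
    # 3999 and 4000 -> crash at step 4000, tau = 4000 * 0.25 fs = 1.0 ps
    g = Geometry(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    rate = 0.65 / 3999.5  # relative bond growth per step
    v = np.array([[0.0, 0, 0], [1.5 * rate / 0.25, 0, 0]])
    _, rep = run_nvt(
        _ZeroForce(), g, T=0.0, steps=10000, dt=0.25, thermostat=None, velocities=v
    )
    assert rep.crash_step == 4000
    assert rep.crash_reason == "bond-ratio"
    assert np.isclose(rep.stability_time_ps, 1.0)


def test_zero_step_run():
    g = Geometry(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    _, rep = run_nvt(_ZeroForce(), g, T=0.0, steps=0, thermostat=None)
    assert rep.steps_run == 0 and not rep.crashed
    assert rep.stability_time_ps == 0.0


class _NaNForce:
    def __init__(self, bad_after):
        self.calls, self.bad_after = 0, bad_after

    def energy_gradient(self, coords):
        self.calls += 1
        if self.calls > self.bad_after:
            return np.nan, np.full_like(coords, np.nan)
        return 0.0, np.zeros_like(coords)


def test_nonfinite_force_counts_as_crash():
    g = Geometry(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    _, rep = run_nvt(_NaNForce(5), g, T=0.0, steps=100, thermostat=None,
                     velocities=np.zeros((2, 3)))
    assert rep.crashed and rep.crash_reason == "non-finite"


def test_nve_energy_conservation_toy_pes(chain5):
    g0, pes = chain5
    traj, rep = run_nve(pes, g0, T=300, steps=8000, dt=0.25, seed=4)
    assert not rep.crashed
    etot = np.array(traj.potential_energies) + np.array(traj.kinetic_energies)
    assert etot.max() - etot.min() < 1e-4


def test_nvt_mean_temperature_toy_pes(chain5):
    g0, pes = chain5
    traj, rep = run_nvt(pes, g0, T=300, steps=80000, dt=0.25, seed=5)
    assert not rep.crashed
    T = np.array(traj.temperatures)
    mean_T = T[len(T) // 5 :].mean()  # discard equilibration
    assert abs(mean_T - 300) / 300 < 0.05


def test_langevin_thermostat_mean_temperature(chain5):
    g0, pes = chain5
    traj, rep = run_nvt(pes, g0, T=300, steps=60000, dt=0.25, seed=6,
                        thermostat="langevin")
    T = np.array(traj.temperatures)
    assert abs(T[len(T) // 5 :].mean() - 300) / 300 < 0.08


def test_crash_step_matches_brute_force_scan(chain5):
    # store every frame and re-derive the first violating step offline
    g0, pes = chain5
    hot = Geometry(list(g0.elements), g0.coords * 1.25)  # strained start
    traj, rep = run_nvt(pes, hot, T=2500, steps=4000, dt=0.25, seed=7,
                        thermostat=None, reference=g0, traj_stride=1)
    if rep.crashed:
        bonds, b0 = rep.bonds, rep.equilibrium_lengths
        first = None
        for k, g in enumerate(traj.frames):
            if traj.steps[k] == 0:
                continue
            bl = np.array(
                [np.linalg.norm(g.coords[i] - g.coords[j]) for i, j in bonds]
            )
            if np.max(np.maximum(bl / b0, b0 / bl)) > 1.65:
                first = traj.steps[k]
                break
        assert first == rep.crash_step


def test_robustness_mean_arithmetic():
    s = RobustnessScore(np.array([1000.0, 1000.0, 500.0]), 3)
    assert np.isclose(s.mean_ps, 833.3333333333334)


def test_robustness_all_survive_equals_cap(chain5):
    g0, pes = chain5
    R = robustness(pes, [g0, g0], T=200, cap_ps=0.5, seeds=[1, 2], reference=g0)
    assert R.mean_ps == 0.5 and R.n_sim == 2


def test_maxwell_boltzmann_zero_momentum(rng):
    m = np.array([12.0, 1.0, 16.0])
    v = maxwell_boltzmann_velocities(m, 300, seed=3)
    assert np.allclose((m[:, None] * v).sum(axis=0), 0.0, atol=1e-12)


def test_perturb_geometry_properties(chain5):
    g0, _ = chain5
    assert np.array_equal(perturb_geometry(g0, 0.0, seed=1).coords, g0.coords)
    p1 = perturb_geometry(g0, 0.25, seed=9)
    p2 = perturb_geometry(g0, 0.25, seed=9)
    assert np.array_equal(p1.coords, p2.coords)
    assert np.max(np.abs(p1.coords - g0.coords)) <= 0.25


def test_bfgs_already_converged(chain5):
    g0, pes = chain5
    opt = bfgs_optimize(pes, g0, fmax=0.1)
    assert opt.converged and opt.n_steps == 0
    assert np.array_equal(opt.geometry.coords, g0.coords)


def test_bfgs_reaches_toy_minimum(chain5):
    from alfpot import rmsd

    g0, pes = chain5
    start = perturb_geometry(g0, 0.2, seed=11)
    opt = bfgs_optimize(pes, start, fmax=0.00045)
    assert opt.converged
    assert opt.max_force_trace[-1] <= 0.00045
    assert rmsd(opt.geometry, g0) < 0.05


def test_structural_metrics_identity_and_rotation(chain5, rng):
    from scipy.spatial.transform import Rotation

    g0, _ = chain5
    m = structural_metrics(g0, g0)
    assert m.rmsd < 1e-12
    R = Rotation.random(rng=rng).as_matrix()
    g2 = Geometry(list(g0.elements), g0.coords @ R.T + 3.0)
    assert structural_metrics(g0, g2).rmsd < 1e-10


def test_dihedral_cis_trans():
    cis = Geometry(
        ["C", "C", "C", "C"],
        [[1.0, 0, 0], [0, 0, 0], [0, 0, 1.5], [1.0, 0, 1.5]],
    )
    trans = Geometry(
        ["C", "C", "C", "C"],
        [[1.0, 0, 0], [0, 0, 0], [0, 0, 1.5], [-1.0, 0, 1.5]],
    )
    m = structural_metrics(cis, trans, dihedral_specs=[(0, 1, 2, 3)])
    assert np.isclose(m.dihedrals_a[0], 0.0, atol=1e-10)
    assert np.isclose(abs(m.dihedrals_b[0]), 180.0, atol=1e-10)


def test_bad_thermostat_and_dt(chain5):
    g0, pes = chain5
    with pytest.raises(ValueError):
        run_nvt(pes, g0, T=300, steps=10, dt=-0.1)
    with pytest.raises(ValueError):
        run_nvt(pes, g0, T=300, steps=10, thermostat="berendsen")
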