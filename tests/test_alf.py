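import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from alfpot import Geometry, build_alf, feature_jacobian, featurize, infer_connectivity
from alfpot.alf import ALFDefinition, DegenerateFrameError, featurize_all, periodic_mask


def test_connectivity_h2():
    g = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
    assert infer_connectivity(g) == [(0, 1)]


def test_connectivity_isolated_atom_error():
    g = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 10.0]])
    with pytest.raises(ValueError, match="atom 0"):
        infer_connectivity(g)


def test_connectivity_water():
    r = 0.96
    ang = np.radians(104.5)
    g = Geometry(
        ["O", "H", "H"],
        [[0, 0, 0], [r, 0, 0], [r * np.cos(ang), r * np.sin(ang), 0]],
    )
    assert sorted(infer_connectivity(g)) == [(0, 1), (0, 2)]


def test_alf_middle_atom_prefers_heavier_neighbour():
    # linear-ish O-C-H chain: for the middle C, x-axis atom is the O
    g = Geometry(["O", "C", "H"], [[0, 0, 0], [1.4, 0, 0], [2.1, 0.8, 0]])
    alf = build_alf(g)
    assert alf.x_axis[1] == 0 and alf.xy_plane[1] == 2


def test_alf_terminal_atom_uses_neighbours_neighbour():
    # 4-atom chain H3-C2-C1-O0: terminal O has the single neighbour C1,
    # whose other neighbours are {C2}; heavier-of-those = C2
    g0, _ = _chain4()
    alf = build_alf(g0)
    assert alf.x_axis[0] == 1
    assert alf.xy_plane[0] == 2


def _chain4():
    from alfpot import make_toy

    return make_toy("chain4")


def test_alf_invariant_under_rigid_motion(rng):
    g0, _ = _chain4()
    alf0 = build_alf(g0)
    for _ in range(10):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 5
        g = Geometry(list(g0.elements), g0.coords @ R.T + t)
        assert build_alf(g) == alf0


def test_featurize_three_atoms_no_periodic():
    from alfpot.units import BOHR_PER_ANGSTROM

    r = 0.96
    ang = np.radians(104.5)
    g = Geometry(
        ["O", "H", "H"],
        [[0, 0, 0], [r, 0, 0], [r * np.cos(ang), r * np.sin(ang), 0]],
    )
    fv = featurize(g, build_alf(g), 0)
    assert fv.values.shape == (3,)
    assert not fv.periodic_mask.any()
    # distances in Bohr, angles in radians
    assert np.isclose(fv.values[0], r * BOHR_PER_ANGSTROM)
    assert np.isclose(fv.values[2], ang)


def test_periodic_mask_predicate():
    # 1-based d with d > 3 and d mod 3 == 0 -> 0-based 5, 8, 11, ...
    assert list(np.where(periodic_mask(9))[0]) == [5, 8]
    assert list(np.where(periodic_mask(6))[0]) == [5]
    assert not periodic_mask(3).any()
    assert not periodic_mask(1).any()


def test_featurize_atom_on_local_x_axis():
    from alfpot.units import BOHR_PER_ANGSTROM

    # A=0 at origin, x-axis atom along +x, plane atom in xy: local frame is
    # the global frame; the remaining atom 2 Å out on +x must read
    # (2 Å in Bohr, pi/2, 0)
    g = Geometry(
        ["C", "C", "C", "C"],
        [[0, 0, 0], [1.5, 0, 0], [0, 1.4, 0], [2.0, 0, 0]],
    )
    alf = ALFDefinition((1, 0, 0, 0), (2, 2, 1, 1))
    fv = featurize(g, alf, 0)
    expected = [2.0 * BOHR_PER_ANGSTROM, np.pi / 2, 0.0]
    assert np.allclose(fv.values[3:6], expected, atol=1e-12)


def test_features_invariant_under_rigid_motions(chain5, rng):
    g0, _ = chain5
    alf = build_alf(g0)
    f0 = featurize_all(g0, alf)
    worst = 0.0
    for _ in range(100):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 10
        g = Geometry(list(g0.elements), g0.coords @ R.T + t)
        worst = max(worst, np.max(np.abs(featurize_all(g, alf) - f0)))
    assert worst < 1e-10


def test_degenerate_collinear_frame_raises():
    g = Geometry(
        ["C", "C", "C", "H"],
        [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [0, 0, 1.5]],
    )
    alf = ALFDefinition((1, 0, 1, 0), (2, 2, 0, 1))
    with pytest.raises(DegenerateFrameError):
        featurize(g, alf, 0)


def test_jacobian_d1_row_closed_form(chain5):
    from alfpot.units import BOHR_PER_ANGSTROM

    g0, _ = chain5
    alf = build_alf(g0)
    a = 2
    B = feature_jacobian(g0, alf, a)
    xi = alf.x_axis[a]
    u = g0.coords[xi] - g0.coords[a]
    u /= np.linalg.norm(u)
    # d1 is in Bohr, coordinates in Å: the unit bond vector scales by
    # the Bohr-per-Å factor, with opposite signs on the two atoms
    assert np.allclose(B[0, 3 * a : 3 * a + 3], -u * BOHR_PER_ANGSTROM, atol=1e-12)
    assert np.allclose(B[0, 3 * xi : 3 * xi + 3], u * BOHR_PER_ANGSTROM, atol=1e-12)


def test_jacobian_translation_invariance(chain5, rng):
    g0, _ = chain5
    g = Geometry(list(g0.elements), g0.coords + rng.normal(scale=0.05, size=(5, 3)))
    alf = build_alf(g0)
    for a in range(g.n_atoms):
        B = feature_jacobian(g, alf, a)
        per_axis = B.reshape(B.shape[0], -1, 3).sum(axis=1)
        assert np.max(np.abs(per_axis)) < 1e-10


def test_jacobian_matches_finite_differences(chain5, rng):
    g0, _ = chain5
    coords = g0.coords + rng.normal(scale=0.05, size=g0.coords.shape)
    g = Geometry(list(g0.elements), coords)
    alf = build_alf(g0)
    h = 1e-6
    for a in range(g.n_atoms):
        B = feature_jacobian(g, alf, a)
        for c in range(3 * g.n_atoms):
            cp = coords.reshape(-1).copy()
            cp[c] += h
            cm = coords.reshape(-1).copy()
            cm[c] -= h
            fp = featurize_all(Geometry(list(g.elements), cp.reshape(-1, 3)), alf)[a]
            fm = featurize_all(Geometry(list(g.elements), cm.reshape(-1, 3)), alf)[a]
            fd = (fp - fm) / (2 * h)
            assert np.max(np.abs(fd - B[:, c])) < 1e-7


def test_diatomic_degenerate_mode():
    from alfpot.units import BOHR_PER_ANGSTROM

    g = Geometry(["C", "H"], [[0, 0, 0], [1.0, 0, 0]])
    alf = build_alf(g)
    assert alf.diatomic
    fv = featurize(g, alf, 0)
    assert fv.values.shape == (1,)
    assert np.isclose(fv.values[0], BOHR_PER_ANGSTROM)
    B = feature_jacobian(g, alf, 0)
    assert np.allclose(B, np.array([[-1, 0, 0, 1, 0, 0]]) * BOHR_PER_ANGSTROM)
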