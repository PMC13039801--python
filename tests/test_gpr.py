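import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alfpot import (
    Geometry,
    KernelParams,
    MolecularGPR,
    compute_mean,
    kernel,
    label_configs,
    make_toy,
)
from alfpot.gpr import MEAN_KINDS, default_sigma_f, fit_weights, kernel_matrix
from alfpot.alf import periodic_mask


# ---------------------------------------------------------------------------
# mean functions


def test_mean_function_worked_example():
    e = [-1.0, 0.0, 1.0]
    vals = {k: compute_mean(k, e).value for k in MEAN_KINDS}
    assert vals["MF1"] == 0.0
    assert np.isclose(vals["MF2"], np.sqrt(2.0 / 3.0))  # population sigma
    assert vals["MF3"] == 1.0
    assert vals["MF4"] == 3.0  # max + range
    assert vals["MF5"] == 11.0  # max + 5*range
    assert vals["MIN"] == -1.0


@pytest.mark.parametrize("energies", [[0.5, 0.5, 0.5], [0.5]])
def test_mean_function_zero_spread_collapse(energies):
    assert all(compute_mean(k, energies).value == 0.5 for k in MEAN_KINDS)


def test_mean_function_errors():
    with pytest.raises(ValueError, match="empty"):
        compute_mean("MF1", [])
    with pytest.raises(ValueError, match="unknown"):
        compute_mean("MF9", [1.0])


@settings(deadline=None, max_examples=200)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
def test_mean_function_ordering(e):
    tol = 1e-12 * max(1.0, float(np.max(np.abs(e))))

    def le(a, b):  # tolerate rounding at the scale of the inputs
        return a <= b + tol

    v = {k: compute_mean(k, e).value for k in MEAN_KINDS}
    assert le(v["MIN"], v["MF1"])
    assert le(v["MF1"], v["MF3"])
    assert le(v["MF3"], v["MF4"])
    assert le(v["MF4"], v["MF5"])
    e = np.asarray(e)
    if e.std() <= e.max() - e.mean():
        assert le(v["MF2"], v["MF3"])


# ---------------------------------------------------------------------------
# kernel


def test_kernel_identity_equals_prefactor(rng):
    x = rng.normal(size=9)
    p = KernelParams(rng.uniform(0, 1, 9), sigma_f=3.7, sigma_n2=1e-8)
    assert np.isclose(kernel(x, x, p), 3.7)


def test_kernel_periodic_hand_value():
    # six features, theta=0.5, sigma_f=1; vectors differ only at the
    # periodic d=6 by pi: phi = sin^2(pi/2) = 1 -> k = exp(-0.5)
    xi = np.zeros(6)
    xj = np.zeros(6)
    xj[5] = np.pi
    p = KernelParams(np.full(6, 0.5), 1.0, 1e-8)
    assert np.isclose(kernel(xi, xj, p), np.exp(-0.5))
    assert np.isclose(kernel(xi, xj, p), 0.606531, atol=1e-6)


def test_kernel_periodic_2pi_shift_is_identity():
    xi = np.zeros(6)
    xj = np.zeros(6)
    xj[5] = 2 * np.pi
    p = KernelParams(np.full(6, 0.5), 2.5, 1e-8)
    assert np.isclose(kernel(xi, xj, p), 2.5)


def test_kernel_length_mismatch():
    p = KernelParams(np.ones(3), 1.0, 1e-8)
    with pytest.raises(ValueError, match="mismatch"):
        kernel(np.zeros(3), np.zeros(4), p)


def test_kernel_symmetry_random_pairs(rng):
    p = KernelParams(rng.uniform(0, 1, 9), 2.0, 1e-8)
    for _ in range(20):
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert np.isclose(kernel(a, b, p), kernel(b, a, p), rtol=0, atol=1e-15)


# ---------------------------------------------------------------------------
# weight fitting


def test_fit_weights_zero_rhs():
    X = np.array([[0.0], [1.0], [2.0]])
    K = kernel_matrix(X, X, np.array([0.5]), 1.0, periodic_mask(1))
    w = fit_weights(K, np.full(3, 0.25), 0.25, 1e-8)
    assert np.allclose(w, 0.0)


def test_fit_weights_2x2_closed_form():
    # one feature, two points: K = [[sf, b], [b, sf]] with
    # b = sf*exp(-theta); closed-form inverse checked to 1e-12
    sf, theta, sn2, m = 2.0, 0.5, 1e-3, 0.1
    X = np.array([[0.0], [1.0]])
    y = np.array([0.3, 0.7])
    K = kernel_matrix(X, X, np.array([theta]), sf, periodic_mask(1))
    w = fit_weights(K, y, m, sn2)
    a = sf + sn2
    b = sf * np.exp(-theta)
    det = a * a - b * b
    Minv = np.array([[a, -b], [-b, a]]) / det
    assert np.allclose(w, Minv @ (y - m), atol=1e-12)


# ---------------------------------------------------------------------------
# model + results


def test_interpolation_at_training_points(chain5_data):
    model = MolecularGPR(chain5_data[:50], mean_function="MF1")
    res = model.fit(sigma_n2=1e-10)
    for cfg in chain5_data[:10]:
        pred = res.predict_atomic(cfg.geometry)
        from alfpot import correct_energies

        target = correct_energies(cfg).corrected_atomic_energies
        assert np.max(np.abs(pred - target)) < 1e-6


def test_molecular_equals_sum_of_atomic(chain5_fit, chain5_data):
    g = chain5_data[130].geometry
    assert np.isclose(
        chain5_fit.predict(g), chain5_fit.predict_atomic(g).sum(), atol=1e-12
    )


def test_far_field_reverts_to_prior_mean():
    g0, pes = make_toy("diatomic")
    rs = np.linspace(0.8, 1.2, 30)
    geoms = [
        Geometry(["C", "H"], [[0, 0, 0], [r, 0, 0]]) for r in rs
    ]
    cfgs = label_configs(pes, geoms, noise_sd=0.0, seed=0)
    for kind in MEAN_KINDS:
        res = MolecularGPR(cfgs, mean_function=kind).fit(sigma_n2=1e-10)
        far = Geometry(["C", "H"], [[0, 0, 0], [11.2, 0, 0]])
        pred = res.predict_atomic(far)
        means = np.array([m.mean.value for m in res.atomic_models])
        assert np.max(np.abs(pred - means)) < 1e-8


def test_zero_weights_predict_mean(chain5_fit, chain5_data):
    import copy

    res = copy.deepcopy(chain5_fit)
    for m in res.atomic_models:
        m.weights = np.zeros_like(m.weights)
    res._packed_cache = None
    g = chain5_data[140].geometry
    assert np.isclose(res.predict(g), res.aggregate_mean, atol=1e-12)


def test_element_mismatch_rejected(chain5_fit):
    g = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
    with pytest.raises(ValueError, match="element"):
        chain5_fit.predict(g)


def test_default_sigma_f_formula():
    assert default_sigma_f(400, 9) == np.sqrt(3600)


def test_summary_mentions_mean_function(chain5_fit):
    s = chain5_fit.summary()
    assert "MF5" in s and "m_A" in s
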