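"""Jit-compiled numerical core.

Everything here is written as plain loops over small fixed-size arrays
so that numba can compile it; the same source runs (slowly) without
numba, which keeps the package importable everywhere.

Feature layout per atom A (3N−6 values):
    0: d1   distance A – x-axis atom
    1: d2   distance A – xy-plane atom
    2: d3   valence angle (x-axis – A – xy-plane), radians
    then for every remaining atom n in ascending global index:
    (r, θ, φ) spherical coordinates of n in A's right-handed local frame.
φ is the azimuthal angle and is periodic; it sits at 1-based feature
indices d with d > 3 and d mod 3 = 0.

The Jacobian (B-matrix) rows are exact analytic derivatives of each
feature with respect to all 3N global Cartesian coordinates (Å⁻¹-free
units: feature-unit per Å).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


DEGENERATE_TOL = 1e-8  # rad; collinear-frame threshold


@njit(cache=True)
def _frame_with_jac(a, x, p):
    """Local right-handed axes at atom position ``a`` plus their Jacobians.

    Returns e1, e2, e3 (3,) and Je1, Je2, Je3 of shape (3, 9); Jacobian
    columns are the perturbations of (a, x, p) concatenated.
    """
    I3 = np.eye(3)

    u = x - a
    r1 = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    e1 = u / r1
    Ju = np.zeros((3, 9))
    for i in range(3):
        Ju[i, i] = -1.0
        Ju[i, 3 + i] = 1.0
    P1 = I3 - np.outer(e1, e1)
    Je1 = (P1 / r1) @ Ju

    v = p - a
    r2 = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    Jv = np.zeros((3, 9))
    for i in range(3):
        Jv[i, i] = -1.0
        Jv[i, 6 + i] = 1.0

    t = v[0] * e1[0] + v[1] * e1[1] + v[2] * e1[2]
    Jt = e1 @ Jv + v @ Je1  # (9,)
    w = v - t * e1
    Jw = Jv - np.outer(e1, Jt) - t * Je1
    nw = np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
    if nw < DEGENERATE_TOL * r2:
        raise ValueError(
            "degenerate atomic local frame: x-axis and xy-plane atoms are "
            "collinear with the origin atom"
        )
    e2 = w / nw
    Je2 = ((I3 - np.outer(e2, e2)) / nw) @ Jw

    e3 = np.empty(3)
    e3[0] = e1[1] * e2[2] - e1[2] * e2[1]
    e3[1] = e1[2] * e2[0] - e1[0] * e2[2]
    e3[2] = e1[0] * e2[1] - e1[1] * e2[0]
    # d(e1×e2) = −[e2]× de1 + [e1]× de2
    C1 = np.zeros((3, 3))
    C1[0, 1] = -e1[2]
    C1[0, 2] = e1[1]
    C1[1, 0] = e1[2]
    C1[1, 2] = -e1[0]
    C1[2, 0] = -e1[1]
    C1[2, 1] = e1[0]
    C2 = np.zeros((3, 3))
    C2[0, 1] = -e2[2]
    C2[0, 2] = e2[1]
    C2[1, 0] = e2[2]
    C2[1, 2] = -e2[0]
    C2[2, 0] = -e2[1]
    C2[2, 1] = e2[0]
    Je3 = -C2 @ Je1 + C1 @ Je2

    return e1, e2, e3, Je1, Je2, Je3


@njit(cache=True)
def _atom_features_jac(coords, ai, xi, pi, others, feats, Brow):
    """Fill ``feats`` (F,) and ``Brow`` (F, 3N) for one atom model."""
    a = coords[ai]
    x = coords[xi]
    p = coords[pi]
    e1, e2, e3, Je1, Je2, Je3 = _frame_with_jac(a, x, p)

    # column offsets of the 9 frame columns in the global 3N layout
    cols9 = np.empty(9, np.int64)
    for c in range(3):
        cols9[c] = 3 * ai + c
        cols9[3 + c] = 3 * xi + c
        cols9[6 + c] = 3 * pi + c

    u = x - a
    v = p - a
    r1 = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    r2 = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    uh = u / r1
    vh = v / r2

    # f0: distance to x-axis atom
    feats[0] = r1
    for c in range(3):
        Brow[0, 3 * ai + c] = -uh[c]
        Brow[0, 3 * xi + c] = uh[c]

    # f1: distance to xy-plane atom
    feats[1] = r2
    for c in range(3):
        Brow[1, 3 * ai + c] = -vh[c]
        Brow[1, 3 * pi + c] = vh[c]

    # f2: valence angle at A
    cosang = uh[0] * vh[0] + uh[1] * vh[1] + uh[2] * vh[2]
    if cosang > 1.0:
        cosang = 1.0
    if cosang < -1.0:
        cosang = -1.0
    ang = np.arccos(cosang)
    sinang = np.sin(ang)
    if sinang < DEGENERATE_TOL:
        raise ValueError(
            "degenerate atomic local frame: frame atoms are collinear "
            "(valence angle within tolerance of 0 or pi)"
        )
    feats[2] = ang
    # dθ/dx = (cosθ·uh − vh)/(r1 sinθ) ; dθ/dp = (cosθ·vh − uh)/(r2 sinθ)
    for c in range(3):
        gx = (cosang * uh[c] - vh[c]) / (r1 * sinang)
        gp = (cosang * vh[c] - uh[c]) / (r2 * sinang)
        Brow[2, 3 * xi + c] += gx
        Brow[2, 3 * pi + c] += gp
        Brow[2, 3 * ai + c] += -(gx + gp)

    # remaining atoms: spherical coordinates in the local frame
    for t in range(others.shape[0]):
        ni = others[t]
        n = coords[ni]
        s = n - a
        r = np.sqrt(s[0] ** 2 + s[1] ** 2 + s[2] ** 2)
        sh = s / r
        sx = e1[0] * s[0] + e1[1] * s[1] + e1[2] * s[2]
        sy = e2[0] * s[0] + e2[1] * s[1] + e2[2] * s[2]
        sz = e3[0] * s[0] + e3[1] * s[1] + e3[2] * s[2]

        row_r = 3 + 3 * t
        row_t = 4 + 3 * t
        row_p = 5 + 3 * t

        # r
        feats[row_r] = r
        for c in range(3):
            Brow[row_r, 3 * ai + c] = -sh[c]
            Brow[row_r, 3 * ni + c] = sh[c]

        # gradients of local components sx, sy, sz
        # d(sα) = s·(Jeα dq9) + eα·(dn − da)
        Jsx = s @ Je1
        Jsy = s @ Je2
        Jsz = s @ Je3

        # θ = acos(sz / r)
        czr = sz / r
        if czr > 1.0:
            czr = 1.0
        if czr < -1.0:
            czr = -1.0
        theta = np.arccos(czr)
        st = np.sin(theta)
        if st < 1e-10:
            st = 1e-10  # clamp at the polar singularity
        feats[row_t] = theta

        # φ = atan2(sy, sx)
        feats[row_p] = np.arctan2(sy, sx)
        rho2 = sx * sx + sy * sy
        if rho2 < 1e-20:
            rho2 = 1e-20

        # assemble gradient contributions
        # frame-atom part (columns cols9) through Je1/Je2/Je3
        for q in range(9):
            gsx = Jsx[q]
            gsy = Jsy[q]
            gsz = Jsz[q]
            gr = 0.0  # r does not depend on frame axes
            gtheta = -(gsz / r - czr * gr / r) / st
            gphi = (sx * gsy - sy * gsx) / rho2
            Brow[row_t, cols9[q]] += gtheta
            Brow[row_p, cols9[q]] += gphi
        # direct dependence through s = n − a
        for c in range(3):
            # d s = dn − da  → handle both with sign
            for sign_i in range(2):
                if sign_i == 0:
                    col = 3 * ni + c
                    sgn = 1.0
                else:
                    col = 3 * ai + c
                    sgn = -1.0
                gsx = sgn * e1[c]
                gsy = sgn * e2[c]
                gsz = sgn * e3[c]
                gr = sgn * sh[c]
                gtheta = -(gsz / r - czr * gr / r) / st
                gphi = (sx * gsy - sy * gsx) / rho2
                Brow[row_t, col] += gtheta
                Brow[row_p, col] += gphi


@njit(cache=True)
def features_and_jacobian_all(coords, alf_x, alf_p, others):
    """Features (N, F) and B-matrices (N, F, 3N) for every atom model."""
    N = coords.shape[0]
    F = 3 * N - 6
    feats = np.zeros((N, F))
    B = np.zeros((N, F, 3 * N))
    for a in range(N):
        _atom_features_jac(coords, a, alf_x[a], alf_p[a], others[a], feats[a], B[a])
    return feats, B


@njit(cache=True)
def features_and_jacobian_single(coords, ai, xi, pi, others_row):
    """Features (F,) and B-matrix (F, 3N) for one atom model only."""
    N = coords.shape[0]
    F = 3 * N - 6
    feats = np.zeros(F)
    B = np.zeros((F, 3 * N))
    _atom_features_jac(coords, ai, xi, pi, others_row, feats, B)
    return feats, B


@njit(cache=True)
def diatomic_features_and_jacobian(coords):
    """Distance-only degenerate mode for N = 2 (one feature per atom)."""
    feats = np.zeros((2, 1))
    B = np.zeros((2, 1, 6))
    d = coords[1] - coords[0]
    r = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    dh = d / r
    for a in range(2):
        feats[a, 0] = r
        for c in range(3):
            B[a, 0, c] = -dh[c]
            B[a, 0, 3 + c] = dh[c]
    return feats, B


@njit(cache=True)
def _is_periodic(d, F):
    """0-based feature index predicate for azimuthal (periodic) features."""
    if F == 1:
        return False
    return d > 2 and (d + 1) % 3 == 0


@njit(cache=True)
def gp_energy_gradient(
    coords, alf_x, alf_p, others, Xtr, W, theta, sigf, mean_total, diatomic
):
    """Molecular GP energy (Ha) and Cartesian gradient dE/dx (Ha/Å).

    Xtr: (N, Ntr, F) training features; W: (N, Ntr) regression weights;
    theta: (N, F) kernel parameters; sigf: (N,) kernel pre-factors.
    """
    N = coords.shape[0]
    if diatomic:
        feats, B = diatomic_features_and_jacobian(coords)
    else:
        feats, B = features_and_jacobian_all(coords, alf_x, alf_p, others)
    F = feats.shape[1]
    Ntr = Xtr.shape[1]
    energy = mean_total
    comp = 0.0  # Kahan compensation: wk terms can exceed the sum by ~1e4
    grad = np.zeros(3 * N)
    dEdf = np.empty(F)
    for a in range(N):
        fa = feats[a]
        th = theta[a]
        for d in range(F):
            dEdf[d] = 0.0
        for i in range(Ntr):
            phi = 0.0
            for d in range(F):
                delta = Xtr[a, i, d] - fa[d]
                if _is_periodic(d, F):
                    sd = np.sin(0.5 * delta)
                    phi += th[d] * sd * sd
                else:
                    phi += th[d] * delta * delta
            k = sigf[a] * np.exp(-phi)
            wk = W[a, i] * k
            y = wk - comp
            t = energy + y
            comp = (t - energy) - y
            energy = t
            for d in range(F):
                delta = Xtr[a, i, d] - fa[d]
                if _is_periodic(d, F):
                    dEdf[d] += wk * th[d] * 0.5 * np.sin(delta)
                else:
                    dEdf[d] += wk * th[d] * 2.0 * delta
        # chain rule through the B-matrix
        for d in range(F):
            g = dEdf[d]
            if g != 0.0:
                for c in range(3 * N):
                    grad[c] += g * B[a, d, c]
    return energy, grad.reshape(N, 3)
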